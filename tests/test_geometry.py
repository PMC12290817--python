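"""Object-distance matrices, automorphism averaging and MDS embedding."""

import numpy as np
import pandas as pd
import pytest

from commrsa.geometry import (
    internal_linking_summary,
    mds_embed,
    object_distance_matrix,
    permutation_average,
)
from commrsa.graphs import automorphism_group, classify_pairs


@pytest.fixture(scope="module")
def perms(modular):
    return automorphism_group(modular)


def _random_symmetric(rng):
    M = rng.uniform(1.0, 2.0, size=(15, 15))
    M = (M + M.T) / 2
    np.fill_diagonal(M, 0.0)
    return M


class TestObjectDistanceMatrix:
    def test_constant_distances_give_constant_matrix(self):
        rows = []
        for i in range(15):
            for j in range(i + 1, 15):
                rows.append(
                    {"observer_id": 0, "parcel_id": 0, "run_id": 0, "k": 0,
                     "l": 1, "obj_i": i, "obj_j": j, "latency": 3,
                     "raw_d": 1.4, "corrected_d": 1.4}
                )
        M = object_distance_matrix(pd.DataFrame(rows))
        off = M[~np.eye(15, dtype=bool)]
        assert np.allclose(off, 1.4)
        assert np.allclose(np.diag(M), 0.0)

    def test_symmetric_and_run_averaged(self, projected_null):
        _, _, dset = projected_null
        M = object_distance_matrix(dset)
        assert np.allclose(M, M.T, equal_nan=True)
        assert np.allclose(np.diag(M), 0.0)
        # all pairs observed somewhere in 6 runs
        assert np.isfinite(M[~np.eye(15, dtype=bool)]).all()

    def test_positive_beta_within_smaller(self, small_study):
        from commrsa.analysis import parcel_distances

        dset = parcel_distances(small_study.responses[(0, 1)])
        M = object_distance_matrix(dset)
        same = small_study.graph.same_community_matrix()
        off = ~np.eye(15, dtype=bool)
        assert M[same & off].mean() < M[~same].mean()


class TestPermutationAverage:
    def test_exact_average_is_projection(self, modular, perms):
        rng = np.random.default_rng(0)
        M = _random_symmetric(rng)
        A1 = permutation_average(M, perms=perms)
        A2 = permutation_average(A1, perms=perms)
        assert np.allclose(A1, A2, atol=1e-12)

    def test_invariant_under_any_automorphism(self, modular, perms):
        rng = np.random.default_rng(1)
        A = permutation_average(_random_symmetric(rng), perms=perms)
        for p in perms[::211]:
            assert np.allclose(A[np.ix_(p, p)], A, atol=1e-12)

    def test_grand_mean_preserved(self, modular, perms):
        rng = np.random.default_rng(2)
        M = _random_symmetric(rng)
        A = permutation_average(M, perms=perms)
        off = ~np.eye(15, dtype=bool)
        assert A[off].mean() == pytest.approx(M[off].mean(), rel=1e-12)

    def test_constant_matrix_unchanged(self, perms):
        M = np.full((15, 15), 1.3)
        np.fill_diagonal(M, 0.0)
        assert np.allclose(permutation_average(M, perms=perms), M)

    def test_sampled_mode_converges_to_exact(self, modular, perms):
        rng = np.random.default_rng(3)
        M = _random_symmetric(rng)
        exact = permutation_average(M, perms=perms)
        sampled = permutation_average(M, perms=perms, n_samples=10_000, seed=4)
        assert np.abs(sampled - exact).max() < 0.02

    def test_rejects_asymmetric(self, perms):
        M = np.zeros((15, 15))
        M[0, 1] = 1.0
        with pytest.raises(ValueError, match="symmetric"):
            permutation_average(M, perms=perms)


class TestMdsEmbed:
    def test_planar_configuration_recovered(self):
        """Distances that come from 15 points in the plane embed with ~zero
        stress and pairwise distances reproduced up to rigid motion."""
        rng = np.random.default_rng(5)
        pts = rng.standard_normal((15, 2))
        D = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        emb = mds_embed(D, seed=0, metric=True)
        D2 = np.linalg.norm(emb.coords[:, None] - emb.coords[None, :], axis=2)
        iu = np.triu_indices(15, 1)
        assert np.corrcoef(D[iu], D2[iu])[0, 1] > 0.999

    def test_stress_nonincreasing_with_dimension(self, modular, perms):
        rng = np.random.default_rng(6)
        M = permutation_average(_random_symmetric(rng), perms=perms)
        s2 = mds_embed(M, seed=0, n_components=2).stress
        s3 = mds_embed(M, seed=0, n_components=3).stress
        assert s3 <= s2 + 1e-6

    def test_averaged_matrix_threefold_symmetry(self, modular, perms, small_study):
        """After automorphism averaging, the three communities are exactly
        exchangeable, so their embedded centroids lie at equal distances from
        the map center."""
        from commrsa.analysis import parcel_distances

        dset = parcel_distances(small_study.responses[(0, 1)])
        M = permutation_average(object_distance_matrix(dset), perms=perms)
        emb = mds_embed(M, seed=1, graph=modular)
        comm = modular.community_index()
        center = emb.coords.mean(axis=0)
        radii = [
            np.linalg.norm(emb.coords[comm == c].mean(axis=0) - center)
            for c in range(3)
        ]
        assert np.ptp(radii) < 0.1 * (np.mean(radii) + 1e-9) + 0.05

    def test_degenerate_matrix_warns(self):
        M = np.full((15, 15), 1.0)
        np.fill_diagonal(M, 0.0)
        with pytest.warns(UserWarning, match="degenerate"):
            mds_embed(M, seed=0)


class TestInternalLinkingSummary:
    def test_constant_matrix_all_cells_equal(self, modular):
        M = np.full((15, 15), 2.0)
        np.fill_diagonal(M, 0.0)
        out = internal_linking_summary(M, modular)
        assert np.allclose(out["mean_d"], 2.0)

    def test_cell_counts_match_graph_combinatorics(self, modular):
        M = np.full((15, 15), 1.0)
        np.fill_diagonal(M, 0.0)
        out = internal_linking_summary(M, modular).set_index(
            ["role_pair", "relation"]
        )
        # linking-linking within community = the SN pairs
        assert out.loc[("linking-linking", "within"), "n_pairs"] == 3
        # internal-internal within: C(3,2)=3 per community
        assert out.loc[("internal-internal", "within"), "n_pairs"] == 9
        assert out["n_pairs"].sum() == 105

    def test_linking_attraction_detected(self, modular):
        """A matrix in which linking objects sit closer to each other shows
        up in the linking-linking cells."""
        rng = np.random.default_rng(7)
        M = _random_symmetric(rng)
        boundary = np.flatnonzero(modular.role_of == "boundary")
        for i in boundary:
            for j in boundary:
                if i != j:
                    M[i, j] -= 0.5
        out = internal_linking_summary(M, modular).set_index(
            ["role_pair", "relation"]
        )
        grand = M[~np.eye(15, dtype=bool)].mean()
        assert out.loc[("linking-linking", "within"), "mean_d"] < grand
        assert out.loc[("linking-linking", "between"), "mean_d"] < grand
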