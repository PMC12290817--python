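"""Representational geometry: object-distance matrices, automorphism
averaging and low-dimensional embedding.

Per (parcel, observer, run) the corrected pairwise distances are condensed to
a 15 x 15 object-distance matrix; run matrices are averaged per observer.
Different observers have no reason to share activity patterns, so their
matrices cannot be averaged entry-wise.  Instead each matrix is averaged over
the node permutations that preserve the modular graph's structure (adjacency
and community membership) — the 1296-element automorphism group — which
yields matrices in a common, structure-referenced frame that *can* be
averaged across observers.  The exact group average is used by default; the
Monte-Carlo variant (random samples from the group) is available for
fidelity checks.

The averaged matrix is embedded in the plane with nonmetric MDS; the
three-fold symmetry of the resulting maps is a consequence of the averaging,
not a property of the data.  A six-cell summary (internal/linking node roles
x within/between community) quantifies the same geometry without embedding.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.manifold import MDS

from .graphs import N_OBJECTS, CommunityGraph, automorphism_group

__all__ = [
    "EmbeddingMap",
    "object_distance_matrix",
    "permutation_average",
    "mds_embed",
    "internal_linking_summary",
    "automorphism_group",
]


@dataclass
class EmbeddingMap:
    """A 2-D MDS embedding of the 15 objects."""

    coords: np.ndarray          # (15, 2)
    stress: float
    communities: np.ndarray
    roles: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "object_id": np.arange(N_OBJECTS),
                "x": self.coords[:, 0],
                "y": self.coords[:, 1],
                "community": self.communities,
                "role": self.roles,
            }
        )


def object_distance_matrix(
    dset: pd.DataFrame, column: str = "corrected_d"
) -> np.ndarray:
    """Run-averaged 15 x 15 mean-distance matrix for one (parcel, observer).

    Entry (i, j) is the mean of ``column`` over trial pairs with objects
    {i, j} within each run, then averaged over runs; pairs never co-occurring
    in a run are excluded from that run's average (NaN if never observed at
    all).  Symmetric with a zero diagonal by convention (the i = j cell holds
    0, not the same-object distance).
    """
    mats = []
    for _, sub in dset.groupby(["observer_id", "run_id"]):
        M = np.full((N_OBJECTS, N_OBJECTS), np.nan)
        g = sub.groupby(["obj_i", "obj_j"])[column].mean()
        for (i, j), v in g.items():
            if i >= N_OBJECTS or j >= N_OBJECTS or i == j:
                continue
            a, b = min(i, j), max(i, j)
            M[a, b] = M[b, a] = v
        mats.append(M)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN entries
        out = np.nanmean(np.stack(mats), axis=0)
    np.fill_diagonal(out, 0.0)
    return out


def permutation_average(
    matrix: np.ndarray,
    perms: list[np.ndarray] | None = None,
    graph: CommunityGraph | None = None,
    n_samples: int | None = None,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Average a 15 x 15 matrix over graph automorphisms.

    With ``n_samples=None`` (default) the exact group average is returned —
    a projection onto the automorphism-invariant subspace, so applying it
    twice changes nothing and the grand mean of off-diagonal entries is
    preserved.  With ``n_samples`` set, that many random group elements are
    drawn instead (the sampled estimator converges to the exact one).
    """
    M = np.asarray(matrix, dtype=float)
    if M.shape != (N_OBJECTS, N_OBJECTS):
        raise ValueError("matrix must be 15 x 15")
    if not np.allclose(M, M.T, equal_nan=True):
        raise ValueError("matrix must be symmetric")
    if perms is None:
        if graph is None:
            raise ValueError("need either perms or graph")
        perms = automorphism_group(graph)
    if n_samples is not None:
        rng = np.random.default_rng(seed)
        idx = rng.integers(len(perms), size=n_samples)
        perms = [perms[i] for i in idx]
    acc = np.zeros_like(M)
    for p in perms:
        # p maps node i -> p[i]; accumulate M expressed in the permuted frame
        acc[np.ix_(p, p)] += M
    return acc / len(perms)


def mds_embed(
    matrix: np.ndarray,
    seed: int = 0,
    n_restarts: int = 20,
    metric: bool = False,
    graph: CommunityGraph | None = None,
    n_components: int = 2,
) -> EmbeddingMap:
    """Embed a 15 x 15 distance matrix in the plane (nonmetric MDS).

    Best of ``n_restarts`` random initializations with a fixed seed; the
    reported stress is normalized (stress-1) for the nonmetric criterion.
    A degenerate all-equal matrix is embedded anyway, with a warning.
    """
    D = np.asarray(matrix, dtype=float).copy()
    np.fill_diagonal(D, 0.0)
    if np.any(~np.isfinite(D)):
        raise ValueError("matrix contains non-finite entries")
    off = D[~np.eye(N_OBJECTS, dtype=bool)]
    if np.allclose(off, off[0]):
        warnings.warn("degenerate distance matrix (all off-diagonal entries equal)")
    import inspect

    params = inspect.signature(MDS).parameters
    kwargs = dict(
        n_components=n_components,
        n_init=n_restarts,
        random_state=seed,
        normalized_stress="auto",
        max_iter=500,
    )
    if "metric_mds" in params:  # scikit-learn >= 1.9 API
        kwargs.update(metric="precomputed", metric_mds=metric, init="random")
    else:
        kwargs.update(metric=metric, dissimilarity="precomputed")
    mds = MDS(**kwargs)
    coords = mds.fit_transform(D)
    if graph is not None:
        communities, roles = graph.community_of, graph.role_of
    else:
        communities = np.full(N_OBJECTS, "?")
        roles = np.full(N_OBJECTS, "?")
    return EmbeddingMap(
        coords=coords,
        stress=float(mds.stress_),
        communities=np.asarray(communities),
        roles=np.asarray(roles),
    )


def plot_embedding(emb: EmbeddingMap, path=None, ax=None):
    """Render an embedding map: communities colored, linking objects
    outlined.  Requires matplotlib (optional dependency); returns the axes.
    """
    import matplotlib

    if path is not None:
        matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    palette = {c: f"C{i}" for i, c in enumerate(sorted(set(emb.communities)))}
    for i in range(N_OBJECTS):
        boundary = emb.roles[i] == "boundary"
        ax.scatter(
            *emb.coords[i],
            s=160,
            color=palette[emb.communities[i]],
            edgecolors="black" if boundary else "none",
            linewidths=1.5,
            zorder=3,
        )
        ax.annotate(str(i), emb.coords[i], ha="center", va="center", fontsize=7)
    ax.set_aspect("equal")
    ax.set_title(f"stress = {emb.stress:.3f}")
    if path is not None:
        ax.figure.savefig(path, bbox_inches="tight")
        plt.close(ax.figure)
    return ax


def internal_linking_summary(
    matrices: np.ndarray | list[np.ndarray], graph: CommunityGraph
) -> pd.DataFrame:
    """Mean distances by node-role pair x community relation.

    Six cells: {internal-internal, internal-linking, linking-linking} x
    {within, between community}.  Accepts one matrix or a stack (one per
    parcel); with a stack, each cell reports the mean and the standard error
    over parcels.
    """
    stack = np.asarray(matrices, dtype=float)
    if stack.ndim == 2:
        stack = stack[None]
    boundary = graph.role_of == "boundary"
    same = graph.same_community_matrix()

    iu = np.triu_indices(N_OBJECTS, k=1)
    rows = []
    for role_pair, mask_fn in [
        ("internal-internal", lambda i, j: ~boundary[i] & ~boundary[j]),
        ("internal-linking", lambda i, j: boundary[i] ^ boundary[j]),
        ("linking-linking", lambda i, j: boundary[i] & boundary[j]),
    ]:
        for relation, rel_mask in [("within", same[iu]), ("between", ~same[iu])]:
            m = mask_fn(iu[0], iu[1]) & rel_mask
            vals = stack[:, iu[0][m], iu[1][m]]
            per_parcel = np.nanmean(vals, axis=1)
            rows.append(
                {
                    "role_pair": role_pair,
                    "relation": relation,
                    "n_pairs": int(m.sum()),
                    "mean_d": float(np.nanmean(per_parcel)),
                    "sem_d": float(
                        np.nanstd(per_parcel, ddof=1) / np.sqrt(len(per_parcel))
                    )
                    if len(per_parcel) > 1
                    else np.nan,
                }
            )
    return pd.DataFrame(rows)
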