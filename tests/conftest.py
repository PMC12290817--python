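import numpy as np
import pytest

from commrsa.graphs import build_complete_graph, build_modular_graph


@pytest.fixture(scope="session")
def modular():
    return build_modular_graph()


@pytest.fixture(scope="session")
def complete():
    return build_complete_graph()


@pytest.fixture(scope="session")
def small_study():
    """A small structured study with three parcels: null, positive and
    negative community effect (shared across tests; treat as read-only)."""
    from commrsa.simulate import ParcelSpec, simulate_study

    specs = [
        ParcelSpec(parcel_id=0, n_vox=45, n_t=1, identity_snr=0.2),
        ParcelSpec(parcel_id=1, n_vox=45, n_t=1, identity_snr=0.2, community_beta=1.0),
        ParcelSpec(parcel_id=2, n_vox=45, n_t=1, identity_snr=0.2, community_beta=-1.0),
    ]
    return simulate_study(
        2, specs, "structured", runs=6, seed=20250901, n_candidates=30
    )


@pytest.fixture(scope="session")
def projected_null(small_study):
    """Leave-one-run-out projected coordinates of the null parcel,
    observer 0, with the pairwise-distance table."""
    from commrsa.analysis import project_loro
    from commrsa.distances import compute_pairwise, delay_profile, residual_correct

    rs = small_study.responses[(0, 0)]
    Y = project_loro(rs)
    dset = compute_pairwise(Y, rs.trial_meta, parcel_id=0, observer_id=0)
    dset = residual_correct(dset, delay_profile(dset))
    return rs, Y, dset
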