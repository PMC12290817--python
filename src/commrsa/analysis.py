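"""High-level drivers: from simulated (or ingested) responses to corrected
pairwise distances and reports.

The discriminant subspace used for *distance* analyses is fit leave-one-run-
out: the trials of run r are projected with a subspace fit on all other
runs.  Fitting and evaluating on the same trials would couple the whitening
step with the evaluated trials' slow drift (the fitted between-class
geometry absorbs episode-shared drift), which biases community statistics
even after the latency-profile correction; out-of-run projection removes
that coupling while preserving the discriminative geometry.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .distances import compute_pairwise, delay_profile, residual_correct
from .dlda import fit_dlda, project
from .simulate import ParcelResponseSet, StudyBundle

__all__ = ["project_loro", "parcel_distances", "study_distances"]


def project_loro(
    rs: ParcelResponseSet, kappa: int | None = None
) -> np.ndarray:
    """Project every trial with a subspace fit on the *other* runs.

    Recurring trials of the held-out run never contribute to the subspace
    that projects them.  Requires at least two runs and every class to have
    two or more trials outside each run.
    """
    meta = rs.trial_meta
    rec = rs.recurring_mask()
    labels = meta["object_id"].to_numpy()
    runs = meta["run_id"].to_numpy()
    run_ids = np.unique(runs)
    if len(run_ids) < 2:
        raise ValueError("leave-one-run-out projection needs at least 2 runs")
    Y = None
    for r in run_ids:
        train = rec & (runs != r)
        test = runs == r
        sub = fit_dlda(
            rs.responses[train],
            labels[train],
            kappa=kappa,
            fitted_on=f"obs{rs.observer_id}/parcel{rs.parcel_id}/runs!={r}",
        )
        out = project(sub, rs.responses[test])
        if Y is None:
            Y = np.zeros((len(meta), out.shape[1]))
        Y[test] = out
    return Y


def parcel_distances(
    rs: ParcelResponseSet, correct: bool = True
) -> pd.DataFrame:
    """Corrected pairwise distances for one (observer, parcel)."""
    Y = project_loro(rs)
    dset = compute_pairwise(
        Y, rs.trial_meta, parcel_id=rs.parcel_id, observer_id=rs.observer_id
    )
    if correct:
        dset = residual_correct(dset, delay_profile(dset))
    return dset


def study_distances(bundle: StudyBundle) -> dict:
    """Per-parcel corrected distance tables, pooled over observers.

    The delay profile is estimated per parcel, pooled over observers and
    runs, and the residual correction applied to the pooled table.
    """
    per_parcel: dict = {}
    for (u, w), rs in sorted(bundle.responses.items()):
        Y = project_loro(rs)
        dset = compute_pairwise(Y, rs.trial_meta, parcel_id=w, observer_id=u)
        per_parcel.setdefault(w, []).append(dset)
    out = {}
    for w, parts in per_parcel.items():
        pooled = pd.concat(parts, ignore_index=True)
        out[w] = residual_correct(pooled, delay_profile(pooled))
    return out
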