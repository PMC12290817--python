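"""Normalized distances in the discriminative subspace and their
temporal-autocorrelation correction.

All representational distances are measured between trial responses projected
into the standardized (kappa-1)-dimensional discriminant subspace.  With
unit-variance coordinates, the *normalized* amplitude of a projected response
a_k = sqrt(mean_j x_jk^2) is ~1 and the normalized distance between two
unrelated responses d_kl = sqrt(mean_j (x_jk - x_jl)^2) is ~1.40 — the mean
Euclidean distance between two random points on the unit hypersphere in 14
dimensions (closed form below).

Successive trials are temporally correlated (overlapping analysis windows and
slow signal drift), which makes short-latency distances smaller.  Because
objects of one community follow each other in structured sequences, this
autocorrelation masquerades as community structure.  The correction estimates
the delay-dependent mean distance profile T_w(Delta) per parcel and
residualizes every pairwise distance:

    d_corrected(Delta) = d(Delta) - T_w(Delta) + <T_w>,

leaving the delay-conditional mean flat while preserving the grand mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist
from scipy.special import gammaln

__all__ = [
    "normalized_amplitude",
    "normalized_distance",
    "expected_random_distance",
    "compute_pairwise",
    "delay_profile",
    "residual_correct",
    "DelayProfile",
]

#: column order of a pairwise-distance table
PAIR_COLUMNS = [
    "observer_id",
    "parcel_id",
    "run_id",
    "k",
    "l",
    "obj_i",
    "obj_j",
    "latency",
    "raw_d",
    "corrected_d",
]


def normalized_amplitude(y: np.ndarray, kappa: int = 15) -> float:
    """Root-mean-square coordinate magnitude a = sqrt(mean(y_j^2)).

    ``y`` must have kappa-1 entries (one per subspace dimension).
    """
    y = np.asarray(y, dtype=float)
    if y.shape[-1] != kappa - 1:
        raise ValueError(f"expected {kappa - 1} coordinates, got {y.shape[-1]}")
    return float(np.sqrt(np.mean(np.square(y), axis=-1)))


def normalized_distance(y_k: np.ndarray, y_l: np.ndarray, kappa: int = 15) -> float:
    """RMS-normalized Euclidean distance between two projected responses."""
    y_k = np.asarray(y_k, dtype=float)
    y_l = np.asarray(y_l, dtype=float)
    if y_k.shape != y_l.shape or y_k.shape[-1] != kappa - 1:
        raise ValueError("inputs must both have kappa-1 coordinates")
    return float(np.sqrt(np.mean(np.square(y_k - y_l), axis=-1)))


def expected_random_distance(n: int) -> float:
    """Mean distance between two uniform random points on the unit n-sphere.

    Uses the topological convention: the n-sphere S^n is embedded in n+1
    coordinates, so n=1 is the circle (4/pi), n=2 the ordinary sphere (4/3),
    and n=14 — the sphere of the 14-dimensional discriminant subspace
    baseline — gives ~1.4017.  Closed form (log-gamma for stability):

        d_ave = 2**n * Gamma((n+1)/2)**2 / (sqrt(pi) * Gamma(n + 1/2))

    d_ave increases monotonically to sqrt(2) as n grows.
    """
    if not isinstance(n, (int, np.integer)) or n < 1:
        raise ValueError("n must be a positive integer")
    log_d = (
        n * np.log(2.0)
        + 2 * gammaln((n + 1) / 2.0)
        - 0.5 * np.log(np.pi)
        - gammaln(n + 0.5)
    )
    return float(np.exp(log_d))


def monte_carlo_random_distance(
    n: int, n_samples: int, seed: int | np.random.Generator
) -> float:
    """Monte-Carlo estimate of :func:`expected_random_distance` (oracle).

    Samples ``n_samples`` independent pairs of points uniform on the unit
    n-sphere (in n+1 coordinates) and returns their mean distance.
    """
    rng = np.random.default_rng(seed)
    mean = 0.0
    done = 0
    while done < n_samples:
        m = min(200_000, n_samples - done)
        x = rng.standard_normal((m, n + 1))
        y = rng.standard_normal((m, n + 1))
        x /= np.linalg.norm(x, axis=1, keepdims=True)
        y /= np.linalg.norm(y, axis=1, keepdims=True)
        d = np.linalg.norm(x - y, axis=1)
        mean += d.sum()
        done += m
    return mean / n_samples


def compute_pairwise(
    projected: np.ndarray,
    trial_meta: pd.DataFrame,
    parcel_id: int | str = 0,
    observer_id: int = 0,
) -> pd.DataFrame:
    """All within-run trial pairs among recurring trials, with distances.

    Parameters
    ----------
    projected:
        (n_trials, kappa-1) standardized subspace coordinates, row-aligned
        with ``trial_meta``.
    trial_meta:
        DataFrame with columns run_id, trial_index, object_id, is_recurring
        (one row per trial, any observer/run ordering).

    Returns
    -------
    DataFrame with one record per within-run pair of recurring trials:
    trial indices (k < l), object pair, latency l - k in trials (singular
    trials occupy index slots, so latency counts real elapsed trials), and
    the normalized raw distance.  ``corrected_d`` is NaN until
    :func:`residual_correct` fills it.
    """
    projected = np.asarray(projected, dtype=float)
    if len(projected) != len(trial_meta):
        raise ValueError("projected rows and trial_meta rows must align")
    n_dim = projected.shape[1]

    frames = []
    meta = trial_meta.reset_index(drop=True)
    for run, idx in meta.groupby("run_id").groups.items():
        sub = meta.loc[idx]
        rec = sub[sub["is_recurring"].astype(bool)]
        if len(rec) < 2:
            continue
        rows = rec.index.to_numpy()
        t_idx = rec["trial_index"].to_numpy()
        order = np.argsort(t_idx)
        rows, t_idx = rows[order], t_idx[order]
        objs = rec["object_id"].to_numpy()[order]

        d = pdist(projected[rows]) / np.sqrt(n_dim)
        a, b = np.triu_indices(len(rows), k=1)
        frames.append(
            pd.DataFrame(
                {
                    "observer_id": observer_id,
                    "parcel_id": parcel_id,
                    "run_id": run,
                    "k": t_idx[a],
                    "l": t_idx[b],
                    "obj_i": objs[a],
                    "obj_j": objs[b],
                    "latency": t_idx[b] - t_idx[a],
                    "raw_d": d,
                    "corrected_d": np.nan,
                }
            )
        )
    if not frames:
        raise ValueError("no run contains two or more recurring trials")
    out = pd.concat(frames, ignore_index=True)
    return out[PAIR_COLUMNS]


@dataclass
class DelayProfile:
    """Delay-dependent mean distance T_w(Delta) for one parcel.

    ``delays`` lists the latencies (in trials) at which at least one pair was
    observed; ``t`` the mean raw distance at each; ``counts`` the pair counts.
    ``grand_mean`` is the unweighted mean of ``t`` over defined delays.
    """

    parcel_id: int | str
    delays: np.ndarray
    t: np.ndarray
    counts: np.ndarray

    @property
    def grand_mean(self) -> float:
        return float(np.mean(self.t))

    def lookup(self, latencies: np.ndarray) -> np.ndarray:
        """T(Delta) for each latency; raises if any delay is missing."""
        pos = np.searchsorted(self.delays, latencies)
        bad = (pos >= len(self.delays)) | (self.delays[np.minimum(pos, len(self.delays) - 1)] != latencies)
        if np.any(bad):
            missing = np.unique(np.asarray(latencies)[bad])
            raise KeyError(f"delays missing from profile: {missing.tolist()}")
        return self.t[pos]


def delay_profile(
    dset: pd.DataFrame, column: str = "raw_d", by_observer: bool = False
) -> dict:
    """Per-parcel delay profiles T_w(Delta), pooled over observers and runs.

    Returns a dict parcel_id -> :class:`DelayProfile` (or, with
    ``by_observer=True``, (parcel_id, observer_id) -> profile).
    """
    if len(dset) == 0:
        raise ValueError("empty pairwise-distance set")
    keys = ["parcel_id", "observer_id"] if by_observer else ["parcel_id"]
    out = {}
    for key, sub in dset.groupby(keys):
        g = sub.groupby("latency")[column]
        delays = np.array(sorted(g.groups))
        out[key if by_observer else key[0]] = DelayProfile(
            parcel_id=key[0],
            delays=delays,
            t=g.mean().loc[delays].to_numpy(),
            counts=g.size().loc[delays].to_numpy(),
        )
    return out


def residual_correct(dset: pd.DataFrame, profiles: dict) -> pd.DataFrame:
    """Residualize distances against the delay profile (fills corrected_d).

    corrected_d = raw_d - T_w(Delta) + <T_w>, per parcel.  Every latency in
    ``dset`` must be covered by the parcel's profile; a missing delay raises
    rather than silently falling back.
    """
    out = dset.copy()
    for parcel, sub in out.groupby("parcel_id"):
        prof = profiles.get(parcel)
        if prof is None:
            raise KeyError(f"no delay profile for parcel {parcel!r}")
        t_at = prof.lookup(sub["latency"].to_numpy())
        out.loc[sub.index, "corrected_d"] = (
            sub["raw_d"].to_numpy() - t_at + prof.grand_mean
        )
    return out
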