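"""Community-sensitivity statistics with latency-consistency control.

A parcel is *community sensitive* when corrected distances between responses
to objects of different communities differ systematically from distances
within a community:

    Delta_BW = D_B - D_W  (mean between - mean within),

assessed with a two-sample t-statistic t_BW.  Because objects of one
community follow each other, within-community pairs have shorter latencies
and any residual temporal autocorrelation inflates Delta_BW.  The consistency
sweep therefore recomputes t_BW(tau_LB) restricted to pairs with latency
>= tau_LB for tau_LB = 1..30, FDR-corrected across parcels within each bound;
tau_sig is the largest bound up to which the parcel stays significant for
*all* smaller bounds, and only tau_sig >= 30 counts as community sensitive.

Pair-type statistics compare each of the SA/DA/SN/DN distance groups against
the pooled distances of all four types (the pool includes the tested type's
own members; the t-test is the standard two-sample form on those overlapping
samples, a documented definitional choice).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .graphs import N_OBJECTS, PAIR_TYPES, CommunityGraph, classify_pairs

__all__ = [
    "SensitivityReport",
    "community_sensitivity",
    "latency_sweep",
    "pair_type_stats",
    "fdr_adjust",
    "sensitivity_report",
]

TAU_MAX_DEFAULT = 30


@dataclass
class SensitivityReport:
    """Per-parcel community-sensitivity summary (one row per parcel)."""

    table: pd.DataFrame
    sweep_t: pd.DataFrame      # parcels x tau_LB t_BW values
    sweep_p: pd.DataFrame      # parcels x tau_LB FDR-adjusted p-values
    alpha: float = 0.05
    tau_max: int = TAU_MAX_DEFAULT

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def _pair_masks(dset: pd.DataFrame, graph: CommunityGraph):
    """Boolean masks: distinct-object pairs, and within-community pairs."""
    comm = graph.community_index()
    obj_i = dset["obj_i"].to_numpy()
    obj_j = dset["obj_j"].to_numpy()
    recurring_pair = (obj_i < N_OBJECTS) & (obj_j < N_OBJECTS)
    distinct = recurring_pair & (obj_i != obj_j)
    within = np.zeros(len(dset), dtype=bool)
    within[distinct] = comm[obj_i[distinct]] == comm[obj_j[distinct]]
    return distinct, within


def _ttest(a: np.ndarray, b: np.ndarray, equal_var: bool = True):
    if len(a) < 2 or len(b) < 2:
        raise ValueError("insufficient data: each group needs >= 2 distances")
    t, p = stats.ttest_ind(a, b, equal_var=equal_var)
    return float(t), float(p)


def community_sensitivity(
    dset: pd.DataFrame,
    graph: CommunityGraph,
    tau_lb: int = 1,
    column: str = "corrected_d",
    equal_var: bool = True,
) -> tuple[float, float, float]:
    """Delta_BW, t_BW and p for one parcel's pairwise-distance records.

    Restricted to pairs of *distinct* recurring objects with latency
    >= ``tau_lb``.  The t-statistic is positive when between-community
    distances exceed within-community distances.
    """
    distinct, within = _pair_masks(dset, graph)
    sel = distinct & (dset["latency"].to_numpy() >= tau_lb)
    d = dset[column].to_numpy()
    d_w = d[sel & within]
    d_b = d[sel & ~within]
    if len(d_w) < 2 or len(d_b) < 2:
        raise ValueError(f"insufficient data at tau_lb={tau_lb}")
    t, p = _ttest(d_b, d_w, equal_var=equal_var)
    delta = float(d_b.mean() - d_w.mean())
    return delta, t, p


def latency_sweep(
    dsets: dict,
    graph: CommunityGraph,
    tau_range: range = range(1, TAU_MAX_DEFAULT + 1),
    alpha: float = 0.05,
    column: str = "corrected_d",
    equal_var: bool = True,
) -> SensitivityReport:
    """Latency-bound sweep with FDR control across parcels, per bound.

    Parameters
    ----------
    dsets:
        Mapping parcel_id -> pairwise-distance DataFrame (corrected
        distances filled).
    tau_range:
        Lower bounds to sweep (default 1..30).

    Returns
    -------
    SensitivityReport whose table has, per parcel: D_W, D_B, delta_bw, t_bw
    and adjusted p at tau_LB=1, tau_sig, the community_sensitive flag and
    sensitivity sign.  A bound with no data in one of the groups is marked
    undefined (NaN) and treated as non-significant for that parcel.
    """
    parcels = sorted(dsets)
    taus = list(tau_range)
    T = pd.DataFrame(index=parcels, columns=taus, dtype=float)
    P_raw = pd.DataFrame(index=parcels, columns=taus, dtype=float)

    cache = {}
    for w in parcels:
        dset = dsets[w]
        distinct, within = _pair_masks(dset, graph)
        cache[w] = (
            dset[column].to_numpy(),
            dset["latency"].to_numpy(),
            distinct,
            within,
        )

    for tau in taus:
        for w in parcels:
            d, lat, distinct, within = cache[w]
            sel = distinct & (lat >= tau)
            d_w, d_b = d[sel & within], d[sel & ~within]
            if len(d_w) < 2 or len(d_b) < 2:
                continue  # leave NaN: undefined, non-significant
            t, p = _ttest(d_b, d_w, equal_var=equal_var)
            T.loc[w, tau] = t
            P_raw.loc[w, tau] = p

    # FDR across the parcel axis within each bound
    P_adj = P_raw.copy()
    for tau in taus:
        col = P_raw[tau]
        ok = col.notna()
        if ok.any():
            P_adj.loc[ok, tau] = fdr_adjust(col[ok].to_numpy())

    rows = []
    for w in parcels:
        d, lat, distinct, within = cache[w]
        sel = distinct & (lat >= taus[0])
        d_w, d_b = d[sel & within], d[sel & ~within]
        significant = (P_adj.loc[w] < alpha).fillna(False).to_numpy()
        # tau_sig: largest tau such that significant at every bound <= tau
        run = 0
        for s in significant:
            if not s:
                break
            run += 1
        tau_sig = taus[run - 1] if run else 0
        sensitive = tau_sig >= max(taus)
        t1 = T.loc[w, taus[0]]
        rows.append(
            {
                "parcel_id": w,
                "D_W": d_w.mean() if len(d_w) else np.nan,
                "D_B": d_b.mean() if len(d_b) else np.nan,
                "delta_bw": (d_b.mean() - d_w.mean())
                if len(d_w) and len(d_b)
                else np.nan,
                "t_bw": t1,
                "p_adj": P_adj.loc[w, taus[0]],
                "tau_sig": tau_sig,
                "community_sensitive": bool(sensitive),
                "sensitivity_sign": int(np.sign(t1)) if sensitive else 0,
            }
        )
    table = pd.DataFrame(rows)
    return SensitivityReport(table, T, P_adj, alpha=alpha, tau_max=max(taus))


def pair_type_stats(
    dset: pd.DataFrame,
    graph: CommunityGraph,
    tau_lb: int = 1,
    column: str = "corrected_d",
    equal_var: bool = True,
) -> pd.DataFrame:
    """Per pair-type means and t-statistics against the pooled distances.

    For each of SA/DA/SN/DN: a two-sample t-test of that type's distances
    against the pool of all four types (which includes the tested type).
    Types absent from the data (e.g. SN/DN on the complete graph) are
    flagged with NaN statistics.
    """
    types = classify_pairs(graph)
    distinct, _ = _pair_masks(dset, graph)
    sel = distinct & (dset["latency"].to_numpy() >= tau_lb)
    sub = dset[sel]
    key = [
        types[(min(i, j), max(i, j))]
        for i, j in zip(sub["obj_i"].to_numpy(), sub["obj_j"].to_numpy())
    ]
    d = sub[column].to_numpy()
    pool = d  # D^diff: distances of all four types
    rows = []
    key = np.asarray(key)
    for t_name in PAIR_TYPES:
        grp = d[key == t_name]
        if len(grp) < 2:
            rows.append({"pair_type": t_name, "n": len(grp), "mean_d": np.nan,
                         "t": np.nan, "p": np.nan})
            continue
        t, p = _ttest(grp, pool, equal_var=equal_var)
        rows.append({"pair_type": t_name, "n": len(grp), "mean_d": grp.mean(),
                     "t": t, "p": p})
    return pd.DataFrame(rows)


def fdr_adjust(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size and (np.nanmin(p) < 0 or np.nanmax(p) > 1):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def sensitivity_report(
    dsets: dict,
    graph: CommunityGraph,
    alpha: float = 0.05,
    tau_max: int = TAU_MAX_DEFAULT,
    column: str = "corrected_d",
) -> SensitivityReport:
    """Full per-parcel report: sweep + pair-type t-scores in one table."""
    rep = latency_sweep(
        dsets, graph, range(1, tau_max + 1), alpha=alpha, column=column
    )
    pt_cols: dict[str, list] = {f"t_{t}": [] for t in PAIR_TYPES}
    pt_cols.update({f"D_{t}": [] for t in PAIR_TYPES})
    for w in rep.table["parcel_id"]:
        pt = pair_type_stats(dsets[w], graph, column=column).set_index("pair_type")
        for t_name in PAIR_TYPES:
            pt_cols[f"t_{t_name}"].append(pt.loc[t_name, "t"])
            pt_cols[f"D_{t_name}"].append(pt.loc[t_name, "mean_d"])
    for c, v in pt_cols.items():
        rep.table[c] = v
    return rep
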