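"""Shared statistical primitives.

Percent change, Šídák family-wise adjustment, an exact small-sample
Mann-Whitney U test (full enumeration of rank splits), and quantification
of small-GTPase (Rac1/RhoA) activation ratios from densitometry tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "percent_change",
    "sidak_adjust",
    "mann_whitney_exact",
    "MannWhitneyResult",
    "activation_analysis",
]

#: Largest per-group size for which the exact enumeration is used.
EXACT_N_MAX = 10


def percent_change(reference: float, value: float) -> float:
    """Percent change from *reference* to *value*; positive = reduction.

    ``100 * (reference - value) / reference``.
    """
    if reference == 0:
        raise ValueError("percent_change undefined for reference = 0")
    return 100.0 * (reference - value) / reference


def sidak_adjust(p, m: int | None = None) -> np.ndarray:
    """Šídák family-wise adjustment ``1 - (1 - p)**m``, clipped to [0, 1].

    Parameters
    ----------
    p : array-like of raw p-values in [0, 1].
    m : family size; defaults to ``len(p)``.
    """
    p = np.atleast_1d(np.asarray(p, dtype=float))
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if m is None:
        m = p.size
    if m < 1:
        raise ValueError("family size m must be >= 1")
    return np.clip(1.0 - (1.0 - p) ** m, 0.0, 1.0)


@dataclass(frozen=True)
class MannWhitneyResult:
    u: float          # U statistic of the first sample
    p: float          # two-sided p-value
    exact: bool       # enumeration (True) or tie-corrected normal approximation


def _midranks(values: np.ndarray) -> np.ndarray:
    return sps.rankdata(values, method="average")


def mann_whitney_exact(x, y) -> MannWhitneyResult:
    """Two-sided Mann-Whitney U test.

    For group sizes up to 10 each, the null distribution of U is obtained by
    full enumeration of the C(n_x + n_y, n_x) assignments of the pooled
    mid-ranks to the first group; the two-sided p-value is the probability of
    an assignment at least as far from E[U] = n_x n_y / 2 as the observed one.
    Ties are handled through mid-ranks (the enumeration conditions on the
    observed tie pattern). Larger samples fall back to the tie-corrected
    normal approximation with continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    nx, ny = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = _midranks(pooled)
    u_obs = float(ranks[:nx].sum() - nx * (nx + 1) / 2.0)
    mu = nx * ny / 2.0

    if nx <= EXACT_N_MAX and ny <= EXACT_N_MAX:
        dev_obs = abs(u_obs - mu)
        total = comb(nx + ny, nx)
        hits = 0
        offset = nx * (nx + 1) / 2.0
        for idx in combinations(range(nx + ny), nx):
            u = ranks[list(idx)].sum() - offset
            if abs(u - mu) >= dev_obs - 1e-12:
                hits += 1
        return MannWhitneyResult(u=u_obs, p=hits / total, exact=True)

    if np.ptp(pooled) == 0:
        return MannWhitneyResult(u=u_obs, p=1.0, exact=False)
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return MannWhitneyResult(u=float(res.statistic), p=float(res.pvalue), exact=False)


def activation_analysis(
    measurements: pd.DataFrame,
    control_condition: str = "vehicle",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Quantify GTPase activation (active/total band ratio) against a control.

    The input table has columns ``sample, condition, timepoint_h, active,
    total`` (densitometry band intensities). Per sample the activation ratio
    is ``active / total``; per timepoint each ratio is normalized by the mean
    control-condition ratio at that timepoint, so the control group's mean
    normalized ratio is 1 by construction. Each treated condition is compared
    with the control per timepoint with the exact two-sided Mann-Whitney test.

    Returns
    -------
    (per_sample, comparisons)
        *per_sample* adds ``ratio`` and ``normalized_ratio`` columns;
        *comparisons* has one row per (timepoint, condition) with columns
        ``timepoint_h, condition, n, mean_normalized_ratio, u, p``.
    """
    required = {"sample", "condition", "timepoint_h", "active", "total"}
    missing = required - set(measurements.columns)
    if missing:
        raise ValueError(f"measurement table missing columns: {sorted(missing)}")
    df = measurements.reset_index(drop=True).copy()
    if (df["active"] <= 0).any() or (df["total"] <= 0).any():
        raise ValueError("band intensities must be positive")
    df["ratio"] = df["active"] / df["total"]

    rows = []
    norm = np.empty(len(df))
    for tp, sub in df.groupby("timepoint_h"):
        ctrl = sub.loc[sub["condition"] == control_condition, "ratio"]
        if ctrl.empty:
            raise ValueError(f"no {control_condition!r} measurements at timepoint {tp}")
        ref = ctrl.mean()
        norm[sub.index.to_numpy()] = sub["ratio"] / ref
        for cond, grp in sub.groupby("condition"):
            if cond == control_condition:
                continue
            res = mann_whitney_exact(grp["ratio"].to_numpy(), ctrl.to_numpy())
            rows.append(
                {
                    "timepoint_h": tp,
                    "condition": cond,
                    "n": len(grp),
                    "mean_normalized_ratio": float((grp["ratio"] / ref).mean()),
                    "u": res.u,
                    "p": res.p,
                }
            )
    df["normalized_ratio"] = norm
    comparisons = pd.DataFrame(
        rows, columns=["timepoint_h", "condition", "n", "mean_normalized_ratio", "u", "p"]
    )
    return df, comparisons
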