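"""Barrier-integrity quantification.

ECIS (electric cell-substrate impedance sensing) resistance traces are a
surrogate for monolayer barrier function: higher resistance, tighter
barrier. This module normalizes traces (to each well's own resistance at
treatment time, or pointwise to the vehicle-condition mean trace), compares
conditions on the mean resistance over the final 30 minutes of the
experiment (one-way ANOVA + Tukey HSD), and quantifies scratch-wound
closure efficiency from wound-area series or binary wound masks.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "ResistanceTrace",
    "WoundSeries",
    "EndpointResult",
    "read_ecis_csv",
    "vehicle_mean_trace",
    "normalize_trace",
    "endpoint_stats",
    "closure_efficiency",
    "wound_area_from_mask",
    "load_mask",
]


@dataclass
class ResistanceTrace:
    """One well's resistance time series (ohm, or dimensionless once normalized)."""

    well_id: str
    condition: str
    times: np.ndarray       # seconds, strictly increasing
    resistance: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.resistance = np.asarray(self.resistance, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.resistance.shape:
            raise ValueError("times and resistance must be 1-D and equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError(f"well {self.well_id}: times must strictly increase")


@dataclass
class WoundSeries:
    field_id: str
    condition: str
    times: np.ndarray  # hours
    area: np.ndarray   # px² or µm²


@dataclass(frozen=True)
class EndpointResult:
    condition: str
    window: tuple[float, float]  # seconds
    mean_resistance: float
    sem: float
    n_wells: int


def read_ecis_csv(path: str | Path) -> list[ResistanceTrace]:
    """Read traces from a CSV with columns ``well,condition,time_s,resistance_ohm``."""
    df = pd.read_csv(path, comment="#")
    traces = []
    for (well, cond), sub in df.groupby(["well", "condition"], sort=True):
        sub = sub.sort_values("time_s")
        traces.append(
            ResistanceTrace(
                well_id=str(well),
                condition=str(cond),
                times=sub["time_s"].to_numpy(),
                resistance=sub["resistance_ohm"].to_numpy(),
            )
        )
    return traces


def vehicle_mean_trace(traces: list[ResistanceTrace], condition: str = "vehicle") -> ResistanceTrace:
    """Across-well mean trace of one condition (shared grid required)."""
    ref = [t for t in traces if t.condition == condition]
    if not ref:
        raise ValueError(f"no traces with condition {condition!r}")
    grid = ref[0].times
    for t in ref[1:]:
        if not np.array_equal(t.times, grid):
            raise ValueError("reference wells are on different time grids")
    mean = np.mean([t.resistance for t in ref], axis=0)
    return ResistanceTrace(well_id=f"mean({condition})", condition=condition,
                           times=grid.copy(), resistance=mean)


def normalize_trace(
    trace: ResistanceTrace,
    mode: str = "baseline",
    treatment_time: float | None = None,
    reference: ResistanceTrace | None = None,
) -> ResistanceTrace:
    """Normalize a resistance trace to dimensionless units.

    mode="baseline": divide by the trace's own value at *treatment_time*
    (nearest sample), so the normalized value there is 1.0.
    mode="vehicle": divide pointwise by *reference* (typically the vehicle
    mean trace), which must share the time grid.
    """
    if mode == "baseline":
        if treatment_time is None:
            raise ValueError("baseline mode requires treatment_time")
        if not (trace.times[0] <= treatment_time <= trace.times[-1]):
            raise ValueError("treatment time outside trace")
        i = int(np.argmin(np.abs(trace.times - treatment_time)))
        ref_val = trace.resistance[i]
        if ref_val == 0:
            raise ValueError("zero resistance at treatment time")
        return replace(trace, times=trace.times.copy(),
                       resistance=trace.resistance / ref_val)
    if mode == "vehicle":
        if reference is None:
            raise ValueError("vehicle mode requires a reference trace")
        if not np.array_equal(trace.times, reference.times):
            raise ValueError("trace and reference are on different time grids")
        if np.any(reference.resistance == 0):
            raise ValueError("reference trace contains zero values")
        return replace(trace, times=trace.times.copy(),
                       resistance=trace.resistance / reference.resistance)
    raise ValueError(f"unknown normalization mode: {mode!r}")


def endpoint_stats(
    traces: list[ResistanceTrace], window_minutes: float = 30.0
) -> tuple[list[EndpointResult], pd.DataFrame]:
    """Final-window endpoint means per condition with ANOVA + Tukey HSD.

    Each well is reduced to its mean resistance over the final
    *window_minutes* of its trace (window inclusive of the final sample);
    conditions are compared on these per-well means by one-way ANOVA followed
    by Tukey's multiple-comparisons test.

    Returns the per-condition endpoint results and a comparison table with
    columns ``condition_a, condition_b, diff, p_adj`` plus the overall ANOVA
    p-value in ``comparisons.attrs["anova_p"]``.
    """
    if not traces:
        raise ValueError("no traces")
    window_s = window_minutes * 60.0
    per_well: dict[str, list[float]] = {}
    windows: dict[str, tuple[float, float]] = {}
    for tr in traces:
        t0, t1 = tr.times[0], tr.times[-1]
        if t1 - t0 < window_s:
            raise ValueError(f"well {tr.well_id}: trace shorter than endpoint window")
        mask = tr.times >= t1 - window_s
        per_well.setdefault(tr.condition, []).append(float(tr.resistance[mask].mean()))
        windows[tr.condition] = (float(t1 - window_s), float(t1))

    results = []
    for cond in sorted(per_well):
        vals = np.array(per_well[cond])
        sem = float(vals.std(ddof=1) / np.sqrt(vals.size)) if vals.size > 1 else 0.0
        results.append(
            EndpointResult(condition=cond, window=windows[cond],
                           mean_resistance=float(vals.mean()), sem=sem,
                           n_wells=vals.size)
        )

    conds = sorted(per_well)
    rows = []
    anova_p = np.nan
    if len(conds) >= 2 and all(len(per_well[c]) >= 2 for c in conds):
        groups = [np.array(per_well[c]) for c in conds]
        if max(np.ptp(g) for g in groups) == 0:
            # degenerate zero-variance wells: differences are exact
            anova_p = 1.0 if np.ptp([g[0] for g in groups]) == 0 else 0.0
            for i in range(len(conds)):
                for j in range(i + 1, len(conds)):
                    d = float(groups[i].mean() - groups[j].mean())
                    rows.append((conds[i], conds[j], d, 1.0 if d == 0 else 0.0))
        else:
            anova_p = float(sps.f_oneway(*groups).pvalue)
            hsd = sps.tukey_hsd(*groups)
            for i in range(len(conds)):
                for j in range(i + 1, len(conds)):
                    rows.append(
                        (conds[i], conds[j],
                         float(groups[i].mean() - groups[j].mean()),
                         float(hsd.pvalue[i, j]))
                    )
    comparisons = pd.DataFrame(rows, columns=["condition_a", "condition_b", "diff", "p_adj"])
    comparisons.attrs["anova_p"] = anova_p
    return results, comparisons


def closure_efficiency(series: WoundSeries, t: float, time_atol: float = 0.25) -> float:
    """Scratch-wound closure efficiency at time *t* (hours).

    ``(A(0) - A(t)) / A(0)``; 0 = no closure, 1 = fully closed; negative if
    the wound expanded. The sample nearest to *t* within *time_atol* hours
    is used.
    """
    times = np.asarray(series.times, dtype=float)
    area = np.asarray(series.area, dtype=float)
    a0 = area[int(np.argmin(times))]
    if a0 == 0:
        raise ValueError("initial wound area is zero")
    i = int(np.argmin(np.abs(times - t)))
    if abs(times[i] - t) > time_atol:
        raise ValueError(f"no sample within {time_atol} h of t={t}")
    return float((a0 - area[i]) / a0)


def wound_area_from_mask(mask: np.ndarray, scale: float | None = None) -> float:
    """Wound area from a binary mask (foreground = open wound pixels).

    Returns pixel² by default; µm² when *scale* (µm per pixel) is given.
    """
    mask = np.asarray(mask)
    if mask.dtype != bool:
        values = np.unique(mask)
        nonzero = values[values != 0]
        if nonzero.size > 1:
            raise ValueError(f"mask is not binary (values {values[:5]}...)")
        mask = mask != 0
    area = float(mask.sum())
    if scale is not None:
        area *= scale ** 2
    return area


def load_mask(path: str | Path) -> np.ndarray:
    """Load a TIFF/PNG wound mask as a 2-D array."""
    import imageio.v3 as iio

    img = iio.imread(path)
    if img.ndim == 3:  # collapse identical channels
        img = img[..., 0]
    return img
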