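"""Cell-track motility statistics.

Parses manually-linked cell tracks (MTrackJ MDF text or long-format CSV) and
computes the motility readouts used for glucocorticoid-treated podocyte
cohorts: per-cell mean speed over the imaging period, the directional
persistence ratio (Euclidean displacement / path length; 1 = perfectly
straight motion), cohort summaries with SEM, per-timepoint instantaneous
speed with Šídák-adjusted between-condition comparisons, and origin-centred
rose-plot paths.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from .stats import sidak_adjust

__all__ = [
    "TrackPoint",
    "Track",
    "MotilityStats",
    "CohortSummary",
    "InstantSpeedSeries",
    "parse_tracks",
    "track_speed",
    "track_persistence",
    "motility_stats",
    "cohort_summary",
    "instantaneous_speed_series",
    "compare_instant_speed",
    "rose_plot_data",
]


@dataclass(frozen=True)
class TrackPoint:
    frame: int
    time: float  # seconds
    x: float     # µm
    y: float     # µm


@dataclass
class Track:
    """One cell's time-ordered positions (µm) with timestamps (s)."""

    cell_id: str
    condition: str
    points: list[TrackPoint] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.points)

    def coords(self) -> np.ndarray:
        return np.array([(p.x, p.y) for p in self.points], dtype=float)

    def times(self) -> np.ndarray:
        return np.array([p.time for p in self.points], dtype=float)

    def frames(self) -> np.ndarray:
        return np.array([p.frame for p in self.points], dtype=int)


@dataclass(frozen=True)
class MotilityStats:
    cell_id: str
    condition: str
    path_length: float            # µm
    euclidean_displacement: float  # µm
    duration: float               # s
    mean_speed: float             # µm/s
    persistence: float | None     # dimensionless in [0,1]; None if undefined


@dataclass(frozen=True)
class CohortSummary:
    condition: str
    n_cells: int
    mean_speed: float
    sem_speed: float
    mean_persistence: float | None
    sem_persistence: float | None
    n_excluded_persistence: int
    degenerate_sem: bool = False  # True when n_cells == 1 (SEM reported as 0)


@dataclass
class InstantSpeedSeries:
    condition: str
    times: np.ndarray              # s; time of the later frame of each step
    cohort_mean_speed: np.ndarray  # µm/s
    sem: np.ndarray
    n_cells: np.ndarray


# ---------------------------------------------------------------------------
# parsing

def _tracks_from_table(df: pd.DataFrame, scale: float, default_condition: str) -> list[Track]:
    tracks: list[Track] = []
    for cell_id, sub in df.groupby("cell", sort=True):
        dup = sub["frame"].duplicated()
        if dup.any():
            f = int(sub.loc[dup, "frame"].iloc[0])
            raise ValueError(f"duplicate (cell, frame) pair: ({cell_id}, {f})")
        sub = sub.sort_values("frame")
        t = sub["time"].to_numpy(dtype=float)
        if np.any(np.diff(t) <= 0):
            raise ValueError(f"non-monotone time within cell {cell_id}")
        cond = str(sub["condition"].iloc[0]) if "condition" in sub else default_condition
        points = [
            TrackPoint(int(f), float(ti), float(x) * scale, float(y) * scale)
            for f, ti, x, y in zip(sub["frame"], t, sub["x"], sub["y"])
        ]
        tracks.append(Track(cell_id=str(cell_id), condition=cond, points=points))
    return tracks


def _parse_csv(text: str, scale: float, default_condition: str) -> list[Track]:
    df = pd.read_csv(io.StringIO(text), comment="#")
    df = df.rename(columns={"time_s": "time"})
    required = {"cell", "frame", "time", "x", "y"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"track CSV missing columns: {sorted(missing)}")
    return _tracks_from_table(df, scale, default_condition)


def _parse_mdf(
    text: str, scale: float, default_condition: str, frame_interval_s: float
) -> list[Track]:
    # Tolerant superset of the MTrackJ text format: a line whose first token
    # is "Track" opens a track (second token = id); a "Point" line carries
    # (index, x, y, z, frame, channel); z and channel are ignored. MDF stores
    # no timestamps, so times are frame * frame_interval_s.
    rows: list[tuple[str, int, float, float]] = []
    current: str | None = None
    for line in text.splitlines():
        tokens = line.split()
        if not tokens:
            continue
        if tokens[0] == "Track":
            current = tokens[1] if len(tokens) > 1 else str(len(rows))
        elif tokens[0] == "Point":
            if current is None:
                raise ValueError("MDF Point record before any Track record")
            vals = [float(v) for v in tokens[1:]]
            if len(vals) < 3:
                raise ValueError(f"malformed MDF Point line: {line!r}")
            x, y = vals[1], vals[2]
            frame = int(vals[4]) if len(vals) >= 5 else len(
                [r for r in rows if r[0] == current]
            ) + 1
            rows.append((current, frame, x, y))
    df = pd.DataFrame(rows, columns=["cell", "frame", "x", "y"])
    df["time"] = df["frame"] * frame_interval_s
    return _tracks_from_table(df, scale, default_condition)


def parse_tracks(
    source: str | Path,
    dialect: str = "csv",
    scale: float = 1.0,
    condition: str = "unknown",
    frame_interval_s: float = 600.0,
) -> list[Track]:
    """Parse cell tracks from an MTrackJ MDF file or a long-format CSV.

    CSV columns: ``cell, frame, time_s (or time), x, y[, condition]``.
    Coordinates are multiplied by *scale* (µm per pixel; default 1.0).
    Tracks are returned sorted by cell_id, points sorted by frame.
    """
    if isinstance(source, str) and "\n" in source:  # literal file content
        text = source
    else:
        text = Path(source).read_text()
    if dialect == "csv":
        return _parse_csv(text, scale, condition)
    if dialect == "mdf":
        return _parse_mdf(text, scale, condition, frame_interval_s)
    raise ValueError(f"unknown track dialect: {dialect!r}")


# ---------------------------------------------------------------------------
# per-track statistics

def _steps(track: Track) -> np.ndarray:
    xy = track.coords()
    return np.hypot(*np.diff(xy, axis=0).T)


def motility_stats(track: Track) -> MotilityStats:
    """Path length, net displacement, duration, mean speed and persistence."""
    if len(track) < 2:
        raise ValueError(f"track {track.cell_id}: >=2 points required")
    xy = track.coords()
    t = track.times()
    duration = float(t[-1] - t[0])
    if duration == 0:
        raise ValueError(f"track {track.cell_id}: zero duration")
    path = float(_steps(track).sum())
    euclid = float(np.hypot(*(xy[-1] - xy[0])))
    persistence = euclid / path if path > 0 else None
    return MotilityStats(
        cell_id=track.cell_id,
        condition=track.condition,
        path_length=path,
        euclidean_displacement=euclid,
        duration=duration,
        mean_speed=path / duration,
        persistence=persistence,
    )


def track_speed(track: Track) -> MotilityStats:
    """Mean speed = total path length / duration (µm/s)."""
    return motility_stats(track)


def track_persistence(track: Track) -> MotilityStats:
    """Persistence ratio = Euclidean displacement / path length; None if 0/0."""
    return motility_stats(track)


def _mean_sem(values: np.ndarray) -> tuple[float, float, bool]:
    n = values.size
    mean = float(values.mean())
    if n < 2:
        return mean, 0.0, True
    return mean, float(values.std(ddof=1) / np.sqrt(n)), False


def cohort_summary(tracks: list[Track], condition: str | None = None) -> CohortSummary:
    """Unweighted per-cell means with SEM across cells of one condition.

    Cells with undefined persistence (zero path length) are excluded from the
    persistence mean and counted in ``n_excluded_persistence``.
    """
    if condition is not None:
        tracks = [t for t in tracks if t.condition == condition]
    if not tracks:
        raise ValueError("empty cohort")
    cond = condition if condition is not None else tracks[0].condition
    stats = [motility_stats(t) for t in tracks]
    speeds = np.array([s.mean_speed for s in stats])
    pers = np.array([s.persistence for s in stats if s.persistence is not None])
    mean_v, sem_v, degenerate = _mean_sem(speeds)
    if pers.size:
        mean_p, sem_p, _ = _mean_sem(pers)
    else:
        mean_p = sem_p = None
    return CohortSummary(
        condition=cond,
        n_cells=len(stats),
        mean_speed=mean_v,
        sem_speed=sem_v,
        mean_persistence=mean_p,
        sem_persistence=sem_p,
        n_excluded_persistence=len(stats) - pers.size,
        degenerate_sem=degenerate,
    )


# ---------------------------------------------------------------------------
# instantaneous speed

def _frame_grid(tracks: list[Track], time_atol: float) -> tuple[np.ndarray, np.ndarray]:
    """Common (frame, time) grid across tracks; frames must agree in time."""
    frame_times: dict[int, float] = {}
    for tr in tracks:
        for p in tr.points:
            if p.frame in frame_times:
                if abs(frame_times[p.frame] - p.time) > time_atol:
                    raise ValueError(
                        f"frame {p.frame} has inconsistent timestamps "
                        f"({frame_times[p.frame]} vs {p.time})"
                    )
            else:
                frame_times[p.frame] = p.time
    frames = np.array(sorted(frame_times), dtype=int)
    times = np.array([frame_times[f] for f in frames])
    return frames, times


def _per_cell_speed_matrix(
    tracks: list[Track], frames: np.ndarray, times: np.ndarray
) -> np.ndarray:
    """(n_cells, n_frames) instantaneous speeds; NaN where a cell is absent.

    Speed at frame i is the step distance from the cell's previous recorded
    frame divided by the actual elapsed time, assigned to the later frame
    (gaps are skipped, not interpolated).
    """
    pos = {f: j for j, f in enumerate(frames)}
    out = np.full((len(tracks), frames.size), np.nan)
    for i, tr in enumerate(tracks):
        xy = tr.coords()
        t = tr.times()
        fr = tr.frames()
        d = np.hypot(*np.diff(xy, axis=0).T)
        dt = np.diff(t)
        for k in range(1, len(tr)):
            out[i, pos[fr[k]]] = d[k - 1] / dt[k - 1]
    return out


def instantaneous_speed_series(
    tracks: list[Track], time_atol: float = 1.0
) -> InstantSpeedSeries:
    """Cohort-mean instantaneous speed at each frame after the first."""
    if not tracks:
        raise ValueError("empty cohort")
    frames, times = _frame_grid(tracks, time_atol)
    if frames.size < 2:
        raise ValueError("fewer than 2 common frames")
    speeds = _per_cell_speed_matrix(tracks, frames, times)[:, 1:]
    n = np.sum(~np.isnan(speeds), axis=0)
    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        # frames where a single cell is present have no sample SD
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(speeds, axis=0)
        sd = np.nanstd(speeds, axis=0, ddof=1)
    sem = np.where(n > 1, sd / np.sqrt(np.maximum(n, 1)), 0.0)
    return InstantSpeedSeries(
        condition=tracks[0].condition,
        times=times[1:],
        cohort_mean_speed=mean,
        sem=sem,
        n_cells=n,
    )


@dataclass
class InstantSpeedComparison:
    times: np.ndarray
    p_raw: np.ndarray
    p_adj: np.ndarray
    first_significant_time: float | None


def compare_instant_speed(
    tracks_a: list[Track],
    tracks_b: list[Track],
    alpha: float = 0.05,
    time_atol: float = 1.0,
) -> InstantSpeedComparison:
    """Per-timepoint Welch comparison of instantaneous speeds, Šídák-adjusted.

    Both cohorts must share the frame grid. Returns per-timepoint raw and
    family-wise adjusted p-values (family = number of compared timepoints)
    and the earliest time with adjusted p < *alpha* (None if there is none).
    """
    fa, ta = _frame_grid(tracks_a, time_atol)
    fb, tb = _frame_grid(tracks_b, time_atol)
    if not np.array_equal(fa, fb) or not np.allclose(ta, tb, atol=time_atol):
        raise ValueError("cohorts are on different frame grids")
    if fa.size < 2:
        raise ValueError("fewer than 2 common frames")
    sa = _per_cell_speed_matrix(tracks_a, fa, ta)[:, 1:]
    sb = _per_cell_speed_matrix(tracks_b, fb, tb)[:, 1:]
    times = ta[1:]
    p_raw = np.ones(times.size)
    for j in range(times.size):
        a = sa[:, j][~np.isnan(sa[:, j])]
        b = sb[:, j][~np.isnan(sb[:, j])]
        if a.size < 2 or b.size < 2:
            continue
        if np.ptp(np.concatenate([a, b])) == 0:
            continue
        p_raw[j] = sps.ttest_ind(a, b, equal_var=False).pvalue
    p_adj = sidak_adjust(p_raw, m=times.size)
    sig = np.nonzero(p_adj < alpha)[0]
    first = float(times[sig[0]]) if sig.size else None
    return InstantSpeedComparison(
        times=times, p_raw=p_raw, p_adj=p_adj, first_significant_time=first
    )


# ---------------------------------------------------------------------------
# rose plots

def rose_plot_data(tracks: list[Track]) -> list[tuple[str, np.ndarray]]:
    """Origin-translated coordinate paths, one (cell_id, Nx2 array) per track."""
    if not tracks:
        raise ValueError("no tracks")
    out = []
    for tr in tracks:
        xy = tr.coords()
        out.append((tr.cell_id, xy - xy[0]))
    return out
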