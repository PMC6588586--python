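"""The Fish Behaviour Index (FBI) engine.

The FBI watches two windowed metrics against a pre-treatment baseline:

* **Activity** — space utilisation: the number of tank zones (out of 9,
  the side-view plane split into horizontal and vertical thirds) visited
  per minute, expressed as a percentage.
* **Distance** — cumulative path length over the window.

Both are evaluated over rolling windows of the latest 1, 10, 20 and 30
minutes, re-evaluated once a minute.  Each metric contributes a sub-score of
up to 3 points that falls linearly with the relative deviation from its
baseline (two-sided: hypo- *and* hyper-activity count as deviation), giving
a 0-6 score, normalised to 0-1 and binned into four welfare categories:

====================  =========  =================
category              score      normalised score
====================  =========  =================
Healthy               (5, 6]     0.84-1.00
Ok                    (4, 5]     0.68-0.83
Unhealthy             (2, 4]     0.34-0.67
Abnormal              [0, 2]     0.00-0.33
====================  =========  =================

The 10-minute window is the intervention timescale: a fish rated Unhealthy
or Abnormal there raises an alert.
"""

from __future__ import annotations

import math
import warnings
from collections import deque
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .trajectory_io import Trajectory

__all__ = [
    "ZoneGrid",
    "MinuteRecord",
    "BaselineProfile",
    "FBIReading",
    "FBIMonitor",
    "DegenerateBaselineError",
    "CATEGORIES",
    "CATEGORY_COLOURS",
    "DEFAULT_WINDOWS",
    "zone_sequence",
    "minute_records",
    "compute_baseline",
    "fbi_score",
    "categorize",
    "score_records",
    "readings_to_frame",
]

DEFAULT_WINDOWS: tuple[int, ...] = (1, 10, 20, 30)

#: Categories in increasing welfare order, with the upper score edge of each bin.
CATEGORY_BINS: tuple[tuple[float, str], ...] = (
    (2.0, "Abnormal"),
    (4.0, "Unhealthy"),
    (5.0, "Ok"),
    (6.0, "Healthy"),
)
CATEGORIES: tuple[str, ...] = tuple(label for _, label in CATEGORY_BINS)

#: Report colour code for rendered timelines.
CATEGORY_COLOURS: dict[str, str] = {
    "Healthy": "#2ca02c",    # green
    "Ok": "#1f77b4",         # blue
    "Unhealthy": "#ffdf00",  # yellow
    "Abnormal": "#ff69b4",   # pink
}


class DegenerateBaselineError(ValueError):
    """Baseline has zero activity or distance and cannot anchor a score."""


@dataclass(frozen=True)
class ZoneGrid:
    """3 x 3 partition of the monitoring plane into 9 zones.

    The plane is horizontal x vertical (side view): the long horizontal tank
    axis and the vertical axis, each split into three equal sections.  Zones
    are numbered 1..9 row-major from the bottom-left; a point exactly on a
    section boundary belongs to the higher-index section.
    """

    n_horizontal: int = 3
    n_vertical: int = 3

    @property
    def n_zones(self) -> int:
        return self.n_horizontal * self.n_vertical


def zone_sequence(traj: Trajectory, grid: ZoneGrid | None = None) -> np.ndarray:
    """Per-sample zone ids (1..9); invalid samples map to 0.

    In 3D mode the horizontal axis of the plane is the tank depth (y); in 2D
    mode it is the single tracked horizontal axis (x).
    """
    grid = grid or ZoneGrid()
    g = traj.geometry
    if traj.y is not None:
        h_coord, h_extent = traj.y, g.depth_cm
    else:
        h_coord, h_extent = traj.x, g.width_cm
    ok = traj.valid_mask
    zones = np.zeros(len(traj), dtype=np.int64)
    with np.errstate(invalid="ignore"):
        col = np.floor(grid.n_horizontal * h_coord / h_extent)
        row = np.floor(grid.n_vertical * traj.z / g.height_cm)
    col = np.clip(np.nan_to_num(col), 0, grid.n_horizontal - 1).astype(np.int64)
    row = np.clip(np.nan_to_num(row), 0, grid.n_vertical - 1).astype(np.int64)
    zones[ok] = (1 + col + grid.n_horizontal * row)[ok]
    return zones


@dataclass(frozen=True)
class MinuteRecord:
    """Per-minute monitoring unit: zones visited, distance, coverage."""

    minute: int
    zones: frozenset[int]
    activity_pct: float
    distance_cm: float
    valid_fraction: float
    low_coverage: bool

    @staticmethod
    def constant(minute: int, activity_pct: float, distance_cm: float) -> "MinuteRecord":
        """Convenience for synthetic constant-behaviour series."""
        n = int(round(activity_pct / (100.0 / 9.0)))
        return MinuteRecord(minute=minute, zones=frozenset(range(1, n + 1)),
                            activity_pct=activity_pct, distance_cm=distance_cm,
                            valid_fraction=1.0, low_coverage=False)


def minute_records(
    traj: Trajectory,
    grid: ZoneGrid | None = None,
    coverage_floor: float = 0.5,
) -> list[MinuteRecord]:
    """Partition a uniform trajectory into consecutive 60 s minute records.

    A step's distance is assigned to the minute containing its interval
    midpoint.  ``valid_fraction`` is the fraction of the minute's expected
    samples that are valid; minutes below ``coverage_floor`` are flagged
    low-coverage and are excluded from window statistics downstream.
    """
    grid = grid or ZoneGrid()
    dt = traj.dt
    span = len(traj) * dt
    n_minutes = int(math.floor(span / 60.0 + 1e-9))
    if n_minutes < 1:
        raise ValueError(f"trajectory spans {span:.1f} s; need at least one full minute")

    rel_t = traj.t - traj.t[0]
    zones = zone_sequence(traj, grid)
    ok = traj.valid_mask
    sample_minute = np.floor(rel_t / 60.0 + 1e-9).astype(int)

    step_len = np.linalg.norm(np.diff(traj.positions, axis=0), axis=1)
    step_valid = ok[:-1] & ok[1:]
    step_len = np.where(step_valid, np.nan_to_num(step_len), 0.0)
    step_minute = np.floor((rel_t[:-1] + dt / 2.0) / 60.0 + 1e-9).astype(int)

    expected = 60.0 / dt
    records = []
    n_zones = grid.n_zones
    for m in range(n_minutes):
        in_bin = sample_minute == m
        visited = frozenset(int(z) for z in np.unique(zones[in_bin & ok]))
        dist = float(step_len[step_minute == m].sum())
        vf = float(np.count_nonzero(in_bin & ok) / expected)
        records.append(MinuteRecord(
            minute=m, zones=visited,
            activity_pct=100.0 * len(visited) / n_zones,
            distance_cm=dist, valid_fraction=min(vf, 1.0),
            low_coverage=vf < coverage_floor,
        ))
    return records


@dataclass
class BaselineProfile:
    """Per-timescale reference Activity and Distance from a pre-treatment recording.

    ``a0[w]`` is the mean windowed activity (%) and ``d0[w]`` the mean
    cumulative distance (cm) over all complete sliding windows of length
    ``w`` minutes.  When the baseline recording is shorter than ``w`` the
    profile falls back to the largest feasible window and scales the distance
    reference proportionally (recorded in ``fallback``).
    """

    a0: dict[int, float]
    d0: dict[int, float]
    source: str = ""
    fallback: dict[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for w in self.a0:
            if not (self.a0[w] > 0 and self.d0[w] > 0):
                raise DegenerateBaselineError(
                    f"degenerate baseline: A0={self.a0[w]:g}, D0={self.d0[w]:g} at w={w}"
                )


def compute_baseline(
    records: Sequence[MinuteRecord],
    windows: Sequence[int] = DEFAULT_WINDOWS,
    source: str = "",
) -> BaselineProfile:
    """Build a :class:`BaselineProfile` from pre-treatment minute records."""
    usable = [r for r in records if not r.low_coverage]
    n = len(records)
    if n < min(windows):
        raise ValueError(f"baseline of {n} minutes is shorter than the smallest window")
    if not usable:
        raise DegenerateBaselineError("baseline has no adequately covered minutes")

    act = np.array([r.activity_pct for r in records])
    dist = np.array([r.distance_cm for r in records])
    covered = np.array([not r.low_coverage for r in records])

    a0: dict[int, float] = {}
    d0: dict[int, float] = {}
    fallback: dict[int, int] = {}
    for w in windows:
        w_eff = min(w, n)
        if w_eff < w:
            warnings.warn(
                f"baseline of {n} min shorter than {w}-min window; "
                f"using {w_eff}-min windows with proportional distance scaling",
                stacklevel=2,
            )
            fallback[w] = w_eff
        acts, dists = [], []
        for start in range(0, n - w_eff + 1):
            sl = slice(start, start + w_eff)
            k = int(covered[sl].sum())
            if k < 0.5 * w_eff or k == 0:
                continue
            acts.append(act[sl][covered[sl]].mean())
            # scale the distance sum up to a full w-minute window equivalent
            dists.append(dist[sl][covered[sl]].sum() * (w / k))
        if not acts:
            raise DegenerateBaselineError(f"no adequately covered {w_eff}-min baseline window")
        a0[w] = float(np.mean(acts))
        d0[w] = float(np.mean(dists))
    return BaselineProfile(a0=a0, d0=d0, source=source, fallback=fallback)


def fbi_score(
    activity_pct: float,
    distance_cm: float,
    a0: float,
    d0: float,
    dev_max: float = 1.0,
) -> tuple[float, float, float]:
    """Score a windowed (Activity, Distance) pair against its baseline.

    Each metric contributes ``3 * max(0, 1 - d / dev_max)`` points where
    ``d = |m/m0 - 1|`` is the two-sided relative deviation; the total is
    clamped to [0, 6].  With the default ``dev_max`` of 1, a metric's
    sub-score reaches 0 at +-100% deviation from baseline.
    """
    if not (a0 > 0 and d0 > 0):
        raise DegenerateBaselineError("baseline values must be strictly positive")
    if not dev_max > 0:
        raise ValueError("dev_max must be positive")
    sub_a = 3.0 * max(0.0, 1.0 - abs(activity_pct / a0 - 1.0) / dev_max)
    sub_d = 3.0 * max(0.0, 1.0 - abs(distance_cm / d0 - 1.0) / dev_max)
    score = min(6.0, max(0.0, sub_a + sub_d))
    return sub_a, sub_d, score


def _round_half_away(x: float, decimals: int = 2) -> float:
    scale = 10 ** decimals
    return math.floor(abs(x) * scale + 0.5) / scale * (1 if x >= 0 else -1)


def categorize(score: float) -> tuple[float, str]:
    """Map a 0-6 score to its (normalised score, category label).

    The normalised score is score/6 reported to two decimals (round half
    away from zero), so the category edges read 0.33 / 0.67 / 0.83 / 1.00.
    """
    if not (0.0 <= score <= 6.0):
        raise ValueError(f"score {score} outside [0, 6]")
    normalized = _round_half_away(score / 6.0)
    for upper, label in CATEGORY_BINS:
        if score <= upper:
            return normalized, label
    return normalized, CATEGORY_BINS[-1][1]  # pragma: no cover


@dataclass(frozen=True)
class FBIReading:
    """One minute's evaluation at one timescale."""

    minute: int
    window_min: int
    activity_pct: Optional[float]
    distance_cm: Optional[float]
    sub_score_activity: Optional[float]
    sub_score_distance: Optional[float]
    score: Optional[float]
    normalized: Optional[float]
    category: Optional[str]
    partial: bool
    alert: bool
    no_data: bool = False


def _evaluate_window(
    minute: int,
    w: int,
    n_seen: int,
    k_covered: int,
    act_sum: float,
    dist_sum: float,
    baseline: BaselineProfile,
    dev_max: float,
    alert_window: int,
) -> FBIReading:
    """Score one window from its covered-minute running sums."""
    partial = n_seen < w
    w_avail = min(w, n_seen)
    if k_covered < 0.5 * w_avail or k_covered == 0:
        return FBIReading(minute, w, None, None, None, None, None, None, None,
                          partial=partial, alert=False, no_data=True)
    activity = act_sum / k_covered
    # scale the covered-minute distance sum up to a full-window equivalent
    distance_eq = dist_sum * (w / k_covered)
    sub_a, sub_d, score = fbi_score(activity, distance_eq,
                                    baseline.a0[w], baseline.d0[w], dev_max)
    normalized, category = categorize(score)
    alert = (w == alert_window and not partial
             and category in ("Unhealthy", "Abnormal"))
    return FBIReading(minute, w, activity, dist_sum, sub_a, sub_d, score,
                      normalized, category, partial=partial, alert=alert)


class FBIMonitor:
    """Minute-by-minute streaming FBI evaluation against a fixed baseline.

    Maintains incremental running sums per timescale; each call to
    :meth:`update` with the next :class:`MinuteRecord` returns one
    :class:`FBIReading` per timescale.  Start-up windows are scored over the
    minutes available and flagged partial; alerts on the intervention
    timescale are suppressed until its window is full.
    """

    def __init__(
        self,
        baseline: BaselineProfile,
        dev_max: float = 1.0,
        windows: Sequence[int] = DEFAULT_WINDOWS,
        alert_window: int = 10,
    ) -> None:
        missing = [w for w in windows if w not in baseline.a0]
        if missing:
            raise ValueError(f"baseline profile lacks windows {missing}")
        self.baseline = baseline
        self.dev_max = dev_max
        self.windows = tuple(windows)
        self.alert_window = alert_window
        self._buffers: dict[int, deque[MinuteRecord]] = {w: deque(maxlen=w) for w in windows}
        self._n_seen = 0

    def update(self, record: MinuteRecord) -> list[FBIReading]:
        self._n_seen += 1
        readings = []
        for w in self.windows:
            buf = self._buffers[w]
            buf.append(record)
            usable = [r for r in buf if not r.low_coverage]
            readings.append(_evaluate_window(
                record.minute, w, self._n_seen, len(usable),
                sum(r.activity_pct for r in usable),
                sum(r.distance_cm for r in usable),
                self.baseline, self.dev_max, self.alert_window,
            ))
        return readings


def score_records(
    records: Sequence[MinuteRecord],
    baseline: BaselineProfile,
    dev_max: float = 1.0,
    windows: Sequence[int] = DEFAULT_WINDOWS,
    alert_window: int = 10,
) -> list[list[FBIReading]]:
    """Batch evaluation: each minute's windows recomputed from scratch.

    Produces readings identical to streaming the same records through
    :class:`FBIMonitor`.
    """
    out = []
    for i in range(len(records)):
        row = []
        for w in windows:
            recent = records[max(0, i + 1 - w): i + 1]
            usable = [r for r in recent if not r.low_coverage]
            row.append(_evaluate_window(
                records[i].minute, w, i + 1, len(usable),
                sum(r.activity_pct for r in usable),
                sum(r.distance_cm for r in usable),
                baseline, dev_max, alert_window,
            ))
        out.append(row)
    return out


def readings_to_frame(readings: Iterable[FBIReading]) -> pd.DataFrame:
    """Flatten readings (possibly nested per-minute lists) into a DataFrame."""
    flat: list[FBIReading] = []
    for r in readings:
        if isinstance(r, FBIReading):
            flat.append(r)
        else:
            flat.extend(r)
    return pd.DataFrame([{
        "minute": r.minute,
        "window_min": r.window_min,
        "activity_pct": r.activity_pct,
        "distance_cm": r.distance_cm,
        "sub_score_activity": r.sub_score_activity,
        "sub_score_distance": r.sub_score_distance,
        "score": r.score,
        "normalized": r.normalized,
        "category": r.category,
        "partial": r.partial,
        "alert": r.alert,
        "no_data": r.no_data,
    } for r in flat])
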