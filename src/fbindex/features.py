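"""The 20-characteristic behavioural ethogram of a trajectory segment.

The characteristics cover distance (total and split by tank half), speed
(averages and maxima per half), manoeuvring (% time active, turns per
minute, fast sharp moves, accelerations/decelerations) and space use
(% time in the bottom half, % of the tank explored, % time near walls).
They are the quantities a tracking-software ethogram reports for a tank-held
fish and the input to the control-vs-pain multivariate analysis.

Kinematic definitions (uniform sampling interval dt, positions p_i):

* step speed      v_i = |p_{i+1} - p_i| / dt              (needs samples i, i+1)
* acceleration    a_i = (v_{i+1} - v_i) / dt              (needs i, i+1, i+2)
* turn angle      angle between steps i and i+1, degrees  (needs i, i+1, i+2)

Any interval touching an invalid sample is excluded from every statistic;
denominators are valid time, never wall-clock time.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .trajectory_io import Trajectory

__all__ = [
    "FeatureConfig",
    "KinematicSeries",
    "FeatureVector",
    "InsufficientDataError",
    "FEATURE_NAMES",
    "kinematics",
    "extract_features",
    "features_to_frame",
]

#: Canonical order of the 20 behavioural characteristics.
FEATURE_NAMES: tuple[str, ...] = (
    "total_distance",
    "distance_top",
    "distance_bottom",
    "avg_speed",
    "avg_speed_top",
    "avg_speed_bottom",
    "max_speed_top",
    "max_speed_bottom",
    "pct_active",
    "avg_turns_per_min",
    "pct_fast_sharp_moves",
    "avg_accel",
    "avg_decel",
    "avg_accel_top",
    "avg_accel_bottom",
    "max_accel_top",
    "max_accel_bottom",
    "pct_time_bottom",
    "pct_tank_explored",
    "pct_time_near_walls",
)


class InsufficientDataError(ValueError):
    """Segment does not contain enough valid data for a feature vector."""


@dataclass(frozen=True)
class FeatureConfig:
    """Thresholds and resolutions behind the ethogram.

    The fast-sharp-move thresholds (12 cm/s, 45 deg) are the printed
    definition of that characteristic; the remaining values are package
    conventions, surfaced here so every analysis states them explicitly.
    """

    active_speed_cms: float = 0.5     # step speed at/above which the fish counts as active
    turn_threshold_deg: float = 45.0  # heading change at/above which an interval is a turn
    fast_speed_cms: float = 12.0      # fast-sharp move: speed strictly above this ...
    sharp_angle_deg: float = 45.0     # ... at a turn angle strictly above this
    grid_cells_per_axis: int = 10     # occupancy grid for % tank explored (per axis)
    wall_margin_frac: float = 0.10    # "near wall" = within this fraction of a lateral extent
    min_valid_s: float = 60.0         # minimum valid step time for a feature vector


@dataclass
class KinematicSeries:
    """Aligned per-interval kinematics derived from one trajectory segment.

    ``speed`` has n-1 entries, ``accel`` and ``turn_deg`` n-2; the ``*_valid``
    masks mark intervals free of invalid samples.  ``step_bottom`` labels each
    speed step by the vertical midpoint of its endpoints; ``accel_bottom``
    labels each acceleration interval by its centre sample.
    """

    dt: float
    speed: np.ndarray
    step_len: np.ndarray
    step_valid: np.ndarray
    step_bottom: np.ndarray
    accel: np.ndarray
    accel_valid: np.ndarray
    accel_bottom: np.ndarray
    turn_deg: np.ndarray
    turn_valid: np.ndarray


def kinematics(traj: Trajectory) -> KinematicSeries:
    """Finite-difference speed, acceleration and turn-angle series."""
    if len(traj) < 3:
        raise InsufficientDataError("need at least 3 samples for kinematics")
    dt = traj.dt
    p = traj.positions
    ok = traj.valid_mask

    steps = np.diff(p, axis=0)
    step_len = np.linalg.norm(steps, axis=1)
    step_valid = ok[:-1] & ok[1:]
    step_len = np.where(step_valid, np.nan_to_num(step_len), np.nan)
    speed = step_len / dt

    mid_z = 0.5 * (traj.z[:-1] + traj.z[1:])
    half = traj.geometry.height_cm / 2.0
    step_bottom = mid_z < half

    accel = np.diff(speed) / dt
    accel_valid = step_valid[:-1] & step_valid[1:]
    accel = np.where(accel_valid, np.nan_to_num(accel), np.nan)
    accel_bottom = traj.z[1:-1] < half

    with np.errstate(invalid="ignore", divide="ignore"):
        dots = np.einsum("ij,ij->i", steps[:-1], steps[1:])
        norms = step_len[:-1] * step_len[1:]
        cosang = np.where(norms > 0, dots / np.where(norms > 0, norms, 1.0), 1.0)
    turn = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    turn = np.where(accel_valid, np.nan_to_num(turn), np.nan)

    if int(np.count_nonzero(accel_valid)) == 0:
        raise InsufficientDataError("no run of 3 consecutive valid samples")
    return KinematicSeries(
        dt=dt, speed=speed, step_len=step_len, step_valid=step_valid,
        step_bottom=step_bottom, accel=accel, accel_valid=accel_valid,
        accel_bottom=accel_bottom, turn_deg=turn, turn_valid=accel_valid,
    )


@dataclass
class FeatureVector:
    """The 20 named characteristics of one (fish, segment) observation.

    ``flags`` records degenerate conditions (e.g. ``empty-half:top`` when no
    valid interval fell in the top half, in which case the half-restricted
    statistics are reported as 0 so grouped matrices stay rectangular).
    """

    total_distance: float
    distance_top: float
    distance_bottom: float
    avg_speed: float
    avg_speed_top: float
    avg_speed_bottom: float
    max_speed_top: float
    max_speed_bottom: float
    pct_active: float
    avg_turns_per_min: float
    pct_fast_sharp_moves: float
    avg_accel: float
    avg_decel: float
    avg_accel_top: float
    avg_accel_bottom: float
    max_accel_top: float
    max_accel_bottom: float
    pct_time_bottom: float
    pct_tank_explored: float
    pct_time_near_walls: float
    valid_time_s: float = 0.0
    flags: tuple[str, ...] = ()

    def to_dict(self) -> dict[str, float]:
        return {name: float(getattr(self, name)) for name in FEATURE_NAMES}

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in FEATURE_NAMES], dtype=float)


def _mean_or_flag(values: np.ndarray, flag: str, flags: list[str]) -> float:
    if values.size == 0:
        flags.append(flag)
        return 0.0
    return float(values.mean())


def _max_or_flag(values: np.ndarray, flag: str, flags: list[str]) -> float:
    if values.size == 0:
        flags.append(flag)
        return 0.0
    return float(values.max())


def extract_features(traj: Trajectory, fcfg: FeatureConfig | None = None) -> FeatureVector:
    """Compute the full 20-characteristic vector for one segment.

    Raises :class:`InsufficientDataError` when the segment holds less than
    ``fcfg.min_valid_s`` of valid step time, rather than returning silent
    zeros.
    """
    fcfg = fcfg or FeatureConfig()
    kin = kinematics(traj)
    flags: list[str] = []

    sv = kin.step_valid
    n_steps = int(np.count_nonzero(sv))
    valid_time_s = n_steps * kin.dt
    if valid_time_s < fcfg.min_valid_s:
        raise InsufficientDataError(
            f"only {valid_time_s:.1f} s of valid data, need {fcfg.min_valid_s:.0f} s"
        )

    speed = kin.speed[sv]
    length = kin.step_len[sv]
    bottom = kin.step_bottom[sv]

    total_distance = float(length.sum())
    distance_bottom = float(length[bottom].sum())
    distance_top = total_distance - distance_bottom

    avg_speed = float(speed.mean())
    avg_speed_top = _mean_or_flag(speed[~bottom], "empty-half:top", flags)
    avg_speed_bottom = _mean_or_flag(speed[bottom], "empty-half:bottom", flags)
    max_speed_top = _max_or_flag(speed[~bottom], "empty-half:top-max", flags)
    max_speed_bottom = _max_or_flag(speed[bottom], "empty-half:bottom-max", flags)

    pct_active = 100.0 * float(np.count_nonzero(speed >= fcfg.active_speed_cms)) / n_steps

    tv = kin.turn_valid
    turn = kin.turn_deg[tv]
    n_turn_intervals = turn.size
    turn_count = int(np.count_nonzero(turn >= fcfg.turn_threshold_deg))
    avg_turns_per_min = turn_count / (valid_time_s / 60.0)

    # speed of the outgoing step of each turn interval
    out_speed = kin.speed[1:][tv]
    fast_sharp = int(np.count_nonzero((turn > fcfg.sharp_angle_deg) & (out_speed > fcfg.fast_speed_cms)))
    pct_fast_sharp_moves = 100.0 * fast_sharp / n_turn_intervals if n_turn_intervals else 0.0

    av = kin.accel_valid
    acc = kin.accel[av]
    acc_bottom = kin.accel_bottom[av]
    pos_acc = acc[acc > 0]
    neg_acc = acc[acc < 0]
    avg_accel = _mean_or_flag(pos_acc, "no-acceleration", flags)
    avg_decel = _mean_or_flag(-neg_acc, "no-deceleration", flags)
    avg_accel_top = _mean_or_flag(acc[(acc > 0) & ~acc_bottom], "empty-half:top-accel", flags)
    avg_accel_bottom = _mean_or_flag(acc[(acc > 0) & acc_bottom], "empty-half:bottom-accel", flags)
    max_accel_top = _max_or_flag(acc[(acc > 0) & ~acc_bottom], "empty-half:top-accel-max", flags)
    max_accel_bottom = _max_or_flag(acc[(acc > 0) & acc_bottom], "empty-half:bottom-accel-max", flags)

    ok = traj.valid_mask
    n_ok = int(np.count_nonzero(ok))
    g = traj.geometry
    pct_time_bottom = 100.0 * float(np.count_nonzero(traj.z[ok] < g.height_cm / 2.0)) / n_ok

    pct_tank_explored = _occupancy_pct(traj, fcfg.grid_cells_per_axis)
    pct_time_near_walls = _near_wall_pct(traj, fcfg.wall_margin_frac)

    return FeatureVector(
        total_distance=total_distance,
        distance_top=distance_top,
        distance_bottom=distance_bottom,
        avg_speed=avg_speed,
        avg_speed_top=avg_speed_top,
        avg_speed_bottom=avg_speed_bottom,
        max_speed_top=max_speed_top,
        max_speed_bottom=max_speed_bottom,
        pct_active=pct_active,
        avg_turns_per_min=avg_turns_per_min,
        pct_fast_sharp_moves=pct_fast_sharp_moves,
        avg_accel=avg_accel,
        avg_decel=avg_decel,
        avg_accel_top=avg_accel_top,
        avg_accel_bottom=avg_accel_bottom,
        max_accel_top=max_accel_top,
        max_accel_bottom=max_accel_bottom,
        pct_time_bottom=pct_time_bottom,
        pct_tank_explored=pct_tank_explored,
        pct_time_near_walls=pct_time_near_walls,
        valid_time_s=valid_time_s,
        flags=tuple(flags),
    )


def _occupancy_pct(traj: Trajectory, cells_per_axis: int) -> float:
    """% of occupancy-grid cells visited by at least one valid sample."""
    g = traj.geometry
    ok = traj.valid_mask
    axes = [(traj.x[ok], g.width_cm), (traj.z[ok], g.height_cm)]
    if traj.y is not None:
        axes.insert(1, (traj.y[ok], g.depth_cm))
    idx = []
    for coords, extent in axes:
        cell = np.floor(cells_per_axis * coords / extent).astype(int)
        idx.append(np.clip(cell, 0, cells_per_axis - 1))
    flat = idx[0]
    for more in idx[1:]:
        flat = flat * cells_per_axis + more
    n_cells = cells_per_axis ** len(axes)
    return 100.0 * len(np.unique(flat)) / n_cells


def _near_wall_pct(traj: Trajectory, margin_frac: float) -> float:
    """% of valid samples within the margin of any lateral (vertical) wall.

    Floor and surface are excluded: vertical preference is already captured
    by % time in the bottom half.
    """
    g = traj.geometry
    ok = traj.valid_mask
    near = (traj.x[ok] < margin_frac * g.width_cm) | (traj.x[ok] > (1 - margin_frac) * g.width_cm)
    if traj.y is not None:
        near |= (traj.y[ok] < margin_frac * g.depth_cm) | (traj.y[ok] > (1 - margin_frac) * g.depth_cm)
    return 100.0 * float(np.count_nonzero(near)) / int(np.count_nonzero(ok))


def features_to_frame(rows: Iterable[tuple[dict, FeatureVector]]) -> pd.DataFrame:
    """Assemble (metadata, FeatureVector) pairs into a tidy feature table."""
    records = []
    for meta, fv in rows:
        rec = dict(meta)
        rec.update(fv.to_dict())
        rec["valid_time_s"] = fv.valid_time_s
        rec["flags"] = ";".join(fv.flags)
        records.append(rec)
    return pd.DataFrame.from_records(records)
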