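"""Reading, validation, calibration and resampling of fish trajectories.

Coordinate convention: origin at a bottom corner of the tank, ``x`` along the
20 cm width, ``y`` along the 30 cm depth (the long horizontal axis), ``z``
vertical.  All coordinates in cm, time in seconds.  A trajectory is a fixed
set of parallel numpy arrays plus a per-sample validity code so that missing
or interpolated samples are never silently mixed with observed ones.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "TankGeometry",
    "CsvDialect",
    "Trajectory",
    "TrajectoryError",
    "INVALID",
    "OBSERVED",
    "INTERPOLATED",
    "read_trajectory",
    "write_trajectory",
    "resample_and_fill",
    "clip_to_tank",
]

# validity codes for each sample
INVALID = 0       # missing / unusable; excluded from every statistic
OBSERVED = 1      # measured sample
INTERPOLATED = 2  # gap-filled sample, usable but flagged

_VALID_TO_TEXT = {INVALID: "0", OBSERVED: "1", INTERPOLATED: "interp"}
_TEXT_TO_VALID = {"0": INVALID, "1": OBSERVED, "interp": INTERPOLATED}


class TrajectoryError(ValueError):
    """Raised for unreadable, degenerate or inconsistent trajectory input."""


@dataclass(frozen=True)
class TankGeometry:
    """Axis-aligned tank box; origin at the front-bottom-left corner.

    Defaults are the 20 x 30 x 20 cm glass tanks of the individual-housing
    monitoring setup.
    """

    width_cm: float = 20.0   # x, short horizontal axis
    depth_cm: float = 30.0   # y, long horizontal axis
    height_cm: float = 20.0  # z, vertical axis

    def __post_init__(self) -> None:
        for name in ("width_cm", "depth_cm", "height_cm"):
            if not getattr(self, name) > 0:
                raise ValueError(f"tank extent {name} must be strictly positive")

    @property
    def extents(self) -> tuple[float, float, float]:
        return (self.width_cm, self.depth_cm, self.height_cm)

    @property
    def diagonal_cm(self) -> float:
        return math.sqrt(sum(e * e for e in self.extents))


@dataclass(frozen=True)
class CsvDialect:
    """Column naming and unit calibration for delimited trajectory files.

    ``scale_*`` convert raw file units to cm (e.g. 0.05 cm/px for pixel
    input); the default 1.0 means the file is already in cm.  For 2D files
    (single camera) supply only two coordinate columns; the second one is the
    vertical axis.
    """

    time_col: str = "time_s"
    x_col: str = "x_cm"
    y_col: Optional[str] = "y_cm"
    z_col: Optional[str] = "z_cm"
    scale_x: float = 1.0
    scale_y: float = 1.0
    scale_z: float = 1.0
    delimiter: Optional[str] = None  # None -> sniff comma vs tab
    monotone_tol_s: float = 1e-6


@dataclass
class Trajectory:
    """Timestamped positions of one fish inside a known tank.

    ``valid`` holds per-sample codes (0 invalid, 1 observed, 2 interpolated).
    ``y`` is ``None`` in 2D (single-camera) mode, where only the horizontal
    ``x`` and vertical ``z`` axes are tracked.
    """

    t: np.ndarray
    x: np.ndarray
    z: np.ndarray
    geometry: TankGeometry
    y: Optional[np.ndarray] = None
    valid: np.ndarray = field(default=None)  # type: ignore[assignment]
    rate_hz: Optional[float] = None
    source: str = ""
    report: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.z = np.asarray(self.z, dtype=float)
        if self.y is not None:
            self.y = np.asarray(self.y, dtype=float)
        if self.valid is None:
            self.valid = np.full(self.t.shape, OBSERVED, dtype=np.uint8)
        else:
            self.valid = np.asarray(self.valid, dtype=np.uint8)
        n = len(self.t)
        arrays = [self.x, self.z, self.valid] + ([self.y] if self.y is not None else [])
        if any(len(a) != n for a in arrays):
            raise TrajectoryError("trajectory arrays have mismatched lengths")
        if n and (not np.all(np.isfinite(self.t)) or self.t[0] < 0):
            raise TrajectoryError("timestamps must be finite and non-negative")
        if n > 1 and np.any(np.diff(self.t) <= 0):
            bad = int(np.argmax(np.diff(self.t) <= 0)) + 1
            raise TrajectoryError(f"timestamps not strictly increasing at row {bad}")

    # -- basic introspection ------------------------------------------------
    def __len__(self) -> int:
        return len(self.t)

    @property
    def mode(self) -> str:
        return "3d" if self.y is not None else "2d"

    @property
    def valid_mask(self) -> np.ndarray:
        return self.valid != INVALID

    @property
    def n_valid(self) -> int:
        return int(np.count_nonzero(self.valid_mask))

    @property
    def dt(self) -> float:
        """Sampling interval; requires a uniform grid (post-resampling)."""
        if len(self.t) < 2:
            raise TrajectoryError("need at least 2 samples for dt")
        diffs = np.diff(self.t)
        if not np.allclose(diffs, diffs[0], rtol=1e-6, atol=1e-9):
            raise TrajectoryError("trajectory is not uniformly sampled; resample first")
        return float(diffs[0])

    @property
    def positions(self) -> np.ndarray:
        """(n, 2) or (n, 3) position array; column order x[, y], z."""
        cols = [self.x] + ([self.y] if self.y is not None else []) + [self.z]
        return np.column_stack(cols)

    @property
    def duration_s(self) -> float:
        """Covered time span: each sample represents one interval dt."""
        if len(self.t) < 2:
            return 0.0
        return float(self.t[-1] - self.t[0]) + self.dt


def _sniff_delimiter(path: Path) -> str:
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
    return "\t" if header.count("\t") > header.count(",") else ","


def read_trajectory(
    path: str | Path,
    dialect: CsvDialect | None = None,
    geometry: TankGeometry | None = None,
) -> Trajectory:
    """Read a delimited trajectory file into a cm-scaled :class:`Trajectory`.

    Rows whose coordinates cannot be parsed are kept but flagged invalid;
    rows with an unparseable time value are dropped (they cannot be placed on
    the time axis) and counted in the parse report.  Timestamps must be
    strictly increasing within ``dialect.monotone_tol_s``.
    """
    path = Path(path)
    if not path.exists():
        raise TrajectoryError(f"trajectory file not found: {path}")
    dialect = dialect or CsvDialect()
    geometry = geometry or TankGeometry()

    sep = dialect.delimiter or _sniff_delimiter(path)
    try:
        df = pd.read_csv(path, sep=sep)
    except pd.errors.EmptyDataError:
        raise TrajectoryError(f"no data rows in {path}") from None
    if df.empty:
        raise TrajectoryError(f"no data rows in {path}")
    if dialect.time_col not in df.columns:
        raise TrajectoryError(
            f"no time column {dialect.time_col!r} in {path} (columns: {list(df.columns)})"
        )

    coord_cols: list[tuple[str, float]] = []
    for col, scale in ((dialect.x_col, dialect.scale_x),
                       (dialect.y_col, dialect.scale_y),
                       (dialect.z_col, dialect.scale_z)):
        if col is not None and col in df.columns:
            coord_cols.append((col, scale))
    if len(coord_cols) < 2:
        raise TrajectoryError(f"need 2 or 3 coordinate columns, found {len(coord_cols)}")

    rows_read = len(df)
    t = pd.to_numeric(df[dialect.time_col], errors="coerce").to_numpy(dtype=float)
    time_ok = np.isfinite(t)
    df = df.loc[time_ok]
    t = t[time_ok]

    dts = np.diff(t)
    if np.any(dts <= -dialect.monotone_tol_s):
        bad = int(np.argmax(dts <= -dialect.monotone_tol_s)) + 1
        raise TrajectoryError(f"non-monotone timestamps: row {bad} (t={t[bad]:g} after {t[bad - 1]:g})")
    # tolerate tiny jitter by dropping exact/near duplicates
    keep = np.concatenate([[True], dts > 0])
    df, t = df.loc[keep], t[keep]

    coords = []
    for col, scale in coord_cols:
        coords.append(pd.to_numeric(df[col], errors="coerce").to_numpy(dtype=float) * scale)
    coord_arr = np.column_stack(coords)
    row_ok = np.all(np.isfinite(coord_arr), axis=1)
    valid = np.where(row_ok, OBSERVED, INVALID).astype(np.uint8)
    if "valid" in df.columns:
        file_codes = df["valid"].astype(str).str.strip().map(_TEXT_TO_VALID)
        file_codes = file_codes.fillna(OBSERVED).to_numpy(dtype=np.uint8)
        valid = np.where(row_ok, file_codes, INVALID).astype(np.uint8)
    coord_arr[~row_ok] = np.nan

    if coord_arr.shape[1] == 3:
        x, y, z = coord_arr.T
    else:
        # 2D mode: (horizontal, vertical)
        x, z = coord_arr.T
        y = None

    report = {
        "rows_read": rows_read,
        "rows_time_dropped": int(rows_read - time_ok.sum()),
        "rows_flagged_invalid": int(np.count_nonzero(valid == INVALID)),
    }
    rate = None
    if len(t) > 1:
        med = float(np.median(np.diff(t)))
        if med > 0:
            rate = 1.0 / med
    return Trajectory(t=t, x=x, y=y, z=z, valid=valid, geometry=geometry,
                      rate_hz=rate, source=str(path), report=report)


def write_trajectory(traj: Trajectory, path: str | Path, delimiter: str = ",") -> None:
    """Write in the standard schema (``time_s,x_cm[,y_cm],z_cm,valid``)."""
    cols: dict[str, object] = {"time_s": traj.t, "x_cm": traj.x}
    if traj.y is not None:
        cols["y_cm"] = traj.y
    cols["z_cm"] = traj.z
    cols["valid"] = [_VALID_TO_TEXT[int(v)] for v in traj.valid]
    df = pd.DataFrame(cols)
    df.to_csv(path, sep=delimiter, index=False, float_format="%.10g")


def resample_and_fill(
    traj: Trajectory, target_rate_hz: float, max_gap_s: float = 2.0
) -> Trajectory:
    """Resample onto a uniform grid, filling short gaps by linear interpolation.

    Grid points landing on (within half a sample of) an existing non-invalid
    sample keep that sample's validity code; points inside a gap no longer
    than ``max_gap_s`` between valid samples are linearly interpolated and
    flagged ``INTERPOLATED``; anything else is ``INVALID``.  The covered span
    is preserved to within one sample.
    """
    if target_rate_hz <= 0:
        raise ValueError("target_rate_hz must be positive")
    mask = traj.valid_mask
    if np.count_nonzero(mask) < 2:
        raise TrajectoryError("need at least 2 valid points to resample")

    dt = 1.0 / target_rate_hz
    t0, t1 = float(traj.t[0]), float(traj.t[-1])
    n = int(math.floor((t1 - t0) / dt + 1e-9)) + 1
    grid = t0 + np.arange(n) * dt

    tv = traj.t[mask]
    codes_v = traj.valid[mask]
    axes_in = [traj.x, traj.z] + ([traj.y] if traj.y is not None else [])
    axes_out = [np.interp(grid, tv, a[mask]) for a in axes_in]

    valid = np.full(n, INVALID, dtype=np.uint8)
    # nearest valid original sample: keep its code if it coincides with the grid
    idx_near = np.clip(np.searchsorted(tv, grid), 1, len(tv) - 1)
    left, right = tv[idx_near - 1], tv[idx_near]
    nearest = np.where(grid - left <= right - grid, idx_near - 1, idx_near)
    coincides = np.abs(tv[nearest] - grid) <= dt / 2 + 1e-12
    valid[coincides] = codes_v[nearest[coincides]]
    # interpolate inside short enough gaps
    inside = (grid >= tv[0]) & (grid <= tv[-1])
    gap = right - left
    fillable = inside & ~coincides & (gap <= max_gap_s + 1e-12)
    valid[fillable] = INTERPOLATED
    for a in axes_out:
        a[valid == INVALID] = np.nan

    x_out = axes_out[0]
    z_out = axes_out[1]
    y_out = axes_out[2] if traj.y is not None else None
    report = dict(traj.report)
    report["resampled_to_hz"] = target_rate_hz
    report["interpolated_samples"] = int(np.count_nonzero(valid == INTERPOLATED))
    return Trajectory(t=grid, x=x_out, y=y_out, z=z_out, valid=valid,
                      geometry=traj.geometry, rate_hz=target_rate_hz,
                      source=traj.source, report=report)


def clip_to_tank(traj: Trajectory) -> tuple[Trajectory, int]:
    """Clamp coordinates into the tank box; returns (clipped, n_clamped).

    Clamping never changes validity flags: an out-of-bounds observed sample
    stays observed, it is merely moved onto the nearest wall.
    """
    g = traj.geometry
    pairs = [(traj.x, g.width_cm), (traj.z, g.height_cm)]
    if traj.y is not None:
        pairs.append((traj.y, g.depth_cm))
    clamped = np.zeros(len(traj), dtype=bool)
    new_axes = []
    for arr, extent in pairs:
        out = np.clip(arr, 0.0, extent)
        with np.errstate(invalid="ignore"):
            clamped |= np.nan_to_num(np.abs(out - arr), nan=0.0) > 0
        new_axes.append(out)
    x_new, z_new = new_axes[0], new_axes[1]
    y_new = new_axes[2] if traj.y is not None else None
    count = int(np.count_nonzero(clamped))
    report = dict(traj.report)
    report["clamped_samples"] = count
    out_traj = Trajectory(t=traj.t.copy(), x=x_new, y=y_new, z=z_new,
                          valid=traj.valid.copy(), geometry=g,
                          rate_hz=traj.rate_hz, source=traj.source, report=report)
    return out_traj, count
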