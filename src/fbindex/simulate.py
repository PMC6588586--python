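"""Synthetic tank-confined fish behaviour.

A two-state (active/paused) bout process at 1 s granularity drives a
correlated random walk in the horizontal plane plus damped mean-reverting
vertical motion toward a preferred depth, all inside a reflecting tank box.
The healthy parameterisation produces constant mid-water swimming with high
tank coverage; the pain-like parameterisations reproduce the three
signatures of a noxious procedure in zebrafish — reduced swimming speed,
increased use of the bottom half, reduced tank exploration — with scenario
schedules over the standard observation windows (pre-treatment and 1, 2, 3,
6 h after treatment, 25 min each).

The dynamics are a simulator convention, chosen as the simplest process able
to vary those three result-bearing behaviours independently; the pain-effect
magnitudes are fixture conventions producing clear category separation, not
estimates of real effect sizes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterator, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import signal, stats

from .trajectory_io import TankGeometry, Trajectory, write_trajectory

__all__ = [
    "BehaviourParams",
    "ScenarioPreset",
    "SimulationError",
    "OBSERVATION_WINDOWS",
    "DEFAULT_GROUPS",
    "HEALTHY",
    "PAIN",
    "simulate",
    "preset",
    "available_scenarios",
    "blend",
    "generate_cohort",
    "iter_cohort",
    "cohort_manifest",
]


class SimulationError(ValueError):
    """Infeasible simulation parameters."""


#: Standard observation windows: pre-treatment then 1, 2, 3, 6 h after.
OBSERVATION_WINDOWS: tuple[str, ...] = ("pre", "1h", "2h", "3h", "6h")

#: The seven-group study design template.
DEFAULT_GROUPS: tuple[str, ...] = (
    "control", "sham", "fin_clip", "pit_tag", "acid_1", "acid_5", "acid_10",
)


@dataclass(frozen=True)
class BehaviourParams:
    """Parameters of the two-state correlated-walk behaviour model.

    ``heading_persistence`` is the autocorrelation of the horizontal heading
    direction over 1 s; ``depth_attraction`` the reversion rate (1/s) of
    depth toward ``preferred_depth_frac`` x tank height; ``p_pause`` /
    ``p_resume`` the per-second transition probabilities of the active/paused
    bout chain.
    """

    mean_speed: float = 6.0            # cm/s, horizontal swim speed while active
    speed_sd: float = 2.0              # cm/s
    heading_persistence: float = 0.85  # in [0, 1)
    preferred_depth_frac: float = 0.55
    depth_attraction: float = 0.25     # 1/s
    vertical_speed_sd: float = 1.5     # cm/s, stationary sd of vertical velocity
    p_pause: float = 0.05              # per second, active -> paused
    p_resume: float = 0.5              # per second, paused -> active
    pause_jitter_cm: float = 2e-4      # per-step positional jitter while paused
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.mean_speed < 0 or self.speed_sd < 0:
            raise ValueError("speeds must be non-negative")
        if not (0.0 <= self.heading_persistence < 1.0):
            raise ValueError("heading_persistence must lie in [0, 1)")
        if not (0.0 <= self.preferred_depth_frac <= 1.0):
            raise ValueError("preferred_depth_frac must lie in [0, 1]")
        for p in (self.p_pause, self.p_resume):
            if not (0.0 <= p <= 1.0):
                raise ValueError("transition probabilities must lie in [0, 1]")


HEALTHY = BehaviourParams()

#: Reference pain-like parameter set (fin-clip severity): slower swimming,
#: bottom dwelling with tight depth holding, tripled pausing.
PAIN = replace(
    HEALTHY,
    mean_speed=HEALTHY.mean_speed * 0.4,
    speed_sd=HEALTHY.speed_sd * 0.4,
    preferred_depth_frac=0.15,
    depth_attraction=1.0,
    vertical_speed_sd=0.6,
    p_pause=HEALTHY.p_pause * 3.0,
)


def blend(a: BehaviourParams, b: BehaviourParams, frac: float) -> BehaviourParams:
    """Linear interpolation between two parameter sets (frac=0 -> a, 1 -> b)."""
    mix = lambda u, v: (1.0 - frac) * u + frac * v
    return replace(
        a,
        mean_speed=mix(a.mean_speed, b.mean_speed),
        speed_sd=mix(a.speed_sd, b.speed_sd),
        heading_persistence=mix(a.heading_persistence, b.heading_persistence),
        preferred_depth_frac=mix(a.preferred_depth_frac, b.preferred_depth_frac),
        depth_attraction=mix(a.depth_attraction, b.depth_attraction),
        vertical_speed_sd=mix(a.vertical_speed_sd, b.vertical_speed_sd),
        p_pause=mix(a.p_pause, b.p_pause),
        p_resume=mix(a.p_resume, b.p_resume),
    )


@dataclass(frozen=True)
class ScenarioPreset:
    """Behaviour schedule over the observation windows for one treatment."""

    label: str
    schedule: dict[str, BehaviourParams]

    def params_at(self, window: str) -> BehaviourParams:
        if window not in self.schedule:
            raise KeyError(f"unknown observation window {window!r}")
        return self.schedule[window]


def _schedule(post: dict[str, BehaviourParams]) -> dict[str, BehaviourParams]:
    sched = {w: HEALTHY for w in OBSERVATION_WINDOWS}
    sched.update(post)
    sched["pre"] = HEALTHY  # every scenario starts from healthy behaviour
    return sched


_TOP_DWELLING = replace(PAIN, preferred_depth_frac=0.85)

_PRESETS: dict[str, ScenarioPreset] = {
    # undisturbed / handled-only fish: time-invariant healthy behaviour
    "control": ScenarioPreset("control", _schedule({})),
    "sham": ScenarioPreset("sham", _schedule({})),
    # fin clip: full effect from 1 h, no recovery within the experiment
    "fin_clip": ScenarioPreset("fin_clip", _schedule(
        {"1h": PAIN, "2h": PAIN, "3h": PAIN, "6h": PAIN})),
    # PIT tag: transient effect peaking around 2 h
    "pit_tag": ScenarioPreset("pit_tag", _schedule(
        {"1h": blend(HEALTHY, PAIN, 0.5), "2h": PAIN,
         "3h": blend(HEALTHY, PAIN, 0.5), "6h": HEALTHY})),
    # 1% acid: mild, transient
    "acid_1": ScenarioPreset("acid_1", _schedule(
        {"2h": blend(HEALTHY, PAIN, 0.4), "3h": blend(HEALTHY, PAIN, 0.4)})),
    # 5%/10% acid: full effect through 3 h, recovered between 3 and 6 h
    "acid_5": ScenarioPreset("acid_5", _schedule(
        {"1h": PAIN, "2h": PAIN, "3h": PAIN, "6h": HEALTHY})),
    "acid_10": ScenarioPreset("acid_10", _schedule(
        {"1h": PAIN, "2h": PAIN, "3h": PAIN, "6h": HEALTHY})),
    # 10% acid top-dwelling variant: some fish shift to the surface instead
    "acid_10_top": ScenarioPreset("acid_10_top", _schedule(
        {"1h": _TOP_DWELLING, "2h": _TOP_DWELLING, "3h": _TOP_DWELLING, "6h": HEALTHY})),
    # effective analgesia rescues fin-clip behaviour to healthy-like
    "fin_clip_lidocaine": ScenarioPreset("fin_clip_lidocaine", _schedule({})),
    "fin_clip_flunixin_8": ScenarioPreset("fin_clip_flunixin_8", _schedule({})),
    "fin_clip_morphine_48": ScenarioPreset("fin_clip_morphine_48", _schedule({})),
}


def preset(label: str) -> ScenarioPreset:
    """Look up a treatment scenario by label."""
    try:
        return _PRESETS[label]
    except KeyError:
        raise ValueError(
            f"unknown scenario {label!r}; known: {sorted(_PRESETS)}"
        ) from None


def available_scenarios() -> list[str]:
    return sorted(_PRESETS)


def _bout_states(n_sec: int, p_pause: float, p_resume: float, rng: np.random.Generator) -> np.ndarray:
    """Per-second active (True) / paused (False) Markov chain, starting active."""
    u = rng.random(n_sec)
    states = np.empty(n_sec, dtype=bool)
    s = True
    for i in range(n_sec):
        if s:
            s = not (u[i] < p_pause)
        else:
            s = u[i] < p_resume
        states[i] = s
    return states


def _truncated_speeds(mean: float, sd: float, size: int, rng: np.random.Generator) -> np.ndarray:
    if sd == 0:
        return np.full(size, mean)
    a = -mean / sd  # truncate at zero
    return stats.truncnorm.rvs(a, np.inf, loc=mean, scale=sd, size=size, random_state=rng)


def _depth_path(
    n: int, dt: float, z_target: float, z0: float, v0: float,
    attraction: float, v_sd: float, rng: np.random.Generator,
) -> np.ndarray:
    """Damped second-order mean reversion of depth toward ``z_target``.

    Discretised dynamics with unit velocity damping gamma = 1/s:
        v' = -gamma v + gamma * attraction * (z* - z) + noise,  z' = v
    which as a recursion in z alone is AR(2); evaluated with lfilter.
    """
    gamma = 1.0
    k = attraction * gamma
    sigma = v_sd * math.sqrt(2.0 * gamma)
    a1 = -(2.0 - gamma * dt)
    a2 = 1.0 - gamma * dt + k * dt * dt
    drive = k * dt * dt * z_target + sigma * dt ** 1.5 * rng.standard_normal(max(n - 2, 0))
    z1 = z0 + v0 * dt
    if n <= 2:
        return np.array([z0, z1][:n])
    zi = signal.lfiltic([1.0], [1.0, a1, a2], y=[z1, z0])
    rest, _ = signal.lfilter([1.0], [1.0, a1, a2], drive, zi=zi)
    return np.concatenate([[z0, z1], rest])


def _fold(pos: np.ndarray, extent: float) -> np.ndarray:
    """Reflect an unbounded path into [0, extent] (billiard unfolding)."""
    r = np.mod(pos, 2.0 * extent)
    return np.where(r > extent, 2.0 * extent - r, r)


def simulate(
    params: BehaviourParams,
    duration_s: float,
    rate_hz: float = 25.0,
    geometry: TankGeometry | None = None,
    seed: Optional[int] = None,
) -> Trajectory:
    """Simulate one recording; identical seed and params give identical output."""
    if duration_s < 60:
        raise SimulationError("duration must be at least 60 s")
    geometry = geometry or TankGeometry()
    dt = 1.0 / rate_hz
    if (params.mean_speed + 4.0 * params.speed_sd) * dt > geometry.diagonal_cm:
        raise SimulationError(
            "mean_speed so large that a single step could exceed the tank diagonal"
        )
    seed = seed if seed is not None else params.seed
    rng = np.random.default_rng(seed)

    n = int(round(duration_s * rate_hz))
    n_steps = n - 1
    t = np.arange(n) * dt

    n_sec = int(math.ceil(n * dt))
    active_sec = _bout_states(n_sec, params.p_pause, params.p_resume, rng)
    step_sec = np.minimum(((np.arange(n_steps) + 0.5) * dt).astype(int), n_sec - 1)
    active = active_sec[step_sec]

    speeds = _truncated_speeds(params.mean_speed, params.speed_sd, n_steps, rng)
    rho = max(params.heading_persistence, 1e-6)
    sd_turn = math.sqrt(max(-2.0 * math.log(rho), 0.0) * dt)
    theta = rng.uniform(0, 2 * math.pi) + np.cumsum(rng.normal(0.0, sd_turn, n_steps))
    dx_active = speeds * dt * np.cos(theta)
    dy_active = speeds * dt * np.sin(theta)

    g = geometry
    z_target = params.preferred_depth_frac * g.height_cm
    z_sd = (params.vertical_speed_sd / math.sqrt(params.depth_attraction)
            if params.depth_attraction > 0 else 0.0)
    z0 = float(np.clip(z_target + rng.normal(0, z_sd or 0.0), 0.05 * g.height_cm, 0.95 * g.height_cm))
    v0 = float(rng.normal(0, params.vertical_speed_sd))
    # depth advances only while active (time-changed path), so the
    # mean-reversion pull always acts from the fish's actual depth
    n_active = int(np.count_nonzero(active))
    z_free = _depth_path(n_active + 1, dt, z_target, z0, v0,
                         params.depth_attraction, params.vertical_speed_sd, rng)
    z_index = np.concatenate([[0], np.cumsum(active)])
    z_base = z_free[z_index]

    jitter = rng.normal(0.0, params.pause_jitter_cm, size=(n_steps, 3))
    dx = np.where(active, dx_active, jitter[:, 0])
    dy = np.where(active, dy_active, jitter[:, 1])
    dz_jitter = np.where(active, 0.0, jitter[:, 2])

    x0 = rng.uniform(0.1, 0.9) * g.width_cm
    y0 = rng.uniform(0.1, 0.9) * g.depth_cm
    x = _fold(x0 + np.concatenate([[0.0], np.cumsum(dx)]), g.width_cm)
    y = _fold(y0 + np.concatenate([[0.0], np.cumsum(dy)]), g.depth_cm)
    z = _fold(z_base + np.concatenate([[0.0], np.cumsum(dz_jitter)]), g.height_cm)

    return Trajectory(t=t, x=x, y=y, z=z, geometry=geometry, rate_hz=rate_hz,
                      source=f"simulated:{seed}")


# ---------------------------------------------------------------------------
# Cohorts shaped like the seven-group study design


def _fish_window_seed(master_seed: int, fish_index: int, window_index: int) -> int:
    ss = np.random.SeedSequence([int(master_seed), fish_index, window_index])
    return int(ss.generate_state(1)[0] % (2 ** 31))


@dataclass(frozen=True)
class CohortItem:
    """Manifest row for one simulated recording."""

    file: str
    fish_id: str
    group: str
    window: str
    seed: int


def cohort_manifest(
    groups: Sequence[str] = DEFAULT_GROUPS,
    n_per_group: int = 7,
    windows: Sequence[str] = OBSERVATION_WINDOWS,
    master_seed: int = 0,
) -> list[CohortItem]:
    """Deterministic manifest of a cohort (no simulation performed)."""
    items = []
    fish_index = 0
    for group in groups:
        preset(group)  # validate label early
        for i in range(n_per_group):
            fish_id = f"{group}_{i + 1:02d}"
            for wi, window in enumerate(windows):
                items.append(CohortItem(
                    file=f"{fish_id}_{window}.csv",
                    fish_id=fish_id, group=group, window=window,
                    seed=_fish_window_seed(master_seed, fish_index, wi),
                ))
            fish_index += 1
    return items


def iter_cohort(
    groups: Sequence[str] = DEFAULT_GROUPS,
    n_per_group: int = 7,
    windows: Sequence[str] = OBSERVATION_WINDOWS,
    master_seed: int = 0,
    duration_s: float = 1500.0,
    rate_hz: float = 25.0,
    geometry: TankGeometry | None = None,
) -> Iterator[tuple[CohortItem, Trajectory]]:
    """Lazily simulate a cohort, yielding (manifest item, trajectory) pairs.

    Defaults mirror the study template: 7 groups x 7 fish x 5 observation
    windows of 25 min at 25 Hz (37 500 samples per recording).
    """
    for item in cohort_manifest(groups, n_per_group, windows, master_seed):
        params = preset(item.group).params_at(item.window)
        yield item, simulate(params, duration_s, rate_hz, geometry, seed=item.seed)


def generate_cohort(
    out_dir: str | Path,
    groups: Sequence[str] = DEFAULT_GROUPS,
    n_per_group: int = 7,
    windows: Sequence[str] = OBSERVATION_WINDOWS,
    master_seed: int = 0,
    duration_s: float = 1500.0,
    rate_hz: float = 25.0,
    geometry: TankGeometry | None = None,
) -> pd.DataFrame:
    """Simulate a cohort to trajectory files plus a manifest; returns the manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for item, traj in iter_cohort(groups, n_per_group, windows, master_seed,
                                  duration_s, rate_hz, geometry):
        write_trajectory(traj, out_dir / item.file)
        rows.append({"file": item.file, "fish_id": item.fish_id,
                     "group": item.group, "window": item.window, "seed": item.seed})
    manifest = pd.DataFrame(rows, columns=["file", "fish_id", "group", "window", "seed"])
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest
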