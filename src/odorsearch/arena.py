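"""Trial orchestration: arena geometry, adjudication, batches, calibration.

A trial places one agent at the start of a rectangular arena (default
2.5 m x 4 m, start at (0, 0), source at (0, 2), wind blowing in -y) and runs
it until the first of:

* success      — the agent enters the 20 cm disk around the source,
* fail_exit    — the agent leaves the arena,
* fail_timeout — the reactive wall-clock cap (300 s) or the infotaxis
                 action cap (125 steps) is reached.

Reactive agents are stepped on a fixed 0.1 s tick; detections are Poisson
samples of the plume rate once per tick and any detection restarts a surge.
The infotaxis agent moves on the belief lattice, observing a detection count
after every action and updating its posterior.

Everything is a pure function of configuration and seed.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from . import infotaxis as it
from . import reactive as rx
from .plume import (DoseLevel, PlumeParams, get_dose, mean_detection_rate,
                    sample_detections)

__all__ = [
    "ArenaConfig",
    "Trajectory",
    "run_trial",
    "run_batch",
    "calibrate_emission",
]

STRATEGIES = ("sp", "za", "ze", "it")

TRAJECTORY_COLUMNS = ["t", "x", "y", "heading_deg", "mode", "n_detections"]


@dataclass(frozen=True)
class ArenaConfig:
    """Arena geometry, adjudication rules and simulation granularity."""

    x_min: float = -1.25
    x_max: float = 1.25
    y_min: float = -1.0
    y_max: float = 3.0
    start: tuple[float, float] = (0.0, 0.0)
    source: tuple[float, float] = (0.0, 2.0)
    success_radius: float = 0.20
    tick: float = 0.1          # reactive simulation step, s
    max_duration: float = 600.0  # reactive wall-clock cap, s
    odometry_noise: float = 0.0  # per-tick position jitter SD, m (off by default)

    def __post_init__(self) -> None:
        if not self.success_radius > 0:
            raise ValueError("success_radius must be positive")
        for p, name in ((self.start, "start"), (self.source, "source")):
            if not self.contains(p):
                raise ValueError(f"{name} must lie inside the arena")

    def contains(self, pos) -> bool:
        x, y = float(pos[0]), float(pos[1])
        return self.x_min <= x <= self.x_max and self.y_min <= y <= self.y_max

    def source_distance(self, pos) -> float:
        return math.hypot(pos[0] - self.source[0], pos[1] - self.source[1])


@dataclass
class Trajectory:
    """One trial: timestamped path samples plus labels and outcome.

    ``data`` has columns t, x, y, heading_deg, mode, n_detections; ``outcome``
    is 'success', 'fail_exit' or 'fail_timeout'.
    """

    data: pd.DataFrame
    strategy: str
    dose: str
    seed: int
    outcome: str

    def __post_init__(self) -> None:
        t = self.data["t"].to_numpy()
        if len(t) > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("trajectory times must be strictly increasing")

    @property
    def n_detections(self) -> int:
        return int(self.data["n_detections"].sum())

    def positions(self) -> np.ndarray:
        return self.data[["x", "y"]].to_numpy()

    def to_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(
                f"# strategy={self.strategy} dose={self.dose} "
                f"seed={self.seed} outcome={self.outcome}\n"
            )
            self.data.to_csv(fh, index=False)

    @classmethod
    def from_csv(cls, path) -> "Trajectory":
        with open(path) as fh:
            header = fh.readline()
            if not header.startswith("#"):
                raise ValueError(f"{path}: line 1: missing '# key=value' metadata line")
            meta = dict(item.split("=", 1) for item in header[1:].split())
            data = pd.read_csv(fh)
        missing = set(TRAJECTORY_COLUMNS) - set(data.columns)
        if missing:
            raise ValueError(f"{path}: missing columns {sorted(missing)}")
        return cls(data=data, strategy=meta["strategy"], dose=meta["dose"],
                   seed=int(meta["seed"]), outcome=meta["outcome"])


def _as_rng(seed) -> tuple[np.random.Generator, int]:
    if isinstance(seed, np.random.SeedSequence):
        seed_int = int(seed.generate_state(1)[0] % (2 ** 31))
        return np.random.default_rng(seed), seed_int
    return np.random.default_rng(int(seed)), int(seed)


def run_trial(strategy: str, dose, plume: PlumeParams, arena: ArenaConfig,
              seed, reactive_cfg: rx.ReactiveConfig | None = None,
              it_cfg: it.InfotaxisConfig | None = None) -> Trajectory:
    """Run one fully reproducible trial of the given strategy and dose."""
    if isinstance(dose, str):
        dose = get_dose(dose)
    if strategy in rx.REACTIVE_STRATEGIES:
        return _run_reactive(strategy, dose, plume, arena, seed, reactive_cfg)
    if strategy == "it":
        return _run_infotaxis(dose, plume, arena, seed, it_cfg)
    raise ValueError(f"unknown strategy {strategy!r}")


def _record(rows, t, pos, heading, mode, k) -> None:
    rows.append((t, float(pos[0]), float(pos[1]),
                 math.degrees(heading), mode, int(k)))


def _finish(rows, strategy, dose: DoseLevel, seed_int, outcome) -> Trajectory:
    data = pd.DataFrame(rows, columns=TRAJECTORY_COLUMNS)
    return Trajectory(data=data, strategy=strategy, dose=dose.label,
                      seed=seed_int, outcome=outcome)


def _run_reactive(strategy, dose: DoseLevel, plume, arena: ArenaConfig, seed,
                  cfg: rx.ReactiveConfig | None) -> Trajectory:
    rng, seed_int = _as_rng(seed)
    if cfg is None:
        cfg = rx.config_for_strategy(strategy)
    state = rx.initial_state(arena.start, cfg)
    rows: list = []
    t = 0.0
    _record(rows, t, state.position, state.heading, state.mode.value, 0)
    if arena.source_distance(state.position) <= arena.success_radius:
        return _finish(rows, strategy, dose, seed_int, "success")
    outcome = None
    while outcome is None:
        k = sample_detections(state.position, arena.tick, dose, plume, rng)
        if k > 0:
            rx.on_detection(state, cfg)
        rx.advance(state, cfg, arena.tick)
        if arena.odometry_noise > 0:
            state.position = state.position + rng.normal(
                0.0, arena.odometry_noise, size=2
            )
        t += arena.tick
        _record(rows, t, state.position, state.heading, state.mode.value, k)
        if arena.source_distance(state.position) <= arena.success_radius:
            outcome = "success"
        elif not arena.contains(state.position):
            outcome = "fail_exit"
        elif t >= arena.max_duration - 1e-9:
            outcome = "fail_timeout"
    return _finish(rows, strategy, dose, seed_int, outcome)


def belief_grid(arena: ArenaConfig, spacing: float) -> tuple[np.ndarray, np.ndarray]:
    """Cell centers aligned with the start position so lattice moves land on
    centers.  Covers the arena with cells at multiples of ``spacing``."""
    x0, y0 = arena.start
    h = spacing

    def centers(origin, lo, hi):
        i0 = math.ceil((lo - origin) / h - 1e-9)
        i1 = math.floor((hi - origin) / h + 1e-9)
        return origin + h * np.arange(i0, i1 + 1)

    return centers(x0, arena.x_min, arena.x_max), centers(y0, arena.y_min, arena.y_max)


def _run_infotaxis(dose: DoseLevel, plume, arena: ArenaConfig, seed,
                   cfg: it.InfotaxisConfig | None) -> Trajectory:
    rng, seed_int = _as_rng(seed)
    if cfg is None:
        cfg = it.InfotaxisConfig()
    # The agent's likelihood model (cfg.model_plume) scales its R0 with the
    # dose, as the robotic assay did; with no pheromone it keeps the
    # minimum-dose rate (the searcher does not know the source is absent).
    model_scale = dose.emission_scale if dose.emission_scale > 0 else 1.0
    model = cfg.model_plume.with_emission_rate(
        cfg.model_plume.emission_rate * model_scale)

    xs, ys = belief_grid(arena, cfg.step_length)
    belief = it.Belief.uniform(xs, ys, exclude=arena.start)
    pos = np.asarray(arena.start, dtype=float)
    rows: list = []
    t = 0.0
    _record(rows, t, pos, 0.0, "it", 0)
    if arena.source_distance(pos) <= arena.success_radius:
        return _finish(rows, "it", dose, seed_int, "success")
    outcome = None
    heading = 0.0
    for _ in range(cfg.max_steps):
        action = it.choose_action(belief, pos, model, rng, cfg)
        dt = cfg.action_dt(action)
        step = it.ACTION_STEPS[action]
        new_pos = pos + cfg.step_length * np.array(step, dtype=float)
        if not np.allclose(new_pos, pos):
            heading = math.atan2(new_pos[0] - pos[0], new_pos[1] - pos[1])
        pos = new_pos
        k = sample_detections(pos, dt, dose, plume, rng)
        belief = it.update_belief(belief, pos, dt, k, model)
        t += dt
        _record(rows, t, pos, heading, "it", k)
        if arena.source_distance(pos) <= arena.success_radius:
            outcome = "success"
            break
        if not arena.contains(pos):
            outcome = "fail_exit"
            break
    if outcome is None:
        outcome = "fail_timeout"
    return _finish(rows, "it", dose, seed_int, outcome)


def run_batch(strategy: str, dose, plume: PlumeParams, arena: ArenaConfig,
              n_trials: int, seed: int, **kwargs) -> list[Trajectory]:
    """Run ``n_trials`` independent trials; per-trial seeds are spawned from
    ``seed`` so batches are reproducible and trials independent."""
    ss = np.random.SeedSequence(seed)
    return [
        run_trial(strategy, dose, plume, arena, child, **kwargs)
        for child in ss.spawn(n_trials)
    ]


def expected_detections(traj: Trajectory, dose, plume: PlumeParams,
                        arena: ArenaConfig) -> float:
    """Expected (not sampled) number of detections along a recorded path."""
    if isinstance(dose, str):
        dose = get_dose(dose)
    pos = traj.positions()
    rate = dose.emission_scale * mean_detection_rate(pos, plume) \
        + dose.false_detection_rate
    return float(rate[:-1].sum() * arena.tick)


def calibrate_emission(plume: PlumeParams, arena: ArenaConfig,
                       target_rate: float, dose="minimum", strategy: str = "za",
                       n_pilot: int = 20, seed: int = 0) -> PlumeParams:
    """Scale R0 so a pilot reactive batch averages ``target_rate`` detections
    per trial.

    The pilot batch is run once at the current R0; the expected detection
    count along the frozen pilot paths is linear in R0, so the fitted value
    is ``R0 * target / pilot_mean`` exactly (doubling the target doubles the
    fitted R0).
    """
    if not target_rate > 0:
        raise ValueError("target_rate must be positive")
    if isinstance(dose, str):
        dose = get_dose(dose)
    pilot = run_batch(strategy, dose, plume, arena, n_pilot, seed)
    contribution = []
    for traj in pilot:
        pos = traj.positions()
        rate = dose.emission_scale * mean_detection_rate(pos, plume)
        contribution.append(float(rate[:-1].sum() * arena.tick))
    mean_emitted = float(np.mean(contribution))
    baseline = dose.false_detection_rate * float(
        np.mean([traj.data["t"].iloc[-1] for traj in pilot])
    )
    if mean_emitted <= 0:
        raise ValueError("pilot batch registered no plume exposure; "
                         "target unreachable at this dose")
    wanted = target_rate - baseline
    if wanted <= 0:
        raise ValueError(
            f"target_rate {target_rate} not reachable: false detections alone "
            f"contribute {baseline:.3g} per trial"
        )
    return plume.with_emission_rate(plume.emission_rate * wanted / mean_emitted)
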