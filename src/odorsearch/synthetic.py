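"""Synthetic inputs: MGC-like spike trains and plume detection sequences.

Every generator is a pure function of its specification and a seed, so all
fixtures regenerate bit-identically.

The triphasic generator emulates the qualitative structure of multiphasic
pheromone responses: irregular Poisson baseline (CV2 ~ 1, Fano ~ 1), an
abrupt trial-locked near-regular On burst (CV2 ~ 0, high trial-to-trial
precision), an inhibitory pause, and an Off phase of intermediate regularity
whose rate decays exponentially back to baseline.  The On spikes are drawn
once per set (a template) and shared across trials up to an optional
Gaussian jitter — with zero jitter the On is perfectly repeatable across
trials, as the trial-correlation statistic expects.  The monophasic
generator switches straight back to baseline after the On.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .plume import DoseLevel, PlumeParams, get_dose, sample_detections
from .spikes import SpikeTrainSet

__all__ = [
    "TriphasicSpec",
    "gen_triphasic",
    "gen_monophasic",
    "gen_detection_sequence",
]


@dataclass(frozen=True)
class TriphasicSpec:
    """Parameters of the synthetic multiphasic response.

    Rates in Hz, durations in seconds.  Defaults are tuned to the
    qualitative magnitudes of the recorded responses: 5 Hz baseline, a
    100 Hz On of 0.3 s, a 0.3 s inhibitory pause, and an Off peaking at
    20 Hz decaying back to baseline with a 3 s time constant over 7 trials.
    ``on_shape``/``off_shape`` are gamma ISI shape parameters controlling
    regularity (large = clockwork, 1 = Poisson).
    """

    baseline_rate: float = 5.0
    on_rate: float = 100.0
    on_duration: float = 0.3
    inhibition_duration: float = 0.3
    off_peak_rate: float = 20.0
    off_decay_tau: float = 3.0
    jitter_sd: float = 0.0
    n_trials: int = 7
    onset: float = 2.0
    t_stop: float = 8.5
    on_shape: float = 100.0
    off_shape: float = 4.0

    def __post_init__(self) -> None:
        if not (self.on_rate > self.off_peak_rate > self.baseline_rate > 0):
            raise ValueError("need on_rate > off_peak_rate > baseline_rate > 0")
        for name in ("on_duration", "off_decay_tau", "t_stop", "onset"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.inhibition_duration < 0:
            raise ValueError("inhibition_duration must be non-negative")
        if self.n_trials < 1:
            raise ValueError("n_trials must be at least 1")


def _poisson_times(rate: float, t0: float, t1: float,
                   rng: np.random.Generator) -> np.ndarray:
    if t1 <= t0 or rate <= 0:
        return np.empty(0)
    n = rng.poisson(rate * (t1 - t0))
    return np.sort(rng.uniform(t0, t1, size=n))


def _gamma_renewal_times(rate: float, shape: float, t0: float, t1: float,
                         rng: np.random.Generator) -> np.ndarray:
    """Gamma-renewal train of mean rate ``rate`` on [t0, t1)."""
    if t1 <= t0 or rate <= 0:
        return np.empty(0)
    mean_isi = 1.0 / rate
    times = []
    # first spike after a fractional ISI so the train is not phase-locked to t0
    t = t0 + rng.gamma(shape, mean_isi / shape) * rng.uniform()
    while t < t1:
        times.append(t)
        t += rng.gamma(shape, mean_isi / shape)
    return np.asarray(times)


def _off_times(spec: TriphasicSpec, t0: float, t1: float,
               rng: np.random.Generator) -> np.ndarray:
    """Inhomogeneous gamma-renewal Off train via time rescaling.

    Operational time Lambda(t) integrates the decaying rate
    baseline + (peak - baseline) exp(-(t - t0)/tau); unit-mean gamma
    increments in Lambda-time give intermediate regularity (CV ~ 0.5 for the
    default shape 4).
    """
    if t1 <= t0:
        return np.empty(0)
    grid = np.linspace(t0, t1, max(16, int((t1 - t0) * 400)))
    rate = spec.baseline_rate + (spec.off_peak_rate - spec.baseline_rate) \
        * np.exp(-(grid - t0) / spec.off_decay_tau)
    lam = np.concatenate([[0.0], np.cumsum(
        (rate[1:] + rate[:-1]) / 2 * np.diff(grid))])
    total = lam[-1]
    times = []
    u = rng.gamma(spec.off_shape, 1.0 / spec.off_shape) * rng.uniform()
    while u < total:
        times.append(u)
        u += rng.gamma(spec.off_shape, 1.0 / spec.off_shape)
    return np.interp(np.asarray(times), lam, grid)


def _on_template(spec: TriphasicSpec, rng: np.random.Generator) -> np.ndarray:
    return _gamma_renewal_times(spec.on_rate, spec.on_shape, spec.onset,
                                spec.onset + spec.on_duration, rng)


def _assemble(parts: list[np.ndarray]) -> np.ndarray:
    spikes = np.sort(np.concatenate([p for p in parts if p.size]))
    if spikes.size > 1:  # enforce strictly increasing times
        keep = np.concatenate([[True], np.diff(spikes) > 1e-9])
        spikes = spikes[keep]
    return spikes


def gen_triphasic(spec: TriphasicSpec, seed: int) -> SpikeTrainSet:
    """Generate a multi-trial triphasic (Bl/On/inhibition/Off) spike set."""
    rng = np.random.default_rng(seed)
    template = _on_template(spec, rng)
    on_end = spec.onset + spec.on_duration
    off_start = on_end + spec.inhibition_duration
    trials = []
    for _ in range(spec.n_trials):
        bl = _poisson_times(spec.baseline_rate, 0.0, spec.onset, rng)
        on = template.copy()
        if spec.jitter_sd > 0:
            on = np.sort(on + rng.normal(0.0, spec.jitter_sd, size=on.size))
        on = on[(on >= spec.onset) & (on < on_end)]
        off = _off_times(spec, off_start, spec.t_stop, rng)
        trials.append(_assemble([bl, on, off]))
    return SpikeTrainSet(trials=trials, stimulus_onset=spec.onset,
                         stimulus_duration=0.2, t_start=0.0, t_stop=spec.t_stop)


def gen_monophasic(spec: TriphasicSpec, seed: int) -> SpikeTrainSet:
    """Generate a monophasic set: the On switches straight back to baseline
    (no inhibition, no Off phase).  The inhibition/Off fields of ``spec``
    are ignored."""
    rng = np.random.default_rng(seed)
    template = _on_template(spec, rng)
    on_end = spec.onset + spec.on_duration
    trials = []
    for _ in range(spec.n_trials):
        bl = _poisson_times(spec.baseline_rate, 0.0, spec.onset, rng)
        on = template.copy()
        if spec.jitter_sd > 0:
            on = np.sort(on + rng.normal(0.0, spec.jitter_sd, size=on.size))
        on = on[(on >= spec.onset) & (on < on_end)]
        post = _poisson_times(spec.baseline_rate, on_end, spec.t_stop, rng)
        trials.append(_assemble([bl, on, post]))
    return SpikeTrainSet(trials=trials, stimulus_onset=spec.onset,
                         stimulus_duration=0.2, t_start=0.0, t_stop=spec.t_stop)


def gen_detection_sequence(dose, path, plume: PlumeParams, seed: int,
                           dt: float = 0.1) -> np.ndarray:
    """Per-tick Poisson detection counts along a path of (x, y) samples."""
    if isinstance(dose, str):
        dose = get_dose(dose)
    rng = np.random.default_rng(seed)
    path = np.asarray(path, dtype=float).reshape(-1, 2)
    return np.array([
        sample_detections(p, dt, dose, plume, rng) for p in path
    ])
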