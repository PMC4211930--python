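"""Spike-train statistics of pheromone responses.

Multiphasic neurons of the moth macroglomerular complex answer a 200 ms
pheromone pulse with a triphasic pattern: an abrupt high-rate On response, an
inhibitory pause, then a transient Off phase that decays back to baseline
(Bl) firing.  This module provides the statistics that expose that structure
across repeated trials of one neuron:

* PSTH — trial-averaged firing rate over time,
* interval segmentation into Bl / On / Off1..Offk windows,
* local coefficient of variation (CV2; 0 = clockwork, ~1 = Poisson),
* trial-to-trial correlation of binned spike counts (spike-time precision),
* Fano factor (across-trial count variance / mean; ~1 = unreliable Poisson,
  0 = perfectly reliable),
* the detection-event criterion used to trigger the searching robot: at
  least three consecutive inter-spike intervals below 70 ms followed by an
  inhibitory gap above 350 ms.

Count statistics use 50 ms (correlation) and 125 ms (Fano) bins by default;
both are arguments.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SpikeTrainSet",
    "Segmentation",
    "psth",
    "segment_intervals",
    "local_cv",
    "local_cv_by_trial",
    "trial_correlation",
    "fano_factor",
    "detect_event",
]


@dataclass
class SpikeTrainSet:
    """Multi-trial spike times of one neuron, aligned to a common stimulus.

    ``trials`` is a list of strictly increasing spike-time arrays (seconds);
    ``stimulus_onset``/``stimulus_duration`` locate the 200 ms pheromone
    pulse; ``t_start``/``t_stop`` bound the recording window.
    """

    trials: list[np.ndarray]
    stimulus_onset: float
    stimulus_duration: float = 0.2
    t_start: float = 0.0
    t_stop: float | None = None

    def __post_init__(self) -> None:
        self.trials = [np.asarray(t, dtype=float) for t in self.trials]
        for i, t in enumerate(self.trials):
            if len(t) > 1 and not np.all(np.diff(t) > 0):
                raise ValueError(f"trial {i}: spike times must be strictly increasing")
        if self.t_stop is None:
            last = max((t[-1] for t in self.trials if len(t)), default=self.stimulus_onset)
            self.t_stop = float(last)

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    def pooled(self) -> np.ndarray:
        if not self.trials:
            return np.empty(0)
        return np.sort(np.concatenate(self.trials))

    # ------------------------------------------------------------------ I/O
    # Dialect: header lines '# key=value ...', then one whitespace-separated
    # line of spike times (seconds) per trial; an empty trial is a blank line.

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# onset={self.stimulus_onset} duration={self.stimulus_duration} "
                     f"t_start={self.t_start} t_stop={self.t_stop}\n")
            for t in self.trials:
                fh.write(" ".join(f"{x:.6f}" for x in t) + "\n")

    @classmethod
    def from_file(cls, path) -> "SpikeTrainSet":
        meta: dict[str, float] = {}
        trials: list[np.ndarray] = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if line.startswith("#"):
                    for item in line[1:].split():
                        key, _, value = item.partition("=")
                        meta[key] = float(value)
                    continue
                try:
                    trials.append(np.array([float(x) for x in line.split()]))
                except ValueError as exc:
                    raise ValueError(f"{path}: line {lineno}: {exc}") from None
        if "onset" not in meta:
            raise ValueError(f"{path}: missing '# onset=<s>' header")
        return cls(trials=trials, stimulus_onset=meta["onset"],
                   stimulus_duration=meta.get("duration", 0.2),
                   t_start=meta.get("t_start", 0.0), t_stop=meta.get("t_stop"))


def _bin_counts(spikes: np.ndarray, t0: float, t1: float, bin_s: float) -> np.ndarray:
    edges = np.arange(t0, t1 + bin_s * 1e-9, bin_s)
    if len(edges) < 2:
        raise ValueError("interval shorter than one bin")
    counts, _ = np.histogram(spikes, bins=edges)
    return counts


def psth(spike_set: SpikeTrainSet, bin_s: float = 0.05,
         t_start: float | None = None, t_stop: float | None = None):
    """Peri-stimulus time histogram: trial-averaged rate per bin, spikes/s.

    Returns ``(bin_left_edges, rates)``.
    """
    if spike_set.n_trials < 1:
        raise ValueError("psth needs at least one trial")
    t0 = spike_set.t_start if t_start is None else t_start
    t1 = spike_set.t_stop if t_stop is None else t_stop
    edges = np.arange(t0, t1 + bin_s * 1e-9, bin_s)
    counts = np.zeros(len(edges) - 1)
    for trial in spike_set.trials:
        counts += np.histogram(trial, bins=edges)[0]
    rates = counts / (spike_set.n_trials * bin_s)
    return edges[:-1], rates


@dataclass
class Segmentation:
    """Labeled analysis intervals (half-open, seconds)."""

    bl: tuple[float, float]
    on: tuple[float, float] | None
    inhibition: tuple[float, float] | None
    offs: list[tuple[float, float]] = field(default_factory=list)
    monophasic: bool = False

    def intervals(self) -> dict[str, tuple[float, float]]:
        out = {"Bl": self.bl}
        if self.on is not None:
            out["On"] = self.on
        for i, w in enumerate(self.offs, start=1):
            out[f"Off{i}"] = w
        return out


def segment_intervals(spike_set: SpikeTrainSet, off_len_s: float = 2.5,
                      bin_s: float = 0.05, n_off: int = 2,
                      threshold_sd: float = 3.0,
                      min_inhibition_s: float = 0.1) -> Segmentation:
    """Threshold-crossing segmentation of a response into Bl/On/Off windows.

    Bl is the pre-onset window.  The On starts at the first PSTH bin after
    stimulus onset whose rate exceeds the Bl mean + ``threshold_sd`` Bl SDs
    and ends when the rate first falls below the Bl mean (inhibition start).
    If firing resumes within ``min_inhibition_s`` the response is labeled
    monophasic (no inhibition, no Off windows); otherwise ``n_off``
    consecutive windows of ``off_len_s`` start at the first post-inhibition
    spike.

    A response with no bin above threshold is labeled monophasic-ambiguous
    (``on=None``, ``monophasic=True``).
    """
    onset = spike_set.stimulus_onset
    if onset <= spike_set.t_start:
        raise ValueError("no pre-onset window available for the baseline")
    edges, rates = psth(spike_set, bin_s)
    bl_mask = edges + bin_s <= onset + 1e-12
    bl_rates = rates[bl_mask]
    if bl_rates.size == 0:
        raise ValueError("baseline window shorter than one PSTH bin")
    bl_mean = float(bl_rates.mean())
    bl_sd = float(bl_rates.std(ddof=1)) if bl_rates.size > 1 else 0.0
    bl = (spike_set.t_start, onset)

    post = np.flatnonzero((edges >= onset - 1e-12)
                          & (rates > bl_mean + threshold_sd * bl_sd))
    if post.size == 0:
        return Segmentation(bl=bl, on=None, inhibition=None, monophasic=True)
    i_on = int(post[0])
    on_start = float(edges[i_on])

    below = np.flatnonzero((np.arange(len(rates)) > i_on) & (rates < bl_mean))
    if below.size == 0:
        # excitation never ends inside the recording; treat end of record
        on_end = float(spike_set.t_stop)
        return Segmentation(bl=bl, on=(on_start, on_end), inhibition=None,
                            monophasic=True)
    on_end = float(edges[int(below[0])])

    pooled = spike_set.pooled()
    after = pooled[pooled > on_end + 1e-12]
    if after.size == 0:
        return Segmentation(bl=bl, on=(on_start, on_end), inhibition=None,
                            monophasic=True)
    first_resume = float(after[0])
    if first_resume - on_end < min_inhibition_s:
        return Segmentation(bl=bl, on=(on_start, on_end), inhibition=None,
                            monophasic=True)
    offs = []
    t0 = first_resume
    for _ in range(n_off):
        t1 = min(t0 + off_len_s, float(spike_set.t_stop))
        if t1 - t0 <= 0:
            break
        offs.append((t0, t1))
        t0 = t1
    return Segmentation(bl=bl, on=(on_start, on_end),
                        inhibition=(on_end, first_resume), offs=offs)


def interval_spikes(trial: np.ndarray, interval: tuple[float, float]) -> np.ndarray:
    t0, t1 = interval
    return trial[(trial >= t0) & (trial < t1)]


def local_cv(isis) -> float:
    """Local coefficient of variation CV2 of an ISI sequence.

    Mean over adjacent ISI pairs of ``2 |I_{i+1} - I_i| / (I_{i+1} + I_i)``:
    0 for clockwork trains, ~1 for Poisson trains.  Needs at least two ISIs
    (three spikes); returns NaN otherwise.
    """
    isis = np.asarray(isis, dtype=float)
    if isis.size < 2:
        return float("nan")
    a, b = isis[:-1], isis[1:]
    return float(np.mean(2.0 * np.abs(b - a) / (b + a)))


def local_cv_by_trial(spike_set: SpikeTrainSet,
                      interval: tuple[float, float]) -> float:
    """Mean CV2 across trials within an interval; trials with fewer than
    three spikes are skipped (NaN if all are)."""
    values = []
    for trial in spike_set.trials:
        s = interval_spikes(trial, interval)
        if len(s) >= 3:
            values.append(local_cv(np.diff(s)))
    return float(np.mean(values)) if values else float("nan")


def trial_correlation(spike_set: SpikeTrainSet, interval: tuple[float, float],
                      bin_s: float = 0.05) -> float:
    """Mean pairwise Pearson correlation of binned counts across trials.

    Measures trial-to-trial spike-time precision: 1 for perfectly repeating
    trains, ~0 for independent Poisson firing.  Pairs with *identical* count
    vectors count as perfectly correlated (1) even when the common vector is
    constant; pairs where exactly one vector is degenerate (zero variance,
    not identical to the other) are skipped.
    """
    if spike_set.n_trials < 2:
        raise ValueError("trial_correlation needs at least two trials")
    t0, t1 = interval
    counts = [_bin_counts(t, t0, t1, bin_s) for t in spike_set.trials]
    values = []
    for i in range(len(counts)):
        for j in range(i + 1, len(counts)):
            a, b = counts[i], counts[j]
            if np.array_equal(a, b):
                values.append(1.0)
                continue
            if a.std() == 0 or b.std() == 0:
                continue  # degenerate pair, skipped
            values.append(float(np.corrcoef(a, b)[0, 1]))
    return float(np.mean(values)) if values else float("nan")


def fano_factor(spike_set: SpikeTrainSet, interval: tuple[float, float],
                bin_s: float = 0.125) -> float:
    """Across-trial variance of per-bin counts divided by their mean,
    averaged over the interval's bins (bins with zero mean are skipped;
    NaN if all are)."""
    if spike_set.n_trials < 2:
        raise ValueError("fano_factor needs at least two trials")
    t0, t1 = interval
    counts = np.vstack([_bin_counts(t, t0, t1, bin_s) for t in spike_set.trials])
    mean = counts.mean(axis=0)
    var = counts.var(axis=0, ddof=1)
    ok = mean > 0
    if not ok.any():
        return float("nan")
    return float(np.mean(var[ok] / mean[ok]))


def detect_event(spike_times, fast_isi: float = 0.070, slow_isi: float = 0.350,
                 n_fast: int = 3) -> np.ndarray:
    """Detection events: a burst of >= ``n_fast`` consecutive ISIs below
    ``fast_isi`` immediately followed by an inhibitory ISI above ``slow_isi``.

    The event time is the spike ending the long ISI.  Events never overlap:
    after an event the burst counter restarts.  Returns an array of event
    times (possibly empty).
    """
    t = np.asarray(spike_times, dtype=float)
    events = []
    fast_run = 0
    for i in range(1, len(t)):
        isi = t[i] - t[i - 1]
        if isi < fast_isi:
            fast_run += 1
        elif isi > slow_isi:
            if fast_run >= n_fast:
                events.append(t[i])
            fast_run = 0
        else:
            fast_run = 0
    return np.array(events)
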