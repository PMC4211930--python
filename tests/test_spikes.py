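import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import odorsearch as osx
from odorsearch.spikes import (SpikeTrainSet, detect_event, fano_factor,
                               local_cv, local_cv_by_trial, psth,
                               segment_intervals, trial_correlation)


def poisson_train(rate, duration, rng):
    n = rng.poisson(rate * duration)
    return np.sort(rng.uniform(0, duration, n))


class TestSpikeTrainSet:
    def test_rejects_unsorted_trains(self):
        with pytest.raises(ValueError):
            SpikeTrainSet(trials=[np.array([0.2, 0.1])], stimulus_onset=1.0)

    def test_file_round_trip(self, tmp_path):
        s = SpikeTrainSet(trials=[np.array([0.1, 0.5]), np.array([])],
                          stimulus_onset=1.0, t_stop=3.0)
        path = tmp_path / "spikes.txt"
        s.to_file(path)
        back = SpikeTrainSet.from_file(path)
        assert back.stimulus_onset == 1.0
        assert back.t_stop == 3.0
        assert len(back.trials) == 2
        assert np.allclose(back.trials[0], [0.1, 0.5])

    def test_malformed_file_reports_line(self, tmp_path):
        path = tmp_path / "bad.txt"
        path.write_text("# onset=1.0\n0.1 oops 0.3\n")
        with pytest.raises(ValueError, match="line 2"):
            SpikeTrainSet.from_file(path)


class TestPsth:
    def test_single_spike_single_trial(self):
        s = SpikeTrainSet(trials=[np.array([0.5])], stimulus_onset=1.0,
                          t_start=0.0, t_stop=3.0)
        edges, rates = psth(s, bin_s=1.0)
        assert rates[0] == pytest.approx(1.0)
        assert rates[1:].sum() == 0.0

    def test_empty_trials_give_zero_psth(self):
        s = SpikeTrainSet(trials=[np.array([]), np.array([])],
                          stimulus_onset=1.0, t_stop=2.0)
        _, rates = psth(s, bin_s=0.5)
        assert np.all(rates == 0)

    def test_homogeneous_rate_recovered(self):
        rng = np.random.default_rng(0)
        s = SpikeTrainSet(trials=[poisson_train(10.0, 50.0, rng)
                                  for _ in range(20)],
                          stimulus_onset=1.0, t_start=0.0, t_stop=50.0)
        _, rates = psth(s, bin_s=1.0)
        assert rates.mean() == pytest.approx(10.0, rel=0.05)


class TestLocalCV:
    def test_clockwork_is_zero(self):
        assert local_cv(np.ones(50)) == 0.0

    def test_pair_closed_form(self):
        assert local_cv([1.0, 3.0]) == pytest.approx(1.0)

    def test_poisson_approaches_one(self):
        rng = np.random.default_rng(1)
        isis = rng.exponential(0.1, size=10_000)
        assert local_cv(isis) == pytest.approx(1.0, abs=0.05)

    def test_undefined_below_two_isis(self):
        assert np.isnan(local_cv([0.5]))

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.floats(0.01, 100.0))
    def test_invariant_under_time_rescaling(self, c):
        rng = np.random.default_rng(7)
        isis = rng.gamma(2.0, 0.05, size=200)
        assert local_cv(c * isis) == pytest.approx(local_cv(isis), rel=1e-9)


class TestTrialCorrelation:
    def test_identical_trials_are_unity(self):
        t = np.array([0.1, 0.22, 0.31, 0.47])
        s = SpikeTrainSet(trials=[t, t.copy(), t.copy()], stimulus_onset=0.5,
                          t_stop=0.5)
        assert trial_correlation(s, (0.0, 0.5)) == 1.0

    def test_anti_aligned_bins_are_minus_one(self):
        a = np.array([0.025, 0.125, 0.225])   # odd bins
        b = np.array([0.075, 0.175, 0.275])   # even bins
        s = SpikeTrainSet(trials=[a, b], stimulus_onset=0.3, t_stop=0.3)
        assert trial_correlation(s, (0.0, 0.3)) == pytest.approx(-1.0)

    def test_independent_poisson_near_zero(self):
        rng = np.random.default_rng(2)
        s = SpikeTrainSet(trials=[poisson_train(5.0, 10.0, rng)
                                  for _ in range(12)],
                          stimulus_onset=10.0, t_stop=10.0)
        assert abs(trial_correlation(s, (0.0, 10.0))) < 0.1

    def test_degenerate_pair_skipped(self):
        a = np.array([0.025, 0.125])   # varying counts
        flat = np.array([0.02, 0.07, 0.12, 0.17, 0.22, 0.27])  # one per bin
        s = SpikeTrainSet(trials=[a, flat], stimulus_onset=0.3, t_stop=0.3)
        assert np.isnan(trial_correlation(s, (0.0, 0.3)))

    def test_jitter_degrades_correlation_monotonically(self):
        base = osx.TriphasicSpec()
        seg_interval = (base.onset, base.onset + base.on_duration)
        values = []
        # small jitters relative to the 50 ms bin: beyond ~bin/10 the
        # correlation is already indistinguishable from noise around zero
        for jitter in (0.0, 0.001, 0.002):
            import dataclasses

            spec = dataclasses.replace(base, jitter_sd=jitter)
            s = osx.gen_triphasic(spec, seed=5)
            values.append(trial_correlation(s, seg_interval))
        assert values[0] > values[1] > values[2]


class TestFanoFactor:
    def test_identical_trains_are_zero(self):
        t = np.array([0.1, 0.4, 0.9, 1.3])
        s = SpikeTrainSet(trials=[t, t.copy(), t.copy()], stimulus_onset=2.0,
                          t_stop=2.0)
        assert fano_factor(s, (0.0, 2.0)) == 0.0

    def test_poisson_is_near_one(self):
        rng = np.random.default_rng(4)
        s = SpikeTrainSet(trials=[poisson_train(8.0, 4.0, rng)
                                  for _ in range(200)],
                          stimulus_onset=4.0, t_stop=4.0)
        assert fano_factor(s, (0.0, 4.0)) == pytest.approx(1.0, abs=0.05)

    def test_doubling_counts_doubles_fano(self):
        rng = np.random.default_rng(5)
        trials = [poisson_train(6.0, 3.0, rng) for _ in range(50)]
        doubled = [np.sort(np.concatenate([t, t + 1e-6])) for t in trials]
        f1 = fano_factor(SpikeTrainSet(trials=trials, stimulus_onset=3.0,
                                       t_stop=3.0), (0.0, 3.0))
        f2 = fano_factor(SpikeTrainSet(trials=doubled, stimulus_onset=3.0,
                                       t_stop=3.0), (0.0, 3.0))
        assert f2 == pytest.approx(2 * f1, rel=1e-6)

    def test_silent_interval_reported_missing(self):
        s = SpikeTrainSet(trials=[np.array([5.0]), np.array([5.0])],
                          stimulus_onset=1.0, t_stop=6.0)
        assert np.isnan(fano_factor(s, (0.0, 1.0)))


class TestDetectEvent:
    def test_canonical_burst_then_gap(self):
        spikes = [0.0, 0.05, 0.10, 0.15, 0.60]
        events = detect_event(spikes)
        assert np.allclose(events, [0.60])

    def test_two_fast_isis_insufficient(self):
        assert detect_event([0.0, 0.05, 0.10, 0.60]).size == 0

    def test_burst_without_gap_waits(self):
        # fast firing with no >350 ms pause: no event until the pause arrives
        fast = list(np.arange(0, 0.5, 0.05))
        assert detect_event(fast).size == 0
        events = detect_event(fast + [fast[-1] + 0.4])
        assert events.size == 1

    def test_intermediate_isi_breaks_run(self):
        # 70-350 ms ISIs are neither fast nor inhibitory: they reset the burst
        spikes = [0.0, 0.05, 0.10, 0.30, 0.35, 0.40, 0.45, 0.90]
        events = detect_event(spikes)
        assert np.allclose(events, [0.90])

    def test_non_overlapping_events(self):
        burst = [0.0, 0.05, 0.10, 0.15]
        spikes = burst + [0.6] + [0.65, 0.70, 0.75, 0.80] + [1.3]
        events = detect_event(spikes)
        assert np.allclose(events, [0.6, 1.3])


class TestSegmentation:
    def test_recovers_known_change_points(self, triphasic_set):
        spec = osx.TriphasicSpec()
        seg = segment_intervals(triphasic_set, bin_s=0.05)
        assert not seg.monophasic
        assert seg.on is not None
        assert abs(seg.on[0] - spec.onset) <= 0.05
        assert abs(seg.on[1] - (spec.onset + spec.on_duration)) <= 0.10
        assert seg.inhibition is not None
        assert len(seg.offs) == 2
        assert seg.offs[0][0] >= seg.on[1] + 0.05  # a real silent gap

    def test_monophasic_has_no_off_structure(self, monophasic_set):
        seg = segment_intervals(monophasic_set, bin_s=0.05)
        assert seg.monophasic
        assert seg.inhibition is None
        assert seg.offs == []

    def test_baseline_window_precedes_onset(self, triphasic_set):
        seg = segment_intervals(triphasic_set)
        assert seg.bl == (0.0, triphasic_set.stimulus_onset)

    def test_recovery_across_parameter_grid(self):
        """On onset within one PSTH bin and inhibition onset within two bins
        across a grid of On rates and inhibition durations."""
        bin_s = 0.05
        for on_rate in (50.0, 100.0, 150.0):
            for inhibition in (0.2, 0.3, 0.5):
                spec = osx.TriphasicSpec(on_rate=on_rate,
                                         inhibition_duration=inhibition)
                s = osx.gen_triphasic(spec, seed=17)
                seg = segment_intervals(s, bin_s=bin_s)
                assert not seg.monophasic, (on_rate, inhibition)
                assert abs(seg.on[0] - spec.onset) <= bin_s
                assert abs(seg.on[1] - (spec.onset + spec.on_duration)) \
                    <= 2 * bin_s
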