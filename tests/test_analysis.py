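"""Burst detection, classification, rhythm statistics and fixtures."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from prebotc.analysis import (
    Burst,
    classify_bursts,
    count_phases,
    detect_bursts,
    make_fixture,
    rhythm_summary,
    burst_profile,
)
from prebotc.simulate import Trace


def rect_series(pulse_starts, width=300, amp=10.0, duration=None, dt=1.0):
    duration = duration or (max(pulse_starts) + width + 1000)
    t = np.arange(0, duration, dt)
    v = np.zeros_like(t)
    for p in pulse_starts:
        v[(t >= p) & (t < p + width)] = amp
    return t, v


class TestDetector:
    def test_constant_series_no_bursts(self):
        t = np.arange(0, 1000.0)
        assert detect_bursts(t, np.full_like(t, -50.0)) == []
        assert detect_bursts(np.array([]), np.array([])) == []

    def test_three_rect_pulses(self):
        t, v = rect_series([1000, 3000, 5000])
        bursts = detect_bursts(t, v)
        assert len(bursts) == 3
        assert [b.onset for b in bursts] == [1000.0, 3000.0, 5000.0]
        assert all(b.offset - b.onset == pytest.approx(299, abs=1) for b in bursts)

    def test_close_pulses_merge(self):
        t, v = rect_series([1000, 1380])  # 80 ms gap < 100 ms min_gap
        assert len(detect_bursts(t, v)) == 1
        t, v = rect_series([1000, 1500])  # 200 ms gap
        assert len(detect_bursts(t, v)) == 2

    def test_threshold_fraction_validated(self):
        t, v = rect_series([1000])
        with pytest.raises(ValueError):
            detect_bursts(t, v, threshold_fraction=1.5)

    def test_offset_invariance(self):
        t, v = rect_series([1000, 3000, 5200], amp=7.0)
        a = detect_bursts(t, v)
        b = detect_bursts(t, v - 61.3)
        assert [(x.onset, x.offset) for x in a] == [(x.onset, x.offset) for x in b]
        assert all(x.peak_amplitude == pytest.approx(y.peak_amplitude)
                   for x, y in zip(a, b))

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(shift=st.integers(0, 2000))
    def test_time_shift_equivariance(self, shift):
        t, v = rect_series([1000, 3000])
        shifted = detect_bursts(t + shift, v)
        base = detect_bursts(t, v)
        assert [b.onset + shift for b in base] == [b.onset for b in shifted]

    @pytest.mark.parametrize("amp,gap", [(5.0, 500), (50.0, 1000), (2.0, 5000)])
    def test_noiseless_count_exact(self, amp, gap):
        starts = [1000 + i * (300 + gap) for i in range(6)]
        t, v = rect_series(starts, amp=amp)
        assert len(detect_bursts(t, v)) == 6


class TestClassifier:
    def test_forced_split(self):
        bursts = [Burst(i * 1000.0, i * 1000.0 + 100, i * 1000.0 + 50, a)
                  for i, a in enumerate([1.0, 1.0, 1.0, 5.0])]
        labels = [b.label for b in classify_bursts(bursts)]
        assert labels == ["eupnea", "eupnea", "eupnea", "sigh"]

    def test_unimodal_all_eupnea(self):
        bursts = [Burst(i * 1000.0, i * 1000.0 + 100, i * 1000.0 + 50, a)
                  for i, a in enumerate([1.0, 1.1, 0.9, 1.05, 0.95])]
        assert all(b.label == "eupnea" for b in classify_bursts(bursts))

    def test_empty_and_singleton(self):
        assert classify_bursts([]) == []
        only = classify_bursts([Burst(0.0, 10.0, 5.0, 3.0)])
        assert only[0].label == "eupnea"

    def test_labels_depend_only_on_amplitude_multiset(self):
        amps = [1.0, 4.0, 1.2, 3.8, 1.1]
        bursts = [Burst(i * 1000.0, i * 1000.0 + 100, i * 1000.0 + 50, a)
                  for i, a in enumerate(amps)]
        ref = {b.peak_amplitude: b.label for b in classify_bursts(bursts)}
        shuffled = list(reversed(bursts))
        for b in classify_bursts(shuffled):
            assert b.label == ref[b.peak_amplitude]

    def test_input_not_mutated(self):
        bursts = [Burst(0.0, 10.0, 5.0, 1.0), Burst(100.0, 110.0, 105.0, 5.0)]
        classify_bursts(bursts)
        assert all(b.label == "unclassified" for b in bursts)


def make_train(eup_times, sigh_times):
    bursts = [Burst(t, t + 300.0, t + 100.0, 1.0, label="eupnea") for t in eup_times]
    bursts += [Burst(t, t + 800.0, t + 200.0, 4.0, label="sigh") for t in sigh_times]
    return sorted(bursts, key=lambda b: b.onset)


class TestRhythmSummary:
    def test_count_over_window(self):
        # 4 events of one class in 2 minutes -> 2 bursts/min
        train = make_train([10_000, 40_000, 70_000, 100_000], [])
        s = rhythm_summary(train, window=120_000.0)
        assert s.freq_eupnea == pytest.approx(2.0)
        assert s.freq_sigh is None
        assert s.period_post_sigh is None

    def test_window_inverse_scaling(self):
        train = make_train([10_000, 40_000, 70_000], [90_000])
        a = rhythm_summary(train, window=120_000.0)
        b = rhythm_summary(train, window=240_000.0)
        assert a.freq_eupnea == pytest.approx(2 * b.freq_eupnea)
        assert a.freq_sigh == pytest.approx(2 * b.freq_sigh)

    def test_post_sigh_and_regular_periods(self):
        # eupnea every 4 s; a sigh at 20 s; first eupnea 6 s after the sigh
        eup = [0, 4_000, 8_000, 12_000, 16_000, 26_000, 30_000, 34_000]
        train = make_train(eup, [20_000])
        s = rhythm_summary(train, window=40_000.0)
        assert s.period_post_sigh == pytest.approx(6.0)
        # regular intervals exclude those adjacent to the sigh
        assert s.period_post_eupnea == pytest.approx(4.0)
        assert s.apnea_increase == pytest.approx(50.0)

    def test_offset_convention(self):
        train = make_train([0, 4_000, 26_000, 30_000], [20_000])
        s = rhythm_summary(train, window=40_000.0, convention="offset_to_onset")
        assert s.period_post_sigh == pytest.approx((26_000 - 20_800) / 1000)

    def test_window_validation(self):
        with pytest.raises(ValueError):
            rhythm_summary([], window=0.0)


class TestCountPhases:
    def test_single_bump(self):
        x = np.linspace(-3, 3, 500)
        assert count_phases(np.exp(-x**2)) == 1

    def test_two_separated_bumps(self):
        x = np.linspace(0, 10, 1000)
        w = np.exp(-((x - 3) ** 2)) + 0.8 * np.exp(-((x - 7) ** 2))
        assert count_phases(w) == 2

    def test_small_secondary_bump_ignored_at_default(self):
        x = np.linspace(0, 10, 1000)
        w = np.exp(-((x - 3) ** 2)) + 0.05 * np.exp(-((x - 7) ** 2) / 0.2)
        assert count_phases(w) == 1
        assert count_phases(w, prominence_fraction=0.01) == 2

    def test_flat_waveform(self):
        assert count_phases(np.zeros(100)) == 0

    def test_monotone_ramp_counts_one(self):
        assert count_phases(np.linspace(0, 1, 100)) == 1


class TestFixture:
    def test_noiseless_recovery(self):
        times = [1000.0, 4000.0, 7000.0, 10_000.0, 13_000.0]
        t, v = make_fixture(times, [1.0] * 5, widths=300.0)
        bursts = detect_bursts(t, v)
        assert len(bursts) == 5
        for b, t0 in zip(bursts, times):
            assert abs(b.onset - t0) <= 20.0  # within the short pulse rise

    def test_amplitude_pattern_classified(self):
        times = [float(1000 + 2000 * i) for i in range(10)]
        amps = [1.0] * 9 + [4.0]
        t, v = make_fixture(times, amps, widths=300.0)
        labeled = classify_bursts(detect_bursts(t, v))
        assert sum(b.label == "sigh" for b in labeled) == 1
        assert labeled[-1].label == "sigh"

    def test_overlap_rejected(self):
        with pytest.raises(ValueError):
            make_fixture([0.0, 100.0], [1.0, 1.0], widths=300.0)

    def test_deterministic_given_seed(self):
        a = make_fixture([1000.0], [1.0], noise_sd=0.1, seed=3)[1]
        b = make_fixture([1000.0], [1.0], noise_sd=0.1, seed=3)[1]
        assert np.array_equal(a, b)

    def test_biphasic_event_shape(self):
        t, v = make_fixture([1000.0], [1.0], widths=800.0, phases=2)
        seg = v[900:2000]
        assert count_phases(seg) == 2

    def test_detection_recall_under_noise(self):
        """Recall >= 0.99 at 5% noise across 100 seeds."""
        times = [float(2000 + 3000 * i) for i in range(10)]
        hits = total = 0
        for seed in range(100):
            t, v = make_fixture(times, [1.0] * 10, widths=400.0,
                                noise_sd=0.05, seed=seed)
            bursts = detect_bursts(t, v)
            onsets = np.array([b.onset for b in bursts]) if bursts else np.array([])
            for t0 in times:
                total += 1
                if len(onsets) and np.min(np.abs(onsets - t0)) < 400.0:
                    hits += 1
        assert hits / total >= 0.99


def test_burst_profile_of_identical_events():
    times = [float(2000 + 4000 * i) for i in range(6)]
    t, v = make_fixture(times, [1.0] * 6, widths=400.0)
    n = len(t)
    trace = Trace(t=t, eupnea=np.zeros((n, 6)), sigh=np.zeros((n, 6)), v_avg=v)
    bursts = classify_bursts(detect_bursts(t, v))
    profiles = burst_profile(trace, bursts, window_pre=600.0, window_post=600.0)
    t_rel, w = profiles["eupnea"]
    # the mean of identical events is the single event shape
    k = bursts[0].peak_time
    single = v[int(k - 600):int(k + 601)]
    np.testing.assert_allclose(w, single, atol=1e-12)
    assert t_rel[0] == -600.0 and t_rel[-1] == 600.0


def test_burst_invariants():
    with pytest.raises(ValueError):
        Burst(onset=10.0, offset=5.0, peak_time=7.0, peak_amplitude=1.0)
    with pytest.raises(ValueError):
        Burst(onset=0.0, offset=5.0, peak_time=2.0, peak_amplitude=-1.0)
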