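import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from subkin import (
    StimulusSegment,
    TrackerSpec,
    detect_type2,
    detect_type3,
    kinematic_profile,
    make_plan,
    min_jerk_pulse,
    rates,
    segment_trial,
    simulate_tracker,
    stimulus_speed_peaks,
    zero_crossings,
)
from tests.conftest import sinusoid_trial

FS = 100.0


class TestZeroCrossings:
    def test_sine_crossing_location(self):
        t = np.linspace(0, 1, 101)
        times = zero_crossings(np.sin(2 * np.pi * t), t, "pos_to_neg")
        assert len(times) == 1
        assert times[0] == pytest.approx(0.5, abs=0.005)

    def test_all_positive_gives_empty(self):
        t = np.arange(100) / FS
        assert len(zero_crossings(np.ones(100) + np.sin(t), t)) == 0

    def test_exact_zero_attaches_to_preceding_run(self):
        # +1 +1 0 +1: the touch does not count as a crossing
        t = np.arange(4.0)
        assert len(zero_crossings(np.array([1.0, 1.0, 0.0, 1.0]), t)) == 0
        # +1 0 -1 crosses once
        assert len(zero_crossings(np.array([1.0, 0.0, -1.0]), t[:3])) == 1

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.lists(st.sampled_from([-1.0, 1.0]), min_size=2, max_size=60))
    def test_count_matches_brute_force_sign_scan(self, ys):
        y = np.array(ys)
        t = np.arange(len(y), dtype=float)
        brute = sum(1 for a, b in zip(y[:-1], y[1:]) if a * b < 0)
        assert len(zero_crossings(y, t)) == brute


class TestStimulusSpeedPeaks:
    def test_quarter_hz_peak_grid(self):
        seg = StimulusSegment(0.25, 20.0, 0.0, 0.0, 20.0)
        peaks = stimulus_speed_peaks(seg)
        np.testing.assert_allclose(peaks, np.arange(0.0, 20.0, 2.0), atol=1e-9)

    def test_count_by_direct_enumeration(self):
        # peaks every 1/(2f) on [t_start, t_end)
        seg = StimulusSegment(0.5625, 6.3, 0.0, 0.0, 18.0)
        peaks = stimulus_speed_peaks(seg)
        half = 1 / (2 * 0.5625)
        expected = [k * half for k in range(100) if k * half < 18.0]
        np.testing.assert_allclose(peaks, expected, atol=1e-9)

    def test_phase_shifts_the_grid(self):
        base = stimulus_speed_peaks(StimulusSegment(0.25, 20.0, 0.0, 0.0, 19.0))
        shifted = stimulus_speed_peaks(
            StimulusSegment(0.25, 20.0, 0.0, 0.0, 19.0, phase=np.pi / 2)
        )
        # phase pi/2 moves every peak by 1/(4f) = 1 s
        np.testing.assert_allclose(shifted[: len(base) - 1], base[:-1] + 1.0, atol=1e-9)


class TestDetectType2:
    def test_perfect_tracking_all_excluded(self, quiet_segment):
        trial, _, seg = quiet_segment
        prof = kinematic_profile(trial.t, trial.x, FS, cutoff=4.0)
        events = detect_type2(prof, seg, window_s=0.05, edge_exclusion_s=0.5)
        assert all(e.excluded for e in events)

    def test_lagged_response_counts_every_speed_peak(self):
        trial, _, seg = sinusoid_trial(lag=0.2, duration=20.0, clamp_onset=False)
        prof = kinematic_profile(trial.t, trial.x, FS, cutoff=4.0)
        events = detect_type2(prof, seg, window_s=0.05, edge_exclusion_s=0.0)
        assert sum(not e.excluded for e in events) == 10

    def test_injected_pulse_detected_at_its_time(self):
        plan = make_plan([0.25], [20.0], target_duration=20.0)
        spec = TrackerSpec(lag=0.0, pulses_per_stroke=0.4, seed=3)
        trial, truth = simulate_tracker(plan, spec)
        seg, sl = segment_trial(trial, plan)[0]
        prof = kinematic_profile(trial.t[sl], trial.x[sl], FS, cutoff=4.0)
        kept = [e for e in detect_type2(prof, seg, 0.05, 0.5) if not e.excluded]
        injected = truth.segments[0].peak_pulse_times
        assert len(kept) == len(injected)
        for e, tc in zip(kept, injected):
            assert abs(e.time - tc) < 0.08

    def test_counts_are_mirror_invariant(self):
        trial, _, seg = sinusoid_trial(lag=0.2)
        a = kinematic_profile(trial.t, trial.x, FS, cutoff=4.0)
        b = kinematic_profile(trial.t, -trial.x, FS, cutoff=4.0)
        na = sum(not e.excluded for e in detect_type2(a, seg, 0.05, 0.5))
        nb = sum(not e.excluded for e in detect_type2(b, seg, 0.05, 0.5))
        assert na == nb


def _pulse_train(events, duration=10.0):
    """Position trace from a baseline of rest plus min-jerk steps."""
    t = np.arange(0, duration, 1 / FS)
    x = np.zeros_like(t)
    for t0, amp, dur in events:
        w = min_jerk_pulse(amp, dur, FS)
        i0 = int(t0 * FS)
        x[i0:i0 + len(w)] += w
        x[i0 + len(w):] += amp
    return t, x


class TestDetectType3:
    def test_single_minimum_jerk_bell_yields_no_event(self):
        # both of the bell's jerk crossings carry the disqualifying
        # acceleration sign, so a lone submovement is not an inflection
        t, x = _pulse_train([(4.0, 5.0, 1.0)])
        prof = kinematic_profile(t, x, FS, cutoff=4.0)
        assert detect_type3(prof, edge_exclusion_s=0.5) == []

    def test_merged_bells_yield_one_shoulder_event(self):
        t, x = _pulse_train([(4.0, 5.0, 1.0), (4.5, 1.5, 1.0)])
        prof = kinematic_profile(t, x, FS, cutoff=4.0)
        events = detect_type3(prof, edge_exclusion_s=0.5)
        assert len(events) == 1
        assert 4.5 < events[0].time < 5.6  # on the shoulder
        # sign rule: pos->neg crossing while decelerating
        assert events[0].crossing_sign == "pos_to_neg"
        assert events[0].accel_at_crossing < 0

    def test_constant_speed_yields_no_event(self):
        t = np.arange(0, 10, 1 / FS)
        prof = kinematic_profile(t, 2.0 * t, FS, cutoff=4.0)
        assert detect_type3(prof, edge_exclusion_s=0.5) == []

    def test_sign_rule_qualification(self):
        trial, _, _ = sinusoid_trial(lag=0.15)
        prof = kinematic_profile(trial.t, trial.x, FS, cutoff=4.0)
        for e in detect_type3(prof, edge_exclusion_s=0.5):
            if e.crossing_sign == "neg_to_pos":
                assert e.accel_at_crossing > 0
            else:
                assert e.accel_at_crossing < 0


class TestTremorRobustness:
    def test_low_cutoff_suppresses_tremor_high_cutoff_does_not(self):
        plan = make_plan([0.25], [20.0], target_duration=20.0)
        base = TrackerSpec(lag=0.12, seed=5)
        with_tremor = TrackerSpec(lag=0.12, tremor_amp=0.001, tremor_freq=6.0, seed=5)

        def counts(spec, cutoff):
            trial, _ = simulate_tracker(plan, spec)
            seg, sl = segment_trial(trial, plan)[0]
            prof = kinematic_profile(trial.t[sl], trial.x[sl], FS, cutoff=cutoff)
            n2 = sum(not e.excluded for e in detect_type2(prof, seg, 0.05, 0.5))
            return n2 + len(detect_type3(prof, 0.5))

        assert counts(with_tremor, 4.0) == counts(base, 4.0)
        assert counts(with_tremor, 10.0) != counts(base, 10.0)


class TestRates:
    def test_arithmetic(self):
        from subkin.submovements import SubmovementEvent

        seg = StimulusSegment(0.25, 20.0, 0.0, 0.0, 20.0)
        events = [
            SubmovementEvent(t, "type2", "pos_to_neg", 0.0) for t in np.linspace(1, 19, 12)
        ]
        r = rates(events, seg, duration_s=20.0)
        assert r.rate_total == pytest.approx(0.6)
        assert r.per_stroke_total == pytest.approx(1.2)

    def test_zero_events(self):
        seg = StimulusSegment(0.25, 20.0, 0.0, 0.0, 20.0)
        r = rates([], seg, duration_s=20.0)
        assert r.rate_total == 0.0 and r.per_stroke_total == 0.0

    def test_zero_duration_rejected(self):
        seg = StimulusSegment(0.25, 20.0, 0.0, 0.0, 20.0)
        with pytest.raises(ValueError):
            rates([], seg, duration_s=0.0)

    def test_excluded_events_do_not_count(self):
        from subkin.submovements import SubmovementEvent

        seg = StimulusSegment(0.25, 20.0, 0.0, 0.0, 20.0)
        events = [
            SubmovementEvent(1.0, "type2", "pos_to_neg", 0.0),
            SubmovementEvent(2.0, "type2", "pos_to_neg", 0.0, excluded=True),
            SubmovementEvent(3.0, "type3", "neg_to_pos", 1.0),
        ]
        r = rates(events, seg, duration_s=10.0)
        assert r.n_type2 == 1 and r.n_type3 == 1
        assert r.rate_total == pytest.approx(r.rate_type2 + r.rate_type3)

    def test_per_stroke_recovery_of_injected_pulses(self):
        # two injected pulses per stroke recovered through the full chain
        plan = make_plan([0.25], [20.0], target_duration=20.0)
        got, want = 0, 0
        for seed in range(12):
            spec = TrackerSpec(lag=0.0, pulses_per_stroke=2.0, seed=seed)
            trial, truth = simulate_tracker(plan, spec)
            seg, sl = segment_trial(trial, plan)[0]
            prof = kinematic_profile(trial.t[sl], trial.x[sl], FS, cutoff=4.0)
            got += sum(not e.excluded for e in detect_type2(prof, seg, 0.05, 0.5))
            want += len(truth.segments[0].peak_pulse_times)
        assert got == pytest.approx(want, rel=0.1)
        # and the placed count per stroke is near the requested rate
        n_strokes = 2 * 0.25 * (plan.segments[0].duration) * 12
        assert want / n_strokes == pytest.approx(2.0, abs=0.35)
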