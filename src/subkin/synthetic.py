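"""Synthetic mirror-game stimuli, tracker responses and whole cohorts.

The generator is open loop: the simulated tracker follows the sinusoidal
target with a constant reaction lag and a (possibly frequency-dependent)
gain error, and corrective submovements are injected on top with known times
so the detectors can be validated against ground truth.

Corrective pulses are two-phase velocity bells - a fast sin^2 attack
followed by a slow sin^2 release - aligned with the instantaneous movement
direction. The asymmetry is deliberate: the strong attack carves the
intended kinematic event while the gentle release blends back into the
ongoing movement with sub-threshold jerk, so each pulse produces exactly one
detectable event rather than an entry/exit pair (and it is also how real
corrective submovements superposed on tracking look: quick correction,
smooth resumption). Two amplitude regimes:

* **peak pulses** - attack acceleration overcomes the baseline deceleration,
  carving a distinct local speed maximum (a type 2 submovement); placed in
  the decelerating half of a stroke.
* **shoulder pulses** - attack stays below the baseline acceleration
  magnitude, bending the speed profile into a single qualifying inflection
  (a type 3 submovement) without creating a new speed peak; placed in
  either half of a stroke, in a calibrated phase zone where the attack jerk
  dominates the baseline jerk even after the 4 Hz analysis filter.

The net displacement each pulse injects is removed as a uniform velocity
over the segment (a constant velocity offset changes no
acceleration-of-speed zero crossings, so the injected event counts stay
interpretable). Placement also avoids the +/-50 ms stimulus speed-peak
exclusion windows, the response's own speed peaks and reversals, and the
segment-edge guard zones, so that each injected pulse is countable by the
corresponding detector.

Optional confounds: a fixed-frequency tremor sinusoid (default 6 Hz, above
the 4 Hz analysis cutoff) and white sensor noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .io import StimulusPlan, StimulusSegment, Trial
from .submovements import stimulus_speed_peaks

__all__ = [
    "TrackerSpec",
    "GroundTruth",
    "CohortSpec",
    "GroupEffects",
    "make_stimulus",
    "min_jerk_pulse",
    "simulate_tracker",
    "make_plan",
    "make_cohort",
    "DEFAULT_FREQUENCIES",
    "DEFAULT_AMPLITUDES",
]

#: six stimulus frequencies (Hz), linearly spaced over the studied range
DEFAULT_FREQUENCIES = tuple(np.round(np.linspace(0.25, 0.5625, 6), 6))

#: end-to-end movement amplitudes (cm) spanning the studied range
DEFAULT_AMPLITUDES = (6.3, 13.0, 19.8, 26.5, 33.2)

_F_REF = float(np.mean(DEFAULT_FREQUENCIES))  # grid centre, 0.40625 Hz


def _as_freq_map(value: float | Mapping[float, float], freq: float) -> float:
    """Resolve a scalar-or-per-frequency parameter at ``freq``."""
    if isinstance(value, Mapping):
        key = min(value, key=lambda k: abs(k - freq))
        return float(value[key])
    return float(value)


#: two-phase pulse timing (s): fast attack, slow release
ATTACK_S = 0.18
RELEASE_S = 0.45

#: attack-peak acceleration relative to the local baseline acceleration
#: magnitude: shoulder pulses stay below it, peak pulses overcome it
SHOULDER_ACCEL_FRAC = 0.6
PEAK_ACCEL_FRAC = 1.7

#: minimum detectable shoulder-pulse acceleration (fraction of the local
#: baseline acceleration), measured by single-pulse simulation through the
#: 4 Hz analysis chain on a (frequency x phase) grid; phase is the fraction
#: of the quarter-cycle from the speed peak toward the reversal. Larger at
#: low phase (high baseline jerk near the peak) and at high frequency
#: (filtered reversal-kink jerk). Pulses are sized at SHOULDER_MARGIN times
#: this threshold, capped by the acceleration-sign constraint - the minimal
#: detectable footprint keeps the injected position error small.
_P3_CF = np.array([0.45, 0.60, 0.75, 0.90])
_P3_F = np.array([0.25, 0.375, 0.4375, 0.5, 0.5625])
_P3_MIN = np.array(
    [
        [0.40, 0.25, 0.15, 0.08],
        [0.60, 0.40, 0.25, 0.15],
        [0.60, 0.40, 0.25, 0.15],
        [0.60, 0.40, 0.40, 0.25],
        [0.90, 0.60, 0.40, 0.25],
    ]
)
SHOULDER_MARGIN = 1.35


def _shoulder_frac(frequency: float, cf: np.ndarray) -> np.ndarray:
    """Shoulder attack acceleration as a fraction of the local baseline."""
    i = int(np.clip(np.searchsorted(_P3_F, frequency) - 1, 0, len(_P3_F) - 2))
    w = (frequency - _P3_F[i]) / (_P3_F[i + 1] - _P3_F[i])
    w = float(np.clip(w, 0.0, 1.0))
    row = (1 - w) * _P3_MIN[i] + w * _P3_MIN[i + 1]
    frac = SHOULDER_MARGIN * np.interp(cf, _P3_CF, row)
    return np.minimum(frac, SHOULDER_ACCEL_FRAC)

#: minimum attack-peak acceleration (cm/s^2) so peak pulses stay detectable
#: near the baseline's acceleration zeros
PEAK_ACCEL_FLOOR_FRAC = 0.25  # of the segment's peak baseline acceleration


@dataclass
class TrackerSpec:
    """Generative parameters of one simulated participant.

    ``pulses_per_stroke`` / ``shoulder_pulses_per_stroke`` may be scalars or
    per-frequency maps (Hz -> rate), which is how frequency-declining
    correction rates are expressed. ``gain`` likewise.
    """

    lag: float = 0.12
    gain: float | Mapping[float, float] = 1.0
    pulses_per_stroke: float | Mapping[float, float] = 0.0
    shoulder_pulses_per_stroke: float | Mapping[float, float] = 0.0
    wobble_sd: float = 0.0
    tremor_freq: float = 6.0
    tremor_amp: float = 0.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.lag, self.noise_sd, self.tremor_amp, self.wobble_sd) < 0:
            raise ValueError("lag, noise_sd, tremor_amp and wobble_sd must be >= 0")


@dataclass
class SegmentTruth:
    segment_index: int
    frequency: float
    peak_pulse_times: list[float]
    shoulder_pulse_times: list[float]


@dataclass
class GroundTruth:
    """What the generator actually injected, per segment."""

    lag: float
    spec: TrackerSpec
    segments: list[SegmentTruth] = field(default_factory=list)

    def n_peak_pulses(self) -> int:
        return sum(len(s.peak_pulse_times) for s in self.segments)

    def n_shoulder_pulses(self) -> int:
        return sum(len(s.shoulder_pulse_times) for s in self.segments)


def _plan_position(plan: StimulusPlan, t: np.ndarray) -> np.ndarray:
    """Analytic target position for arbitrary times (lead-in = first centre)."""
    t = np.asarray(t, dtype=float)
    first = plan.segments[0]
    x = np.full_like(t, first.position(np.array([first.t_start]))[0])
    for seg in plan.segments:
        m = (t >= seg.t_start) & (t < seg.t_end)
        x[m] = seg.position(t[m])
    last = plan.segments[-1]
    m = t >= last.t_end
    if np.any(m):
        x[m] = last.position(np.array([last.t_end]))[0]
    return x


def make_stimulus(
    plan: StimulusPlan,
    fs: float = 100.0,
    participant_id: str = "stimulus",
    group: str = "YC",
    trial_index: int = 0,
) -> Trial:
    """Sample the analytic target of ``plan`` on a uniform time base."""
    n = int(round(plan.duration * fs))
    t = np.arange(n) / fs
    return Trial(
        participant_id=participant_id,
        group=group,
        trial_index=trial_index,
        t=t,
        x=_plan_position(plan, t),
    )


def min_jerk_pulse(amplitude: float, duration: float, fs: float) -> np.ndarray:
    """Displacement waveform of a minimum-jerk corrective pulse.

    Returns position samples rising smoothly from 0 to ``amplitude`` over
    ``duration``; the corresponding speed profile is the bell
    ``30*(A/T)*u^2*(1-u)^2`` with a single interior peak of height
    ``1.875*A/T`` at the midpoint.
    """
    n = int(round(duration * fs)) + 1
    if n < 10:
        raise ValueError("pulse duration must span at least 10 samples")
    u = np.linspace(0.0, 1.0, n)
    return amplitude * (10 * u**3 - 15 * u**4 + 6 * u**5)


def _stroke_edges(seg: StimulusSegment) -> np.ndarray:
    """Reversal times (position extremes) of a segment's target, absolute s."""
    f, ph = seg.frequency, seg.phase
    w = 2 * np.pi * f
    half = 1.0 / (2 * f)
    tau0 = ((np.pi / 2 - ph) / w) % half
    taus = np.arange(tau0, seg.duration, half)
    return seg.t_start + taus


def _pulse_displacement(
    tseg: np.ndarray, t_start: float, vp: float, reverse: bool = False
) -> np.ndarray:
    """Displacement of one two-phase pulse starting at ``t_start``.

    Forward: ``sin^2`` velocity rise over ``ATTACK_S`` then a ``cos^2`` fall
    over ``RELEASE_S`` (closed-form integral). ``reverse`` time-mirrors the
    waveform (slow rise, fast fall) - under the zero-phase analysis filter
    the reversed pulse behaves on an accelerating quarter exactly as the
    forward pulse does on a decelerating one.
    """
    extent = ATTACK_S + RELEASE_S
    tr = tseg - t_start
    if reverse:
        tr = extent - tr
    disp = np.zeros_like(tseg)
    m1 = (tr >= 0) & (tr < ATTACK_S)
    u = tr[m1] / ATTACK_S
    disp[m1] = vp * ATTACK_S * (u / 2 - np.sin(np.pi * u) / (2 * np.pi))
    d1 = vp * ATTACK_S / 2
    m2 = (tr >= ATTACK_S) & (tr < extent)
    w = (tr[m2] - ATTACK_S) / RELEASE_S
    disp[m2] = d1 + vp * RELEASE_S * (w / 2 + np.sin(np.pi * w) / (2 * np.pi))
    total = d1 + vp * RELEASE_S / 2
    disp[tr >= extent] = total
    if reverse:
        disp = total - disp
    return disp


#: duration (s) of the slow smooth return that undoes each pulse's
#: displacement; its acceleration and jerk stay below the detection
#: thresholds, so the return itself produces no events
RETURN_S = 1.8


def _smooth_step(u: np.ndarray) -> np.ndarray:
    """C1 monotone 0->1 ramp (cos^2 velocity profile)."""
    u = np.clip(u, 0.0, 1.0)
    return u - np.sin(2 * np.pi * u) / (2 * np.pi)


def _add_pulses(
    x: np.ndarray,
    tseg: np.ndarray,
    centres: np.ndarray,
    signs: np.ndarray,
    vps: np.ndarray,
    reversed_flags: np.ndarray,
    lo: int,
    hi: int,
) -> None:
    """Superpose pulses (centre = fast-phase midpoint) with slow returns.

    Each pulse's net displacement is taken back by a smooth sub-threshold
    return over ``RETURN_S`` starting at the pulse end (for time-reversed
    pulses the return precedes the pulse), so the trace deviates from the
    baseline only transiently and the segment carries no net drift.
    """
    if len(centres) == 0:
        return
    extent = ATTACK_S + RELEASE_S
    for c, s, vp, rev in zip(centres, signs, vps, reversed_flags):
        start = c - (extent - ATTACK_S / 2 if rev else ATTACK_S / 2)
        x[lo:hi] += s * _pulse_displacement(tseg, start, vp, bool(rev))
        disp = vp * extent / 2
        x[lo:hi] -= s * disp * _smooth_step((tseg - (start + extent)) / RETURN_S)


#: calibrated placement zone for shoulder pulses, as a fraction of the
#: quarter-cycle between a speed peak and the adjacent reversal: inside
#: this band the fast-phase jerk dominates the baseline jerk after the 4 Hz
#: analysis filter while its acceleration stays below the baseline's
def _shoulder_zone(frequency: float) -> tuple[float, float]:
    if frequency > 0.52:
        return (0.70, 0.92)
    if frequency > 0.33:
        return (0.60, 0.92)
    return (0.45, 0.92)


#: placement zone for peak pulses; kept near the speed peak, where the
#: baseline acceleration (and hence the required pulse size) is smallest
PEAK_ZONE = (0.25, 0.60)

#: minimum spacing between the fast-phase centres of two pulses (s)
PULSE_SPACING_S = 0.20

#: passband (Hz) of the motor-wobble process, inside the 4 Hz analysis band
_WOBBLE_BAND = (1.5, 3.5)

#: reference end-to-end amplitude (cm, incl. unit gain) at which
#: ``TrackerSpec.wobble_sd`` is the realised wobble SD
_WOBBLE_REF_AMP = 22.8

# ---------------------------------------------------------------------------
# Cohort operating point (calibrated by simulation through the full
# filtering + detection chain, at 100 Hz, 4 Hz analysis cutoff, sensor noise
# 0.005 cm, lag ~0.12 s, gain ~1.15, amplitudes cycling over the default
# grid). The motor wobble supplies the frequency-declining inflection
# (type 3) base - its jerk is fixed while the movement's own jerk grows as
# V*omega^2, so slow strokes collect far more inflections - and the group
# offset rides on the wobble amplitude plus a high-frequency shoulder-pulse
# top-up where the wobble sensitivity flattens. Peak (type 2) pulses follow
# a fixed declining profile; the tracker's own lagged speed peaks (2f per
# second, outside the 50 ms exclusion window whenever the lag exceeds it)
# supply the rest of the type 2 count.
# ---------------------------------------------------------------------------
_CAL_F = np.array([0.25, 0.3125, 0.375, 0.4375, 0.5, 0.5625])
#: baseline wobble amplitude (cm, SD of the band-limited process)
WOBBLE_BASE = 0.018
#: wobble amplitude change per unit detected type-3 rate offset (cm per
#: events/s), valid in the sub-saturation band ~[0.004, 0.032] cm
_SW_PER_RATE = 0.033
#: shoulder-pulse top-up (requested events/s per unit type-3 offset) where
#: the wobble channel alone under-delivers the offset
_CAL_R3_TOPUP = np.array([0.0, 0.0, 0.0, 0.45, 0.75, 0.75])
#: peak-pulse injection profile (requested events/s)
_CAL_R2PROF = np.array([1.00, 0.82, 0.64, 0.46, 0.28, 0.10])
#: relative position error contributed by the pulses + wobble + sensor
#: noise at this operating point (beyond the gain-error closed form)
_CAL_DX_EXC = np.array([0.117, 0.183, 0.254, 0.341, 0.340, 0.202])


def _dx_to_gain(dx: float) -> float:
    """Gain whose closed-form relative position error is ``dx``."""
    return 1.0 + 2.0 * dx / (2.0 - dx)


def simulate_tracker(
    plan: StimulusPlan,
    spec: TrackerSpec,
    fs: float = 100.0,
    participant_id: str = "sim",
    group: str = "YC",
    trial_index: int = 0,
    exclusion_window_s: float = 0.05,
    edge_exclusion_s: float = 0.5,
) -> tuple[Trial, GroundTruth]:
    """Simulate one trial of tracking behaviour with known ground truth."""
    centers = {seg.center for seg in plan.segments}
    if len(centers) > 1:
        raise ValueError("simulate_tracker requires a common segment centre")
    c = plan.segments[0].center
    rng = np.random.default_rng(spec.seed)

    n = int(round(plan.duration * fs))
    t = np.arange(n) / fs
    stim_delayed = _plan_position(plan, t - spec.lag)

    # gain-scaled, lag-delayed baseline (gain resolved per segment of t)
    x = np.full(n, c, dtype=float)
    truth = GroundTruth(lag=spec.lag, spec=spec)
    for k, seg in enumerate(plan.segments):
        lo = int(np.searchsorted(t, seg.t_start, "left"))
        hi = int(np.searchsorted(t, seg.t_end, "left"))
        g = _as_freq_map(spec.gain, seg.frequency)
        x[lo:hi] = c + g * (stim_delayed[lo:hi] - c)

        tseg = t[lo:hi]
        f = seg.frequency
        w = 2 * np.pi * f
        quarter = 1.0 / (4.0 * f)
        extent = ATTACK_S + RELEASE_S
        # response-timeline features (shifted by the reaction lag)
        resp_peaks = stimulus_speed_peaks(seg) + spec.lag
        stim_peaks = stimulus_speed_peaks(seg)
        V = g * np.pi * f * seg.amplitude_p2p  # response peak speed
        a_peak = V * w  # response peak |accel| (of speed)

        def phase_tau(times: np.ndarray) -> np.ndarray:
            """Signed offset from the nearest response speed peak (s)."""
            if len(resp_peaks) == 0:
                return np.full_like(times, np.inf)
            i = np.argmin(np.abs(times[:, None] - resp_peaks[None, :]), axis=1)
            return times - resp_peaks[i]

        def far(times_ref: np.ndarray, times: np.ndarray, radius: float) -> np.ndarray:
            if len(times_ref) == 0:
                return np.ones_like(times, dtype=bool)
            d = np.min(np.abs(times[:, None] - times_ref[None, :]), axis=1)
            return d > radius

        lo_t = seg.t_start + edge_exclusion_s + ATTACK_S
        hi_t = seg.t_end - edge_exclusion_s - ATTACK_S  # slow tail may run on
        interior = (tseg >= lo_t) & (tseg <= hi_t)
        tau = phase_tau(tseg)

        # decelerating quarters lie after a speed peak (tau > 0): forward
        # pulses; accelerating quarters before one (tau < 0): time-reversed
        # pulses. Peak pulses must additionally clear the stimulus-peak
        # exclusion windows so the carved speed peak stays countable.
        z2l, z2h = PEAK_ZONE
        in_zone2 = (np.abs(tau) >= z2l * quarter) & (np.abs(tau) <= z2h * quarter)
        ok2 = interior & in_zone2 & far(stim_peaks, tseg, exclusion_window_s + 0.08)
        z3l, z3h = _shoulder_zone(f)
        ok3 = interior & (np.abs(tau) >= z3l * quarter) & (np.abs(tau) <= z3h * quarter)

        pps2 = _as_freq_map(spec.pulses_per_stroke, f)
        pps3 = _as_freq_map(spec.shoulder_pulses_per_stroke, f)
        n_strokes = 2.0 * f * seg.duration
        n2 = rng.poisson(pps2 * n_strokes) if pps2 > 0 else 0
        n3 = rng.poisson(pps3 * n_strokes) if pps3 > 0 else 0

        # interleaved placement: each pulse takes the first feasible
        # candidate of a fresh random permutation of its zone, so neither
        # kind systematically crowds the other out
        placed: list[float] = []  # fast-phase centres
        cand2, cand3 = np.flatnonzero(ok2), np.flatnonzero(ok3)
        kinds = np.array(["2"] * n2 + ["3"] * n3)
        rng.shuffle(kinds)
        out2: list[float] = []
        out3: list[float] = []
        for kind in kinds:
            cand = cand2 if kind == "2" else cand3
            if len(cand) == 0:
                continue
            for i in rng.permutation(len(cand)):
                tc = tseg[cand[i]]
                if all(abs(tc - p) > PULSE_SPACING_S for p in placed):
                    placed.append(tc)
                    (out2 if kind == "2" else out3).append(tc)
                    break
        c2, c3 = np.array(sorted(out2)), np.array(sorted(out3))

        def signs_at(times: np.ndarray) -> np.ndarray:
            """Pulse direction = instantaneous direction of response motion."""
            v = np.cos(w * (times - spec.lag - seg.t_start) + seg.phase)
            s = np.sign(v)
            s[s == 0] = 1.0
            return s

        def local_kin(times: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
            ph = w * (times - spec.lag - seg.t_start) + seg.phase
            return a_peak * np.abs(np.sin(ph)), a_peak * w * np.abs(np.cos(ph))

        if len(c2):
            a_local, _ = local_kin(c2)
            P = np.maximum(PEAK_ACCEL_FRAC * a_local, PEAK_ACCEL_FLOOR_FRAC * a_peak)
            _add_pulses(
                x, tseg, c2, signs_at(c2), 2.0 * P * ATTACK_S / np.pi,
                phase_tau(c2) < 0, lo, hi,
            )
        if len(c3):
            a_local, _ = local_kin(c3)
            cf3 = np.abs(phase_tau(c3)) / quarter
            P = _shoulder_frac(f, cf3) * a_local
            _add_pulses(
                x, tseg, c3, signs_at(c3), 2.0 * P * ATTACK_S / np.pi,
                phase_tau(c3) < 0, lo, hi,
            )
        truth.segments.append(
            SegmentTruth(
                segment_index=k,
                frequency=f,
                peak_pulse_times=list(c2),
                shoulder_pulse_times=list(c3),
            )
        )

    if spec.wobble_sd > 0:
        # in-band (1.5-3.5 Hz) motor wobble: smooth involuntary corrections
        # below the analysis cutoff; its jerk rides over the baseline's on
        # slow strokes, which is what makes slow tracking unsmooth. The
        # wobble is signal-dependent (scaled by each segment's movement
        # amplitude including the gain error), as motor noise grows with
        # movement size; ``wobble_sd`` is the SD at the reference amplitude.
        from scipy import signal as _sig

        sos = _sig.butter(2, _WOBBLE_BAND, btype="bandpass", fs=fs, output="sos")
        wob = _sig.sosfiltfilt(sos, rng.normal(0.0, 1.0, n))
        sd = float(np.std(wob))
        if sd > 0:
            env = np.zeros(n)
            for seg in plan.segments:
                lo = int(np.searchsorted(t, seg.t_start, "left"))
                hi = int(np.searchsorted(t, seg.t_end, "left"))
                g = _as_freq_map(spec.gain, seg.frequency)
                env[lo:hi] = g * seg.amplitude_p2p / _WOBBLE_REF_AMP
            x += spec.wobble_sd / sd * env * wob
    if spec.tremor_amp > 0:
        x += spec.tremor_amp * np.sin(
            2 * np.pi * spec.tremor_freq * t + rng.uniform(0, 2 * np.pi)
        )
    if spec.noise_sd > 0:
        x += rng.normal(0.0, spec.noise_sd, n)

    trial = Trial(
        participant_id=participant_id,
        group=group,
        trial_index=trial_index,
        t=t,
        x=x,
    )
    return trial, truth


def make_plan(
    frequencies: list[float],
    amplitudes: list[float],
    lead_in: float = 5.0,
    target_duration: float = 18.33,
    center: float = 0.0,
) -> StimulusPlan:
    """Build a contiguous plan from (frequency, amplitude) pairs.

    Each segment's duration is quantised to a whole number of half-periods
    near ``target_duration`` (within the study's 18-22 s band when the
    frequency permits), so segments start and end at the movement centre and
    the target stays position-continuous across frequency changes. The phase
    of each segment continues the direction of motion of the previous one.
    """
    segs: list[StimulusSegment] = []
    t0 = lead_in
    direction = 1.0
    for f, a in zip(frequencies, amplitudes):
        n_half = max(1, int(round(2 * f * target_duration)))
        dur = n_half / (2 * f)
        phase = 0.0 if direction > 0 else np.pi
        segs.append(
            StimulusSegment(
                frequency=f, amplitude_p2p=a, center=center,
                t_start=t0, t_end=t0 + dur, phase=phase,
            )
        )
        # direction at segment end: sign of cos(pi*n_half + phase_offset)
        direction = direction * (1.0 if n_half % 2 == 0 else -1.0)
        t0 += dur
    return StimulusPlan(segments=segs, lead_in=lead_in)


@dataclass
class GroupEffects:
    """Generative group-level behaviour, defaulting to the studied cohorts.

    ``type3_rate_offset`` is a detected-scale rate offset (events/s)
    relative to the older-control baseline; ``dT_mean`` is the group's mean
    reaction lag (s); dX values are relative-position-error targets, with a
    per-Hz slope across the frequency grid.
    """

    type3_rate_offset: float = 0.0
    dT_mean: float = 0.12
    dX_mean: float = 0.25
    dX_slope_per_hz: float = 0.6
    dX_slope_sd: float = 0.5


#: defaults emulating the three studied groups (people with Parkinson's,
#: age-matched older controls, younger controls)
DEFAULT_GROUP_EFFECTS: dict[str, GroupEffects] = {
    "PwP": GroupEffects(
        type3_rate_offset=0.31, dT_mean=0.183,
        dX_mean=0.389, dX_slope_per_hz=1.16, dX_slope_sd=0.73,
    ),
    "OC": GroupEffects(
        type3_rate_offset=0.0, dT_mean=0.147,
        dX_mean=0.265, dX_slope_per_hz=0.75, dX_slope_sd=0.49,
    ),
    "YC": GroupEffects(
        type3_rate_offset=0.04, dT_mean=0.102,
        dX_mean=0.181, dX_slope_per_hz=0.53, dX_slope_sd=0.43,
    ),
}


@dataclass
class CohortSpec:
    """Design of a synthetic cohort.

    Defaults reproduce the study conditions: three groups, ~30 participants
    each, 11 trials per participant of three 18-22 s constant-frequency
    segments after a 5 s stationary lead-in, six frequencies between 0.25
    and 0.5625 Hz crossed with end-to-end amplitudes 6.3-33.2 cm.
    """

    n_per_group: int = 30
    groups: tuple[str, ...] = ("PwP", "OC", "YC")
    group_effects: dict[str, GroupEffects] = field(
        default_factory=lambda: dict(DEFAULT_GROUP_EFFECTS)
    )
    frequency_grid: tuple[float, ...] = DEFAULT_FREQUENCIES
    amplitude_grid: tuple[float, ...] = DEFAULT_AMPLITUDES
    n_trials: int = 11
    segments_per_trial: int = 3
    segment_duration: float = 18.33
    # between-participant spreads (SD), at the scale of each measure
    wobble_sd_spread: float = 0.011
    type2_scale_sd: float = 0.25
    dT_sd: float = 0.05
    dX_sd: float = 0.12
    wobble_base: float = WOBBLE_BASE
    noise_sd: float = 0.005
    tremor_amp: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")


def _participant_spec(
    eff: GroupEffects,
    spec: CohortSpec,
    rng: np.random.Generator,
    seed: int,
) -> tuple[TrackerSpec, dict]:
    """Draw one participant's tracker parameters from the group distribution."""
    freqs = np.asarray(spec.frequency_grid)
    lag = float(np.clip(rng.normal(eff.dT_mean, spec.dT_sd), 0.06, 0.45))
    dx0 = rng.normal(eff.dX_mean, spec.dX_sd)
    dx_slope = rng.normal(eff.dX_slope_per_hz, eff.dX_slope_sd)
    # the type-3 offset rides on the wobble amplitude (with the personal
    # smoothness drawn on the same scale) plus the high-frequency shoulder
    # top-up; the wobble band is kept inside its calibrated monotone range
    sw = float(
        np.clip(
            rng.normal(
                spec.wobble_base + _SW_PER_RATE * eff.type3_rate_offset,
                spec.wobble_sd_spread,
            ),
            0.004,
            0.032,
        )
    )
    r2_scale = max(0.0, rng.normal(1.0, spec.type2_scale_sd))

    gain_map, pps2_map, pps3_map = {}, {}, {}
    for f in freqs:
        r2 = r2_scale * float(np.interp(f, _CAL_F, _CAL_R2PROF))
        r3 = eff.type3_rate_offset * float(np.interp(f, _CAL_F, _CAL_R3_TOPUP))
        # pulses, wobble and sensor noise already contribute position
        # error; the gain error supplies the remainder of the dX target
        dx_tgt = float(np.clip(dx0 + dx_slope * (f - _F_REF), 0.01, 1.5))
        dx_gain = float(
            np.clip(dx_tgt - np.interp(f, _CAL_F, _CAL_DX_EXC), 0.005, 1.5)
        )
        gain_map[float(f)] = _dx_to_gain(dx_gain)
        pps2_map[float(f)] = r2 / (2.0 * f)
        pps3_map[float(f)] = r3 / (2.0 * f)

    tracker = TrackerSpec(
        lag=lag,
        gain=gain_map,
        pulses_per_stroke=pps2_map,
        shoulder_pulses_per_stroke=pps3_map,
        wobble_sd=sw,
        noise_sd=spec.noise_sd,
        tremor_amp=spec.tremor_amp,
        seed=seed,
    )
    truth_row = {
        "lag": lag,
        "dX_target": float(dx0),
        "dX_slope_target": float(dx_slope),
        "wobble_sd": sw,
        "type3_rate_offset": float(eff.type3_rate_offset),
        "type2_scale": float(r2_scale),
    }
    return tracker, truth_row


def make_cohort(
    spec: CohortSpec,
    fs: float = 100.0,
) -> tuple[list[tuple[Trial, StimulusPlan]], pd.DataFrame]:
    """Generate a full synthetic cohort.

    Returns one (trial, plan) pair per participant x trial and a truth table
    with one row per participant recording the generative parameters.
    Deterministic for a fixed ``spec.seed``.
    """
    master = np.random.default_rng(spec.seed)
    n_seg_total = spec.n_trials * spec.segments_per_trial
    freqs = list(spec.frequency_grid)
    amps = list(spec.amplitude_grid)

    dataset: list[tuple[Trial, StimulusPlan]] = []
    truth_rows: list[dict] = []
    for group in spec.groups:
        eff = spec.group_effects[group]
        for i in range(spec.n_per_group):
            pid = f"{group}{i:03d}"
            prng = np.random.default_rng(master.integers(0, 2**31 - 1))
            tracker, row = _participant_spec(eff, spec, prng, int(prng.integers(0, 2**31 - 1)))
            # counterbalanced segment list: every frequency equally often
            seg_freqs = [freqs[k % len(freqs)] for k in range(n_seg_total)]
            seg_amps = [amps[k % len(amps)] for k in range(n_seg_total)]
            order = prng.permutation(n_seg_total)
            seg_freqs = [seg_freqs[k] for k in order]
            seg_amps = [seg_amps[k] for k in order]
            for j in range(spec.n_trials):
                fa = slice(j * spec.segments_per_trial, (j + 1) * spec.segments_per_trial)
                plan = make_plan(
                    seg_freqs[fa], seg_amps[fa],
                    target_duration=spec.segment_duration,
                )
                trial, _ = simulate_tracker(
                    plan,
                    replace(tracker, seed=int(prng.integers(0, 2**31 - 1))),
                    fs=fs,
                    participant_id=pid,
                    group=group,
                    trial_index=j,
                )
                dataset.append((trial, plan))
            truth_rows.append({"participant_id": pid, "group": group, **row})
    return dataset, pd.DataFrame(truth_rows)
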