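"""Type 2 and type 3 submovement detection.

Submovements are discrete kinematic sub-units visible as structure in the
speed profile of an ostensibly smooth movement:

* **type 2** - a peak in the speed profile, detected as a zero crossing of
  the acceleration (d speed / dt) from positive to negative. Speed peaks
  that merely mirror the sinusoidal target's own speed peaks (within a
  +/-50 ms window of an analytic stimulus speed-peak time) are flagged
  ``excluded`` and do not enter rate computations.
* **type 3** - an inflection ("re-acceleration") in the speed profile,
  detected as a jerk zero crossing from negative to positive while the
  acceleration is positive, or from positive to negative while the
  acceleration is negative. No stimulus-peak exclusion applies.

Type 1 submovements (overshoot corrections) are not computed: overshoot is
not a feature of continuous tracking.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .io import StimulusSegment
from .preprocess import KinematicProfile

__all__ = [
    "SubmovementEvent",
    "zero_crossings",
    "stimulus_speed_peaks",
    "detect_type2",
    "detect_type3",
    "rates",
    "SegmentRates",
]

#: below this |acceleration| (cm/s^2) a type 3 crossing is treated as
#: degenerate (flat) and disqualified
ACCEL_EPS = 1e-9


@dataclass
class SubmovementEvent:
    time: float
    kind: Literal["type2", "type3"]
    crossing_sign: Literal["pos_to_neg", "neg_to_pos"]
    accel_at_crossing: float
    excluded: bool = False
    exclusion_reason: str | None = None


def zero_crossings(
    y: np.ndarray,
    t: np.ndarray,
    direction: Literal["pos_to_neg", "neg_to_pos", "both"] = "both",
) -> np.ndarray:
    """Linearly interpolated zero-crossing times of ``y``.

    A sample exactly at zero is attached to the preceding sign run, so a
    touch-and-return does not count as a crossing and a plateau at zero
    crosses only once, at its far end.
    """
    y = np.asarray(y, dtype=float)
    t = np.asarray(t, dtype=float)
    if y.shape != t.shape:
        raise ValueError("y and t must have the same shape")
    s = np.sign(y)
    # zeros inherit the preceding nonzero sign
    for i in range(1, len(s)):
        if s[i] == 0:
            s[i] = s[i - 1]
    idx = np.flatnonzero(s[:-1] * s[1:] < 0)
    if direction == "pos_to_neg":
        idx = idx[s[idx] > 0]
    elif direction == "neg_to_pos":
        idx = idx[s[idx] < 0]
    # linear interpolation between the flanking samples
    y0, y1 = y[idx], y[idx + 1]
    frac = np.where(y1 != y0, y0 / (y0 - y1), 0.5)
    return t[idx] + frac * (t[idx + 1] - t[idx])


def stimulus_speed_peaks(segment: StimulusSegment) -> np.ndarray:
    """Analytic speed-peak times (absolute s) of a sinusoidal target.

    The target speed is proportional to |cos(2*pi*f*(t - t_start) + phase)|,
    peaking every 1/(2f) s. Boundary rule: peaks are enumerated on the
    half-open interval [t_start, t_end).
    """
    f = segment.frequency
    # peaks where 2*pi*f*tau + phase = k*pi  ->  tau = (k*pi - phase)/(2*pi*f)
    half = 1.0 / (2.0 * f)
    tau0 = (-segment.phase / (2.0 * np.pi * f)) % half
    n = int(np.floor((segment.duration - tau0) / half - 1e-12)) + 1
    if segment.duration - tau0 <= 1e-12:
        n = 0
    taus = tau0 + half * np.arange(max(n, 0))
    return segment.t_start + taus


def _interp_at(t: np.ndarray, y: np.ndarray, times: np.ndarray) -> np.ndarray:
    return np.interp(times, t, y)


def _edge_mask(times: np.ndarray, t: np.ndarray, edge_exclusion_s: float) -> np.ndarray:
    """True for event times inside the analysed interior of the segment."""
    return (times >= t[0] + edge_exclusion_s) & (times <= t[-1] - edge_exclusion_s)


def detect_type2(
    profile: KinematicProfile,
    segment: StimulusSegment,
    window_s: float = 0.05,
    edge_exclusion_s: float = 0.5,
) -> list[SubmovementEvent]:
    """Speed peaks (acceleration pos->neg crossings), with the stimulus-peak
    exclusion window applied.

    All interior events are returned; those within ``window_s`` (two-sided)
    of an analytic stimulus speed-peak time carry ``excluded=True``.
    """
    times = zero_crossings(profile.accel, profile.t, "pos_to_neg")
    times = times[_edge_mask(times, profile.t, edge_exclusion_s)]
    peaks = stimulus_speed_peaks(segment)
    events: list[SubmovementEvent] = []
    for tt in times:
        dist = np.min(np.abs(peaks - tt)) if len(peaks) else np.inf
        excl = bool(dist <= window_s)
        events.append(
            SubmovementEvent(
                time=float(tt),
                kind="type2",
                crossing_sign="pos_to_neg",
                accel_at_crossing=0.0,
                excluded=excl,
                exclusion_reason="near stimulus speed peak" if excl else None,
            )
        )
    return events


def detect_type3(
    profile: KinematicProfile,
    edge_exclusion_s: float = 0.5,
) -> list[SubmovementEvent]:
    """Speed-profile inflections from sign-qualified jerk zero crossings."""
    events: list[SubmovementEvent] = []
    for direction, wanted in (("neg_to_pos", 1.0), ("pos_to_neg", -1.0)):
        times = zero_crossings(profile.jerk, profile.t, direction)
        times = times[_edge_mask(times, profile.t, edge_exclusion_s)]
        accel = _interp_at(profile.t, profile.accel, times)
        ok = wanted * accel > ACCEL_EPS
        for tt, aa in zip(times[ok], accel[ok]):
            events.append(
                SubmovementEvent(
                    time=float(tt),
                    kind="type3",
                    crossing_sign=direction,
                    accel_at_crossing=float(aa),
                )
            )
    events.sort(key=lambda e: e.time)
    return events


@dataclass
class SegmentRates:
    """Per-second and per-stroke submovement rates for one segment."""

    rate_type2: float
    rate_type3: float
    rate_total: float
    per_stroke_type2: float
    per_stroke_type3: float
    per_stroke_total: float
    n_type2: int
    n_type3: int
    duration_s: float
    n_strokes: float


def rates(
    events: list[SubmovementEvent],
    segment: StimulusSegment,
    duration_s: float,
) -> SegmentRates:
    """Convert event lists to per-second and per-stroke rates.

    ``duration_s`` is the analysed duration (segment minus edge-exclusion
    zones). The stroke count is the analytic ``2 * f * duration_s`` - in a
    tracking task the stimulus defines the stroke structure, so strokes are
    not counted from empirical reversals.
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    n2 = sum(1 for e in events if e.kind == "type2" and not e.excluded)
    n3 = sum(1 for e in events if e.kind == "type3" and not e.excluded)
    n_strokes = 2.0 * segment.frequency * duration_s
    return SegmentRates(
        rate_type2=n2 / duration_s,
        rate_type3=n3 / duration_s,
        rate_total=(n2 + n3) / duration_s,
        per_stroke_type2=n2 / n_strokes,
        per_stroke_type3=n3 / n_strokes,
        per_stroke_total=(n2 + n3) / n_strokes,
        n_type2=n2,
        n_type3=n3,
        duration_s=duration_s,
        n_strokes=n_strokes,
    )
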