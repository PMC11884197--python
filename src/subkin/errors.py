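"""Tracking-error measures: timing error dT and relative position error dX.

The participant trace is first registered to the analytic stimulus by a grid
search over non-negative integer-sample lags (participants react to a visible
target, so the trace lags the stimulus); the minimising lag is the mean
timing error dT. The relative position error is then computed on the
registered pair:

    dX = (2/n) * sum_i |x1_i - x2_i| / |x1_i + x2_i - 2*x_c|

where x1 is the registered participant position, x2 the stimulus and x_c the
sine midpoint; the denominator normalises by the instantaneous distance from
the movement centre (i.e. by movement amplitude). Samples whose denominator
falls below a pixel threshold are excluded to keep the measure stable near
the centre crossing. Both measures are zero or positive by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import AnalysisConfig
from .io import StimulusSegment
from .preprocess import lowpass

__all__ = ["RegistrationResult", "register", "relative_position_error", "segment_errors"]


@dataclass
class RegistrationResult:
    lag: float
    lag_samples: int
    objective_curve: np.ndarray
    registered_x: np.ndarray
    stimulus_x: np.ndarray


def register(
    x_part: np.ndarray,
    x_stim: np.ndarray,
    fs: float,
    max_lag_s: float = 1.0,
    allow_negative_lag: bool = False,
) -> RegistrationResult:
    """Estimate the participant's lag behind the stimulus.

    Minimises the mean squared difference between the participant trace
    advanced by tau samples and the stimulus, over integer tau in
    [0, max_lag_s*fs] (or symmetric if ``allow_negative_lag``), evaluated on
    the overlapping support. Ties break toward the smaller |lag|. The
    reported lag (dT) is |tau|/fs, so it is always non-negative.
    """
    x_part = np.asarray(x_part, dtype=float)
    x_stim = np.asarray(x_stim, dtype=float)
    if x_part.shape != x_stim.shape:
        raise ValueError("traces must have equal length")
    if np.ptp(x_part) == 0 or np.ptp(x_stim) == 0:
        raise ValueError("cannot register flat (zero-variance) traces")
    n = len(x_part)
    max_lag = int(round(max_lag_s * fs))
    if max_lag >= n // 2:
        raise ValueError("max_lag_s too large for the segment length")
    lags = np.arange(-max_lag, max_lag + 1) if allow_negative_lag else np.arange(max_lag + 1)
    curve = np.empty(len(lags))
    for i, tau in enumerate(lags):
        if tau >= 0:
            d = x_part[tau:] - x_stim[: n - tau]
        else:
            d = x_part[: n + tau] - x_stim[-tau:]
        curve[i] = np.mean(d * d)
    # tie-break toward smaller |lag|: argmin scans lags sorted by |lag|
    order = np.argsort(np.abs(lags), kind="stable")
    best = order[np.argmin(curve[order])]
    tau = int(lags[best])
    if tau >= 0:
        reg, stim = x_part[tau:], x_stim[: n - tau]
    else:
        reg, stim = x_part[: n + tau], x_stim[-tau:]
    return RegistrationResult(
        lag=abs(tau) / fs,
        lag_samples=tau,
        objective_curve=curve,
        registered_x=reg,
        stimulus_x=stim,
    )


def relative_position_error(
    x1: np.ndarray,
    x2: np.ndarray,
    x_c: float,
    min_denominator_px: float = 10.0,
    pixels_per_cm: float = 42.9,
) -> tuple[float, int]:
    """Amplitude-normalised mean absolute position error (dX).

    ``x1`` is the registered participant trace, ``x2`` the stimulus (cm) and
    ``x_c`` the sine midpoint. Samples with |x1 + x2 - 2*x_c| below
    ``min_denominator_px`` (converted to cm) are dropped from the sum and
    counted in the returned exclusion tally. Raises ``ValueError`` when every
    sample is excluded (degenerate, e.g. both traces resting at the centre).
    """
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    if x1.shape != x2.shape:
        raise ValueError("traces must have equal length")
    denom = np.abs(x1 + x2 - 2.0 * x_c)
    keep = denom >= min_denominator_px / pixels_per_cm
    n_excluded = int(np.sum(~keep))
    if not np.any(keep):
        raise ValueError("all samples excluded by the denominator threshold")
    dx = 2.0 * np.mean(np.abs(x1[keep] - x2[keep]) / denom[keep])
    return float(dx), n_excluded


def segment_errors(
    t: np.ndarray,
    x: np.ndarray,
    fs: float,
    segment: StimulusSegment,
    config: AnalysisConfig | None = None,
) -> tuple[float, float, int]:
    """dT and dX for one raw trial segment.

    Filters the raw positions at the error cutoff (10 Hz by default),
    registers against the analytic stimulus sampled on the same time base,
    then computes dX on the registered pair. Returns
    ``(dT, dX, n_samples_excluded)``.
    """
    config = config or AnalysisConfig()
    x_f = lowpass(x, fs, config.cutoff_errors, config.filter_order)
    x_stim = segment.position(np.asarray(t, dtype=float))
    reg = register(
        x_f, x_stim, fs,
        max_lag_s=config.max_lag_s,
        allow_negative_lag=config.allow_negative_lag,
    )
    dx, n_excl = relative_position_error(
        reg.registered_x,
        reg.stimulus_x,
        segment.center,
        min_denominator_px=config.min_denominator_px,
        pixels_per_cm=config.pixels_per_cm,
    )
    return reg.lag, dx, n_excl
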