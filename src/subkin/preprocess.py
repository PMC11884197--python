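"""Zero-phase filtering and the kinematic derivative chain.

The submovement detectors operate on the *speed* (velocity magnitude) of the
filtered left-right position, and on its first and second time derivatives
(referred to throughout as acceleration and jerk, i.e. the derivatives of
speed, not of signed velocity). Filtering is two-way (forward-backward)
Butterworth, so the pass is zero-phase and the effective magnitude response
is the squared design response.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

__all__ = ["KinematicProfile", "lowpass", "differentiate", "kinematic_profile"]


@dataclass
class KinematicProfile:
    """Filtered position and the speed/acceleration/jerk chain."""

    t: np.ndarray
    x_f: np.ndarray
    velocity: np.ndarray
    speed: np.ndarray
    accel: np.ndarray
    jerk: np.ndarray
    cutoff: float
    fs: float


def lowpass(x: np.ndarray, fs: float, cutoff: float, order: int = 4) -> np.ndarray:
    """Two-way (zero-phase) low-pass Butterworth filter.

    ``order`` is the design order of the single pass; the forward-backward
    application squares the magnitude response. Edge transients are reduced
    by ``filtfilt``'s odd reflection padding (3 filter lengths).
    """
    x = np.asarray(x, dtype=float)
    if cutoff >= fs / 2:
        raise ValueError(f"cutoff {cutoff} Hz must be below Nyquist ({fs / 2} Hz)")
    if len(x) <= 3 * (order + 1):
        raise ValueError("input too short for the requested filter order")
    sos = signal.butter(order, cutoff, btype="low", fs=fs, output="sos")
    padlen = min(len(x) - 1, 3 * 2 * (order + 1))
    return signal.sosfiltfilt(sos, x, padlen=padlen)


def differentiate(y: np.ndarray, fs: float) -> np.ndarray:
    """Finite-difference time derivative, length preserving.

    Central differences in the interior, one-sided (first-order) differences
    at the two endpoints.
    """
    y = np.asarray(y, dtype=float)
    if len(y) < 3:
        raise ValueError("need at least 3 samples to differentiate")
    return np.gradient(y, 1.0 / fs, edge_order=1)


def kinematic_profile(
    t: np.ndarray,
    x: np.ndarray,
    fs: float,
    cutoff: float = 4.0,
    order: int = 4,
) -> KinematicProfile:
    """Build the kinematic chain the detectors consume.

    Pipeline: low-pass the position, differentiate to signed velocity,
    rectify to speed, then differentiate twice more. Derivatives are taken
    on the already-filtered position; no re-filtering between stages.
    """
    t = np.asarray(t, dtype=float)
    x_f = lowpass(x, fs, cutoff, order)
    velocity = differentiate(x_f, fs)
    speed = np.abs(velocity)
    accel = differentiate(speed, fs)
    jerk = differentiate(accel, fs)
    return KinematicProfile(
        t=t, x_f=x_f, velocity=velocity, speed=speed, accel=accel, jerk=jerk,
        cutoff=cutoff, fs=fs,
    )
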