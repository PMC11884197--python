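"""Analysis configuration.

All numerical thresholds of the analysis live here rather than as literals in
the processing code, so that variant analyses (e.g. re-running the submovement
detection with a 10 Hz instead of a 4 Hz cutoff) are a configuration change.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import yaml

__all__ = ["AnalysisConfig"]


@dataclass(frozen=True)
class AnalysisConfig:
    """Thresholds and filter settings for the tracking analysis.

    Parameters
    ----------
    cutoff_submovements : float
        Low-pass cutoff (Hz) for the kinematic chain feeding the submovement
        detectors. Kept deliberately low so that 4-6 Hz tremor is not counted
        as submovements.
    cutoff_errors : float
        Low-pass cutoff (Hz) used before registration / error computation.
    filter_order : int
        Design order of the Butterworth filter (applied forward and backward,
        so the effective magnitude response is the squared design response).
    window_ms : float
        Half-width (ms) of the exclusion window around analytic stimulus
        speed peaks: participant speed peaks closer than this are not counted
        as type 2 submovements.
    max_lag_s : float
        Upper bound (s) of the non-negative lag grid searched during
        registration.
    min_denominator_px : float
        Samples whose relative-error denominator |x1 + x2 - 2*x_c| falls
        below this many pixels are excluded from the dX sum.
    pixels_per_cm : float
        Display resolution used to convert the pixel threshold to cm.
    edge_exclusion_s : float
        Zone (s) at each end of a segment within which detected events are
        discarded (guards against zero-phase filter edge transients).
    settle_margin_s : float
        Extra margin (s) trimmed from the start of each segment when slicing
        a trial (0 by default: transition periods are analysed).
    allow_negative_lag : bool
        If True, registration searches signed lags and reports |lag|.
    refractory_s : float
        Optional minimum spacing between detected events (0 disables; the
        default analysis applies no refractory constraint).
    seed : int
        Seed for any randomised stage run under this configuration.
    """

    cutoff_submovements: float = 4.0
    cutoff_errors: float = 10.0
    filter_order: int = 4
    window_ms: float = 50.0
    max_lag_s: float = 1.0
    min_denominator_px: float = 10.0
    pixels_per_cm: float = 42.9
    edge_exclusion_s: float = 0.5
    settle_margin_s: float = 0.0
    allow_negative_lag: bool = False
    refractory_s: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "cutoff_submovements",
            "cutoff_errors",
            "filter_order",
            "max_lag_s",
            "pixels_per_cm",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.window_ms < 0 or self.edge_exclusion_s < 0:
            raise ValueError("window_ms and edge_exclusion_s must be >= 0")

    @property
    def window_s(self) -> float:
        return self.window_ms / 1000.0

    @property
    def min_denominator_cm(self) -> float:
        return self.min_denominator_px / self.pixels_per_cm

    def replace(self, **kwargs) -> "AnalysisConfig":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def digest(self) -> str:
        """Stable hash of the configuration, recorded in run manifests."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]
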