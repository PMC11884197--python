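"""Trial, stimulus-plan and metrics-table I/O.

Canonical on-disk trial format: delimited text with a header and columns
``t_s`` (time, seconds) and ``x_cm`` (left-right stylus position, cm).
Foreign layouts are mapped through a :class:`Dialect`, which can rename
columns and convert pixel positions to cm. Stimulus plans are YAML/JSON
documents listing constant-frequency sinusoidal segments; metrics tables are
plain CSV with one row per participant x segment.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

__all__ = [
    "Trial",
    "StimulusSegment",
    "StimulusPlan",
    "MetricsRow",
    "Dialect",
    "TrialFormatError",
    "TrialDataError",
    "read_trial",
    "write_trial",
    "segment_trial",
    "load_figshare_dataset",
    "read_plan",
    "write_plan",
    "METRICS_COLUMNS",
    "metrics_to_frame",
]

GROUPS = ("PwP", "OC", "YC")

#: nominal sampling interval of the tablet (100 Hz)
NOMINAL_DT = 0.01


class TrialFormatError(ValueError):
    """The file does not have the expected columns/structure."""


class TrialDataError(ValueError):
    """The file parsed but its contents violate trial invariants."""


@dataclass
class Trial:
    """One participant's raw left-right position record.

    ``x`` is in cm along the tablet's left-right axis (screen-left negative
    relative to the centre; only relative positions enter the analysis).
    """

    participant_id: str
    group: str
    trial_index: int
    t: np.ndarray
    x: np.ndarray
    pixels_per_cm: float = 42.9

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        if self.group not in GROUPS:
            raise TrialDataError(f"group must be one of {GROUPS}, got {self.group!r}")
        if self.t.ndim != 1 or self.t.shape != self.x.shape:
            raise TrialDataError("t and x must be 1-D arrays of equal length")
        if len(self.t) < 2:
            raise TrialDataError("trial needs at least 2 samples")
        dt = np.diff(self.t)
        if np.any(dt <= 0):
            raise TrialDataError("time must be strictly increasing")
        med = float(np.median(dt))
        if abs(med - NOMINAL_DT) > 0.1 * NOMINAL_DT:
            raise TrialDataError(
                f"median sampling interval {med:.4g}s deviates >10% from 0.01s"
            )
        if not (np.all(np.isfinite(self.x)) and np.all(np.isfinite(self.t))):
            raise TrialDataError("non-finite samples in trial")
        if self.pixels_per_cm <= 0:
            raise TrialDataError("pixels_per_cm must be positive")

    @property
    def fs(self) -> float:
        """Sampling rate (Hz) from the median sampling interval."""
        return 1.0 / float(np.median(np.diff(self.t)))

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0])


@dataclass(frozen=True)
class StimulusSegment:
    """Analytic spec of one constant-frequency sinusoidal target segment.

    Target position for t in [t_start, t_end):
    ``x_stim(t) = center + (amplitude_p2p / 2) * sin(2*pi*frequency*(t - t_start) + phase)``
    """

    frequency: float
    amplitude_p2p: float
    center: float
    t_start: float
    t_end: float
    phase: float = 0.0

    def __post_init__(self) -> None:
        if self.frequency <= 0:
            raise ValueError("frequency must be positive")
        if self.amplitude_p2p <= 0:
            raise ValueError("amplitude_p2p must be positive")
        if self.t_end <= self.t_start:
            raise ValueError("t_end must exceed t_start")

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start

    @property
    def peak_velocity(self) -> float:
        """Peak target speed, pi*f*A for end-to-end amplitude A (cm/s)."""
        return np.pi * self.frequency * self.amplitude_p2p

    def position(self, t: np.ndarray) -> np.ndarray:
        """Analytic target position at times ``t`` (absolute seconds)."""
        t = np.asarray(t, dtype=float)
        return self.center + 0.5 * self.amplitude_p2p * np.sin(
            2.0 * np.pi * self.frequency * (t - self.t_start) + self.phase
        )


@dataclass
class StimulusPlan:
    """Ordered, contiguous segments preceded by a stationary lead-in."""

    segments: list[StimulusSegment]
    lead_in: float = 5.0

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError("plan must contain at least one segment")
        if self.lead_in < 0:
            raise ValueError("lead_in must be >= 0")
        prev_end = self.lead_in
        for seg in self.segments:
            if abs(seg.t_start - prev_end) > 1e-6:
                raise ValueError(
                    "segments must be contiguous after the lead-in "
                    f"(gap at t={seg.t_start:g}, expected {prev_end:g})"
                )
            prev_end = seg.t_end

    @property
    def duration(self) -> float:
        return self.segments[-1].t_end

    def to_dict(self) -> dict:
        return {
            "lead_in": self.lead_in,
            "segments": [
                {
                    "frequency": float(s.frequency),
                    "amplitude_p2p": float(s.amplitude_p2p),
                    "center": float(s.center),
                    "t_start": float(s.t_start),
                    "t_end": float(s.t_end),
                    "phase": float(s.phase),
                }
                for s in self.segments
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StimulusPlan":
        return cls(
            segments=[StimulusSegment(**s) for s in d["segments"]],
            lead_in=float(d.get("lead_in", 5.0)),
        )


@dataclass
class MetricsRow:
    """Per participant x segment outcome measures."""

    participant_id: str
    group: str
    trial_index: int
    frequency: float
    peak_velocity: float
    rate_type2: float
    rate_type3: float
    rate_total: float
    per_stroke_type2: float
    per_stroke_type3: float
    dX: float
    dT: float
    n_samples_excluded_dX: int = 0

    def __post_init__(self) -> None:
        for name in ("rate_type2", "rate_type3", "rate_total", "dX", "dT"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


METRICS_COLUMNS = [
    "participant_id",
    "group",
    "trial_index",
    "frequency",
    "peak_velocity",
    "rate_type2",
    "rate_type3",
    "rate_total",
    "per_stroke_type2",
    "per_stroke_type3",
    "dX",
    "dT",
    "n_samples_excluded_dX",
]


def metrics_to_frame(rows: Iterable[MetricsRow]) -> pd.DataFrame:
    df = pd.DataFrame([vars(r) for r in rows])
    return df[METRICS_COLUMNS]


@dataclass(frozen=True)
class Dialect:
    """Column/unit mapping for foreign trial files.

    ``position_unit`` is ``"cm"`` or ``"px"``; pixel positions are divided by
    ``pixels_per_cm`` on read. ``time_unit`` is ``"s"`` or ``"ms"``.
    """

    time_column: str = "t_s"
    position_column: str = "x_cm"
    position_unit: str = "cm"
    time_unit: str = "s"
    delimiter: str = ","
    pixels_per_cm: float = 42.9


def read_trial(
    path: str | Path,
    dialect: Dialect | None = None,
    *,
    participant_id: str = "unknown",
    group: str = "YC",
    trial_index: int = 0,
) -> Trial:
    """Read a single trial from delimited text.

    Raises :class:`TrialFormatError` for missing columns and
    :class:`TrialDataError` for non-monotone time or >5% missing samples.
    """
    dialect = dialect or Dialect()
    path = Path(path)
    try:
        df = pd.read_csv(path, sep=dialect.delimiter)
    except Exception as exc:  # malformed text
        raise TrialFormatError(f"{path}: could not parse ({exc})") from exc
    for col in (dialect.time_column, dialect.position_column):
        if col not in df.columns:
            raise TrialFormatError(
                f"{path}: missing column {col!r} (have {list(df.columns)})"
            )
    t = df[dialect.time_column].to_numpy(dtype=float)
    x = df[dialect.position_column].to_numpy(dtype=float)
    n_bad = int(np.sum(~np.isfinite(t) | ~np.isfinite(x)))
    if n_bad > 0.05 * len(t):
        raise TrialDataError(f"{path}: {n_bad}/{len(t)} missing samples (>5%)")
    if n_bad:
        # fill isolated gaps by linear interpolation on the time base
        good = np.isfinite(t) & np.isfinite(x)
        t = t[good] if np.all(np.isfinite(t[good])) else t
        idx = np.arange(len(x))
        x = np.interp(idx, idx[good], x[np.flatnonzero(good)])
        t = np.interp(idx, idx[good], df[dialect.time_column].to_numpy(dtype=float)[good])
    if dialect.time_unit == "ms":
        t = t / 1000.0
    if dialect.position_unit == "px":
        x = x / dialect.pixels_per_cm
    if np.any(np.diff(t) <= 0):
        raise TrialDataError(f"{path}: time not strictly increasing")
    return Trial(
        participant_id=participant_id,
        group=group,
        trial_index=trial_index,
        t=t,
        x=x,
        pixels_per_cm=dialect.pixels_per_cm,
    )


def write_trial(trial: Trial, path: str | Path) -> None:
    """Write a trial in the canonical two-column CSV format."""
    df = pd.DataFrame({"t_s": trial.t, "x_cm": trial.x})
    df.to_csv(path, index=False, float_format="%.10g")


def segment_trial(
    trial: Trial,
    plan: StimulusPlan,
    settle_margin_s: float = 0.0,
    duration_tolerance_s: float = 0.5,
) -> list[tuple[StimulusSegment, slice]]:
    """Slice a trial into per-segment sample ranges, excluding the lead-in.

    Returns (segment, slice) pairs; the slice covers samples with
    ``t_start + settle_margin_s <= t < t_end`` relative to the trial start.
    A segment extending past the end of the recording by more than
    ``duration_tolerance_s`` raises :class:`TrialDataError`.
    """
    t0 = trial.t[0]
    out: list[tuple[StimulusSegment, slice]] = []
    for seg in plan.segments:
        if seg.t_end - (trial.t[-1] - t0) > duration_tolerance_s:
            raise TrialDataError(
                f"segment [{seg.t_start:g},{seg.t_end:g})s extends past trial "
                f"end ({trial.duration:g}s) by more than {duration_tolerance_s}s"
            )
        lo = int(np.searchsorted(trial.t, t0 + seg.t_start + settle_margin_s, "left"))
        hi = int(np.searchsorted(trial.t, t0 + seg.t_end, "left"))
        if hi - lo < 2:
            raise TrialDataError("segment contains fewer than 2 samples")
        out.append((seg, slice(lo, hi)))
    return out


def write_plan(plan: StimulusPlan, path: str | Path) -> None:
    path = Path(path)
    if path.suffix == ".json":
        path.write_text(json.dumps(plan.to_dict(), indent=2))
    else:
        path.write_text(yaml.safe_dump(plan.to_dict(), sort_keys=False))


def read_plan(path: str | Path) -> StimulusPlan:
    path = Path(path)
    text = path.read_text()
    d = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    return StimulusPlan.from_dict(d)


def load_figshare_dataset(
    root_dir: str | Path,
    dialect: Dialect | None = None,
) -> tuple[list[tuple[Trial, StimulusPlan]], int]:
    """Load a locally unpacked copy of the deposited tracking dataset.

    Expected layout (adapter default; remap via ``dialect`` and per-directory
    ``plan_*.yaml`` files if the deposit differs)::

        root/<group>/<participant_id>/trial_<k>.csv
        root/<group>/<participant_id>/plan_<k>.yaml

    Unparseable files are logged and skipped; the function returns the parsed
    (trial, plan) pairs and the number of files skipped. An empty result
    raises ``FileNotFoundError``.
    """
    root = Path(root_dir)
    if not root.is_dir():
        raise FileNotFoundError(f"{root} is not a directory")
    pairs: list[tuple[Trial, StimulusPlan]] = []
    n_skipped = 0
    for group_dir in sorted(p for p in root.iterdir() if p.is_dir()):
        group = group_dir.name
        if group not in GROUPS:
            logger.warning("skipping unrecognised group directory %s", group_dir)
            continue
        for part_dir in sorted(p for p in group_dir.iterdir() if p.is_dir()):
            pid = part_dir.name
            for trial_file in sorted(part_dir.glob("trial_*.csv")):
                k = trial_file.stem.split("_")[-1]
                plan_file = part_dir / f"plan_{k}.yaml"
                try:
                    trial = read_trial(
                        trial_file,
                        dialect,
                        participant_id=pid,
                        group=group,
                        trial_index=int(k),
                    )
                    plan = read_plan(plan_file)
                except (TrialFormatError, TrialDataError, FileNotFoundError, ValueError) as exc:
                    n_skipped += 1
                    warnings.warn(f"skipping {trial_file}: {exc}", stacklevel=2)
                    continue
                pairs.append((trial, plan))
    if not pairs:
        raise FileNotFoundError(f"no parseable trials found under {root}")
    return pairs, n_skipped
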