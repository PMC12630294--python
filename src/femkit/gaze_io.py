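"""Reading, validating, calibrating, segmenting and quality-scoring gaze data.

The canonical on-disk form is a delimited text file with header
``t_s,x_deg,y_deg,valid``: time in seconds, gaze in degrees of visual angle
(+x rightward, +y upward from the participant's view), validity encoded 0/1.
Samples whose position could not be determined by the tracker (data loss,
blinks) carry ``valid=0`` and empty/NaN positions.  A :class:`GazeDialect`
adapts differently named or scaled columns to this canonical form.

Quality metrics follow standard eye-tracking data-quality practice:
RMS-S2S (root mean square of sample-to-sample displacements, in arcmin)
quantifies precision, and the data-loss fraction quantifies completeness.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import (
    CalibrationError,
    GazeDataError,
    GazeFormatError,
    SegmentationError,
)

__all__ = [
    "GazeDialect",
    "GazeRecording",
    "TrialSpec",
    "TrialManifest",
    "Segment",
    "QualityReport",
    "read_gaze",
    "write_gaze",
    "calibrate_zero",
    "apply_offset",
    "split_segments",
    "rms_s2s",
    "data_loss_fraction",
    "quality_report",
]

#: Fixation target labels used in the five-target protocol.
TARGET_LABELS = ("Gaussian", "Bessel", "Circle", "Point", "CCP")
POLARITIES = ("black-on-grey", "white-on-black")


@dataclass(frozen=True)
class GazeDialect:
    """Column mapping and numeric conventions of a delimited gaze file.

    ``time_scale``/``pos_scale`` convert the file's units to seconds and
    degrees (e.g. ``time_scale=1e-3`` for millisecond timestamps), which is
    how externally deposited datasets are adapted to the canonical form.
    """

    time_col: str = "t_s"
    x_col: str = "x_deg"
    y_col: str = "y_deg"
    valid_col: str | None = "valid"
    delimiter: str = ","
    time_scale: float = 1.0
    pos_scale: float = 1.0
    decimals: int = 9  # written precision of the canonical form


@dataclass
class GazeRecording:
    """A monocular gaze time series in degrees of visual angle.

    Invariants enforced at construction: equal-length arrays, strictly
    increasing timestamps, and positions finite wherever ``valid`` is true
    (non-finite positions are demoted to invalid).  A warning is issued when
    the median sample interval deviates more than 20% from the nominal rate.
    """

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    valid: np.ndarray
    nominal_rate: float = 620.0

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        n = len(self.t)
        if not (len(self.x) == len(self.y) == len(self.valid) == n):
            raise GazeDataError("t, x, y, valid must have equal length")
        if n == 0:
            raise GazeDataError("empty recording")
        if self.nominal_rate <= 0:
            raise GazeDataError("nominal_rate must be positive")
        dt = np.diff(self.t)
        bad = np.flatnonzero(dt <= 0)
        if bad.size:
            raise GazeDataError(
                f"timestamps not strictly increasing at index {bad[0] + 1}"
            )
        # Positions that the tracker could not determine are invalid samples.
        finite = np.isfinite(self.x) & np.isfinite(self.y)
        self.valid = self.valid & finite
        if n > 1:
            med_dt = float(np.median(dt))
            if not (0.8 / self.nominal_rate <= med_dt <= 1.2 / self.nominal_rate):
                warnings.warn(
                    f"median sample interval {med_dt:.6g}s deviates >20% from "
                    f"nominal 1/{self.nominal_rate:g}s",
                    stacklevel=2,
                )

    def __len__(self) -> int:
        return len(self.t)

    @property
    def median_dt(self) -> float:
        if len(self.t) < 2:
            return 1.0 / self.nominal_rate
        return float(np.median(np.diff(self.t)))

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0])


@dataclass(frozen=True)
class TrialSpec:
    """One fixation-target presentation in a session."""

    label: str
    polarity: str
    t_on: float
    t_off: float
    center: tuple[float, float] = (0.0, 0.0)


@dataclass
class TrialManifest:
    """Trial schedule of a session plus zero-point calibration windows."""

    trials: list[TrialSpec] = field(default_factory=list)
    calibration_windows: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        prev_off = -np.inf
        for i, tr in enumerate(self.trials):
            if tr.t_off <= tr.t_on:
                raise GazeDataError(f"trial {i}: t_off must exceed t_on")
            if tr.t_on < prev_off:
                raise GazeDataError(f"trial {i} overlaps the previous trial")
            prev_off = tr.t_off

    def to_json(self, path: str | Path) -> None:
        obj = {
            "trials": [
                {
                    "label": tr.label,
                    "polarity": tr.polarity,
                    "t_on": tr.t_on,
                    "t_off": tr.t_off,
                    "center": list(tr.center),
                }
                for tr in self.trials
            ],
            "calibration_windows": [list(w) for w in self.calibration_windows],
        }
        Path(path).write_text(json.dumps(obj, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "TrialManifest":
        obj = json.loads(Path(path).read_text())
        trials = [
            TrialSpec(
                label=tr["label"],
                polarity=tr["polarity"],
                t_on=float(tr["t_on"]),
                t_off=float(tr["t_off"]),
                center=tuple(tr.get("center", (0.0, 0.0))),
            )
            for tr in obj.get("trials", [])
        ]
        windows = [tuple(map(float, w)) for w in obj.get("calibration_windows", [])]
        return cls(trials=trials, calibration_windows=windows)


@dataclass
class Segment:
    """A view on one 30-s fixation trial within a recording.

    ``start``/``stop`` are 0-based sample indices with half-open semantics
    (``stop`` exclusive), mirroring the half-open ``[t_on, t_off)`` trial
    interval convention.
    """

    recording: GazeRecording
    start: int
    stop: int
    label: str = ""
    polarity: str = ""
    center: tuple[float, float] = (0.0, 0.0)
    t_on: float = 0.0

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.stop <= len(self.recording)):
            raise SegmentationError(
                f"segment [{self.start}, {self.stop}) outside recording bounds"
            )

    def __len__(self) -> int:
        return self.stop - self.start

    @property
    def t(self) -> np.ndarray:
        return self.recording.t[self.start : self.stop]

    @property
    def x(self) -> np.ndarray:
        return self.recording.x[self.start : self.stop]

    @property
    def y(self) -> np.ndarray:
        return self.recording.y[self.start : self.stop]

    @property
    def valid(self) -> np.ndarray:
        return self.recording.valid[self.start : self.stop]

    @property
    def median_dt(self) -> float:
        t = self.t
        if len(t) < 2:
            return 1.0 / self.recording.nominal_rate
        return float(np.median(np.diff(t)))

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0])


@dataclass(frozen=True)
class QualityReport:
    """Data-quality summary of a recording or segment."""

    rms_s2s: float  # arcmin
    data_loss: float  # fraction in [0, 1]
    n_samples: int

    def to_dict(self) -> dict:
        return {
            "rms_s2s_arcmin": self.rms_s2s,
            "data_loss": self.data_loss,
            "n_samples": self.n_samples,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


# ---------------------------------------------------------------------------
# Reading and writing


def read_gaze(
    path: str | Path,
    dialect: GazeDialect = GazeDialect(),
    nominal_rate: float = 620.0,
) -> GazeRecording:
    """Read a delimited gaze file into a :class:`GazeRecording`.

    Samples with blank or non-finite positions become invalid; their
    positions are retained as NaN rather than fabricated.  Missing required
    columns raise :class:`GazeFormatError`; non-monotonic timestamps raise
    :class:`GazeDataError` naming the first offending index.
    """
    path = Path(path)
    if not path.exists():
        raise GazeFormatError(f"no such file: {path}")
    df = pd.read_csv(path, sep=dialect.delimiter)
    required = [dialect.time_col, dialect.x_col, dialect.y_col]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise GazeFormatError(f"{path}: missing required column(s) {missing}")
    t = df[dialect.time_col].to_numpy(dtype=float) * dialect.time_scale
    x = df[dialect.x_col].to_numpy(dtype=float) * dialect.pos_scale
    y = df[dialect.y_col].to_numpy(dtype=float) * dialect.pos_scale
    if dialect.valid_col is not None and dialect.valid_col in df.columns:
        valid = df[dialect.valid_col].to_numpy(dtype=float) > 0.5
    else:
        valid = np.ones(len(t), dtype=bool)
    return GazeRecording(t=t, x=x, y=y, valid=valid, nominal_rate=nominal_rate)


def write_gaze(
    recording: GazeRecording,
    path: str | Path,
    dialect: GazeDialect = GazeDialect(),
) -> None:
    """Write a recording in the canonical delimited dialect."""
    df = pd.DataFrame(
        {
            dialect.time_col: recording.t,
            dialect.x_col: recording.x,
            dialect.y_col: recording.y,
            dialect.valid_col or "valid": recording.valid.astype(int),
        }
    )
    df.to_csv(
        path,
        sep=dialect.delimiter,
        index=False,
        float_format=f"%.{dialect.decimals}f",
    )


# ---------------------------------------------------------------------------
# Zero-point calibration


def calibrate_zero(
    recording: GazeRecording,
    windows: Sequence[tuple[float, float]],
    settle: float = 0.5,
    min_valid: int = 50,
) -> tuple[float, float]:
    """Estimate the zero-point offset from central-fixation windows.

    The offset is the per-axis median of all valid samples pooled across the
    windows, after discarding the first ``settle`` seconds of each window
    (the saccade acquiring the central target).  The median is used rather
    than the mean so that saccades within the calibration fixations cannot
    drag the zero point.  Subtracting the returned offset places the robust
    center of the pooled fixations at (0, 0).
    """
    if not windows:
        raise CalibrationError("no calibration windows given")
    xs, ys = [], []
    for t0, t1 in windows:
        sel = (recording.t >= t0 + settle) & (recording.t < t1) & recording.valid
        n_ok = int(np.count_nonzero(sel))
        if n_ok < min_valid:
            warnings.warn(
                f"calibration window ({t0:g}, {t1:g}) has only {n_ok} valid "
                f"samples after settle time",
                stacklevel=2,
            )
        xs.append(recording.x[sel])
        ys.append(recording.y[sel])
    x = np.concatenate(xs)
    y = np.concatenate(ys)
    if x.size == 0:
        raise CalibrationError("no valid samples in any calibration window")
    return float(np.median(x)), float(np.median(y))


def apply_offset(
    recording: GazeRecording, offset: tuple[float, float]
) -> GazeRecording:
    """Return a copy of the recording recentred by subtracting ``offset``."""
    return replace(
        recording, x=recording.x - offset[0], y=recording.y - offset[1]
    )


# ---------------------------------------------------------------------------
# Segmentation


def split_segments(
    recording: GazeRecording, manifest: TrialManifest
) -> list[Segment]:
    """Slice the recording into one segment per manifest trial.

    Samples are assigned by the half-open interval ``[t_on, t_off)``; a
    sample exactly at ``t_off`` belongs to the next trial only, so no sample
    is ever assigned to two segments.
    """
    segments: list[Segment] = []
    for i, tr in enumerate(manifest.trials):
        if tr.t_off > recording.t[-1] + recording.median_dt:
            raise SegmentationError(
                f"trial {i} ({tr.label}) extends past the end of the recording"
            )
        start = int(np.searchsorted(recording.t, tr.t_on, side="left"))
        stop = int(np.searchsorted(recording.t, tr.t_off, side="left"))
        if stop <= start:
            raise SegmentationError(f"trial {i} ({tr.label}) contains no samples")
        segments.append(
            Segment(
                recording=recording,
                start=start,
                stop=stop,
                label=tr.label,
                polarity=tr.polarity,
                center=tr.center,
                t_on=tr.t_on,
            )
        )
    return segments


# ---------------------------------------------------------------------------
# Data quality


def _xyv(obj) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    return np.asarray(obj.x), np.asarray(obj.y), np.asarray(obj.valid)


def rms_s2s(obj) -> float:
    """RMS sample-to-sample deviation in arcmin.

    ``sqrt(mean(Δx² + Δy²))`` over consecutive valid sample pairs, converted
    from degrees to arcmin.  Pairs spanning an invalid sample are skipped
    rather than interpolated: no positions are fabricated.
    """
    x, y, valid = _xyv(obj)
    pair = valid[:-1] & valid[1:]
    if not pair.any():
        raise GazeDataError("rms_s2s undefined: no consecutive valid sample pair")
    dx = np.diff(x)[pair]
    dy = np.diff(y)[pair]
    return float(np.sqrt(np.mean(dx**2 + dy**2)) * 60.0)


def data_loss_fraction(obj) -> float:
    """Fraction of samples for which no gaze position could be determined."""
    _, _, valid = _xyv(obj)
    return float(np.count_nonzero(~valid) / len(valid))


def quality_report(obj) -> QualityReport:
    return QualityReport(
        rms_s2s=rms_s2s(obj),
        data_loss=data_loss_fraction(obj),
        n_samples=len(np.asarray(obj.valid)),
    )
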