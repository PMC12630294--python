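"""Fixation-stability and per-event metrics, and condition-level aggregation.

The bivariate contour ellipse area (BCEA) summarises the spatial spread of
gaze positions during fixation: it is the area of the ellipse, derived from
the bivariate distribution of gaze positions, that contains a stated
fraction P of those positions.  Under a bivariate normal model,

    BCEA = 2π · k · σx · σy · sqrt(1 − ρ²),    k = −ln(1 − P)

with σx, σy the per-axis standard deviations and ρ the Pearson correlation
(the Crossland & Rubin parametric convention).  The default P = 0.6827
corresponds to ±1 SD coverage of a univariate normal.

Per-event metrics: microsaccade rate, displacement and direction; drift
displacement, direction, path length and mean speed (velocity by
second-order central differences via ``numpy.gradient``).  Aggregation runs
segment → session → participant → grand mean, with each participant
weighted equally.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import DegenerateGeometryError, GazeDataError
from .event_detection import DetectionParams, DriftEpisode, SaccadeEvent

__all__ = [
    "BCEAResult",
    "SegmentMetrics",
    "ConditionSummary",
    "bcea",
    "pooled_positions",
    "displacement_and_direction",
    "drift_path_length",
    "drift_speed",
    "saccade_rate",
    "segment_metrics",
    "aggregate",
    "METRIC_COLUMNS",
]

#: Metric columns carried through aggregation.
METRIC_COLUMNS = [
    "bcea_area_deg2",
    "saccade_rate_hz",
    "saccade_displacement_deg",
    "drift_displacement_deg",
    "drift_path_length_deg",
    "drift_speed_deg_s",
]


@dataclass(frozen=True)
class BCEAResult:
    """Parametric BCEA of a gaze position cloud."""

    sigma_x: float
    sigma_y: float
    rho: float
    coverage: float
    area: float
    mean_x: float
    mean_y: float

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Boolean mask of points inside the coverage ellipse.

        The ellipse is the Mahalanobis ball of squared radius
        ``2k = −2 ln(1 − P)`` around the sample mean.
        """
        p = np.atleast_2d(np.asarray(points, dtype=float))
        dx = (p[:, 0] - self.mean_x) / self.sigma_x
        dy = (p[:, 1] - self.mean_y) / self.sigma_y
        k = -math.log(1.0 - self.coverage)
        maha2 = (dx**2 - 2.0 * self.rho * dx * dy + dy**2) / (1.0 - self.rho**2)
        return maha2 <= 2.0 * k


def bcea(points: np.ndarray, coverage: float = 0.6827) -> BCEAResult:
    """Bivariate contour ellipse area of a point cloud (deg²).

    Sample SDs and Pearson correlation parameterise the ellipse scaled to
    contain the fraction ``coverage`` of a bivariate normal with those
    moments.  Fewer than 3 points, zero variance on an axis, or collinear
    points raise :class:`DegenerateGeometryError`.
    """
    p = np.asarray(points, dtype=float)
    if p.ndim != 2 or p.shape[1] != 2:
        p = p.reshape(-1, 2)
    if len(p) < 3:
        raise DegenerateGeometryError(f"BCEA needs ≥ 3 points, got {len(p)}")
    if not (0.0 < coverage < 1.0):
        raise DegenerateGeometryError("coverage must lie in (0, 1)")
    sx = float(np.std(p[:, 0], ddof=1))
    sy = float(np.std(p[:, 1], ddof=1))
    if sx <= 0.0 or sy <= 0.0:
        raise DegenerateGeometryError("zero variance on an axis")
    rho = float(np.corrcoef(p[:, 0], p[:, 1])[0, 1])
    if not np.isfinite(rho) or abs(rho) >= 1.0 - 1e-12:
        raise DegenerateGeometryError("points are (numerically) collinear")
    k = -math.log(1.0 - coverage)
    area = 2.0 * math.pi * k * sx * sy * math.sqrt(1.0 - rho * rho)
    return BCEAResult(
        sigma_x=sx,
        sigma_y=sy,
        rho=rho,
        coverage=coverage,
        area=area,
        mean_x=float(np.mean(p[:, 0])),
        mean_y=float(np.mean(p[:, 1])),
    )


def pooled_positions(
    segment,
    saccades: Sequence[SaccadeEvent],
    drifts: Sequence[DriftEpisode],
) -> np.ndarray:
    """Gaze positions (n, 2) inside the selected saccade and drift episodes.

    Only valid samples inside retained events contribute; warm-up samples,
    excluded events and data loss are omitted by construction.
    """
    x, y, valid = np.asarray(segment.x), np.asarray(segment.y), np.asarray(segment.valid)
    sel = np.zeros(len(x), dtype=bool)
    for sac in saccades:
        sel[sac.onset_idx : sac.offset_idx + 1] = True
    for dr in drifts:
        sel[dr.start_idx : dr.end_idx + 1] = True
    sel &= valid
    return np.column_stack((x[sel], y[sel]))


def displacement_and_direction(
    p_from: tuple[float, float], p_to: tuple[float, float]
) -> tuple[float, float]:
    """Euclidean displacement (deg) and direction (deg, 0°=right, 90°=up)."""
    dx = p_to[0] - p_from[0]
    dy = p_to[1] - p_from[1]
    return math.hypot(dx, dy), float(np.degrees(np.arctan2(dy, dx)) % 360.0)


def drift_path_length(xy: np.ndarray) -> float:
    """Sum of Euclidean distances between adjacent episode samples (deg)."""
    p = np.asarray(xy, dtype=float).reshape(-1, 2)
    if len(p) < 2:
        raise GazeDataError("path length undefined for fewer than 2 samples")
    return float(np.hypot(np.diff(p[:, 0]), np.diff(p[:, 1])).sum())


def drift_speed(xy: np.ndarray, t: np.ndarray) -> float:
    """Mean gaze speed during a drift episode (deg/s).

    Per-axis velocity is the gradient of the position signal by
    second-order central differences (one-sided at the two episode boundary
    samples); the result is the mean magnitude of the 2D velocity.
    """
    p = np.asarray(xy, dtype=float).reshape(-1, 2)
    t = np.asarray(t, dtype=float)
    if len(p) < 3:
        raise GazeDataError("drift speed undefined for fewer than 3 samples")
    vx = np.gradient(p[:, 0], t)
    vy = np.gradient(p[:, 1], t)
    return float(np.mean(np.hypot(vx, vy)))


def saccade_rate(n_selected: int, analyzed_duration: float) -> float:
    """Microsaccade rate in Hz over the analysed duration."""
    if analyzed_duration <= 0:
        raise GazeDataError("analyzed_duration must be positive")
    return n_selected / analyzed_duration


@dataclass
class SegmentMetrics:
    """All fixational eye-movement metrics of one segment."""

    bcea: BCEAResult | None
    saccade_rate: float
    saccade_displacements: list[float]
    saccade_directions: list[float]
    drift_displacements: list[float]
    drift_directions: list[float]
    drift_path_lengths: list[float]
    drift_speeds: list[float]
    analyzed_duration: float

    def to_row(self) -> dict:
        """Flatten to one table row; per-event lists become segment means."""

        def _mean(v: list[float]) -> float:
            return float(np.mean(v)) if v else float("nan")

        return {
            "bcea_area_deg2": self.bcea.area if self.bcea else float("nan"),
            "saccade_rate_hz": self.saccade_rate,
            "saccade_displacement_deg": _mean(self.saccade_displacements),
            "drift_displacement_deg": _mean(self.drift_displacements),
            "drift_path_length_deg": _mean(self.drift_path_lengths),
            "drift_speed_deg_s": _mean(self.drift_speeds),
            "n_saccades": len(self.saccade_displacements),
            "n_drifts": len(self.drift_displacements),
            "analyzed_duration_s": self.analyzed_duration,
        }


def segment_metrics(
    segment,
    saccades: Sequence[SaccadeEvent],
    drifts: Sequence[DriftEpisode],
    params: DetectionParams = DetectionParams(),
    coverage: float = 0.6827,
) -> SegmentMetrics:
    """Compute all metrics of one segment from its selected events.

    The rate denominator is the segment duration minus the warm-up (the
    analysed stretch).  BCEA is None when the pooled positions are
    degenerate (e.g. no events survived selection).
    """
    x, y, t = np.asarray(segment.x), np.asarray(segment.y), np.asarray(segment.t)
    analyzed = segment.duration - params.warmup
    pos = pooled_positions(segment, saccades, drifts)
    try:
        bc = bcea(pos, coverage)
    except DegenerateGeometryError:
        bc = None

    s_disp, s_dir = [], []
    for sac in saccades:
        s_disp.append(sac.magnitude)
        s_dir.append(sac.direction)
    d_disp, d_dir, d_path, d_speed = [], [], [], []
    for dr in drifts:
        sel = slice(dr.start_idx, dr.end_idx + 1)
        mag, ang = displacement_and_direction(
            (x[dr.start_idx], y[dr.start_idx]), (x[dr.end_idx], y[dr.end_idx])
        )
        d_disp.append(mag)
        d_dir.append(ang)
        xy = np.column_stack((x[sel], y[sel]))
        d_path.append(drift_path_length(xy))
        d_speed.append(drift_speed(xy, t[sel]))
    return SegmentMetrics(
        bcea=bc,
        saccade_rate=saccade_rate(len(saccades), analyzed),
        saccade_displacements=s_disp,
        saccade_directions=s_dir,
        drift_displacements=d_disp,
        drift_directions=d_dir,
        drift_path_lengths=d_path,
        drift_speeds=d_speed,
        analyzed_duration=analyzed,
    )


@dataclass
class ConditionSummary:
    """Participant-level and grand-mean condition tables.

    ``per_participant`` has one row per participant × target × polarity
    (mean over that participant's sessions); ``grand`` averages those rows
    across participants with equal weight, so each participant counts once
    regardless of how many sessions they contributed.
    """

    per_participant: pd.DataFrame
    grand: pd.DataFrame
    missing_cells: list[tuple] = field(default_factory=list)


def aggregate(table: pd.DataFrame, metrics: Sequence[str] = METRIC_COLUMNS) -> ConditionSummary:
    """Aggregate a per-segment metrics table to condition means.

    The table must carry ``participant``, ``session``, ``target`` and
    ``polarity`` label columns.  Values are averaged within participant ×
    target × polarity across sessions, then across participants without
    weighting.  Missing participant × condition cells are reported via a
    warning and listed in the summary, never silently dropped.
    """
    required = {"participant", "session", "target", "polarity"}
    lacking = required - set(table.columns)
    if lacking:
        raise GazeDataError(f"metrics table missing label column(s) {sorted(lacking)}")
    metrics = [m for m in metrics if m in table.columns]
    per_part = (
        table.groupby(["participant", "target", "polarity"], sort=True)[list(metrics)]
        .mean()
        .reset_index()
    )
    participants = sorted(table["participant"].unique())
    conditions = sorted(
        table.groupby(["target", "polarity"]).groups.keys()
    )
    have = set(map(tuple, per_part[["participant", "target", "polarity"]].to_numpy()))
    missing = [
        (p, tg, pol)
        for p in participants
        for tg, pol in conditions
        if (p, tg, pol) not in have
    ]
    if missing:
        warnings.warn(f"{len(missing)} missing participant×condition cell(s): {missing}")
    grand = (
        per_part.groupby(["target", "polarity"], sort=True)[list(metrics)]
        .mean()
        .reset_index()
    )
    return ConditionSummary(per_participant=per_part, grand=grand, missing_cells=missing)
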