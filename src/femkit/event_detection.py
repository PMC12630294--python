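"""Microsaccade detection and drift-episode coding.

Microsaccades are detected with the Engbert–Kliegl velocity-threshold
algorithm: gaze velocity is computed with a smoothing difference stencil, a
per-axis noise level σ is estimated with the robust median estimator
``σ = sqrt(median(v²) − median(v)²)``, and samples whose velocity exceeds
the elliptic criterion ``(vx/ηx)² + (vy/ηy)² > 1`` with ``η = λ·σ`` are
candidate saccade samples.  Maximal supra-threshold runs of at least
``min_duration`` samples are candidate saccades; candidates closer together
than ``merge_gap`` are merged (post-saccadic oscillations would otherwise be
detected as separate saccades); events whose operational displacement — from
the last sample before onset to the first sample after offset — falls below
``min_displacement`` are removed.

Every interval between retained saccades that is free of data loss and
longer than ``min_drift_duration`` is coded as a drift episode.  Events in
the first ``warmup`` seconds of a segment (target-acquisition saccades after
the mask interval) and events further than ``exclusion_radius`` from the
target center are excluded, with per-rule counts kept in a discard log.

Detection is fully deterministic: identical input and parameters always
yield identical events.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, DegenerateSignalError, DetectionError

__all__ = [
    "DetectionParams",
    "VelocitySeries",
    "Thresholds",
    "SaccadeEvent",
    "DriftEpisode",
    "DiscardLog",
    "DetectionResult",
    "compute_velocity",
    "estimate_thresholds",
    "detect_candidates",
    "merge_candidates",
    "finalize_saccades",
    "segment_drift",
    "apply_exclusions",
    "detect_saccades_and_drift",
    "events_to_frame",
]


@dataclass(frozen=True)
class DetectionParams:
    """Detection parameters; defaults are the study's analysis settings.

    ``lambda_thresh`` is the multiple of the median-based velocity noise
    estimate that sets the detection threshold.  ``velocity_window`` is the
    odd length (in samples) of the velocity stencil; ``min_duration`` the
    minimum supra-threshold run length; ``merge_gap`` the inter-candidate
    gap below which candidates merge; ``min_displacement`` (arcmin) the
    minimum operational saccade displacement; ``warmup`` the discarded
    initial stretch of each segment; ``exclusion_radius`` (deg) the maximum
    distance from the target center; ``min_drift_duration`` the minimum
    drift-episode duration.
    """

    lambda_thresh: float = 6.0
    velocity_window: int = 5
    min_duration: int = 3
    merge_gap: float = 0.020
    min_displacement: float = 4.0
    warmup: float = 0.5
    exclusion_radius: float = 2.5
    min_drift_duration: float = 0.100

    def __post_init__(self) -> None:
        positive = {
            "lambda_thresh": self.lambda_thresh,
            "velocity_window": self.velocity_window,
            "min_duration": self.min_duration,
            "merge_gap": self.merge_gap,
            "min_displacement": self.min_displacement,
            "warmup": self.warmup,
            "exclusion_radius": self.exclusion_radius,
            "min_drift_duration": self.min_drift_duration,
        }
        for name, value in positive.items():
            if not value > 0:
                raise ConfigError(f"{name} must be strictly positive, got {value}")
        if self.velocity_window % 2 == 0:
            raise ConfigError("velocity_window must be odd")


@dataclass
class VelocitySeries:
    """Per-sample gaze velocity (deg/s) with a defined-mask.

    ``defined`` is false at the (window−1)/2 edge samples and wherever the
    stencil touches an invalid sample; velocities there are NaN and never
    enter threshold estimation or detection.
    """

    vx: np.ndarray
    vy: np.ndarray
    defined: np.ndarray
    dt: float

    @property
    def speed(self) -> np.ndarray:
        return np.hypot(self.vx, self.vy)


@dataclass(frozen=True)
class Thresholds:
    """Median-based noise estimates σ and detection thresholds η = λ·σ."""

    sigma_x: float
    sigma_y: float
    eta_x: float
    eta_y: float


@dataclass
class SaccadeEvent:
    """A detected (micro)saccade.

    ``onset_idx``/``offset_idx`` are inclusive segment-local sample indices
    of the supra-threshold run.  Displacement is measured from the last
    sample before onset to the first sample after offset, so the
    post-saccadic overshoot does not contaminate it.  Direction follows the
    atan2 convention with +y up: 0° rightward, 90° upward, in [0°, 360°).
    """

    onset_idx: int
    offset_idx: int
    onset_t: float
    offset_t: float
    displacement: tuple[float, float]
    magnitude: float
    direction: float
    peak_speed: float


@dataclass
class DriftEpisode:
    """A loss-free inter-saccadic interval coded as ocular drift."""

    start_idx: int
    end_idx: int
    start_t: float
    end_t: float

    @property
    def duration(self) -> float:
        return self.end_t - self.start_t


class DiscardLog:
    """Per-rule record of events removed during detection and exclusion."""

    def __init__(self) -> None:
        self.records: list[dict] = []

    def add(self, rule: str, kind: str, **info) -> None:
        self.records.append({"rule": rule, "kind": kind, **info})

    def counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for r in self.records:
            out[r["rule"]] = out.get(r["rule"], 0) + 1
        return out

    def to_frame(self) -> pd.DataFrame:
        cols = ["rule", "kind", "onset_idx", "offset_idx"]
        if not self.records:
            return pd.DataFrame(columns=cols)
        return pd.DataFrame(self.records)

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class DetectionResult:
    """Output of the composed detection chain on one segment."""

    saccades: list[SaccadeEvent]
    drifts: list[DriftEpisode]
    log: DiscardLog
    thresholds: Thresholds
    velocity: VelocitySeries


# ---------------------------------------------------------------------------
# Velocity


def compute_velocity(segment, params: DetectionParams = DetectionParams()) -> VelocitySeries:
    """Smoothed gaze velocity via the Engbert–Kliegl difference stencil.

    For an odd window ``w = 2m+1``::

        v_n = sum_{k=1..m} (p_{n+k} − p_{n−k}) / (2·Δt·sum_{k=1..m} k)

    which for the default window of 5 is
    ``(p_{n+2} + p_{n+1} − p_{n−1} − p_{n−2}) / (6Δt)`` per axis.  Δt is the
    segment's median sample interval (robust to timestamp jitter; the
    stencil assumes uniform sampling).  Velocities whose stencil touches an
    invalid or out-of-range sample are undefined rather than interpolated.
    """
    x, y, valid = np.asarray(segment.x), np.asarray(segment.y), np.asarray(segment.valid)
    n = len(x)
    w = params.velocity_window
    if n < w:
        raise DetectionError(f"segment of {n} samples shorter than velocity window {w}")
    m = w // 2
    t = np.asarray(segment.t)
    dt = float(np.median(np.diff(t)))
    denom = 2.0 * dt * (m * (m + 1) / 2.0)

    vx = np.full(n, np.nan)
    vy = np.full(n, np.nan)
    core = slice(m, n - m)
    sx = np.zeros(n - 2 * m)
    sy = np.zeros(n - 2 * m)
    ok = np.ones(n - 2 * m, dtype=bool)
    for k in range(1, m + 1):
        sx += x[m + k : n - m + k] - x[m - k : n - m - k]
        sy += y[m + k : n - m + k] - y[m - k : n - m - k]
        ok &= valid[m + k : n - m + k] & valid[m - k : n - m - k]
    ok &= valid[core]
    vx[core] = sx / denom
    vy[core] = sy / denom
    defined = np.zeros(n, dtype=bool)
    defined[core] = ok
    vx[~defined] = np.nan
    vy[~defined] = np.nan
    return VelocitySeries(vx=vx, vy=vy, defined=defined, dt=dt)


# ---------------------------------------------------------------------------
# Thresholds


def estimate_thresholds(
    vel: VelocitySeries, lambda_thresh: float = 6.0, sigma_floor: float = 1e-9
) -> Thresholds:
    """Per-axis median-based noise estimate and elliptic threshold.

    ``σ = sqrt(median(v²) − median(v)²)`` is a robust scale estimate that is
    insensitive to the saccades themselves; ``η = λ·σ``.
    """
    if int(np.count_nonzero(vel.defined)) < 10:
        raise DetectionError("fewer than 10 defined velocity samples")
    sigmas = []
    for v in (vel.vx[vel.defined], vel.vy[vel.defined]):
        med = float(np.median(v))
        msq = float(np.median(v * v))
        sigmas.append(math.sqrt(max(msq - med * med, 0.0)))
    sx, sy = sigmas
    if sx < sigma_floor or sy < sigma_floor:
        raise DegenerateSignalError(
            f"velocity noise estimate below floor (σx={sx:g}, σy={sy:g}); "
            "constant or pathological input"
        )
    return Thresholds(
        sigma_x=sx,
        sigma_y=sy,
        eta_x=lambda_thresh * sx,
        eta_y=lambda_thresh * sy,
    )


# ---------------------------------------------------------------------------
# Candidate detection and merging


def detect_candidates(
    vel: VelocitySeries, thr: Thresholds, params: DetectionParams = DetectionParams()
) -> list[tuple[int, int]]:
    """Maximal supra-threshold runs of at least ``min_duration`` samples.

    A sample is supra-threshold when ``(vx/ηx)² + (vy/ηy)² > 1``.  Runs
    cannot span undefined velocity samples (the criterion is false there).
    Returned intervals are inclusive ``(onset_idx, offset_idx)`` pairs.
    """
    if not (np.isfinite(thr.eta_x) and np.isfinite(thr.eta_y)):
        raise DetectionError("thresholds must be finite")
    if thr.eta_x <= 0 or thr.eta_y <= 0:
        raise DetectionError("thresholds must be positive")
    crit = np.zeros(len(vel.vx), dtype=bool)
    d = vel.defined
    crit[d] = (vel.vx[d] / thr.eta_x) ** 2 + (vel.vy[d] / thr.eta_y) ** 2 > 1.0
    idx = np.flatnonzero(crit)
    if idx.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate(([0], breaks + 1))
    ends = np.concatenate((breaks, [idx.size - 1]))
    runs = [(int(idx[s]), int(idx[e])) for s, e in zip(starts, ends)]
    return [(a, b) for a, b in runs if b - a + 1 >= params.min_duration]


def merge_candidates(
    intervals: Sequence[tuple[int, int]],
    merge_gap: float,
    t: np.ndarray,
) -> list[tuple[int, int]]:
    """Merge candidate intervals separated by less than ``merge_gap``.

    The gap is measured in time from the end of one candidate to the start
    of the next; merging is applied iteratively to a fixed point.  This
    prevents oscillations at the end of a saccade from being detected as
    separate saccades.
    """
    out = [tuple(iv) for iv in intervals]
    changed = True
    while changed:
        changed = False
        merged: list[tuple[int, int]] = []
        for iv in out:
            if merged and t[iv[0]] - t[merged[-1][1]] < merge_gap:
                merged[-1] = (merged[-1][0], iv[1])
                changed = True
            else:
                merged.append(iv)
        out = merged
    return out


# ---------------------------------------------------------------------------
# Finalization


def _direction_deg(dx: float, dy: float) -> float:
    return float(np.degrees(np.arctan2(dy, dx)) % 360.0)


def finalize_saccades(
    segment,
    intervals: Sequence[tuple[int, int]],
    params: DetectionParams = DetectionParams(),
    vel: VelocitySeries | None = None,
    log: DiscardLog | None = None,
) -> tuple[list[SaccadeEvent], DiscardLog]:
    """Turn candidate intervals into saccade events and filter them.

    Displacement is taken from the last gaze sample before onset to the
    first gaze sample after offset.  Candidates lacking a valid flanking
    sample, or containing data loss, are dropped (logged, not raised).  The
    minimum-displacement filter runs after merging, since merging changes
    event extents.
    """
    if vel is None:
        vel = compute_velocity(segment, params)
    if log is None:
        log = DiscardLog()
    x, y, valid = np.asarray(segment.x), np.asarray(segment.y), np.asarray(segment.valid)
    t = np.asarray(segment.t)
    n = len(x)
    min_disp_deg = params.min_displacement / 60.0
    events: list[SaccadeEvent] = []
    for i0, i1 in intervals:
        if i0 - 1 < 0 or i1 + 1 >= n or not (valid[i0 - 1] and valid[i1 + 1]):
            log.add("no-flanking-sample", "saccade", onset_idx=i0, offset_idx=i1)
            continue
        if not valid[i0 : i1 + 1].all():
            log.add("loss-within-saccade", "saccade", onset_idx=i0, offset_idx=i1)
            continue
        dx = float(x[i1 + 1] - x[i0 - 1])
        dy = float(y[i1 + 1] - y[i0 - 1])
        mag = math.hypot(dx, dy)
        if mag < min_disp_deg:
            log.add("below-min-displacement", "saccade", onset_idx=i0, offset_idx=i1)
            continue
        inside = slice(i0, i1 + 1)
        speeds = np.hypot(vel.vx[inside], vel.vy[inside])
        peak = float(np.nanmax(speeds)) if np.isfinite(speeds).any() else float("nan")
        events.append(
            SaccadeEvent(
                onset_idx=i0,
                offset_idx=i1,
                onset_t=float(t[i0]),
                offset_t=float(t[i1]),
                displacement=(dx, dy),
                magnitude=mag,
                direction=_direction_deg(dx, dy),
                peak_speed=peak,
            )
        )
    return events, log


def segment_drift(
    segment,
    saccades: Sequence[SaccadeEvent],
    params: DetectionParams = DetectionParams(),
) -> list[DriftEpisode]:
    """Code inter-saccadic intervals as drift episodes.

    The complement of the saccade intervals within the segment — including
    the stretches before the first and after the last saccade — yields
    candidate episodes; any episode containing an invalid sample is
    discarded whole, as is any episode not longer than
    ``min_drift_duration``.
    """
    t = np.asarray(segment.t)
    valid = np.asarray(segment.valid)
    n = len(t)
    bounds: list[tuple[int, int]] = []
    prev_end = -1
    for sac in saccades:
        if sac.onset_idx - 1 >= prev_end + 1:
            bounds.append((prev_end + 1, sac.onset_idx - 1))
        prev_end = sac.offset_idx
    if prev_end + 1 <= n - 1:
        bounds.append((prev_end + 1, n - 1))
    episodes = []
    for a, b in bounds:
        if b <= a:
            continue
        if not valid[a : b + 1].all():
            continue
        if t[b] - t[a] <= params.min_drift_duration:
            continue
        episodes.append(
            DriftEpisode(start_idx=a, end_idx=b, start_t=float(t[a]), end_t=float(t[b]))
        )
    return episodes


def apply_exclusions(
    saccades: Sequence[SaccadeEvent],
    drifts: Sequence[DriftEpisode],
    segment,
    params: DetectionParams = DetectionParams(),
    log: DiscardLog | None = None,
) -> tuple[list[SaccadeEvent], list[DriftEpisode], DiscardLog]:
    """Apply the warm-up and target-distance exclusion rules.

    Saccades with onset inside the first ``warmup`` seconds of the segment,
    or starting or landing more than ``exclusion_radius`` from the target
    center, are discarded; drift episodes starting inside the warm-up or
    with a mean position beyond the radius likewise.  The discard log counts
    removals per rule.
    """
    if log is None:
        log = DiscardLog()
    x, y = np.asarray(segment.x), np.asarray(segment.y)
    t0 = float(np.asarray(segment.t)[0])
    cx, cy = segment.center
    r = params.exclusion_radius

    kept_sacs: list[SaccadeEvent] = []
    for sac in saccades:
        if sac.onset_t - t0 < params.warmup:
            log.add("warmup", "saccade", onset_idx=sac.onset_idx, offset_idx=sac.offset_idx)
            continue
        pre = (x[sac.onset_idx - 1], y[sac.onset_idx - 1])
        post = (x[sac.offset_idx + 1], y[sac.offset_idx + 1])
        if (
            math.hypot(pre[0] - cx, pre[1] - cy) > r
            or math.hypot(post[0] - cx, post[1] - cy) > r
        ):
            log.add("distance", "saccade", onset_idx=sac.onset_idx, offset_idx=sac.offset_idx)
            continue
        kept_sacs.append(sac)

    kept_drifts: list[DriftEpisode] = []
    for dr in drifts:
        if dr.start_t - t0 < params.warmup:
            log.add("warmup", "drift", onset_idx=dr.start_idx, offset_idx=dr.end_idx)
            continue
        sel = slice(dr.start_idx, dr.end_idx + 1)
        mx, my = float(np.mean(x[sel])), float(np.mean(y[sel]))
        if math.hypot(mx - cx, my - cy) > r:
            log.add("distance", "drift", onset_idx=dr.start_idx, offset_idx=dr.end_idx)
            continue
        kept_drifts.append(dr)
    return kept_sacs, kept_drifts, log


# ---------------------------------------------------------------------------
# Composed chain


def detect_saccades_and_drift(
    segment, params: DetectionParams = DetectionParams()
) -> DetectionResult:
    """Run the full detection chain on one segment.

    velocity → median thresholds → elliptic criterion → merge → displacement
    filter → drift coding → warm-up/distance exclusions.
    """
    vel = compute_velocity(segment, params)
    thr = estimate_thresholds(vel, params.lambda_thresh)
    cand = detect_candidates(vel, thr, params)
    merged = merge_candidates(cand, params.merge_gap, np.asarray(segment.t))
    saccades, log = finalize_saccades(segment, merged, params, vel)
    drifts = segment_drift(segment, saccades, params)
    saccades, drifts, log = apply_exclusions(saccades, drifts, segment, params, log)
    return DetectionResult(
        saccades=saccades, drifts=drifts, log=log, thresholds=thr, velocity=vel
    )


def events_to_frame(result: DetectionResult, segment=None) -> pd.DataFrame:
    """Tabulate detected events (one row per event) for the events CSV."""
    rows = []
    for sac in result.saccades:
        rows.append(
            {
                "type": "saccade",
                "onset_idx": sac.onset_idx,
                "offset_idx": sac.offset_idx,
                "onset_t": sac.onset_t,
                "offset_t": sac.offset_t,
                "dx_deg": sac.displacement[0],
                "dy_deg": sac.displacement[1],
                "magnitude_deg": sac.magnitude,
                "direction_deg": sac.direction,
                "peak_speed_deg_s": sac.peak_speed,
                "discarded": False,
                "discard_rule": "",
            }
        )
    for dr in result.drifts:
        rows.append(
            {
                "type": "drift",
                "onset_idx": dr.start_idx,
                "offset_idx": dr.end_idx,
                "onset_t": dr.start_t,
                "offset_t": dr.end_t,
                "dx_deg": np.nan,
                "dy_deg": np.nan,
                "magnitude_deg": np.nan,
                "direction_deg": np.nan,
                "peak_speed_deg_s": np.nan,
                "discarded": False,
                "discard_rule": "",
            }
        )
    for rec in result.log.records:
        rows.append(
            {
                "type": rec["kind"],
                "onset_idx": rec.get("onset_idx", -1),
                "offset_idx": rec.get("offset_idx", -1),
                "onset_t": np.nan,
                "offset_t": np.nan,
                "dx_deg": np.nan,
                "dy_deg": np.nan,
                "magnitude_deg": np.nan,
                "direction_deg": np.nan,
                "peak_speed_deg_s": np.nan,
                "discarded": True,
                "discard_rule": rec["rule"],
            }
        )
    cols = [
        "type", "onset_idx", "offset_idx", "onset_t", "offset_t",
        "dx_deg", "dy_deg", "magnitude_deg", "direction_deg",
        "peak_speed_deg_s", "discarded", "discard_rule",
    ]
    return pd.DataFrame(rows, columns=cols)
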