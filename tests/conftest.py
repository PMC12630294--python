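"""Shared fixtures and the independent brute-force detector oracle."""

from __future__ import annotations

import math
import statistics

import numpy as np
import pytest

from femkit import GazeRecording, Segment
from femkit.event_detection import DetectionParams


def make_recording(x, y, rate=620.0, valid=None, t=None) -> GazeRecording:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if t is None:
        t = np.arange(len(x)) / rate
    if valid is None:
        valid = np.ones(len(x), dtype=bool)
    return GazeRecording(t=t, x=x, y=y, valid=np.asarray(valid, bool), nominal_rate=rate)


def make_segment(x, y, rate=620.0, valid=None, center=(0.0, 0.0), label="Point",
                 polarity="white-on-black") -> Segment:
    rec = make_recording(x, y, rate=rate, valid=valid)
    return Segment(recording=rec, start=0, stop=len(rec), label=label,
                   polarity=polarity, center=center, t_on=float(rec.t[0]))


def segment_of(recording: GazeRecording, **kw) -> Segment:
    return Segment(recording=recording, start=0, stop=len(recording),
                   t_on=float(recording.t[0]), **kw)


def brute_force_saccades(t, x, y, valid, params: DetectionParams):
    """Independent saccade detector: direct per-sample loops throughout.

    Pure-Python reimplementation of the velocity-threshold criterion scan,
    naive repeated merging, and the displacement filter, used as the oracle
    for the composed detection chain.
    """
    t = list(map(float, t))
    x = list(map(float, x))
    y = list(map(float, y))
    valid = list(map(bool, valid))
    n = len(x)
    m = params.velocity_window // 2
    dt = statistics.median(t[i + 1] - t[i] for i in range(n - 1))
    denom = 2.0 * dt * sum(range(1, m + 1))
    vx: list = [None] * n
    vy: list = [None] * n
    for i in range(n):
        if i - m < 0 or i + m >= n:
            continue
        if not all(valid[j] for j in range(i - m, i + m + 1)):
            continue
        vx[i] = sum(x[i + k] - x[i - k] for k in range(1, m + 1)) / denom
        vy[i] = sum(y[i + k] - y[i - k] for k in range(1, m + 1)) / denom
    defined = [i for i in range(n) if vx[i] is not None]
    assert len(defined) >= 10

    def robust_sigma(vs):
        med = statistics.median(vs)
        msq = statistics.median(v * v for v in vs)
        return math.sqrt(max(msq - med * med, 0.0))

    ex = params.lambda_thresh * robust_sigma([vx[i] for i in defined])
    ey = params.lambda_thresh * robust_sigma([vy[i] for i in defined])
    above = [
        vx[i] is not None and (vx[i] / ex) ** 2 + (vy[i] / ey) ** 2 > 1.0
        for i in range(n)
    ]
    runs = []
    i = 0
    while i < n:
        if above[i]:
            j = i
            while j + 1 < n and above[j + 1]:
                j += 1
            if j - i + 1 >= params.min_duration:
                runs.append((i, j))
            i = j + 1
        else:
            i += 1
    changed = True
    while changed:
        changed = False
        for a in range(len(runs) - 1):
            if t[runs[a + 1][0]] - t[runs[a][1]] < params.merge_gap:
                runs[a] = (runs[a][0], runs[a + 1][1])
                del runs[a + 1]
                changed = True
                break
    events = []
    for i0, i1 in runs:
        if i0 - 1 < 0 or i1 + 1 >= n:
            continue
        if not (valid[i0 - 1] and valid[i1 + 1]):
            continue
        if not all(valid[j] for j in range(i0, i1 + 1)):
            continue
        dx = x[i1 + 1] - x[i0 - 1]
        dy = y[i1 + 1] - y[i0 - 1]
        mag = math.hypot(dx, dy)
        if mag < params.min_displacement / 60.0:
            continue
        events.append((i0, i1, mag))
    return events


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
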