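"""Velocity, thresholds, candidate detection, merging, drift coding, rules."""

import numpy as np
import pytest
from conftest import brute_force_saccades, make_segment, segment_of

from femkit import (
    ConfigError,
    DegenerateSignalError,
    DetectionError,
    DetectionParams,
    SaccadeEvent,
    SimulationConfig,
    apply_exclusions,
    compute_velocity,
    detect_candidates,
    detect_saccades_and_drift,
    estimate_thresholds,
    finalize_saccades,
    merge_candidates,
    segment_drift,
    simulate_session,
    split_segments,
)
from femkit.event_detection import Thresholds, VelocitySeries


class TestParams:
    @pytest.mark.parametrize("field,value", [
        ("lambda_thresh", 0), ("velocity_window", -5), ("merge_gap", 0.0),
        ("min_displacement", -1), ("warmup", 0), ("min_drift_duration", 0),
    ])
    def test_nonpositive_rejected(self, field, value):
        with pytest.raises(ConfigError):
            DetectionParams(**{field: value})

    def test_even_window_rejected(self):
        with pytest.raises(ConfigError):
            DetectionParams(velocity_window=4)


class TestVelocity:
    def test_constant_position_zero_velocity(self):
        seg = make_segment(np.full(50, 0.2), np.full(50, -0.1))
        vel = compute_velocity(seg)
        assert np.all(vel.vx[vel.defined] == 0.0)
        assert np.all(vel.vy[vel.defined] == 0.0)

    def test_linear_ramp_exact(self):
        # the stencil is exact for linear signals
        slope = 1.7
        t = np.arange(100) / 620.0
        seg = make_segment(slope * t, np.zeros(100))
        vel = compute_velocity(seg)
        np.testing.assert_allclose(vel.vx[vel.defined], slope, rtol=1e-9)

    def test_step_stencil_value(self):
        # x = [0,0,0,1,1,1] deg at 620 Hz: v_2 = (1+1-0-0)/(6Δt) = 620/3
        seg = make_segment(np.array([0.0, 0, 0, 1, 1, 1]), np.zeros(6))
        vel = compute_velocity(seg)
        assert vel.vx[2] == pytest.approx(620.0 / 3.0)
        assert vel.vx[3] == pytest.approx(620.0 / 3.0)

    def test_window_three_central_difference(self):
        slope = -0.5
        t = np.arange(30) / 620.0
        seg = make_segment(np.zeros(30), slope * t)
        vel = compute_velocity(seg, DetectionParams(velocity_window=3))
        assert not vel.defined[0] and not vel.defined[-1]
        np.testing.assert_allclose(vel.vy[vel.defined], slope, rtol=1e-9)

    def test_undefined_at_edges_and_around_invalid(self):
        valid = np.ones(30, bool)
        valid[10] = False
        seg = make_segment(np.zeros(30), np.zeros(30), valid=valid)
        vel = compute_velocity(seg)
        assert not vel.defined[:2].any() and not vel.defined[-2:].any()
        assert not vel.defined[8:13].any()  # stencil touches sample 10
        assert vel.defined[7] and vel.defined[13]

    def test_too_short_segment_raises(self):
        seg = make_segment(np.zeros(4), np.zeros(4))
        with pytest.raises(DetectionError):
            compute_velocity(seg)


def _vel(vx, vy=None):
    vx = np.asarray(vx, float)
    vy = np.zeros_like(vx) if vy is None else np.asarray(vy, float)
    return VelocitySeries(vx=vx, vy=vy, defined=np.ones(len(vx), bool), dt=1 / 620)


class TestThresholds:
    def test_hand_evaluated_sigma(self):
        # vx = [-2,-1,0,1,2]: median 0, median of squares 1 → σ = 1, η = 6
        vx = np.tile([-2.0, -1.0, 0.0, 1.0, 2.0], 2)
        vy = np.tile([-4.0, -2.0, 0.0, 2.0, 4.0], 2)
        thr = estimate_thresholds(_vel(vx, vy), 6.0)
        assert thr.sigma_x == pytest.approx(1.0)
        assert thr.eta_x == pytest.approx(6.0)
        assert thr.sigma_y == pytest.approx(2.0)
        assert thr.eta_y == pytest.approx(12.0)

    def test_constant_velocity_degenerate(self):
        with pytest.raises(DegenerateSignalError):
            estimate_thresholds(_vel(np.full(20, 3.0), np.full(20, 3.0)))

    def test_gaussian_sigma_converges_to_0_6745_sd(self, rng):
        # median(χ²₁) = 0.4549 → σ_est ≈ 0.6745·s for centred Gaussian v
        s = 2.3
        v = rng.normal(0, s, 100_000)
        thr = estimate_thresholds(_vel(v, v[::-1]), 6.0)
        assert thr.sigma_x == pytest.approx(0.6745 * s, rel=0.02)

    def test_too_few_defined_raises(self):
        with pytest.raises(DetectionError):
            estimate_thresholds(_vel(np.arange(5.0)))


class TestCandidates:
    def test_all_sub_threshold_empty(self):
        thr = Thresholds(1.0, 1.0, 6.0, 6.0)
        assert detect_candidates(_vel(np.ones(50)), thr) == []

    def test_short_run_dropped_by_min_duration(self):
        vx = np.zeros(50)
        vx[20:22] = 10.0  # 2 samples < min_duration 3
        thr = Thresholds(1.0, 1.0, 6.0, 6.0)
        assert detect_candidates(_vel(vx), thr) == []

    def test_embedded_run_found_exactly(self):
        vx = np.zeros(50)
        vx[20:25] = 10.0
        thr = Thresholds(1.0, 1.0, 6.0, 6.0)
        assert detect_candidates(_vel(vx), thr) == [(20, 24)]

    def test_elliptic_combination(self):
        # each axis below its own η but jointly above the ellipse
        vx = np.zeros(30)
        vy = np.zeros(30)
        vx[10:13] = 5.0
        vy[10:13] = 5.0
        thr = Thresholds(1.0, 1.0, 6.0, 6.0)
        assert detect_candidates(_vel(vx, vy), thr) == [(10, 12)]


class TestMerging:
    t = np.arange(1000) / 620.0

    def test_15ms_gap_merges(self):
        gap = 9  # 9/620 ≈ 14.5 ms < 20 ms
        ivs = [(100, 110), (110 + gap, 130)]
        assert merge_candidates(ivs, 0.020, self.t) == [(100, 130)]

    def test_25ms_gap_does_not_merge(self):
        gap = 16  # 16/620 ≈ 25.8 ms
        ivs = [(100, 110), (110 + gap, 130)]
        assert merge_candidates(ivs, 0.020, self.t) == ivs

    def test_single_interval_unchanged(self):
        assert merge_candidates([(5, 9)], 0.020, self.t) == [(5, 9)]

    def test_chain_merges_to_fixed_point(self):
        ivs = [(100, 105), (110, 115), (120, 125)]
        assert merge_candidates(ivs, 0.020, self.t) == [(100, 125)]

    def test_idempotent(self):
        ivs = [(10, 20), (100, 120), (300, 310)]
        once = merge_candidates(ivs, 0.020, self.t)
        assert merge_candidates(once, 0.020, self.t) == once


def _step_segment(amp_deg, k=100, n=300):
    """Constant position with an instantaneous step of amp_deg at index k."""
    x = np.zeros(n)
    x[k:] = amp_deg
    return make_segment(x, np.zeros(n))


class TestFinalize:
    def test_step_displacement_measured_pre_to_post(self):
        seg = _step_segment(10 / 60.0)
        events, log = finalize_saccades(seg, [(98, 102)])
        assert len(events) == 1
        assert events[0].magnitude == pytest.approx(10 / 60.0)
        assert events[0].direction == pytest.approx(0.0)

    def test_three_arcmin_step_filtered(self):
        seg = _step_segment(3 / 60.0)
        events, log = finalize_saccades(seg, [(98, 102)])
        assert events == []
        assert log.counts() == {"below-min-displacement": 1}

    def test_opposite_steps_opposite_directions(self):
        n = 600
        x = np.zeros(n)
        x[200:] += 10 / 60.0
        x[400:] -= 10 / 60.0
        seg = make_segment(x, np.zeros(n))
        events, _ = finalize_saccades(seg, [(198, 202), (398, 402)])
        assert len(events) == 2
        d = abs(events[0].direction - events[1].direction)
        assert min(d, 360 - d) == pytest.approx(180.0)

    def test_invalid_flank_drops_event(self):
        seg = _step_segment(10 / 60.0)
        seg.recording.valid[97] = False
        events, log = finalize_saccades(seg, [(98, 102)])
        assert events == []
        assert log.counts() == {"no-flanking-sample": 1}

    def test_loss_inside_candidate_drops_event(self):
        seg = _step_segment(10 / 60.0)
        seg.recording.valid[100] = False
        seg.recording.x[100] = np.nan
        events, log = finalize_saccades(seg, [(98, 102)])
        assert events == []
        assert "loss-within-saccade" in log.counts()


def _sac(onset, offset, t):
    return SaccadeEvent(
        onset_idx=onset, offset_idx=offset,
        onset_t=float(t[onset]), offset_t=float(t[offset]),
        displacement=(0.2, 0.0), magnitude=0.2, direction=0.0, peak_speed=20.0,
    )


class TestDriftCoding:
    def test_no_saccades_whole_segment_is_drift(self):
        seg = make_segment(np.zeros(1000), np.zeros(1000))
        eps = segment_drift(seg, [])
        assert len(eps) == 1
        assert (eps[0].start_idx, eps[0].end_idx) == (0, 999)

    def test_one_saccade_two_episodes(self):
        seg = make_segment(np.zeros(1000), np.zeros(1000))
        eps = segment_drift(seg, [_sac(500, 510, seg.t)])
        assert [(e.start_idx, e.end_idx) for e in eps] == [(0, 499), (511, 999)]

    def test_80ms_interval_not_drift_120ms_is(self):
        seg = make_segment(np.zeros(2000), np.zeros(2000))
        # gaps of 50 samples (79 ms) and 75 samples (119 ms) between saccades
        sacs = [_sac(500, 510, seg.t), _sac(561, 571, seg.t),
                _sac(647, 657, seg.t)]
        eps = segment_drift(seg, sacs)
        gaps = [(e.start_idx, e.end_idx) for e in eps]
        assert (511, 560) not in gaps  # 49/620 ≈ 79 ms ≤ 100 ms
        assert (572, 646) in gaps      # 74/620 ≈ 119 ms > 100 ms

    def test_episode_with_loss_discarded_whole(self):
        valid = np.ones(1000, bool)
        valid[700] = False
        seg = make_segment(np.zeros(1000), np.zeros(1000), valid=valid)
        eps = segment_drift(seg, [_sac(300, 310, seg.t)])
        assert [(e.start_idx, e.end_idx) for e in eps] == [(0, 299)]


class TestExclusions:
    def test_warmup_saccade_discarded(self):
        seg = _step_segment(10 / 60.0, k=186, n=1000)  # onset ≈ 0.3 s
        events, _ = finalize_saccades(seg, [(184, 188)])
        kept, _, log = apply_exclusions(events, [], seg)
        assert kept == []
        assert log.counts() == {"warmup": 1}

    def test_distant_landing_discarded(self):
        n = 1000
        x = np.zeros(n)
        x[500:] = 2.6  # lands 2.6 deg from center
        seg = make_segment(x, np.zeros(n))
        events, _ = finalize_saccades(seg, [(498, 502)])
        kept, _, log = apply_exclusions(events, [], seg)
        assert kept == []
        assert log.counts() == {"distance": 1}

    def test_near_center_events_retained(self):
        seg = _step_segment(10 / 60.0, k=500, n=1000)
        events, _ = finalize_saccades(seg, [(498, 502)])
        drifts = segment_drift(seg, events)
        kept_s, kept_d, log = apply_exclusions(events, drifts, seg)
        assert len(kept_s) == 1
        # the pre-saccade episode starts at t=0 (warm-up); the post one stays
        assert len(kept_d) == 1
        assert kept_d[0].start_idx == 503
        assert log.counts() == {"warmup": 1}

    def test_distant_drift_mean_position_discarded(self):
        seg = make_segment(np.full(1000, 2.6), np.zeros(1000))
        drifts = segment_drift(seg, [])
        # shift drift start past warm-up by cutting the episode
        drifts[0].start_idx = 400
        drifts[0].start_t = float(seg.t[400])
        _, kept, log = apply_exclusions([], drifts, seg)
        assert kept == []
        assert log.counts() == {"distance": 1}


class TestComposedDetection:
    def _session_segment(self, seed, **kw):
        cfg = SimulationConfig(amplitude_min=0.1, noise_rms_s2s=0.16, **kw)
        rec, truth, man = simulate_session(cfg, seed)
        return split_segments(rec, man)[0], truth

    def test_determinism(self):
        seg, _ = self._session_segment(7)
        r1 = detect_saccades_and_drift(seg)
        r2 = detect_saccades_and_drift(seg)
        assert [(s.onset_idx, s.offset_idx) for s in r1.saccades] == \
               [(s.onset_idx, s.offset_idx) for s in r2.saccades]
        assert [(d.start_idx, d.end_idx) for d in r1.drifts] == \
               [(d.start_idx, d.end_idx) for d in r2.drifts]

    def test_events_disjoint_ordered_and_drift_rules_hold(self):
        seg, _ = self._session_segment(8)
        res = detect_saccades_and_drift(seg)
        ivs = sorted(
            [(s.onset_idx, s.offset_idx) for s in res.saccades]
            + [(d.start_idx, d.end_idx) for d in res.drifts]
        )
        for (a0, a1), (b0, b1) in zip(ivs, ivs[1:]):
            assert a1 < b0  # mutually disjoint, jointly ordered
        for d in res.drifts:
            assert d.duration > 0.100
            assert seg.valid[d.start_idx : d.end_idx + 1].all()

    @pytest.mark.parametrize("seed,mode", [(21, "diffusion"), (22, "directed"),
                                           (23, "diffusion")])
    def test_matches_brute_force_oracle(self, seed, mode):
        # composed chain equals the independent per-sample scan, event for event
        cfg = SimulationConfig(
            duration=2000 / 620.0, amplitude_min=0.1, noise_rms_s2s=0.16,
            drift_mode=mode, saccade_rate=2.0,
        )
        rec, _, man = simulate_session(cfg, seed)
        seg = split_segments(rec, man)[0]
        params = DetectionParams()
        vel = compute_velocity(seg, params)
        thr = estimate_thresholds(vel, params.lambda_thresh)
        cand = detect_candidates(vel, thr, params)
        merged = merge_candidates(cand, params.merge_gap, seg.t)
        events, _ = finalize_saccades(seg, merged, params, vel)
        oracle = brute_force_saccades(seg.t, seg.x, seg.y, seg.valid, params)
        assert [(e.onset_idx, e.offset_idx) for e in events] == \
               [(o[0], o[1]) for o in oracle]
        for e, o in zip(events, oracle):
            assert e.magnitude == pytest.approx(o[2], abs=1e-12)
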