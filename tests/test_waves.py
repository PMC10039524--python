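"""Phase analysis, winding numbers, centers, and wave classification."""

import numpy as np
import pytest

import spiralwave as sw
from spiralwave.containers import SnapshotStack
from spiralwave.waves import CenterOfMass, locate_core, wrap_phase

from conftest import planar_on_background, spiral_on_background


def canonical_singularity(n=64, center=(32.5, 32.5)):
    """Phase field atan2(row - r0, col - c0): winding +1 by construction."""
    rr = np.arange(n)[:, None] - (center[0] - 1)
    cc = np.arange(n)[None, :] - (center[1] - 1)
    return np.arctan2(rr, cc)


class TestInstantaneousPhase:
    def test_unwrapped_slope_matches_two_hertz(self):
        t = np.arange(2000) / 1000.0
        frames = np.cos(2 * np.pi * 2.0 * t)[:, None, None] * np.ones((1, 2, 2))
        stack = SnapshotStack(frames)
        phases = sw.instantaneous_phase(stack)
        trace = np.unwrap(phases.frames[:, 0, 0].astype(float))
        mid = slice(200, 1800)
        slope = np.polyfit(t[mid], trace[mid], 1)[0]
        assert slope == pytest.approx(4 * np.pi, rel=0.02)

    def test_sine_lags_cosine_by_quarter_cycle(self):
        t = np.arange(2000) / 1000.0
        frames = np.stack([np.stack([np.cos(2 * np.pi * 2 * t),
                                     np.sin(2 * np.pi * 2 * t)])] * 1, axis=2)
        stack = SnapshotStack(frames.T.reshape(-1, 2, 1))
        phases = sw.instantaneous_phase(stack)
        diff = wrap_phase(phases.frames[500:1500, 0, 0]
                          - phases.frames[500:1500, 1, 0])
        assert np.median(diff) == pytest.approx(np.pi / 2, abs=0.05)

    def test_constant_trace_flagged_degenerate(self):
        frames = np.ones((100, 2, 2))
        frames[:, 0, 0] = np.sin(np.arange(100) / 5.0)
        phases = sw.instantaneous_phase(SnapshotStack(frames))
        assert phases.degenerate[1, 1]
        assert not phases.degenerate[0, 0]
        assert np.allclose(phases.frames[:, 1, 1], 0.0)

    def test_too_few_frames_rejected(self):
        with pytest.raises(ValueError):
            sw.instantaneous_phase(SnapshotStack(np.zeros((4, 2, 2))))


class TestCenterOfMass:
    def test_uniform_frame_centers_at_grid_middle(self):
        com = sw.center_of_mass(np.ones((64, 64)))
        assert (com.r, com.c) == (32.5, 32.5)

    def test_single_pixel(self):
        frame = np.zeros((30, 30))
        frame[9, 19] = 4.0           # 1-based (10, 20)
        com = sw.center_of_mass(frame)
        assert (com.r, com.c) == (10.0, 20.0)

    def test_two_pixel_hand_example(self):
        # a_22 = a_33 = 2 on a 3x3 grid -> center (2.5, 2.5)
        frame = np.zeros((3, 3))
        frame[1, 1] = 2.0
        frame[2, 2] = 2.0
        com = sw.center_of_mass(frame)
        assert (com.r, com.c) == (2.5, 2.5)

    def test_translation_equivariance(self):
        rng = np.random.default_rng(0)
        frame = np.zeros((64, 64))
        frame[20:30, 20:30] = rng.uniform(1, 2, (10, 10))
        base = sw.center_of_mass(frame)
        shifted = sw.center_of_mass(np.roll(frame, (5, 7), axis=(0, 1)))
        assert shifted.r == pytest.approx(base.r + 5, abs=1e-9)
        assert shifted.c == pytest.approx(base.c + 7, abs=1e-9)

    def test_all_zero_frame_rejected(self):
        with pytest.raises(ValueError, match="undefined center"):
            sw.center_of_mass(np.zeros((4, 4)))


class TestWaveCenter:
    def test_constant_center_has_zero_scatter(self):
        frame = np.zeros((64, 64))
        frame[29, 29] = 1.0          # 1-based (30, 30)
        com, _, scatter = sw.wave_center(np.stack([frame] * 5))
        assert (com.r, com.c) == (30.0, 30.0)
        assert scatter == 0.0

    def test_mean_of_two_centers(self):
        f1 = np.zeros((64, 64)); f1[29, 29] = 1.0
        f2 = np.zeros((64, 64)); f2[31, 29] = 1.0
        com, _, _ = sw.wave_center(np.stack([f1, f2]))
        assert (com.r, com.c) == (31.0, 30.0)

    def test_rotation_core_recovered_within_two_grid_units(self):
        errors = []
        for seed in range(8):
            params, stack = spiral_on_background(200 + seed)
            phases = sw.instantaneous_phase(stack)
            core = locate_core(phases)
            errors.append(np.hypot(core.r - params.center[0],
                                   core.c - params.center[1]))
        assert np.mean(errors) < 2.0


class TestVectorField:
    def test_spiral_field_is_tangential(self, noiseless_spiral):
        params, stack = noiseless_spiral
        phases = sw.instantaneous_phase(stack)
        vf = sw.vector_field(phases, stack.n_frames // 2)
        rr = np.arange(64)[:, None] - (params.center[0] - 1)
        cc = np.arange(64)[None, :] - (params.center[1] - 1)
        radial = np.arctan2(rr, cc)
        rho = np.hypot(rr, cc)
        mask = (rho > 3) & (rho < 12) & ~vf.degenerate
        cosang = np.cos(np.arctan2(vf.v, vf.u) - radial)[mask]
        assert np.abs(cosang).mean() < 0.2

    def test_static_phases_give_zero_field(self):
        frames = np.tile(canonical_singularity(16, (8.5, 8.5)), (30, 1, 1))
        phases = sw.instantaneous_phase(SnapshotStack(frames + 0.0))
        # static input: temporal difference is zero everywhere
        vf = sw.vector_field(sw.PhaseStack(frames.astype(np.float32), 0.001),
                             0, lag_s=0.01)
        assert np.allclose(vf.u, 0.0) and np.allclose(vf.v, 0.0)

    def test_lag_outside_stack_rejected(self):
        phases = sw.PhaseStack(np.zeros((5, 4, 4), np.float32), 0.001)
        with pytest.raises(ValueError):
            sw.vector_field(phases, 4, lag_s=0.01)


class TestWindingNumber:
    def test_canonical_singularity_is_plus_one(self):
        pm = canonical_singularity()
        assert sw.winding_number(pm, (32.5, 32.5), 8) == +1

    def test_negated_field_is_minus_one(self):
        pm = -canonical_singularity()
        assert sw.winding_number(pm, (32.5, 32.5), 8) == -1

    def test_planar_gradient_is_zero(self):
        cc = np.arange(64)[None, :] * np.ones((64, 1))
        pm = wrap_phase(0.3 * cc)
        assert sw.winding_number(pm, (32.5, 32.5), 10) == 0

    def test_quarter_turn_rotation_invariance_and_mirror_negation(self):
        pm = canonical_singularity()
        rotated = np.rot90(pm)
        assert sw.winding_number(rotated, (32.5, 32.5), 8) == +1
        mirrored = pm[:, ::-1]
        assert sw.winding_number(mirrored, (32.5, 32.5), 8) == -1

    def test_small_radius_rejected(self):
        with pytest.raises(ValueError):
            sw.winding_number(canonical_singularity(), (32.5, 32.5), 1.0)


class TestRotationAndCycles:
    @pytest.mark.parametrize("arms, expected", [(1, "CCW"), (-1, "CW")])
    def test_direction_recovered_from_programmed_arm_sign(self, arms, expected):
        for seed in (11, 12, 13):
            params, stack = spiral_on_background(seed, arms=arms)
            phases = sw.instantaneous_phase(stack)
            core = locate_core(phases) or CenterOfMass(*params.center)
            assert sw.rotation_direction(phases, core) == expected

    def test_mirroring_flips_direction(self, spiral_event):
        params, stack = spiral_event
        mirrored = SnapshotStack(stack.frames[:, :, ::-1].copy(),
                                 stack.frame_interval)
        ph = sw.instantaneous_phase(stack)
        ph_m = sw.instantaneous_phase(mirrored)
        center = CenterOfMass(params.center[0], 65 - params.center[1])
        d = sw.rotation_direction(ph, CenterOfMass(*params.center))
        d_m = sw.rotation_direction(ph_m, center)
        assert {d, d_m} == {"CW", "CCW"}

    @pytest.mark.parametrize("cycles", [1, 2])
    def test_cycle_count_exact_at_low_noise(self, cycles):
        for seed in (21, 22, 23):
            params, stack = spiral_on_background(seed, cycles=cycles)
            phases = sw.instantaneous_phase(stack)
            core = locate_core(phases) or CenterOfMass(*params.center)
            assert sw.count_cycles(phases, core, 8.0) == cycles


class TestClassifyWave:
    def test_spiral_event_satisfies_all_four_criteria(self, spiral_event):
        _, stack = spiral_event
        ev = sw.classify_wave(stack)
        assert ev.kind == "spiral"
        assert ev.criteria["broad_phases"]
        assert ev.criteria["rotating"]
        assert ev.criteria["core_dip"]
        assert ev.criteria["distance_correlations"]

    def test_planar_event_identified_by_aligned_fields(self):
        _, stack = planar_on_background(31)
        ev = sw.classify_wave(stack)
        assert ev.kind == "planar"
        assert ev.criteria["vector_alignment"] > 0.8
        assert ev.criteria["median_winding"] == 0

    def test_baseline_segment_is_other(self, baseline_stack):
        ev = sw.classify_wave(baseline_stack)
        assert ev.kind == "other"

    def test_deterministic_given_stack(self, spiral_event):
        _, stack = spiral_event
        a = sw.classify_wave(stack)
        b = sw.classify_wave(stack)
        assert a.kind == b.kind and a.criteria == b.criteria

    def test_pooled_phase_distribution_spans_circle(self, spiral_event):
        _, stack = spiral_event
        phases = sw.instantaneous_phase(stack)
        pooled = phases.frames[:: max(stack.n_frames // 5, 1)]
        from spiralwave.waves import resultant_length
        assert resultant_length(pooled) < 0.4

    def test_too_short_stack_rejected(self):
        with pytest.raises(ValueError):
            sw.classify_wave(SnapshotStack(np.zeros((10, 64, 64))))


class TestDetectWaves:
    def test_recovers_programmed_events(self, demo_dataset, detection_result):
        _, _, truth = demo_dataset
        res = detection_result

        def jaccard(a, b):
            inter = max(0.0, min(a[1], b[1]) - max(a[0], b[0]))
            return inter / ((a[1] - a[0]) + (b[1] - b[0]) - inter)

        hits = 0
        for gt in truth.of_kind("spiral"):
            best = max(res.events, default=None,
                       key=lambda e: jaccard((gt.start_s, gt.end_s),
                                             (e.start_s, e.end_s)))
            if best is not None and best.kind == "spiral" and jaccard(
                    (gt.start_s, gt.end_s), (best.start_s, best.end_s)) > 0.5:
                hits += 1
                assert best.direction == gt.direction
        assert hits >= len(truth.of_kind("spiral")) - 1   # >= 90%

    def test_rate_within_twenty_percent_of_programmed(self, demo_dataset,
                                                      detection_result):
        _, rec, truth = demo_dataset
        programmed = len(truth.of_kind("spiral")) / (rec.duration_s / 60.0)
        assert detection_result.rate_per_min == pytest.approx(programmed,
                                                              rel=0.2)

    def test_duration_statistics_reported(self, detection_result):
        assert 0.8 <= detection_result.duration_mean_s <= 6.0
        assert detection_result.duration_sd_s >= 0.0

    def test_pure_baseline_yields_no_spirals(self):
        rec = sw.generate_baseline(sw.BaselineParams(duration=60.0, seed=701))
        res = sw.detect_waves(sw.bandpass_delta(rec))
        assert len(res.spirals()) == 0
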