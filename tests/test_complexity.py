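"""Eigenspectra, participation ratio, intrinsic dimension, correlations."""

import numpy as np
import pytest

import spiralwave as sw
from spiralwave.complexity import MODES
from spiralwave.containers import ElectrodeLayout, SnapshotStack

from conftest import spiral_on_background

try:
    from hypothesis import given, strategies as st
    HAVE_HYPOTHESIS = True
except ImportError:                                    # pragma: no cover
    HAVE_HYPOTHESIS = False


class TestEigenspectrum:
    def test_rank_one_frame_has_single_nonzero_value(self):
        u = np.arange(1.0, 9.0)
        frame = np.outer(u, u[::-1])
        for mode in MODES:
            spec = sw.eigenspectrum(frame[None], mode)
            if mode != "channel-covariance":   # centering removes the mean
                assert spec.n_nonzero == 1

    def test_identity_frame_has_equal_values(self):
        spec = sw.eigenspectrum(np.eye(64)[None], "stacked-svd")
        assert spec.eigenvalues.shape[0] >= 64
        assert np.allclose(spec.eigenvalues[:64], 1.0)

    def test_total_equals_squared_frobenius_norm(self):
        rng = np.random.default_rng(0)
        frames = rng.normal(size=(3, 16, 16))
        for mode in ("stacked-svd", "spatial-svd-pooled", "snapshot-gram"):
            spec = sw.eigenspectrum(frames, mode)
            assert spec.eigenvalues.sum() == pytest.approx(
                (frames ** 2).sum(), rel=1e-8)

    def test_channel_covariance_matches_dense_eigensolver(self):
        rng = np.random.default_rng(1)
        frames = rng.normal(size=(12, 8, 8))
        spec = sw.eigenspectrum(frames, "channel-covariance")
        brute = np.linalg.eigvalsh(np.cov(frames.reshape(12, -1).T))[::-1]
        nz = spec.eigenvalues[: 11]
        assert np.allclose(nz, brute[: 11], rtol=1e-8, atol=1e-10)

    def test_empty_stack_rejected(self):
        with pytest.raises(ValueError):
            sw.eigenspectrum(np.zeros((0, 4, 4)))


class TestParticipationRatio:
    @pytest.mark.parametrize("spectrum, expected", [
        ((1.0, 1.0, 1.0, 1.0), 4.0),       # flat spectrum: PR = N
        ((1.0, 0.0, 0.0, 0.0), 1.0),       # single mode: PR = 1
        ((2.0, 1.0, 1.0), 16.0 / 6.0),     # hand-evaluated
    ])
    def test_closed_form_values(self, spectrum, expected):
        assert sw.participation_ratio(np.array(spectrum)).pr == pytest.approx(
            expected)

    if HAVE_HYPOTHESIS:
        @given(st.lists(st.floats(0.01, 100.0), min_size=1, max_size=30),
               st.floats(0.001, 1000.0))
        def test_scale_invariance(self, values, scale):
            ev = np.asarray(values)
            a = sw.participation_ratio(ev).pr
            b = sw.participation_ratio(ev * scale).pr
            assert a == pytest.approx(b, rel=1e-9)

        @given(st.lists(st.floats(0.01, 100.0), min_size=1, max_size=30))
        def test_bounded_by_nonzero_count(self, values):
            ev = np.asarray(values)
            pr = sw.participation_ratio(ev).pr
            assert 1.0 - 1e-9 <= pr <= len(values) + 1e-9

    def test_all_zero_spectrum_rejected(self):
        with pytest.raises(ValueError):
            sw.participation_ratio(np.zeros(5))

    def test_normalizations(self):
        res = sw.ComplexityResult(pr=32.0, mode="stacked-svd",
                                  n_channels=1024, n_snapshots=36)
        assert sw.normalized_pr(res, "channels") == pytest.approx(1.0)
        res6 = sw.ComplexityResult(pr=6.0, mode="stacked-svd",
                                   n_channels=64, n_snapshots=36)
        assert sw.normalized_pr(res6, "snapshots") == pytest.approx(1.0)

    def test_normalization_preserves_order(self):
        prs = [4.0, 9.0, 25.0]
        results = [sw.ComplexityResult(p, "raw", 64, 6) for p in prs]
        normed = [sw.normalized_pr(r, "channels") for r in results]
        assert normed == sorted(normed)


class TestScalingCurves:
    def test_pr_grows_with_channel_count(self, long_spiral_event):
        from scipy.stats import spearmanr
        _, stack = long_spiral_event
        curve = sw.pr_vs_channel_count(stack, [16, 32, 64, 128, 256, 512],
                                       reps=5, seed=0)
        rho = spearmanr(curve.n_channels, curve.pr_mean).statistic
        assert rho > 0.9

    def test_full_channel_count_has_no_subsampling_randomness(self,
                                                              baseline_stack):
        small = SnapshotStack(baseline_stack.frames[:50, :8, :8])
        curve = sw.pr_vs_channel_count(small, [64], reps=4, seed=1)
        assert curve.pr_sd.iloc[0] == pytest.approx(0.0, abs=1e-9)

    def test_count_below_two_rejected(self, baseline_stack):
        with pytest.raises(ValueError):
            sw.pr_vs_channel_count(baseline_stack, [1])

    def test_pr_grows_with_snapshot_count(self, long_spiral_event):
        _, stack = long_spiral_event
        curve = sw.pr_vs_snapshot_count(stack, [1, 2, 4, 6, 12, 24])
        diffs = np.diff(curve.pr.values)
        assert (diffs < -0.05 * curve.pr.values[:-1]).sum() <= 1
        assert curve.pr.values[-1] > curve.pr.values[0]

    def test_single_snapshot_equals_single_frame_spectrum(self,
                                                          long_spiral_event):
        _, stack = long_spiral_event
        curve = sw.pr_vs_snapshot_count(stack, [1])
        direct = sw.pr_of_stack(stack.frames[:1])
        assert curve.pr.iloc[0] == pytest.approx(direct.pr)


class TestNoiseSweep:
    def test_pr_rises_then_saturates_with_noise_sd(self, long_spiral_event):
        _, stack = long_spiral_event
        six = sw.select_evenly_spaced(stack, 6)
        table = sw.pr_noise_sweep(six, means=[0.0],
                                  sds=[0.0, 50.0, 500.0, 1000.0],
                                  reps=3, seed=0)
        by_sd = table.set_index("sd").pr_mean
        rise = by_sd[500.0] - by_sd[50.0]
        assert rise > 0
        assert abs(by_sd[1000.0] - by_sd[500.0]) < 0.25 * rise

    def test_pr_is_maximal_at_zero_mean(self, long_spiral_event):
        _, stack = long_spiral_event
        six = sw.select_evenly_spaced(stack, 6)
        table = sw.pr_noise_sweep(six, means=[-200.0, -50.0, 0.0, 50.0, 200.0],
                                  sds=[100.0], reps=3, seed=0)
        by_mean = table.set_index("mean").pr_mean
        assert by_mean.idxmax() == 0.0

    def test_clean_setting_reproduces_clean_pr_exactly(self, long_spiral_event):
        _, stack = long_spiral_event
        six = sw.select_evenly_spaced(stack, 6)
        table = sw.pr_noise_sweep(six, means=[0.0], sds=[0.0], reps=2, seed=0)
        assert table.pr_mean.iloc[0] == pytest.approx(sw.pr_of_stack(six).pr)


class TestLBMLE:
    def test_recovers_planar_manifold_dimension(self):
        rng = np.random.default_rng(5)
        points = rng.uniform(size=(2000, 2)) @ rng.standard_normal((2, 10))
        assert 1.8 <= sw.lbmle_dimension(points) <= 2.2

    def test_recovers_line_dimension(self):
        rng = np.random.default_rng(6)
        points = rng.uniform(size=(400, 1)) * rng.standard_normal((1, 5))
        assert 0.9 <= sw.lbmle_dimension(points) <= 1.1

    def test_invariant_to_isotropic_scaling(self):
        rng = np.random.default_rng(7)
        points = rng.normal(size=(300, 3))
        a = sw.lbmle_dimension(points)
        b = sw.lbmle_dimension(points * 137.0)
        assert a == pytest.approx(b, rel=1e-9)

    def test_duplicate_points_are_collapsed(self):
        rng = np.random.default_rng(8)
        points = rng.normal(size=(200, 2))
        doubled = np.vstack([points, points])
        assert sw.lbmle_dimension(doubled) == pytest.approx(
            sw.lbmle_dimension(points))

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            sw.lbmle_dimension(np.zeros((10, 2)))


class TestCorrelations:
    def test_identical_channels_fully_correlated(self):
        t = np.sin(np.arange(100) / 3.0)
        frames = np.tile(t[:, None, None], (1, 2, 2))
        corr = sw.pairwise_correlations(SnapshotStack(frames))
        off = corr.matrix[np.triu_indices_from(corr.matrix, k=1)]
        assert np.allclose(off, 1.0)

    def test_independent_channels_nearly_uncorrelated(self):
        rng = np.random.default_rng(0)
        frames = rng.normal(size=(2000, 4, 4))
        corr = sw.pairwise_correlations(SnapshotStack(frames))
        off = corr.matrix[np.triu_indices_from(corr.matrix, k=1)]
        assert abs(off.mean()) < 0.05

    def test_matrix_symmetric_with_unit_diagonal(self, baseline_stack):
        corr = sw.pairwise_correlations(baseline_stack, channel_step=8)
        assert np.allclose(corr.matrix, corr.matrix.T, equal_nan=True)
        assert np.allclose(np.diag(corr.matrix), 1.0)

    def test_zero_variance_channels_recorded_missing(self):
        frames = np.zeros((50, 2, 2))
        frames[:, 0, 0] = np.sin(np.arange(50.0))
        frames[:, 0, 1] = np.cos(np.arange(50.0))
        corr = sw.pairwise_correlations(SnapshotStack(frames))
        assert np.isnan(corr.matrix[2, 3])
        assert np.isfinite(corr.matrix[0, 1])

    def test_mean_matrix_averages_events(self, baseline_stack):
        a = sw.pairwise_correlations(baseline_stack, channel_step=16)
        mean = sw.mean_correlation_matrix([a, a])
        assert np.allclose(mean.matrix, a.matrix, equal_nan=True)


class TestCorrelationVsDistance:
    def test_spiral_correlations_decay_with_distance(self, spiral_event):
        _, stack = spiral_event
        corr = sw.pairwise_correlations(stack, channel_step=4)
        reg = sw.correlation_vs_distance(corr)
        assert reg.slope < 0
        assert reg.p_value < 0.05

    def test_common_signal_gives_flat_regression(self):
        t = np.sin(np.arange(500) / 7.0)
        frames = np.tile(t[:, None, None], (1, 8, 8))
        frames = frames + np.random.default_rng(0).normal(
            0, 1e-3, frames.shape)
        corr = sw.pairwise_correlations(SnapshotStack(frames))
        reg = sw.correlation_vs_distance(corr)
        assert abs(reg.slope) < 1e-5

    def test_center_referenced_variant_decays_for_correlated_field(self):
        rec = sw.generate_baseline(sw.BaselineParams(
            noise_sd=10.0, spatial_corr_um=400.0, duration=3.0, seed=9))
        stack = sw.extract_snapshots(rec)
        corr = sw.pairwise_correlations(stack, channel_step=4)
        reg = sw.correlation_vs_distance(corr, center=(32.5, 32.5))
        assert reg.slope < 0
        assert reg.p_value < 0.05

    def test_short_range_correlations_exceed_long_range(self):
        rec = sw.generate_baseline(sw.BaselineParams(
            noise_sd=10.0, spatial_corr_um=100.0, duration=2.0, seed=2))
        full = sw.extract_snapshots(rec)
        # full-pitch sub-grid so sub-100 um pairs exist; 32 x 32 spans
        # beyond 1 mm
        stack = sw.SnapshotStack(full.frames[:, :32, :32],
                                 full.frame_interval,
                                 layout=sw.ElectrodeLayout(32, 32, 42.0))
        corr = sw.pairwise_correlations(stack)
        pos = corr.layout.positions_um()[corr.channel_indices]
        iu, ju = np.triu_indices(corr.matrix.shape[0], k=1)
        d = np.sqrt(((pos[iu] - pos[ju]) ** 2).sum(axis=1))
        c = corr.matrix[iu, ju]
        assert c[d < 100].mean() > c[d > 1000].mean()


class TestCompareConditions:
    def test_identical_samples_give_null_result(self):
        res = sw.compare_conditions([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.t == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_textbook_pooled_variance_value(self):
        res = sw.compare_conditions([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
        assert res.t == pytest.approx(-3.674, abs=0.001)
        assert res.df == 4

    def test_swapping_negates_t_and_preserves_p(self):
        a, b = [1.0, 2.0, 4.0], [3.0, 6.0, 7.0]
        r1 = sw.compare_conditions(a, b)
        r2 = sw.compare_conditions(b, a)
        assert r1.t == pytest.approx(-r2.t)
        assert r1.p_value == pytest.approx(r2.p_value)

    def test_degenerate_zero_variance_flagged(self):
        res = sw.compare_conditions([2.0, 2.0], [2.0, 2.0])
        assert res.degenerate


class TestConditionOrdering:
    def test_spiral_exceeds_baseline_exceeds_planar(self, baseline_stack):
        from conftest import planar_on_background
        pr = {"spiral": [], "baseline": [], "planar": []}
        for s in range(5):
            _, st = spiral_on_background(400 + s)
            pr["spiral"].append(
                sw.pr_of_stack(sw.select_evenly_spaced(st, 6)).pr)
            bl = sw.extract_snapshots(sw.generate_baseline(
                sw.BaselineParams(duration=2.0, seed=500 + s)))
            pr["baseline"].append(
                sw.pr_of_stack(sw.select_evenly_spaced(bl, 6)).pr)
            _, pl = planar_on_background(600 + s, direction_angle=s * 0.7)
            pr["planar"].append(
                sw.pr_of_stack(sw.select_evenly_spaced(pl, 6)).pr)
        assert np.mean(pr["spiral"]) > np.mean(pr["baseline"])
        assert np.mean(pr["baseline"]) > np.mean(pr["planar"])
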