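import numpy as np
import pytest
from dataclasses import replace

import statsmodels.api as sm

import revpet as rp
from revpet.kinetics import SingularFitError, _running_integral_min
from revpet.tacsim import simulate_voxel_grid

REV = 2280.0


class TestBaselineFit:
    def test_identical_tissues_give_unit_r1_zero_bp(self, clean_pair):
        ref, _, _ = clean_pair
        fit = rp.mrtm_baseline_fit(ref, ref, k2_prime=0.35)
        assert fit.r1 == pytest.approx(1.0, abs=1e-6)
        assert fit.bp_nd_baseline == pytest.approx(0.0, abs=1e-6)

    def test_identical_tissues_unconstrained_is_singular(self, clean_pair):
        ref, _, _ = clean_pair
        with pytest.raises(SingularFitError):
            rp.mrtm_baseline_fit(ref, ref, k2_prime=None)

    def test_constant_tacs_are_singular(self):
        fs = rp.FrameSchedule.default_68min()
        const = rp.TAC(fs, np.full(53, 5.0))
        with pytest.raises(SingularFitError):
            rp.mrtm_baseline_fit(const, const)

    @pytest.mark.parametrize("bp_true", [1.0, 2.0, 3.5])
    def test_noiseless_recovery_within_one_percent(self, bp_true):
        spec = rp.TacSimSpec(base_params=rp.BaseKineticParams(bp_nd=bp_true))
        ref, tgt, _ = rp.simulate_tac(spec)
        fit = rp.mrtm_baseline_fit(tgt, ref)
        assert fit.bp_nd_baseline == pytest.approx(bp_true, rel=0.01)
        assert fit.r1 == pytest.approx(1.0, rel=0.01)
        assert fit.k2_per_min == pytest.approx(0.35, rel=0.01)

    def test_midpoint_trapezoid_matches_fine_quadrature(self, clean_pair):
        ref, _, _ = clean_pair
        fs = ref.frame_schedule
        coarse = _running_integral_min(fs.midpoints_s, ref.activity)[-1]
        params = rp.RefInputParams()
        fine_t = np.linspace(0.0, fs.midpoints_s[-1], 200_001)
        fine = np.trapezoid(params.value(fine_t), fine_t) / 60.0
        assert coarse == pytest.approx(fine, rel=0.005)

    def test_mismatched_schedules_rejected(self, clean_pair):
        ref, tgt, _ = clean_pair
        short = rp.FrameSchedule(ref.frame_schedule.start_s[:10], ref.frame_schedule.end_s[:10])
        with pytest.raises(ValueError):
            rp.mrtm_baseline_fit(rp.TAC(short, tgt.activity[:10]), ref)


class TestBasis:
    def test_default_count_and_unit_peaks(self, basis_set):
        assert len(basis_set) == 5
        t = np.linspace(0.0, 4080.0, 40801)
        for b in basis_set:
            v = b.value(t)
            assert v.max() == pytest.approx(1.0, abs=1e-6)
            assert t[np.argmax(v)] == pytest.approx(b.peak_s, abs=0.2)
            assert (v[t < REV] == 0).all()

    def test_peak_grid_spans_one_to_twelve_minutes(self, basis_set):
        offsets = [(b.peak_s - b.onset_s) / 60.0 for b in basis_set]
        assert offsets == [1.0, 2.0, 4.0, 8.0, 12.0]

    def test_custom_count_uses_geometric_grid(self):
        basis = rp.build_reversal_basis(REV, n_basis=3, scan_end_s=4080.0)
        assert len(basis) == 3

    def test_peak_beyond_scan_end_raises(self):
        with pytest.raises(ValueError, match="scan end"):
            rp.build_reversal_basis(4000.0, scan_end_s=4080.0)


class TestLpNtpet:
    def test_noiseless_release_recovery(self, release_pair, basis_set, k2_prime, windows):
        ref, tgt, truth = release_pair
        fit = rp.lp_ntpet_fit(tgt, ref, basis_set, k2_prime)
        occ = rp.occupancy_curve(fit, windows["pre"], windows["post"])
        assert abs(occ.peak_occupancy_pct - truth.peak_occupancy_pct) < 1.0
        # winning basis is the true 2-min response
        assert fit.basis.peak_s == pytest.approx(truth.peak_s)

    def test_nested_rss_inequality(self, basis_set, k2_prime):
        spec = rp.TacSimSpec()
        for seed in range(8):
            ref, tgt, _ = rp.simulate_tac(replace(spec, noise_scale=0.15, seed=seed))
            base = rp.mrtm_baseline_fit(tgt, ref, k2_prime)
            full = rp.lp_ntpet_fit(tgt, ref, basis_set, k2_prime)
            assert full.rss <= base.rss + 1e-10

    def test_uptake_increase_clamps_gamma(self, clean_pair, basis_set, k2_prime):
        ref, tgt, _ = clean_pair
        bumped = tgt.activity.copy()
        bumped[tgt.frame_schedule.midpoints_s > REV] *= 1.03  # anti-displacement
        fit = rp.lp_ntpet_fit(rp.TAC(tgt.frame_schedule, bumped), ref, basis_set, k2_prime)
        assert fit.gamma_clamped
        assert fit.gamma_per_min == 0.0
        assert fit.f_stat == 0.0

    def test_empty_basis_rejected(self, clean_pair, k2_prime):
        ref, tgt, _ = clean_pair
        with pytest.raises(ValueError):
            rp.lp_ntpet_fit(tgt, ref, [], k2_prime)


class TestFStatistic:
    def test_hand_worked_value(self):
        assert rp.f_statistic(12.0, 10.0, 3, 4, 53) == pytest.approx((2.0 / 1.0) / (10.0 / 49.0))
        assert rp.f_statistic(12.0, 10.0, 3, 4, 53) == pytest.approx(9.8)

    def test_equal_rss_gives_zero(self):
        assert rp.f_statistic(5.0, 5.0, 2, 3, 53) == 0.0

    @pytest.mark.parametrize("args", [(10.0, 12.0, 2, 3, 53), (10.0, 5.0, 3, 3, 53), (10.0, 5.0, 2, 3, 3)])
    def test_degenerate_inputs_raise(self, args):
        with pytest.raises(ValueError):
            rp.f_statistic(*args)

    def test_agrees_with_ols_nested_f_test(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            n = 40
            x = rng.normal(size=(n, 3))
            y = x @ np.array([1.0, 0.5, 0.0]) + rng.normal(size=n)
            small = sm.OLS(y, sm.add_constant(x[:, :2])).fit()
            full = sm.OLS(y, sm.add_constant(x)).fit()
            f_ref, _, _ = full.compare_f_test(small)
            mine = rp.f_statistic(small.ssr, full.ssr, 3, 4, n)
            assert mine == pytest.approx(f_ref, rel=1e-9)


class TestOccupancy:
    def test_occupancy_identity(self, release_pair, basis_set, k2_prime, windows):
        ref, tgt, _ = release_pair
        fit = rp.lp_ntpet_fit(tgt, ref, basis_set, k2_prime)
        occ = rp.occupancy_curve(fit, windows["pre"], windows["post"])
        manual = (occ.pre_bp - fit.dynamic_bp(occ.times_s)) / occ.pre_bp * 100.0
        assert np.allclose(occ.occupancy_pct, manual)
        assert occ.peak_occupancy_pct == pytest.approx(
            (occ.pre_bp - occ.post_bp) / occ.pre_bp * 100.0
        )
        assert 0.0 <= occ.peak_occupancy_pct <= 100.0

    def test_no_release_fit_gives_zero_occupancy(self, clean_pair, basis_set, k2_prime, windows):
        ref, tgt, _ = clean_pair
        fit = rp.lp_ntpet_fit(tgt, ref, basis_set, k2_prime)
        occ = rp.occupancy_curve(fit, windows["pre"], windows["post"])
        assert abs(occ.peak_occupancy_pct) < 0.5

    def test_peak_is_localized_near_reversal(self, release_pair, basis_set, k2_prime, windows):
        ref, tgt, _ = release_pair
        fit = rp.lp_ntpet_fit(tgt, ref, basis_set, k2_prime)
        occ = rp.occupancy_curve(fit, windows["pre"], windows["post"])
        # within the first two post-reversal (2-min) frames
        assert REV <= occ.peak_time_s <= REV + 240.0

    def test_nonpositive_pre_bp_raises(self, clean_pair, basis_set, k2_prime):
        ref, tgt, _ = clean_pair
        fit = rp.lp_ntpet_fit(tgt, ref, basis_set, k2_prime)
        bad = replace(fit, k2a_per_min=2 * fit.k2_per_min)  # BP < 0 everywhere
        with pytest.raises(ValueError, match="pre-reversal"):
            rp.occupancy_curve(bad, (480.0, REV), (REV, REV + 600.0))


class TestPredictedPath:
    def test_zero_gamma_path_equals_fit(self, clean_pair, basis_set, k2_prime):
        ref, tgt, _ = clean_pair
        fit = rp.lp_ntpet_fit(tgt, ref, basis_set, k2_prime)
        path = rp.predicted_path(fit)
        assert np.allclose(path.activity, fit.fitted, atol=1e-8)

    def test_path_exceeds_observed_after_release(self, release_pair, basis_set, k2_prime):
        ref, tgt, _ = release_pair
        fit = rp.lp_ntpet_fit(tgt, ref, basis_set, k2_prime)
        path = rp.predicted_path(fit)
        mid = tgt.frame_schedule.midpoints_s
        post = (mid > REV + 60.0) & (mid < REV + 600.0)
        assert (path.activity[post] > tgt.activity[post]).all()
        assert (path.activity >= 0).all()


class TestTemporalSmooth:
    def test_constant_unchanged(self):
        fs = rp.FrameSchedule.default_68min()
        tac = rp.TAC(fs, np.full(53, 7.0))
        assert np.allclose(rp.temporal_smooth(tac).activity, 7.0)

    def test_unit_impulse_spreads_kernel(self):
        fs = rp.FrameSchedule.default_68min()
        x = np.zeros(53)
        x[25] = 1.0
        sm_ = rp.temporal_smooth(rp.TAC(fs, x)).activity
        assert np.allclose(sm_[24:27], [0.25, 0.5, 0.25])

    def test_total_activity_conserved_within_edge_effects(self, clean_pair):
        _, tgt, _ = clean_pair
        sm_ = rp.temporal_smooth(tgt)
        total_before = tgt.activity.sum()
        total_after = sm_.activity.sum()
        # only the renormalized edges can leak mass
        assert total_after == pytest.approx(total_before, rel=0.01)

    def test_too_few_frames_raises(self):
        fs = rp.FrameSchedule(np.array([0.0, 10.0]), np.array([10.0, 20.0]))
        with pytest.raises(ValueError):
            rp.temporal_smooth(rp.TAC(fs, np.array([1.0, 2.0])))


class TestVoxelwise:
    def test_phantom_detection(self, basis_set):
        gamma = rp.gamma_for_peak_occupancy(12.0, 0.35, 2.5)
        spec = rp.TacSimSpec(release=rp.ReleaseSpec(REV, REV + 120.0, gamma))
        ref, grid, truth = simulate_voxel_grid(
            (5, 5, 5), (slice(1, 3), slice(1, 3), slice(1, 3)), spec, seed=7
        )
        res = rp.voxelwise_fit(grid, ref, basis_set)
        assert res.mask[truth].mean() > 0.8
        assert res.mask[~truth].mean() <= 0.05
        assert res.roi_fit is not None

    def test_noiseless_null_grid_has_empty_mask(self, basis_set):
        spec = rp.TacSimSpec()
        ref, grid, _ = simulate_voxel_grid((2, 2, 2), None, spec, noise_scale=0.0, seed=0)
        res = rp.voxelwise_fit(grid, ref, basis_set)
        assert res.n_masked == 0
        assert res.roi_fit is None

    def test_two_step_refit_less_variable_than_voxels(self, basis_set, k2_prime):
        gamma = rp.gamma_for_peak_occupancy(12.0, 0.35, 2.5)
        spec = rp.TacSimSpec(release=rp.ReleaseSpec(REV, REV + 120.0, gamma))
        fs = rp.FrameSchedule.default_68min()
        voxel_gammas, roi_gammas = [], []
        for seed in range(6):
            ref, grid, _ = simulate_voxel_grid((4, 1, 1), (slice(0, 4), slice(0, 1), slice(0, 1)), spec, seed=seed)
            singles = [
                rp.lp_ntpet_fit(rp.TAC(fs, grid[i, 0, 0]), ref, basis_set, k2_prime).gamma_per_min
                for i in range(4)
            ]
            roi = rp.lp_ntpet_fit(rp.TAC(fs, grid.reshape(4, -1).mean(axis=0)), ref, basis_set, k2_prime)
            voxel_gammas.extend(singles)
            roi_gammas.append(roi.gamma_per_min)
        assert np.var(roi_gammas) < np.var(voxel_gammas)

    def test_shape_validation(self, clean_pair, basis_set):
        ref, _, _ = clean_pair
        with pytest.raises(ValueError):
            rp.voxelwise_fit(np.zeros((2, 2, 53)), ref, basis_set)
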