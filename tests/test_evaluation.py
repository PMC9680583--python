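"""Image metrics against independent literal transcriptions, gamma analysis
against closed forms and the brute-force oracle, and the paired t-test."""

import numpy as np
import pytest

from sctsynth.containers import DoseGrid, HUVolume
from sctsynth.evaluation import (
    DOSE_THRESHOLDS, GAMMA_CRITERIA, brute_force_gamma_oracle,
    gamma_grid_report, gamma_index_map, gamma_passing_rate, mae,
    metric_report, paired_ttest, psnr, ssim,
)

# ---------------------------------------------------------------------------
# independent literal transcriptions of the three metric formulas,
# kept deliberately naive (explicit loops where practical)
# ---------------------------------------------------------------------------


def _mae_literal(a, b):
    return np.abs(a - b).sum() / a.size


def _psnr_literal(a, b):
    q = max(a.max(), b.max())
    mse = ((a - b) ** 2).sum() / a.size
    return 10.0 * np.log10(q ** 2 / mse)


def _ssim_literal(a, b):
    q = max(a.max(), b.max())
    c1, c2 = (0.01 * q) ** 2, (0.03 * q) ** 2
    mu_a, mu_b = a.mean(), b.mean()
    da, db = a.std(), b.std()
    cov = ((a - mu_a) * (b - mu_b)).mean()
    return ((2 * mu_a * mu_b + c1) * (2 * cov + c2)
            / ((mu_a ** 2 + mu_b ** 2 + c1) * (da ** 2 + db ** 2 + c2)))


def _random_pair(seed, shape=(8, 8, 8)):
    rng = np.random.default_rng(seed)
    a = rng.uniform(-800, 2000, shape)
    return HUVolume(a), HUVolume(np.clip(a + rng.normal(0, 60, shape), -1024, None))


class TestImageMetrics:
    @pytest.mark.parametrize("seed", range(20))
    def test_metrics_match_literal_transcriptions(self, seed):
        ct, sct = _random_pair(seed)
        roi = np.ones(ct.voxels.shape, bool)
        a, b = ct.voxels, sct.voxels
        assert mae(ct, sct, roi) == pytest.approx(_mae_literal(a, b), rel=1e-10)
        assert psnr(ct, sct, roi) == pytest.approx(_psnr_literal(a, b), rel=1e-10)
        assert ssim(ct, sct, roi) == pytest.approx(_ssim_literal(a, b), rel=1e-10)

    def test_identical_volumes(self):
        ct, _ = _random_pair(0)
        roi = np.ones(ct.voxels.shape, bool)
        assert mae(ct, ct, roi) == 0.0
        assert ssim(ct, ct, roi) == pytest.approx(1.0, abs=1e-14)
        assert psnr(ct, ct, roi) == float("inf")

    def test_mae_constant_offset_and_hand_example(self):
        ct = HUVolume(np.zeros((2, 2, 2)))
        sct = HUVolume(np.full((2, 2, 2), 25.0))
        roi = np.ones((2, 2, 2), bool)
        assert mae(ct, sct, roi) == pytest.approx(25.0)
        a = HUVolume(np.array([0.0, 100.0]).reshape(1, 1, 2))
        b = HUVolume(np.array([10.0, 80.0]).reshape(1, 1, 2))
        assert mae(a, b, np.ones((1, 1, 2), bool)) == pytest.approx(15.0)

    def test_mae_scale_equivariance(self):
        ct, sct = _random_pair(3)
        roi = np.ones(ct.voxels.shape, bool)
        k = 2.5
        scaled = mae(HUVolume(k * np.abs(ct.voxels)),
                     HUVolume(k * np.abs(sct.voxels)), roi)
        base = mae(HUVolume(np.abs(ct.voxels)), HUVolume(np.abs(sct.voxels)), roi)
        assert scaled == pytest.approx(k * base, rel=1e-12)

    def test_psnr_closed_form_and_halving(self):
        # Q = 1000, MSE = 100 -> 40 dB exactly
        ct = HUVolume(np.full((4, 4, 4), 1000.0))
        sct = HUVolume(np.full((4, 4, 4), 990.0))
        roi = np.ones((4, 4, 4), bool)
        assert psnr(ct, sct, roi) == pytest.approx(40.0, abs=1e-12)
        # halving the MSE raises PSNR by 10 log10(2)
        sct2 = HUVolume(np.full((4, 4, 4), 1000.0 - 10 / np.sqrt(2)))
        assert psnr(ct, sct2, roi) - psnr(ct, sct, roi) == \
            pytest.approx(10 * np.log10(2), abs=1e-9)

    def test_ssim_symmetric(self):
        ct, sct = _random_pair(5)
        roi = np.ones(ct.voxels.shape, bool)
        assert ssim(ct, sct, roi) == pytest.approx(ssim(sct, ct, roi), abs=1e-12)

    def test_roi_restricts_computation(self):
        ct, sct = _random_pair(6)
        roi = np.zeros(ct.voxels.shape, bool)
        roi[2:5, 2:5, 2:5] = True
        sub_ct = HUVolume(ct.voxels[2:5, 2:5, 2:5])
        sub_sct = HUVolume(sct.voxels[2:5, 2:5, 2:5])
        full = np.ones(sub_ct.voxels.shape, bool)
        assert mae(ct, sct, roi) == pytest.approx(mae(sub_ct, sub_sct, full))
        rep = metric_report(ct, sct, roi)
        assert rep.n_voxels == 27

    def test_empty_roi_rejected(self):
        ct, sct = _random_pair(7)
        with pytest.raises(ValueError, match="ROI"):
            mae(ct, sct, np.zeros(ct.voxels.shape, bool))


def _smooth_dose_pair(seed, n=12, scale=1.0):
    rng = np.random.default_rng(seed)
    z, y, x = np.meshgrid(*[np.linspace(0, 1, n)] * 3, indexing="ij")
    c = rng.uniform(0.4, 0.6, 3)
    ref = 50 * np.exp(-((z - c[0]) ** 2 + (y - c[1]) ** 2 + (x - c[2]) ** 2) / 0.2)
    ev = ref * (1 + scale * 0.01 * rng.uniform(-1, 1)) \
        + scale * 0.3 * np.sin(5 * (z + y))
    return (DoseGrid(ref, prescription=50.0),
            DoseGrid(np.maximum(ev, 0.0), prescription=50.0))


class TestGamma:
    def test_identical_grids_gamma_zero_and_full_pass(self):
        ref, _ = _smooth_dose_pair(0)
        assert np.all(gamma_index_map(ref, ref, 3, 3) == 0.0)
        assert gamma_passing_rate(ref, ref, 3, 3, 10).passing_rate == 100.0

    def test_uniform_offset_closed_forms(self):
        """Uniform field offset by exactly 3% of prescription: the dose term
        saturates at gamma = offset/dd and DTA cannot help."""
        ref = DoseGrid(np.full((8, 8, 8), 30.0), prescription=50.0)
        ev = DoseGrid(np.full((8, 8, 8), 31.5), prescription=50.0)
        np.testing.assert_allclose(gamma_index_map(ref, ev, 3, 3), 1.0)
        np.testing.assert_allclose(gamma_index_map(ref, ev, 2, 2), 1.5)
        # gamma <= 1 passes (boundary inclusion); 1.5 fails everywhere
        assert gamma_passing_rate(ref, ev, 3, 3, 10).passing_rate == 100.0
        assert gamma_passing_rate(ref, ev, 2, 2, 10).passing_rate == 0.0

    @pytest.mark.parametrize("seed", range(4))
    def test_radius_limited_matches_brute_force_oracle(self, seed):
        ref, ev = _smooth_dose_pair(seed)
        gm = gamma_index_map(ref, ev, 2, 2)
        oracle = brute_force_gamma_oracle(ref, ev, 2, 2)
        valid = oracle <= 1.5        # within the radius-cutoff validity zone
        assert valid.any()
        np.testing.assert_allclose(gm[valid], oracle[valid], atol=1e-9)

    def test_oracle_never_exceeds_radius_limited_search(self):
        ref, ev = _smooth_dose_pair(9, scale=3.0)
        gm = gamma_index_map(ref, ev, 2, 2)
        oracle = brute_force_gamma_oracle(ref, ev, 2, 2)
        assert np.all(oracle <= gm + 1e-12)

    def test_oracle_refuses_large_grids(self):
        big = DoseGrid(np.ones((33, 33, 33)))
        with pytest.raises(ValueError, match="32"):
            brute_force_gamma_oracle(big, big, 2, 2)

    @pytest.mark.parametrize("seed", range(10))
    def test_passing_rate_monotone_in_criteria(self, seed):
        ref, ev = _smooth_dose_pair(seed, scale=2.0)
        rates = {}
        for dd in (1.0, 2.0, 3.0):
            for dta in (1.0, 2.0, 3.0):
                rates[(dd, dta)] = gamma_passing_rate(ref, ev, dd, dta,
                                                      10).passing_rate
        for dd in (1.0, 2.0):
            for dta in (1.0, 2.0, 3.0):
                assert rates[(dd, dta)] <= rates[(dd + 1, dta)] + 1e-12
                assert rates[(dta, dd)] <= rates[(dta, dd + 1)] + 1e-12

    def test_gamma_is_directional(self):
        """Reference/evaluated roles are not interchangeable: a narrow hot
        spike in the evaluated grid can rescue every reference voxel via
        DTA, while the reverse direction has no matching dose nearby."""
        ref = DoseGrid(np.full((1, 1, 9), 25.0), prescription=50.0)
        ev_dose = np.full((1, 1, 9), 28.0)     # +6% of prescription everywhere
        ev_dose[0, 0, 4] = 25.0                # except one matching voxel
        ev = DoseGrid(ev_dose, prescription=50.0)
        fwd = gamma_passing_rate(ref, ev, 3, 3, 10,
                                 search_radius_mm=12.0).passing_rate
        rev = gamma_passing_rate(ev, ref, 3, 3, 10,
                                 search_radius_mm=12.0).passing_rate
        assert fwd != rev

    def test_threshold_masking_monotone_in_voxel_count(self):
        ref, ev = _smooth_dose_pair(1)
        counts = [gamma_passing_rate(ref, ev, 3, 3, thr).n_evaluated
                  for thr in DOSE_THRESHOLDS]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_spacing_mismatch_rejected(self):
        a = DoseGrid(np.ones((4, 4, 4)), spacing=(1, 1, 1))
        b = DoseGrid(np.ones((4, 4, 4)), spacing=(2, 1, 1))
        with pytest.raises(ValueError, match="spacing"):
            gamma_index_map(a, b, 3, 3)


class TestGammaGridReport:
    def test_identical_grids_all_entries_100(self):
        ref, _ = _smooth_dose_pair(2)
        report = gamma_grid_report(ref, ref)
        assert len(report) == 10
        assert all(r.passing_rate == 100.0 for r in report)

    def test_layout_matches_criteria_by_thresholds(self):
        ref, ev = _smooth_dose_pair(3)
        report = gamma_grid_report(ref, ev)
        layout = [(r.dd_percent, r.dta_mm, r.threshold_percent) for r in report]
        expected = [(dd, dta, thr) for dd, dta in GAMMA_CRITERIA
                    for thr in DOSE_THRESHOLDS]
        assert layout == expected

    def test_entries_match_individual_calls(self):
        ref, ev = _smooth_dose_pair(4)
        for entry in gamma_grid_report(ref, ev):
            single = gamma_passing_rate(ref, ev, entry.dd_percent,
                                        entry.dta_mm, entry.threshold_percent)
            assert entry.passing_rate == pytest.approx(single.passing_rate)


class TestPairedTTest:
    def test_textbook_hand_computation(self):
        t, p = paired_ttest([1, 2, 3, 4], [2, 2, 2, 2])
        assert t == pytest.approx(0.7745966692, rel=1e-9)
        assert 0 < p < 1

    def test_identical_sequences_degenerate(self):
        with pytest.raises(ValueError, match="degenerate|variance"):
            paired_ttest([1, 2, 3], [1, 2, 3])

    def test_constant_nonzero_difference_degenerate(self):
        with pytest.raises(ValueError, match="degenerate|variance"):
            paired_ttest([2, 3, 4, 5], [1, 2, 3, 4])

    def test_matches_scipy_on_random_data(self):
        from scipy import stats
        rng = np.random.default_rng(0)
        a = rng.normal(size=12)
        b = a + rng.normal(0.3, 0.5, size=12)
        t, p = paired_ttest(a, b)
        t2, p2 = stats.ttest_rel(a, b)
        assert (t, p) == (pytest.approx(t2), pytest.approx(p2))
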