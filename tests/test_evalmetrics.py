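"""Image-quality metrics, agreement statistics, segmental summed score."""

import math

import numpy as np
import pytest
from scipy import stats

import spectdenoise as sd
from spectdenoise.evalmetrics import segment_labels, segment_scores


class TestRmse:
    def test_identity_is_zero(self):
        x = np.arange(12.0).reshape(3, 4)
        assert sd.rmse(x, x) == 0.0

    def test_hand_example(self):
        assert sd.rmse(np.array([1, 2, 3, 4]), np.array([1, 2, 3, 8])) == pytest.approx(2.0, abs=1e-12)

    def test_homogeneity(self):
        a = np.array([1.0, 5.0, 2.0])
        b = np.array([0.0, 4.0, 7.0])
        assert sd.rmse(3 * a, 3 * b) == pytest.approx(3 * sd.rmse(a, b))

    def test_shape_mismatch(self):
        with pytest.raises(ValueError, match="shape"):
            sd.rmse(np.zeros(3), np.zeros(4))


class TestPsnr:
    def test_identical_inputs_infinite(self):
        x = np.ones((4, 4)) * 7
        assert math.isinf(sd.psnr(x, x))

    def test_hand_example_default_variant(self):
        ref = np.array([10.0, 10, 10, 10])
        test = np.array([8.0, 12, 8, 12])
        # peak = max(test) = 12, RMSE = 2 -> 20 log10(6)
        assert sd.psnr(ref, test) == pytest.approx(20 * np.log10(6), abs=1e-9)
        assert sd.psnr(ref, test) == pytest.approx(15.563, abs=5e-4)

    def test_as_printed_variant_divides_by_mse(self):
        ref = np.array([10.0, 10, 10, 10])
        test = np.array([8.0, 12, 8, 12])
        assert sd.psnr(ref, test, formula_variant="peak_over_mse") == pytest.approx(
            20 * np.log10(12 / 4), abs=1e-12)

    def test_scale_invariance_of_default_variant(self):
        rng = np.random.default_rng(0)
        ref, test = rng.random(50), rng.random(50)
        assert sd.psnr(2 * ref, 2 * test) == pytest.approx(sd.psnr(ref, test), abs=1e-9)

    def test_peak_conventions(self):
        ref = np.array([0.0, 100.0])
        test = np.array([0.0, 50.0])
        assert sd.psnr(ref, test, "ref_max") > sd.psnr(ref, test, "test_max")


class TestSsimGlobal:
    def test_identity_is_one(self):
        x = np.random.default_rng(0).random((8, 8))
        assert sd.ssim_global(x, x) == pytest.approx(1.0, abs=1e-12)

    def test_constant_zero_pair_stabilized(self):
        z = np.zeros(10)
        assert sd.ssim_global(z, z) == pytest.approx(1.0, abs=1e-12)

    def test_hand_example_anticorrelated(self):
        # mu both 0.5, variances 0.25, covariance -0.25
        val = sd.ssim_global(np.array([0.0, 1.0]), np.array([1.0, 0.0]))
        expect = (2 * 0.25 + 0.01) * (2 * -0.25 + 0.02) / ((0.5 + 0.01) * (0.5 + 0.02))
        assert val == pytest.approx(expect, abs=1e-12)


class TestPearson:
    def test_affine_relations(self):
        x = np.array([1.0, 2, 3, 4, 5])
        assert sd.pearson(x, 2 * x + 1) == pytest.approx(1.0)
        assert sd.pearson(x, -x) == pytest.approx(-1.0)

    def test_hand_example_against_direct_sum(self):
        x = np.array([1.0, 2, 3, 4, 5])
        y = np.array([2.0, 1, 4, 3, 5])
        # direct product-moment evaluation: cov 8, var_x 10, var_y 10
        assert sd.pearson(x, y) == pytest.approx(0.8, abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            sd.pearson(np.ones(5), np.arange(5.0))


class TestBlandAltman:
    def test_identical_vectors(self):
        x = np.array([1.0, 2.0, 3.0])
        rep = sd.bland_altman(x, x)
        assert rep.bias == 0 and rep.loa_low == 0 and rep.loa_high == 0

    def test_constant_shift(self):
        x = np.array([1.0, 2.0, 3.0])
        rep = sd.bland_altman(x, x + 3)
        assert rep.bias == pytest.approx(3.0)
        assert rep.loa_low == rep.loa_high == pytest.approx(3.0)

    def test_hand_example_limits(self):
        ref = np.zeros(4)
        test = np.array([1.0, -1.0, 2.0, -2.0])
        rep = sd.bland_altman(ref, test)
        sd_diff = math.sqrt(10 / 3)
        assert rep.bias == pytest.approx(0.0)
        assert rep.loa_high == pytest.approx(1.96 * sd_diff, abs=1e-12)
        assert rep.loa_low == pytest.approx(-1.96 * sd_diff, abs=1e-12)

    def test_paired_t_matches_scipy(self):
        rng = np.random.default_rng(1)
        a = rng.normal(10, 2, 30)
        b = a + rng.normal(0.5, 1, 30)
        rep = sd.bland_altman(a, b)
        t = stats.ttest_rel(b, a)
        assert rep.t_stat == pytest.approx(t.statistic)
        assert rep.p_value == pytest.approx(t.pvalue)

    def test_limits_cover_95pct_of_gaussian_differences(self):
        rng = np.random.default_rng(2)
        ref = rng.normal(0, 1, 10_000)
        test = ref + rng.normal(0.3, 0.7, 10_000)
        rep = sd.bland_altman(ref, test)
        diffs = test - ref
        inside = np.mean((diffs >= rep.loa_low) & (diffs <= rep.loa_high))
        assert inside == pytest.approx(0.95, abs=0.01)


class TestPercentChange:
    def test_no_change_is_zero(self):
        assert sd.percent_change(5.0, 5.0) == 0.0

    def test_zero_baseline_rejected(self):
        with pytest.raises(ValueError):
            sd.percent_change(0.0, 1.0)

    @pytest.mark.parametrize("baseline,new,direction,expected", [
        (33.22, 37.34, "increase", 12.4),
        (5.69, 3.50, "decrease", 38.5),
    ])
    def test_reported_dose_examples(self, baseline, new, direction, expected):
        assert round(sd.percent_change(baseline, new, direction), 1) == expected


class TestSegmentScores:
    @staticmethod
    def _ring_volume(defect_sector=None):
        """32^3 SA stack with a radius-6..11 ring on slices 4..28.

        ``defect_sector``: optional (theta_lo, theta_hi, z_lo, z_hi) zeroed out.
        """
        n = 32
        vol = np.zeros((n, n, n))
        c = (n - 1) / 2.0
        xs, ys = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
        r = np.hypot(xs - c, ys - c)
        ring = (r >= 6) & (r <= 11)
        for z in range(4, 28):
            vol[:, :, z][ring] = 1.0
        if defect_sector is not None:
            tlo, thi, zlo, zhi = defect_sector
            theta = np.degrees(np.arctan2(ys - c, xs - c)) % 360.0
            cut = ring & (theta >= tlo) & (theta < thi)
            for z in range(zlo, zhi):
                vol[:, :, z][cut] = 0.0
        return vol

    def test_uniform_ring_scores_zero(self):
        scores = segment_scores(self._ring_volume(), (4, 28))
        assert scores.summed_score == 0
        assert np.all(scores.segment_score == 0)
        assert len(scores.segment_score) == 17

    def test_single_segment_full_defect(self):
        # mid-third slices are 12..20; sector 60-120 deg is mid segment 8
        vol = self._ring_volume(defect_sector=(60.0, 120.0, 12, 20))
        scores = segment_scores(vol, (4, 28))
        assert scores.segment_score[7] == 4
        others = np.delete(scores.segment_score, 7)
        assert np.all(others == 0)
        assert scores.summed_score == 4

    def test_score_monotone_in_uptake(self):
        from spectdenoise.evalmetrics import _uptake_to_score
        fracs = np.linspace(0, 1, 101)
        scores = [_uptake_to_score(f) for f in fracs]
        assert all(a >= b for a, b in zip(scores, scores[1:]))
        assert scores[0] == 4 and scores[-1] == 0

    def test_labels_partition_the_range(self):
        labels = segment_labels((32, 32, 32), (4, 28))
        assert set(np.unique(labels[:, :, 4:28])) == set(range(1, 18))
        assert np.all(labels[:, :, :4] == 0) and np.all(labels[:, :, 28:] == 0)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="mask"):
            segment_scores(np.zeros((16, 16, 16)), (2, 14),
                           myocardial_mask=np.zeros((16, 16, 16), dtype=bool))
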