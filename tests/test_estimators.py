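import math
from types import SimpleNamespace

import numpy as np
import pytest

from twosample_mr.estimators import (
    InsufficientInstrumentsError,
    cochrans_q,
    ivw,
    leave_one_out,
    leave_one_out_sweep,
    mr_egger,
    per_doubling,
    wald_ratio,
    weighted_median,
)
from twosample_mr.synthetic import SyntheticConfig, generate_pair
from twosample_mr.harmonize import harmonize_pair
from twosample_mr.sumstats import select_instruments

from conftest import hset_from_arrays


class TestWaldRatio:
    def test_unit_exposure(self):
        v = SimpleNamespace(rsid="rs1", beta_exp=1.0, beta_out=0.5, se_out=0.1)
        est = wald_ratio(v)
        assert est.beta == pytest.approx(0.5)
        assert est.se == pytest.approx(0.1)

    def test_negative_exposure_scales_and_signs(self):
        v = SimpleNamespace(rsid="rs1", beta_exp=-0.5, beta_out=0.25, se_out=0.05)
        est = wald_ratio(v)
        assert est.beta == pytest.approx(-0.5)
        assert est.se == pytest.approx(0.1)

    def test_zero_exposure_raises(self):
        v = SimpleNamespace(rsid="rs1", beta_exp=0.0, beta_out=0.1, se_out=0.1)
        with pytest.raises(ZeroDivisionError):
            wald_ratio(v)


class TestIVW:
    def test_equal_weight_mean(self):
        s = hset_from_arrays([1.0, 1.0], [0.01, 0.01], [0.2, 0.4], [0.1, 0.1])
        assert ivw(s).beta == pytest.approx(0.3)

    def test_single_variant_delegates_to_wald(self):
        s = hset_from_arrays([0.5], [0.01], [0.1], [0.05])
        est = ivw(s)
        assert est.beta == pytest.approx(0.2)
        assert est.n_snps == 1

    @pytest.mark.parametrize("seed", range(100))
    def test_weighted_mean_equals_regression_formulation(self, seed, random_hset):
        """The ratio-scale weighted mean agrees with the independent
        zero-intercept WLS of outcome on exposure betas to 1e-10."""
        import statsmodels.api as sm

        s = random_hset(n_snps=10, theta=0.3, seed=seed, pleio_sd=0.01)
        bx = np.array([v.beta_exp for v in s.variants])
        by = np.array([v.beta_out for v in s.variants])
        sy = np.array([v.se_out for v in s.variants])
        wls = sm.WLS(by, bx, weights=1.0 / sy**2).fit()
        assert ivw(s).beta == pytest.approx(float(wls.params[0]), abs=1e-10)

    def test_fixed_vs_random_se(self, random_hset):
        s = random_hset(n_snps=30, theta=0.2, seed=5, pleio_sd=0.05)
        fixed = ivw(s, model="fixed")
        rand = ivw(s, model="multiplicative_random")
        assert rand.beta == pytest.approx(fixed.beta)
        assert rand.se > fixed.se  # heterogeneous set inflates the SE
        # residual scaling is not floored: an underdispersed set shrinks it
        s2 = hset_from_arrays([1.0, 1.0, 1.0], [0.01] * 3,
                              [0.2000, 0.2001, 0.1999], [0.1] * 3)
        assert ivw(s2).se < ivw(s2, model="fixed").se


class TestMREgger:
    def test_exact_linear_data_recovers_slope_and_zero_intercept(self):
        bx = np.array([0.1, 0.2, 0.3, 0.4])
        s = hset_from_arrays(bx, [0.01] * 4, 0.7 * bx, [0.05] * 4)
        est = mr_egger(s)
        assert est.beta == pytest.approx(0.7, abs=1e-12)
        assert est.intercept == pytest.approx(0.0, abs=1e-12)

    def test_exact_affine_data_recovers_intercept(self):
        bx = np.array([0.1, 0.2, 0.3, 0.4, 0.5])
        s = hset_from_arrays(bx, [0.01] * 5, 0.01 + 0.5 * bx, [0.05] * 5)
        est = mr_egger(s)
        assert est.intercept == pytest.approx(0.01, abs=1e-12)
        assert est.beta == pytest.approx(0.5, abs=1e-12)

    def test_requires_three_variants(self):
        s = hset_from_arrays([0.1, 0.2], [0.01] * 2, [0.1, 0.2], [0.05] * 2)
        with pytest.raises(InsufficientInstrumentsError):
            mr_egger(s)

    def test_recovers_planted_directional_pleiotropy(self):
        """Mean Egger intercept over 200 synthetic replicates is within 2 SE
        of the planted per-SNP pleiotropic offset of 0.01."""
        intercepts = []
        for seed in range(200):
            exp, out, _ = generate_pair(
                SyntheticConfig(n_snps=30, theta=-0.1, seed=seed,
                                pleiotropy_mode="directional",
                                pleiotropy_magnitude=0.01)
            )
            h = harmonize_pair(select_instruments(exp), out)
            intercepts.append(mr_egger(h).intercept)
        mean = float(np.mean(intercepts))
        se_mean = float(np.std(intercepts, ddof=1) / math.sqrt(len(intercepts)))
        assert abs(mean - 0.01) < 2 * se_mean + 1e-4


class TestWeightedMedian:
    def test_equal_weight_middle_ratio(self):
        s = hset_from_arrays([1.0] * 3, [0.01] * 3, [0.1, 0.2, 0.9], [0.1] * 3)
        est = weighted_median(s, n_boot=50, seed=1)
        assert est.beta == pytest.approx(0.2)

    def test_equals_plain_median_for_equal_weights_odd_n(self):
        rng = np.random.default_rng(3)
        ratios = rng.normal(0.3, 0.2, 7)
        s = hset_from_arrays([1.0] * 7, [0.01] * 7, ratios, [0.1] * 7)
        est = weighted_median(s, n_boot=50, seed=1)
        assert est.beta == pytest.approx(float(np.median(ratios)))

    @pytest.mark.parametrize("seed", range(0, 500, 10))
    def test_estimate_within_ratio_range(self, seed, random_hset):
        s = random_hset(n_snps=9, theta=0.4, seed=seed, pleio_sd=0.05)
        ratios = [v.beta_out / v.beta_exp for v in s.variants]
        est = weighted_median(s, n_boot=10, seed=0)
        assert min(ratios) - 1e-12 <= est.beta <= max(ratios) + 1e-12

    def test_robust_to_30pct_pleiotropic_snps(self):
        """With 30% of SNPs carrying a large offset, the weighted median stays
        near the true effect while IVW is pulled away."""
        theta = 0.2
        rng = np.random.default_rng(11)
        n = 30
        bx = rng.uniform(0.1, 0.4, n)
        sy = np.full(n, 0.02)
        by = theta * bx + rng.normal(0, sy)
        by[:9] += 0.3  # 30% invalid instruments
        s = hset_from_arrays(bx, [0.01] * n, by, sy)
        wm = weighted_median(s, n_boot=200, seed=4)
        est_ivw = ivw(s)
        assert abs(wm.beta - theta) < 2 * wm.se
        assert abs(est_ivw.beta - theta) > 2 * est_ivw.se


class TestHeterogeneity:
    def test_identical_ratios_give_zero_q(self):
        bx = np.array([0.1, 0.2, 0.4])
        s = hset_from_arrays(bx, [0.01] * 3, 0.5 * bx, [0.05] * 3)
        h = cochrans_q(s, 0.5)
        assert h.Q == pytest.approx(0.0, abs=1e-20)
        assert h.I2 == 0.0

    def test_hand_computed_three_snp_case(self):
        # ratios 0, 1, 2 with unit weights about reference 1 -> Q = 2
        s = hset_from_arrays([1.0] * 3, [0.01] * 3, [0.0, 1.0, 2.0], [1.0] * 3)
        h = cochrans_q(s, 1.0)
        assert h.Q == pytest.approx(2.0)
        assert h.df == 2
        assert h.I2 == pytest.approx(0.0)  # Q == df


class TestLeaveOneOut:
    def test_removing_on_estimate_variant_leaves_beta_unchanged(self):
        # build a set where rs_extra's ratio equals the IVW estimate of the rest
        s = hset_from_arrays([1.0, 1.0], [0.01] * 2, [0.2, 0.4], [0.1] * 2)
        full = hset_from_arrays([1.0, 1.0, 1.0], [0.01] * 3,
                                [0.2, 0.4, 0.3], [0.1] * 3)
        assert leave_one_out(full, "rs2").beta == pytest.approx(ivw(s).beta)
        assert leave_one_out(full, "rs2").beta == pytest.approx(ivw(full).beta)

    def test_sweep_matches_direct_recomputation(self, random_hset):
        s = random_hset(n_snps=12, theta=0.25, seed=8, pleio_sd=0.02)
        sweep = leave_one_out_sweep(s)
        assert len(sweep) == 12
        for rsid, est in sweep.items():
            direct = ivw(s.without(rsid))
            assert est.beta == pytest.approx(direct.beta)
            assert est.se == pytest.approx(direct.se)

    def test_absent_rsid_raises(self, random_hset):
        with pytest.raises(KeyError):
            leave_one_out(random_hset(), "rs_nope")


class TestPerDoubling:
    def test_definitional_values(self):
        s = hset_from_arrays([1.0, 1.0], [0.01] * 2, [1.0, 1.0], [0.1] * 2,
                             exposure_type="binary")
        est = per_doubling(ivw(s))
        assert est.beta == pytest.approx(math.log(2), abs=1e-9)
        assert est.or_scale[0] == pytest.approx(2.0, abs=1e-6)

    def test_zero_beta_stays_zero_and_p_unchanged(self):
        s = hset_from_arrays([1.0, 1.0], [0.01] * 2, [0.05, -0.05], [0.1] * 2,
                             exposure_type="binary")
        base = ivw(s)
        scaled = per_doubling(base)
        assert scaled.beta == pytest.approx(0.0)
        assert scaled.pvalue == base.pvalue

    @pytest.mark.parametrize("beta", [-0.5, -0.1, 0.3, 1.2])
    def test_scale_then_exp_equals_exp_then_power(self, beta):
        s = hset_from_arrays([1.0, 1.0], [0.01] * 2, [beta, beta], [0.1] * 2,
                             exposure_type="binary")
        est = ivw(s)
        scaled = per_doubling(est)
        assert scaled.or_scale[0] == pytest.approx(est.or_scale[0] ** math.log(2))

    def test_continuous_exposure_rejected(self):
        s = hset_from_arrays([1.0, 1.0], [0.01] * 2, [0.1, 0.2], [0.1] * 2)
        with pytest.raises(ValueError, match="binary"):
            per_doubling(ivw(s))
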