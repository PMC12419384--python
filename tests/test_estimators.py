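import numpy as np
import pytest
import statsmodels.api as sm

from lipidmr import estimators as est
from lipidmr.estimators import Z95

from conftest import make_instruments, random_instruments


class TestWaldRatio:
    def test_direct_formula(self):
        r = est.wald_ratio(0.1, 0.05, 0.01)
        assert r.beta == pytest.approx(0.5)
        assert r.se == pytest.approx(0.1)
        assert r.ci_low == pytest.approx(0.5 - Z95 * 0.1)

    def test_null_outcome_effect(self):
        r = est.wald_ratio(0.1, 0.0, 0.01)
        assert r.beta == 0.0
        assert r.pvalue == pytest.approx(1.0)

    def test_second_order_se_dominates_first_order(self, rng):
        for _ in range(20):
            be, bo = rng.uniform(0.02, 0.3), rng.normal(0, 0.1)
            se_e, se_o = rng.uniform(0.001, 0.05, 2)
            first = est.wald_ratio(be, bo, se_o)
            second = est.wald_ratio(be, bo, se_o, se_exp=se_e, second_order=True)
            assert second.se >= first.se

    def test_zero_exposure_effect_rejected(self):
        with pytest.raises(est.EstimationError):
            est.wald_ratio(0.0, 0.1, 0.01)


def _wls_origin_oracle(insts):
    """IVW as weighted regression of beta_out on beta_exp through the origin."""
    w = 1.0 / insts["se_out"] ** 2
    fit = sm.WLS(insts["beta_out"], insts[["beta_exp"]], weights=w).fit()
    se_fixed = float(np.sqrt(fit.normalized_cov_params.iloc[0, 0]))
    return float(fit.params.iloc[0]), se_fixed


def _wls_egger_oracle(insts):
    flip = np.sign(insts["beta_exp"].to_numpy())
    x = insts["beta_exp"].to_numpy() * flip
    y = insts["beta_out"].to_numpy() * flip
    w = 1.0 / insts["se_out"].to_numpy() ** 2
    fit = sm.WLS(y, sm.add_constant(x), weights=w).fit()
    unit_se = np.sqrt(np.diag(fit.normalized_cov_params))
    phi = max(1.0, np.sqrt(fit.scale))  # scale = weighted RSS / (n - 2)
    return np.asarray(fit.params), unit_se * phi


class TestIVW:
    def test_single_snp_reduces_to_wald(self):
        insts = make_instruments([0.1], [0.05], [0.01])
        r = est.ivw(insts)
        w = est.wald_ratio(0.1, 0.05, 0.01)
        assert r.method == "ivw_fixed"
        assert (r.beta, r.se) == (w.beta, w.se)

    def test_homogeneous_ratios_give_zero_q(self):
        insts = make_instruments([0.1, 0.2, 0.05], [0.05, 0.10, 0.025], [0.01])
        r = est.ivw(insts)
        assert r.beta == pytest.approx(0.5)
        assert r.q_stat == pytest.approx(0.0, abs=1e-20)
        assert r.q_pvalue == pytest.approx(1.0)

    def test_matches_weighted_regression_oracle(self, rng):
        for _ in range(100):
            insts = random_instruments(rng, n=int(rng.integers(2, 12)))
            r = est.ivw(insts)
            beta, se = _wls_origin_oracle(insts)
            assert r.beta == pytest.approx(beta, abs=1e-10)
            assert r.se == pytest.approx(se, abs=1e-10)

    def test_random_effects_se_never_below_fixed(self, rng):
        for _ in range(20):
            insts = random_instruments(rng, n=6)
            fixed = est.ivw(insts, random_effects=False)
            random_ = est.ivw(insts, random_effects=True)
            assert random_.se >= fixed.se
            assert random_.beta == fixed.beta

    def test_empty_set_rejected(self):
        with pytest.raises(est.EstimationError):
            est.ivw(make_instruments([], [], []))


class TestCochranQ:
    def test_hand_computed_two_instrument_case(self):
        # equal unit weights (beta_exp 1, se_out 1), ratios 0 and 1
        insts = make_instruments([1.0, 1.0], [0.0, 1.0], [1.0])
        r = est.ivw(insts)
        assert r.beta == pytest.approx(0.5)
        q, q_p = est.cochran_q(insts, r.beta)
        assert q == pytest.approx(0.5)

    def test_single_instrument_is_not_applicable(self):
        q, p = est.cochran_q(make_instruments([0.1], [0.05], [0.01]), 0.5)
        assert np.isnan(q) and np.isnan(p)


class TestEgger:
    def test_exact_proportional_fit(self):
        be = np.array([0.05, 0.1, 0.15, 0.2])
        insts = make_instruments(be, 0.3 * be, [0.01])
        slope, intercept = est.egger(insts)
        assert slope.beta == pytest.approx(0.3, abs=1e-12)
        assert intercept.beta == pytest.approx(0.0, abs=1e-12)

    def test_exact_affine_fit_recovers_pleiotropy_intercept(self):
        be = np.array([0.05, 0.1, 0.15, 0.2])
        insts = make_instruments(be, 0.02 + 0.3 * be, [0.01])
        slope, intercept = est.egger(insts)
        assert slope.beta == pytest.approx(0.3, abs=1e-12)
        assert intercept.beta == pytest.approx(0.02, abs=1e-12)

    def test_matches_weighted_normal_equations_oracle(self, rng):
        for _ in range(100):
            insts = random_instruments(rng, n=int(rng.integers(3, 12)))
            slope, intercept = est.egger(insts)
            params, ses = _wls_egger_oracle(insts)
            assert intercept.beta == pytest.approx(params[0], abs=1e-10)
            assert slope.beta == pytest.approx(params[1], abs=1e-10)
            assert intercept.se == pytest.approx(ses[0], abs=1e-10)
            assert slope.se == pytest.approx(ses[1], abs=1e-10)

    def test_orientation_invariance(self, rng):
        """Recoding any SNP's effect allele (negating both betas) leaves the
        Egger fit unchanged, thanks to the beta_exp >= 0 pre-orientation."""
        insts = random_instruments(rng, n=8)
        slope1, int1 = est.egger(insts)
        flipped = insts.copy()
        flipped.loc[0:3, ["beta_exp", "beta_out"]] *= -1
        slope2, int2 = est.egger(flipped)
        assert slope1.beta == pytest.approx(slope2.beta, abs=1e-12)
        assert int1.beta == pytest.approx(int2.beta, abs=1e-12)

    def test_too_few_instruments_not_applicable(self):
        assert est.egger(make_instruments([0.1, 0.2], [0.03, 0.06], [0.01])) is None


class TestWeightedMedian:
    def test_plain_median_with_equal_weights(self):
        insts = make_instruments([0.1, 0.1, 0.1], [0.01, 0.05, 0.09], [0.01])
        r = est.weighted_median(insts, n_boot=100, seed=1)
        assert r.beta == pytest.approx(0.5)

    def test_concentrated_weight_approaches_that_ratio(self):
        # middle SNP carries ~10000x the weight of the others
        insts = make_instruments([0.01, 1.0, 0.01], [0.002, 0.7, 0.009], [0.01])
        r = est.weighted_median(insts, n_boot=100, seed=1)
        assert r.beta == pytest.approx(0.7, abs=0.01)

    def test_robust_to_minority_invalid_instruments(self, rng):
        # 3 valid SNPs at ratio 0.3, 2 outliers far away
        be = np.array([0.1, 0.12, 0.14, 0.1, 0.12])
        bo = 0.3 * be
        bo[3:] += 0.1
        insts = make_instruments(be, bo, [0.005])
        r = est.weighted_median(insts, n_boot=500, seed=2)
        assert abs(r.beta - 0.3) < 2 * r.se


class TestWeightedMode:
    def test_identical_ratios(self):
        be = np.array([0.1, 0.2, 0.3])
        insts = make_instruments(be, 0.5 * be, [0.01])
        r = est.weighted_mode(insts, n_boot=100, seed=1)
        assert r.beta == pytest.approx(0.5, abs=1e-12)

    def test_bimodal_majority_mode_wins(self):
        be = np.full(6, 0.1)
        bo = np.array([0.05, 0.05, 0.05, 0.05, 0.2, 0.2])  # ratios 0.5 x4, 2.0 x2
        insts = make_instruments(be, bo, [0.01])
        r = est.weighted_mode(insts, n_boot=100, seed=1)
        assert r.beta == pytest.approx(0.5, abs=0.05)

    def test_grid_refinement_converges(self, rng):
        from lipidmr.estimators import _weighted_mode_point

        insts = random_instruments(rng, n=10)
        ratio = (insts["beta_out"] / insts["beta_exp"]).to_numpy()
        w = (insts["beta_exp"] ** 2 / insts["se_out"] ** 2).to_numpy()
        wn = w / w.sum()
        center = est._weighted_median_point(ratio, wn)
        h = 1.4826 * est._weighted_median_point(np.abs(ratio - center), wn)
        coarse = _weighted_mode_point(ratio, w, 1.0, n_grid=512)
        fine = _weighted_mode_point(ratio, w, 1.0, n_grid=1024)
        assert abs(coarse - fine) < h / 50


class TestMrPresso:
    def test_no_flags_means_corrected_equals_ivw(self, rng):
        insts = random_instruments(rng, n=8)
        out = est.mr_presso(insts, n_sim=500, seed=3)
        assert out is not None
        report, corrected = out
        if not report.outliers_flagged:
            full = est.ivw(insts)
            assert corrected.beta == full.beta
            assert corrected.se == full.se

    def test_global_p_bounded_below_by_rank(self, rng):
        insts = random_instruments(rng, n=6)
        report, _ = est.mr_presso(insts, n_sim=200, seed=4)
        assert report.global_p >= 1 / 201
        assert set(report.per_snp_outlier_p) == set(insts["snp"])
        assert report.outliers_flagged <= set(insts["snp"])

    def test_null_global_test_calibrated(self):
        from lipidmr.simulate import SyntheticTruth, simulate_two_sample
        from lipidmr.summary_stats import harmonize, retained

        n_pass = 0
        for seed in range(100):
            ds = simulate_two_sample(SyntheticTruth(theta=0.3, seed=50_000 + seed))
            insts = retained(harmonize(ds.exposure, ds.outcome))
            report, _ = est.mr_presso(insts, n_sim=1000, seed=seed)
            n_pass += report.global_p > 0.05
        assert n_pass >= 95

    def test_too_few_instruments_not_applicable(self):
        assert est.mr_presso(make_instruments([0.1] * 3, [0.03] * 3, [0.01])) is None


class TestLeaveOneOut:
    def test_two_instruments_give_single_snp_walds(self):
        insts = make_instruments([0.1, 0.2], [0.05, 0.08], [0.01])
        table, _ = est.leave_one_out(insts)
        assert len(table) == 2
        assert table["n_snp"].tolist() == [1, 1]
        # dropping rs001 leaves rs002's Wald ratio
        assert table.loc[table.snp_dropped == "rs001", "beta"].item() == pytest.approx(0.4)

    def test_homogeneous_strong_effect_keeps_sign_everywhere(self, rng):
        be = rng.uniform(0.08, 0.2, 6)
        insts = make_instruments(be, 0.5 * be + rng.normal(0, 0.002, 6), [0.002])
        table, same_side = est.leave_one_out(insts)
        assert same_side
        assert (table["beta"] > 0).all()

    def test_outlier_removal_moves_estimate_most(self):
        be = np.full(6, 0.1)
        bo = 0.3 * be
        bo[0] += 0.05  # planted outlier
        insts = make_instruments(be, bo, [0.01])
        table, _ = est.leave_one_out(insts)
        full = est.ivw(insts).beta
        shifts = (table["beta"] - full).abs()
        assert shifts.idxmax() == table.index[table.snp_dropped == "rs001"][0]


class TestPvalueFromEstimate:
    @pytest.mark.parametrize("beta,lo,hi,bound", [
        (-0.087, -0.136, -0.038, 1e-3),  # below the published bound
        (-0.319, -0.408, -0.231, 1e-3),
    ])
    def test_published_rows_fall_below_their_bound(self, beta, lo, hi, bound):
        assert est.pvalue_from_estimate(beta, lo, hi) < bound

    def test_statin_row_value(self):
        assert est.pvalue_from_estimate(-0.087, -0.136, -0.038) == pytest.approx(
            5.0e-4, rel=0.01
        )

    def test_centered_null(self):
        assert est.pvalue_from_estimate(0.0, -0.1, 0.1) == pytest.approx(1.0)

    def test_degenerate_interval_rejected(self):
        with pytest.raises(est.EstimationError):
            est.pvalue_from_estimate(0.1, 0.2, 0.2)


class TestScaleEquivariance:
    @pytest.mark.parametrize("c", [2.0, 0.5, -1.5])
    def test_outcome_scaling_scales_estimates(self, rng, c):
        insts = random_instruments(rng, n=8)
        scaled = insts.copy()
        scaled["beta_out"] *= c
        scaled["se_out"] *= abs(c)
        for fn, check_se in (
            (lambda d: est.ivw(d), True),
            (lambda d: est.egger(d)[0], True),
            # bootstrap SEs are equivariant only in distribution, not draw by
            # draw, so only the point estimate is compared for the median
            (lambda d: est.weighted_median(d, n_boot=50, seed=9), False),
        ):
            base, after = fn(insts), fn(scaled)
            assert after.beta == pytest.approx(c * base.beta, rel=1e-9)
            if check_se:
                assert after.se == pytest.approx(abs(c) * base.se, rel=1e-9)

    def test_exposure_scaling_divides_estimates(self, rng):
        insts = random_instruments(rng, n=8)
        c = 2.0
        scaled = insts.copy()
        scaled["beta_exp"] *= c
        scaled["se_exp"] *= c
        assert est.ivw(scaled).beta == pytest.approx(est.ivw(insts).beta / c, rel=1e-9)
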