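"""MR estimators: closed forms, oracle agreement, robustness simulations,
scale/sign equivariance."""

import numpy as np
import pytest
from scipy import stats

from coagmr.estimators import (
    CMConfig,
    EstimatorError,
    MREstimate,
    PressoConfig,
    RatioEstimate,
    SingleInstrumentError,
    contamination_mixture,
    egger,
    ivw_mre,
    mr_presso,
    ratio_estimates,
    wald_ratio,
    weighted_median,
)
from coagmr.simulate import SimulationConfig, simulate_mr_study
from coagmr.sumstats import HarmonizedPair


def _pair(vid, bx, sx, by, sy):
    return HarmonizedPair(vid, bx, sx, by, sy)


def _forward_pairs(seed, theta=-0.5, n_valid=50, n_pleio=0, pleio_sd=0.0, mu_alpha=0.0,
                   n_snps=None, beta_range=(0.08, 0.15)):
    cfg = SimulationConfig(
        theta=theta, n_valid=n_valid, n_pleiotropic=n_pleio, pleiotropy_sd=pleio_sd,
        mu_alpha=mu_alpha, n_snps=n_snps or max(2 * (n_valid + n_pleio), 60),
        ld_rho=0.0, seed=seed, instrument_beta_range=beta_range,
    )
    return simulate_mr_study(cfg).instrument_pairs()


class TestWaldRatio:
    def test_closed_form(self):
        est = wald_ratio(_pair("rs1", 0.5, 0.05, -0.2, 0.1))
        assert est.theta == pytest.approx(-0.4)
        assert est.se == pytest.approx(0.2)

    def test_null_outcome(self):
        est = wald_ratio(_pair("rs1", 0.5, 0.05, 0.0, 0.1))
        assert est.theta == 0.0 and est.pval == pytest.approx(1.0)

    def test_inhibition_framing(self):
        est = wald_ratio(_pair("rs1", 0.5, 0.05, -0.2, 0.1))
        assert est.or_per_sd_lower == pytest.approx(np.exp(0.4), rel=1e-12)
        assert est.or_per_sd_higher == pytest.approx(np.exp(-0.4), rel=1e-12)

    def test_degenerate_instrument(self):
        with pytest.raises(EstimatorError):
            wald_ratio(_pair("rs1", 0.0, 0.05, 0.1, 0.1))


class TestIVW:
    def test_two_ratio_worked_example(self):
        # weighted-least-squares oracle numbers
        est = ivw_mre([RatioEstimate("a", 0.4, 0.2), RatioEstimate("b", 0.6, 0.3)])
        assert est.theta == pytest.approx(0.46153846, rel=1e-6)
        assert est.q_stat == pytest.approx(0.30769, rel=1e-4)
        assert est.se == pytest.approx(0.16641, rel=1e-4)  # underdispersion floor active

    def test_single_ratio_signals_wald(self):
        with pytest.raises(SingleInstrumentError):
            ivw_mre([RatioEstimate("a", 0.4, 0.2)])

    def test_overdispersion_inflates_se(self):
        # construct ratios with known dispersion phi = 4: Q = phi * (n-1)
        theta_j = np.array([0.0, 2.0, 0.0, 2.0, 0.0, 2.0])
        se_j = np.full(6, 1.0)
        # center 1.0, Q = 6 * 1 = 6, phi = 6/5
        est = ivw_mre([RatioEstimate(str(i), t, s) for i, (t, s) in enumerate(zip(theta_j, se_j))])
        fe_se = 1 / np.sqrt(6)
        assert est.q_stat == pytest.approx(6.0)
        assert est.se == pytest.approx(fe_se * np.sqrt(6 / 5))

    def test_equals_wls_oracle_on_random_sets(self, rng):
        # 100 random instrument sets: IVW equals explicit normal-equations WLS
        # through the origin to 1e-10 relative
        for _ in range(100):
            n = rng.integers(2, 40)
            theta_j = rng.normal(0, 1, n)
            se_j = rng.uniform(0.05, 2.0, n)
            est = ivw_mre([RatioEstimate(str(i), t, s) for i, (t, s) in enumerate(zip(theta_j, se_j))])
            w = 1 / se_j**2
            oracle = np.linalg.solve(np.array([[np.sum(w)]]), np.array([np.sum(w * theta_j)]))[0]
            assert est.theta == pytest.approx(oracle, rel=1e-10)
            q = np.sum(w * (theta_j - oracle) ** 2)
            se_oracle = np.sqrt(1 / w.sum()) * np.sqrt(max(1.0, q / (n - 1)))
            assert est.se == pytest.approx(se_oracle, rel=1e-10)


class TestEgger:
    def test_insufficient_instruments(self):
        with pytest.raises(EstimatorError):
            egger([_pair("a", 0.1, 0.01, 0.1, 0.01), _pair("b", 0.2, 0.01, 0.1, 0.01)])

    def test_no_pleiotropy_recovers_theta(self):
        hits = 0
        for seed in range(20):
            pairs = _forward_pairs(seed, theta=-0.5, n_valid=50)
            est = egger(pairs)
            if abs(est.theta + 0.5) < 3 * est.se:
                hits += 1
        assert hits >= 18

    def test_directional_pleiotropy_detected_by_intercept(self):
        # Egger's intercept needs spread in instrument strength to separate
        # from the slope, hence the wide exposure-effect range here
        detected = 0
        reps = 25
        for seed in range(reps):
            pairs = _forward_pairs(
                seed, theta=-0.5, n_valid=10, n_pleio=40, pleio_sd=0.02, mu_alpha=0.1,
                beta_range=(0.03, 0.3),
            )
            est = egger(pairs)
            if est.egger_intercept_p < 0.05 and est.egger_intercept > 0:
                detected += 1
        assert detected >= 0.8 * reps

    def test_singular_design_rejected(self):
        pairs = [_pair(str(i), 0.1, 0.01, 0.05, 0.01) for i in range(4)]
        with pytest.raises(EstimatorError, match="singular"):
            egger(pairs)


class TestWeightedMedian:
    def test_equal_weight_median(self):
        ratios = [RatioEstimate("a", 0.3, 0.1), RatioEstimate("b", 0.5, 0.1), RatioEstimate("c", 0.9, 0.1)]
        est = weighted_median(ratios, seed=0)
        assert est.theta == pytest.approx(0.5)

    def test_robust_to_40pct_invalid(self):
        # 40% of instruments carry large positive-mean pleiotropic effects: the
        # weighted median stays near truth while IVW is dragged upward
        pairs = _forward_pairs(3, theta=-0.5, n_valid=30, n_pleio=20, pleio_sd=0.5, mu_alpha=0.5)
        ratios = ratio_estimates(pairs)
        wm = weighted_median(ratios, seed=1)
        ivw = ivw_mre(ratios)
        assert abs(wm.theta + 0.5) < 3 * wm.se
        assert ivw.theta > wm.theta

    def test_seed_reproducible(self):
        ratios = [RatioEstimate(str(i), t, 0.1) for i, t in enumerate([0.1, 0.4, 0.5, 0.8])]
        a = weighted_median(ratios, seed=42)
        b = weighted_median(ratios, seed=42)
        assert a.se == b.se

    def test_too_few(self):
        with pytest.raises(EstimatorError):
            weighted_median([RatioEstimate("a", 0.1, 0.1), RatioEstimate("b", 0.2, 0.1)], seed=0)


class TestContaminationMixture:
    def test_all_valid_agrees_with_ivw(self):
        pairs = _forward_pairs(5, theta=-0.5, n_valid=50)
        ratios = ratio_estimates(pairs)
        cm = contamination_mixture(ratios)
        ivw = ivw_mre(ratios)
        grid_step = (cm.ci_high - cm.ci_low) / 100  # generous bound on one step
        assert abs(cm.theta - ivw.theta) < max(grid_step, 2 * ivw.se / 100)

    def test_robust_under_contamination(self):
        covered = 0
        reps = 20
        for seed in range(reps):
            pairs = _forward_pairs(
                seed, theta=-0.5, n_valid=30, n_pleio=20, pleio_sd=0.5, mu_alpha=0.5
            )
            cm = contamination_mixture(ratio_estimates(pairs))
            if cm.ci_low <= -0.5 <= cm.ci_high:
                covered += 1
        assert covered >= 0.9 * reps

    def test_single_ratio_wald_like_width(self):
        cm = contamination_mixture([RatioEstimate("a", 1.0, 0.1)])
        wald_width = 2 * 1.96 * 0.1
        width = cm.ci_high - cm.ci_low
        assert wald_width / 2 < width < wald_width * 2
        assert cm.theta == pytest.approx(1.0, abs=0.01)

    def test_explicit_grid_respected(self):
        ratios = [RatioEstimate("a", 0.5, 0.1), RatioEstimate("b", 0.55, 0.1)]
        cm = contamination_mixture(ratios, CMConfig(grid_lo=-2, grid_hi=2, grid_points=4001))
        assert -2 < cm.theta < 2


class TestMRPresso:
    def _outlier_pairs(self, seed):
        cfg = SimulationConfig(
            theta=-0.5, n_valid=20, n_pleiotropic=1, pleiotropy_sd=1e-12, mu_alpha=1.0,
            n_snps=60, ld_rho=0.0, seed=seed,
        )
        study = simulate_mr_study(cfg)
        pairs = study.instrument_pairs()
        outlier_id = pairs[-1].variant_id  # pleiotropic instrument is last
        return pairs, outlier_id

    def test_planted_outlier_flagged_and_corrected(self):
        pairs, outlier_id = self._outlier_pairs(7)
        est = mr_presso(pairs, PressoConfig(seed=1))
        assert outlier_id in est.outliers
        assert abs(est.theta + 0.5) < 3 * est.se
        assert est.global_p < 0.05

    def test_null_global_p_uniform(self):
        # without outliers the global test p-value is approximately uniform
        pvals = []
        for seed in range(200):
            pairs = _forward_pairs(seed, theta=-0.3, n_valid=10, n_snps=30)
            est = mr_presso(pairs, PressoConfig(n_sim=200, seed=seed))
            pvals.append(est.global_p)
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01

    def test_seed_reproducible(self):
        pairs, _ = self._outlier_pairs(3)
        a = mr_presso(pairs, PressoConfig(seed=5))
        b = mr_presso(pairs, PressoConfig(seed=5))
        assert a.global_p == b.global_p

    def test_too_few(self):
        with pytest.raises(EstimatorError):
            mr_presso([_pair(str(i), 0.1, 0.01, 0.0, 0.01) for i in range(3)])


ESTIMATOR_RUNNERS = {
    "wald": lambda pairs: wald_ratio(pairs[0]),
    "ivw_mre": lambda pairs: ivw_mre(ratio_estimates(pairs)),
    "egger": lambda pairs: egger(pairs),
    "weighted_median": lambda pairs: weighted_median(ratio_estimates(pairs), seed=9),
    "contamination_mixture": lambda pairs: contamination_mixture(ratio_estimates(pairs)),
}


class TestEquivariance:
    @pytest.mark.parametrize("name", list(ESTIMATOR_RUNNERS))
    def test_exposure_scaling_inverts_theta(self, name):
        pairs = _forward_pairs(11, theta=-0.5, n_valid=20, n_snps=60)
        scaled = [
            HarmonizedPair(p.variant_id, 2 * p.beta_exp, p.se_exp, p.beta_out, p.se_out)
            for p in pairs
        ]
        run = ESTIMATOR_RUNNERS[name]
        a, b = run(pairs), run(scaled)
        assert b.theta == pytest.approx(a.theta / 2, rel=1e-9, abs=1e-12)

    @pytest.mark.parametrize("name", list(ESTIMATOR_RUNNERS))
    def test_outcome_negation_negates_theta(self, name):
        pairs = _forward_pairs(13, theta=-0.5, n_valid=20, n_snps=60)
        flipped = [
            HarmonizedPair(p.variant_id, p.beta_exp, p.se_exp, -p.beta_out, p.se_out)
            for p in pairs
        ]
        run = ESTIMATOR_RUNNERS[name]
        a, b = run(pairs), run(flipped)
        assert b.theta == pytest.approx(-a.theta, rel=1e-9, abs=1e-12)

    def test_presso_scaling_preserves_outlier_set(self):
        pairs = _forward_pairs(15, theta=-0.5, n_valid=20, n_snps=60)
        scaled = [
            HarmonizedPair(p.variant_id, 2 * p.beta_exp, p.se_exp / 2, p.beta_out, p.se_out)
            for p in pairs
        ]
        a = mr_presso(pairs, PressoConfig(seed=2))
        b = mr_presso(scaled, PressoConfig(seed=2))
        assert a.outliers == b.outliers
        assert b.theta == pytest.approx(a.theta / 2, rel=1e-9)
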