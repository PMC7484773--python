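import math

import numpy as np
import pytest
from scipy.stats import norm

from seqmonitor import (
    BayesianMonitorModel,
    ContingencyTable,
    DecisionRule,
    GridResolutionError,
    GridSpec,
    SkepticalPrior,
    SyntheticTrialConfig,
    generate,
    monitor,
    odds_ratio,
    posterior_conjugate,
    posterior_grid,
    tabulate,
)
from seqmonitor.estimate import EffectEstimate


def wald(log_or, se):
    return EffectEstimate(math.exp(log_or), log_or, se, 0.0, math.inf, 0.95, 1.0, False)


class TestSkepticalPriorAndRule:
    def test_prior_sd_must_be_positive(self):
        with pytest.raises(ValueError):
            SkepticalPrior(0, 0)

    def test_rule_validates_interval_and_thresholds(self):
        with pytest.raises(ValueError):
            DecisionRule(futility_low=2.0, futility_high=1.0)
        with pytest.raises(ValueError):
            DecisionRule(success_prob_threshold=1.5)

    def test_default_futility_interval_is_symmetric(self):
        rule = DecisionRule()
        assert rule.futility_low == pytest.approx(1 / rule.futility_high)

    def test_prior_only_decision_state(self):
        """Before any data the monitor sits at P(success)=1/2 and a futility
        mass of 2*Phi(ln(1.25)/0.2)-1, so neither criterion can fire."""
        s = SkepticalPrior().summary(DecisionRule())
        assert s.prob_success == pytest.approx(0.5, abs=1e-12)
        expected = 2 * norm.cdf(math.log(1.25) / 0.2) - 1
        assert s.prob_futility == pytest.approx(expected, abs=1e-12)
        assert s.prob_futility == pytest.approx(0.7354, abs=1e-3)
        rule = DecisionRule()
        assert s.prob_success < rule.success_prob_threshold
        assert s.prob_futility < rule.futility_prob_threshold


class TestPosteriorConjugate:
    def test_hand_computed_precision_weighted_update(self):
        # prior (0, 0.2), data (0.5, 0.3): var = 1/(1/0.04 + 1/0.09)
        post = posterior_conjugate(wald(0.5, 0.3), SkepticalPrior(0, 0.2))
        var = 1 / (1 / 0.04 + 1 / 0.09)
        assert post.mean == pytest.approx(var * 0.5 / 0.09, abs=1e-9)
        assert post.mean == pytest.approx(0.15385, abs=1e-5)
        assert post.sd == pytest.approx(math.sqrt(var), abs=1e-9)
        assert post.sd == pytest.approx(0.16641, abs=1e-5)
        assert post.median_or == pytest.approx(math.exp(post.mean))

    def test_flat_prior_limit(self):
        post = posterior_conjugate(wald(0.37, 0.2), SkepticalPrior(0, 100.0))
        assert post.mean == pytest.approx(0.37, abs=1e-3)

    def test_posterior_tighter_than_prior_and_data(self):
        post = posterior_conjugate(wald(0.4, 0.25), SkepticalPrior(0, 0.2))
        assert post.sd < min(0.2, 0.25)

    def test_requires_finite_positive_se(self):
        with pytest.raises(ValueError):
            posterior_conjugate(wald(0.2, 0.0))

    @pytest.mark.parametrize("log_or", [-1.2, -0.3, 0.0, 0.3, 1.2])
    def test_shrinkage_towards_null_prior(self, log_or):
        post = posterior_conjugate(wald(log_or, 0.3), SkepticalPrior(0, 0.2))
        assert abs(post.mean) <= abs(log_or)

    def test_posterior_mean_monotone_in_prior_sd(self):
        sds = [0.05, 0.1, 0.2, 0.5, 1.0, 5.0]
        means = [posterior_conjugate(wald(0.8, 0.3), SkepticalPrior(0, sd)).mean for sd in sds]
        assert means == sorted(means)
        assert 0 < means[0] < means[-1] < 0.8

    def test_success_and_complement_sum_to_one(self):
        for bound in (0.8, 1.0, 1.4):
            rule = DecisionRule(success_or_bound=bound)
            post = posterior_conjugate(wald(0.3, 0.4), rule=rule)
            below = norm.cdf((math.log(bound) - post.mean) / post.sd)
            assert post.prob_success + below == pytest.approx(1.0, abs=1e-12)


class TestPosteriorGrid:
    def test_symmetric_table_has_null_median(self):
        post = posterior_grid(ContingencyTable(20, 20, 20, 20))
        assert post.median_or == pytest.approx(1.0, abs=5e-3)
        assert post.prob_success == pytest.approx(0.5, abs=5e-3)

    def test_agrees_with_conjugate_on_moderate_table(self):
        table = ContingencyTable(40, 60, 20, 80)
        g = posterior_grid(table)
        c = posterior_conjugate(odds_ratio(table))
        assert abs(g.prob_success - c.prob_success) <= 0.02
        assert abs(g.median_or - c.median_or) <= 0.05

    def test_suite_oracle_agreement(self, table_suite):
        """Conjugate approximation vs exact grid posterior across the suite."""
        for table in table_suite:
            g = posterior_grid(table)
            c = posterior_conjugate(odds_ratio(table))
            assert abs(g.prob_success - c.prob_success) <= 0.02
            assert abs(g.median_or - c.median_or) <= 0.05

    def test_probability_complement_both_methods(self):
        table = ContingencyTable(30, 40, 20, 50)
        g = posterior_grid(table)
        assert 0 <= g.prob_success <= 1
        assert 0 <= g.prob_futility <= 1

    def test_too_coarse_grid_rejected(self):
        with pytest.raises(GridResolutionError):
            posterior_grid(
                ContingencyTable(40, 60, 20, 80),
                grid=GridSpec(n_log_or=9, tail_sd=1.0),
            )

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            posterior_grid(ContingencyTable(0, 0, 0, 0))


class TestMonitor:
    def test_below_start_n_yields_no_looks(self):
        records = generate(SyntheticTrialConfig(n=1, p_control=0.3, true_or=1.0, seed=0))
        res = monitor(records, start_n=2)
        assert res.looks == ()
        assert res.stop_n is None

    def test_strong_effect_stops_for_success(self):
        records = generate(SyntheticTrialConfig(n=2000, p_control=0.2, true_or=3.0, seed=11))
        res = monitor(records)
        assert res.stop_reason == "stop_success"
        stop_look = res.looks[-1]
        assert stop_look.n == res.stop_n
        assert stop_look.posterior.prob_success > 0.95

    def test_null_trial_stops_for_futility(self):
        records = generate(SyntheticTrialConfig(n=5000, p_control=0.3, true_or=1.0, seed=11))
        res = monitor(records)
        assert res.stop_reason == "stop_futility"
        assert res.looks[-1].posterior.prob_futility > 0.95

    def test_no_looks_after_stop(self):
        records = generate(SyntheticTrialConfig(n=2000, p_control=0.2, true_or=3.0, seed=11))
        res = monitor(records)
        assert res.looks[-1].n == res.stop_n
        assert all(l.decision == "continue" for l in res.looks[:-1])

    def test_grid_method_agrees_with_conjugate_on_stopping(self):
        records = generate(SyntheticTrialConfig(n=400, p_control=0.2, true_or=3.0, seed=11))
        # sparse schedule keeps the exact-likelihood method quick
        res_c = monitor(records, start_n=50, step=50)
        res_g = monitor(records, start_n=50, step=50, method="grid")
        for lc, lg in zip(res_c.looks, res_g.looks):
            assert lc.n == lg.n
            # small-cell early looks make the normal approximation rougher
            assert lg.posterior.prob_success == pytest.approx(lc.posterior.prob_success, abs=0.05)

    def test_early_look_protection_vs_naive_peeking(self):
        """On paired null trials, the skeptical monitor reaches a false
        success verdict less often than naive p<alpha peeking."""
        from seqmonitor import run_oc

        oc = run_oc(
            SyntheticTrialConfig(n=500, p_control=0.3, true_or=1.0),
            start_n=2,
            reps=200,
            base_seed=77,
        )
        assert oc.bayes_false_success_rate < oc.naive_cross_rate

    def test_posterior_interval_calibration_under_vague_prior(self):
        """95% credible intervals from the conjugate engine cover the true
        log-OR at ~nominal rate when the prior carries no information."""
        true_log_or = math.log(1.8)
        prior = SkepticalPrior(0, 10.0)
        z = norm.ppf(0.975)
        covered = 0
        reps = 200
        for rep in range(reps):
            records = generate(
                SyntheticTrialConfig(n=535, p_control=0.25, true_or=1.8, seed=3000 + rep)
            )
            est = odds_ratio(tabulate(records, sum(r.responded for r in records)))
            post = posterior_conjugate(est, prior)
            covered += post.mean - z * post.sd <= true_log_or <= post.mean + z * post.sd
        assert 0.90 <= covered / reps <= 0.99


class TestBayesianMonitorModel:
    def test_fit_frame_and_summary(self):
        records = generate(SyntheticTrialConfig(n=300, p_control=0.3, true_or=1.0, seed=2))
        res = BayesianMonitorModel(records).fit()
        frame = res.frame()
        assert list(frame.columns) == ["n", "median_or", "prob_success", "prob_futility", "decision"]
        assert "prior: normal(mean=0.0, sd=0.2)" in res.summary()
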