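"""Analysis models: ANCOVA, logistic codings, GEE logistic."""

import math

import numpy as np
import pytest
import statsmodels.api as sm

from prepost import (
    AllocationSpec,
    BinaryModelSpec,
    CorrelationSpec,
    TrialDataset,
    fit_ancova,
    fit_gee_logistic,
    fit_logistic,
    simulate_binary,
    simulate_continuous,
    variance_structured,
)
from prepost.fit import _empirical_logit


def _continuous_trial(seed=0, n=50, s=2, t=1, rho_xy=0.5, rho_x=0.6, delta=0.3):
    return simulate_continuous(
        n, n, AllocationSpec(s, t), CorrelationSpec(rho_x, rho_x, rho_xy), delta, seed=seed
    )


def _binary_trial(seed=0, n=50, s=2, t=1, rho_xy=0.5, rho_x=0.6, p=0.4, beta1=0.8):
    return simulate_binary(
        n, n, AllocationSpec(s, t), CorrelationSpec(rho_x, rho_x, rho_xy),
        BinaryModelSpec(p, beta1), seed=seed,
    )


class TestAncova:
    def test_matches_statsmodels_ols(self):
        """The closed-form solver reproduces statsmodels OLS exactly."""
        trial = _continuous_trial(seed=42)
        res = fit_ancova(trial)
        xbar = trial.pre.mean(axis=1)
        design = sm.add_constant(
            np.column_stack([trial.arm, xbar - xbar.mean()])
        )
        ols = sm.OLS(trial.post.mean(axis=1), design).fit()
        assert res.estimate == pytest.approx(ols.params[1], rel=1e-10)
        assert res.std_error == pytest.approx(ols.bse[1], rel=1e-10)
        assert res.p_value == pytest.approx(ols.pvalues[1], rel=1e-8)
        assert res.df == int(ols.df_resid)

    def test_orthogonal_covariate_recovers_raw_difference(self):
        """When pre and post are independent the adjustment is inert."""
        trial = _continuous_trial(seed=1, n=2000, rho_xy=0.0, delta=0.5)
        res = fit_ancova(trial)
        ybar = trial.post.mean(axis=1)
        raw = ybar[trial.arm == 1].mean() - ybar[trial.arm == 0].mean()
        assert res.estimate == pytest.approx(raw, abs=0.03)

    def test_location_invariance(self):
        """Centering makes the baseline covariate location-free."""
        trial = _continuous_trial(seed=2)
        shifted = TrialDataset(pre=trial.pre + 37.5, post=trial.post, arm=trial.arm)
        a, b = fit_ancova(trial), fit_ancova(shifted)
        assert a.estimate == pytest.approx(b.estimate, rel=1e-12)
        assert a.statistic == pytest.approx(b.statistic, rel=1e-12)

    def test_collinear_covariate_rejected(self):
        trial = _continuous_trial(seed=3)
        flat = TrialDataset(
            pre=np.ones_like(trial.pre), post=trial.post, arm=trial.arm
        )
        with pytest.raises(ValueError, match="zero variance"):
            fit_ancova(flat)

    def test_empirical_variance_matches_closed_form(self):
        """var(delta-hat) over 20,000 null replicates agrees with theory within 5%."""
        corr = CorrelationSpec(0.6, 0.6, 0.5)
        alloc = AllocationSpec(2, 1)
        reps = 20_000
        estimates = np.empty(reps)
        for i, ss in enumerate(np.random.SeedSequence(314).spawn(reps)):
            rng = np.random.Generator(np.random.PCG64(ss))
            trial = simulate_continuous(50, 50, alloc, corr, 0.0, seed=rng)
            estimates[i] = fit_ancova(trial).estimate
        theory = variance_structured(corr, alloc, 50, 50)
        assert np.var(estimates) == pytest.approx(theory, rel=0.05)


class TestLogistic:
    def test_empirical_logit_mapping(self):
        """X in {0, 1, 2} maps to {-log 5, 0, log 5} under the 1/2 correction."""
        got = _empirical_logit(np.array([0.0, 1.0, 2.0]), 2)
        assert got == pytest.approx([-math.log(5), 0.0, math.log(5)])

    def test_model2_equivalent_to_linear_count(self):
        """The empirical-logit coding is an affine recoding of X for S=2."""
        trial = _binary_trial(seed=11, n=100)
        res2 = fit_logistic(trial, model=2)
        x = trial.pre.sum(axis=1).astype(float)
        design = sm.add_constant(np.column_stack([trial.arm.astype(float), x]))
        linear = sm.Logit(trial.post[:, 0].astype(float), design).fit(disp=0)
        z_linear = linear.params[1] / linear.bse[1]
        from scipy.stats import norm

        assert res2.p_value == pytest.approx(2 * norm.sf(abs(z_linear)), abs=1e-10)

    def test_model1_uses_last_pre_column_only(self):
        trial = _binary_trial(seed=12, n=100, s=2)
        baseline_only = TrialDataset(
            pre=trial.pre[:, [1]], post=trial.post, arm=trial.arm
        )
        assert fit_logistic(trial, 1).p_value == pytest.approx(
            fit_logistic(baseline_only, 1).p_value, abs=1e-12
        )

    def test_model3_categorical_runs(self):
        res = fit_logistic(_binary_trial(seed=13, n=150), model=3)
        assert res.usable and 0 <= res.p_value <= 1

    def test_separation_flagged(self):
        """Y deterministic in arm diverges and is flagged, not raised."""
        n = 40
        arm = np.repeat([0, 1], n // 2)
        pre = np.tile([[0, 1]], (n, 1))
        post = arm[:, None].astype(np.int8)
        res = fit_logistic(TrialDataset(pre=pre, post=post, arm=arm), model=1)
        assert res.separation and not res.converged
        assert np.isnan(res.p_value)

    def test_requires_single_follow_up(self):
        with pytest.raises(ValueError, match="T = 1"):
            fit_logistic(_binary_trial(seed=14, t=2), model=1)

    def test_models_2_3_require_two_baselines(self):
        with pytest.raises(ValueError, match="S = 2"):
            fit_logistic(_binary_trial(seed=15, s=3), model=2)


class TestGee:
    def test_t1_dispatches_to_logistic(self):
        """A single follow-up collapses to ordinary logistic regression."""
        trial = _binary_trial(seed=21, n=100, t=1)
        res = fit_gee_logistic(trial, model=1)
        x = trial.pre.sum(axis=1).astype(float)
        design = sm.add_constant(np.column_stack([trial.arm.astype(float), x]))
        logit = sm.Logit(trial.post[:, 0].astype(float), design).fit(disp=0)
        assert res.estimate == pytest.approx(logit.params[1], rel=1e-6)

    def test_generalized_empirical_logit_denominator(self):
        # For S=3 the transform caps at the count S, reducing to the
        # printed two-baseline form when S=2.
        got = _empirical_logit(np.array([0.0, 3.0]), 3)
        assert got == pytest.approx([math.log(0.5 / 3.5), math.log(3.5 / 0.5)])

    @pytest.mark.parametrize("working", ["exchangeable", "independence"])
    def test_working_correlations_both_run(self, working):
        trial = _binary_trial(seed=22, n=100, s=2, t=3, beta1=0.5)
        res = fit_gee_logistic(trial, model=2, working=working)
        assert res.usable and 0 <= res.p_value <= 1

    def test_matches_statsmodels_gee_directly(self):
        trial = _binary_trial(seed=23, n=80, s=2, t=3, beta1=0.5)
        res = fit_gee_logistic(trial, model=1)
        n, t = trial.n, 3
        y = trial.post.astype(float).ravel()
        design = np.column_stack(
            [
                np.ones(n * t),
                np.repeat(trial.arm.astype(float), t),
                np.repeat(trial.pre.sum(axis=1).astype(float), t),
            ]
        )
        from statsmodels.genmod.cov_struct import Exchangeable

        gee = sm.GEE(
            y,
            design,
            groups=np.repeat(np.arange(n), t),
            family=sm.families.Binomial(),
            cov_struct=Exchangeable(),
        ).fit()
        assert res.estimate == pytest.approx(gee.params[1], rel=1e-10)
        assert res.std_error == pytest.approx(gee.bse[1], rel=1e-10)

    def test_invalid_arguments(self):
        trial = _binary_trial(seed=24, t=2)
        with pytest.raises(ValueError):
            fit_gee_logistic(trial, model=3)
        with pytest.raises(ValueError):
            fit_gee_logistic(trial, model=1, working="ar1")
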