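"""Treatment-effect tests for simulated pre-post trials.

Continuous endpoints are analyzed by ANCOVA on the subject-level means: the
post-visit mean is regressed on the treatment indicator and the centered
pre-visit mean, and the treatment coefficient is tested with a two-sided t
test on ``n0 + n1 - 3`` degrees of freedom.  The regression is solved in
closed form (it has three parameters) for speed in Monte-Carlo loops; a unit
test pins it to the statsmodels OLS answer.

Binary endpoints with a single follow-up use logistic regression (three
baseline-covariate codings); with multiple follow-ups, GEE logistic
regression with a robust sandwich variance.  Perfect separation and
non-convergence are flagged on the result rather than raised, so Monte-Carlo
drivers can apply an exclusion policy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy.stats import norm
from scipy.stats import t as t_dist
from statsmodels.genmod.cov_struct import Exchangeable, Independence

from .simulate import TrialDataset

__all__ = ["TestResult", "fit_ancova", "fit_logistic", "fit_gee_logistic"]

# Wald standard errors beyond this are treated as symptomatic of separation
# (diverging logistic coefficients).
_SE_SEPARATION_LIMIT = 50.0


@dataclass(frozen=True)
class TestResult:
    """A fitted treatment-effect test.

    ``estimate`` is the treatment coefficient (delta-hat for ANCOVA, the
    log-odds shift beta1-hat for the binary models), ``statistic`` its t or
    Z value, and ``df`` the residual degrees of freedom for t tests (None
    for asymptotic Z tests).  ``separation=True`` marks replicates the
    Monte-Carlo engine excludes.
    """

    estimate: float
    std_error: float
    statistic: float
    p_value: float
    df: int | None
    converged: bool
    separation: bool
    model_tag: str

    @classmethod
    def failed(cls, model_tag: str) -> "TestResult":
        return cls(
            estimate=np.nan,
            std_error=np.nan,
            statistic=np.nan,
            p_value=np.nan,
            df=None,
            converged=False,
            separation=True,
            model_tag=model_tag,
        )

    @property
    def usable(self) -> bool:
        return self.converged and not self.separation and np.isfinite(self.statistic)


def fit_ancova(trial: TrialDataset) -> TestResult:
    """ANCOVA of the post-visit mean on arm and the centered pre-visit mean."""
    xbar = trial.pre.mean(axis=1)
    ybar = trial.post.mean(axis=1)
    arm = np.asarray(trial.arm, dtype=float)
    n = xbar.shape[0]
    xc = xbar - xbar.mean()
    if np.allclose(xc, 0.0):
        raise ValueError("pre-treatment means have zero variance (collinear covariate)")
    design = np.column_stack([np.ones(n), arm, xc])
    xtx = design.T @ design
    beta = np.linalg.solve(xtx, design.T @ ybar)
    resid = ybar - design @ beta
    df = n - 3
    s2 = float(resid @ resid) / df
    cov = s2 * np.linalg.inv(xtx)
    se = float(np.sqrt(cov[1, 1]))
    stat = float(beta[1]) / se
    return TestResult(
        estimate=float(beta[1]),
        std_error=se,
        statistic=stat,
        p_value=2 * t_dist.sf(abs(stat), df),
        df=df,
        converged=True,
        separation=False,
        model_tag="ancova",
    )


def _empirical_logit(x: np.ndarray, max_count: int) -> np.ndarray:
    # The 1/2 continuity correction keeps the transform finite at the
    # boundary counts 0 and max_count.
    return np.log((x + 0.5) / (max_count - x + 0.5))


def _wald_from_logit(y, design, model_tag: str) -> TestResult:
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y, design).fit(disp=0, maxiter=100)
    except Exception:
        return TestResult.failed(model_tag)
    converged = bool(res.mle_retvals.get("converged", True))
    se = float(res.bse[1])
    if not np.isfinite(se) or se > _SE_SEPARATION_LIMIT or not converged:
        return TestResult.failed(model_tag)
    stat = float(res.params[1]) / se
    return TestResult(
        estimate=float(res.params[1]),
        std_error=se,
        statistic=stat,
        p_value=2 * norm.sf(abs(stat)),
        df=None,
        converged=True,
        separation=False,
        model_tag=model_tag,
    )


def fit_logistic(trial: TrialDataset, model: int = 1) -> TestResult:
    """Logistic regression for a single binary follow-up.

    Baseline coding by model number:

    1. the last pre-treatment column (the "baseline" visit) entered linearly;
    2. the empirical logit ``log[(X + 1/2) / (2 - X + 1/2)]`` of the summed
       screening + baseline count ``X`` (requires ``S = 2``);
    3. ``X`` as a categorical covariate, reference level ``X = 0`` (requires
       ``S = 2``).
    """
    if trial.post.shape[1] != 1:
        raise ValueError("fit_logistic requires a single post-treatment visit (T = 1)")
    s = trial.pre.shape[1]
    y = trial.post[:, 0].astype(float)
    arm = np.asarray(trial.arm, dtype=float)
    n = y.shape[0]
    if model == 1:
        cov = trial.pre[:, -1].astype(float)[:, None]
    elif model in (2, 3):
        if s != 2:
            raise ValueError(f"model {model} requires exactly S = 2 pre-treatment visits")
        x = trial.pre.sum(axis=1).astype(float)
        if model == 2:
            cov = _empirical_logit(x, 2)[:, None]
        else:
            cov = np.column_stack([(x == 1).astype(float), (x == 2).astype(float)])
    else:
        raise ValueError(f"model must be 1, 2 or 3; got {model}")
    design = np.column_stack([np.ones(n), arm, cov])
    return _wald_from_logit(y, design, model_tag=f"logistic-{model}")


def fit_gee_logistic(
    trial: TrialDataset, model: int = 1, working: str = "exchangeable"
) -> TestResult:
    """Marginal logistic regression of the repeated binary follow-ups.

    The pre-treatment summary is the summed count ``X+`` (model 1) or its
    empirical logit ``log[(X+ + 1/2) / (S - X+ + 1/2)]`` (model 2; the
    denominator generalizes the two-baseline form to any ``S``).  With
    ``T >= 2`` a GEE with the chosen working correlation ("exchangeable" or
    "independence") and robust sandwich variance is fit; with ``T = 1`` the
    model collapses to ordinary logistic regression on the same covariates.
    """
    if model not in (1, 2):
        raise ValueError(f"model must be 1 or 2; got {model}")
    s = trial.pre.shape[1]
    t = trial.post.shape[1]
    xplus = trial.pre.sum(axis=1).astype(float)
    cov = xplus if model == 1 else _empirical_logit(xplus, s)
    arm = np.asarray(trial.arm, dtype=float)
    n = arm.shape[0]
    tag = f"gee-{model}"

    if t == 1:
        design = np.column_stack([np.ones(n), arm, cov])
        res = _wald_from_logit(trial.post[:, 0].astype(float), design, model_tag=tag)
        return res

    y = trial.post.astype(float).ravel()
    design = np.column_stack(
        [np.ones(n * t), np.repeat(arm, t), np.repeat(cov, t)]
    )
    groups = np.repeat(np.arange(n), t)
    cov_struct = {"exchangeable": Exchangeable, "independence": Independence}
    if working not in cov_struct:
        raise ValueError(f"working must be 'exchangeable' or 'independence'; got {working!r}")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.GEE(
                y,
                design,
                groups=groups,
                family=sm.families.Binomial(),
                cov_struct=cov_struct[working](),
            ).fit(maxiter=60)
            se = float(res.bse[1])
    except Exception:
        return TestResult.failed(tag)
    converged = bool(getattr(res, "converged", True))
    if not np.isfinite(se) or se > _SE_SEPARATION_LIMIT or not converged:
        return TestResult.failed(tag)
    stat = float(res.params[1]) / se
    return TestResult(
        estimate=float(res.params[1]),
        std_error=se,
        statistic=stat,
        p_value=2 * norm.sf(abs(stat)),
        df=None,
        converged=True,
        separation=False,
        model_tag=tag,
    )
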