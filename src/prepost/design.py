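"""Closed-form ANCOVA variance and sample size for pre-post designs.

A two-arm randomized trial measures the same continuous endpoint at ``S``
pre-treatment (baseline) visits and ``T`` post-treatment (follow-up) visits.
The analysis regresses the subject-level follow-up mean on the treatment
indicator with the baseline mean as covariate (ANCOVA).  Under a multivariate
normal model the variance of the estimated treatment effect, and hence the
per-group sample size, has a closed form driven by the block means of the
(S+T) x (S+T) covariance matrix.

Two covariance parameterizations are supported:

* an *exchangeable-block* structure (:class:`CorrelationSpec`): all within-pre
  correlations equal ``rho_x``, all within-post equal ``rho_y``, all
  cross-period equal ``rho_xy``;
* an arbitrary user-supplied matrix (:func:`variance_general`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

__all__ = [
    "CorrelationSpec",
    "AllocationSpec",
    "DesignInputs",
    "SampleSizeResult",
    "InvalidCorrelationError",
    "DegeneratePreBlockError",
    "BEAT_THE_BLUES",
    "BEAT_THE_BLUES_DELTA",
    "exchangeable_covariance",
    "variance_bracket",
    "variance_general",
    "variance_structured",
    "sample_size_per_group",
    "sample_size_ratio",
]

# Eigenvalue floor below which the implied covariance matrix is rejected.
_PSD_TOL = -1e-10


class InvalidCorrelationError(ValueError):
    """The correlation parameters do not define a valid covariance for (S, T)."""


class DegeneratePreBlockError(ValueError):
    """The mean of the pre-treatment covariance block is not positive."""


@dataclass(frozen=True)
class CorrelationSpec:
    """Exchangeable-block correlation/variance parameters.

    Parameters
    ----------
    rho_x : float
        Correlation between any two pre-treatment measurements.
    rho_y : float
        Correlation between any two post-treatment measurements.
    rho_xy : float
        Correlation between any pre-treatment and any post-treatment
        measurement.
    sigma2_x, sigma2_y : float
        Marginal variances of the pre- and post-treatment measurements
        (defaults 1.0, the scale used throughout the simulation studies).
    """

    rho_x: float
    rho_y: float
    rho_xy: float
    sigma2_x: float = 1.0
    sigma2_y: float = 1.0

    def __post_init__(self) -> None:
        if not (-1.0 < self.rho_x < 1.0 and -1.0 < self.rho_y < 1.0):
            raise InvalidCorrelationError(
                f"rho_x and rho_y must lie in (-1, 1); got {self.rho_x}, {self.rho_y}"
            )
        if not (-1.0 <= self.rho_xy <= 1.0):
            raise InvalidCorrelationError(f"rho_xy must lie in [-1, 1]; got {self.rho_xy}")
        if self.sigma2_x <= 0 or self.sigma2_y <= 0:
            raise InvalidCorrelationError("variances must be positive")


@dataclass(frozen=True)
class AllocationSpec:
    """Visit allocation: ``s`` pre-treatment and ``t`` post-treatment visits."""

    s: int
    t: int

    def __post_init__(self) -> None:
        if self.s < 1 or self.t < 1:
            raise ValueError(f"need s >= 1 and t >= 1; got s={self.s}, t={self.t}")

    @property
    def m(self) -> int:
        """Total number of visits ``M = S + T``."""
        return self.s + self.t


@dataclass(frozen=True)
class DesignInputs:
    """Effect size and error levels for a sample-size calculation.

    ``delta`` is the treatment effect on the outcome scale, ``alpha`` the
    two-sided Type-I level and ``power`` the target power ``1 - beta``.
    ``n0``/``n1`` are only used by variance computations, not by the
    equal-allocation sample-size formula.
    """

    delta: float
    alpha: float = 0.05
    power: float = 0.8
    n0: int = 2
    n1: int = 2

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if not 0.0 < self.power < 1.0:
            raise ValueError("power must be in (0, 1)")
        if self.n0 < 2 or self.n1 < 2:
            raise ValueError("per-group sizes must be at least 2")


#: Parameter estimates printed for the "Beat the Blues" depression trial
#: (interactive multimedia program vs. treatment as usual): variances 117.5
#: (pre) and 116.8 (post), cross correlation 0.52 and within-period
#: correlation 0.77 (the single-baseline design forces rho_x = rho_y).
BEAT_THE_BLUES = CorrelationSpec(
    rho_x=0.77, rho_y=0.77, rho_xy=0.52, sigma2_x=117.5, sigma2_y=116.8
)

#: Treatment effect estimated from the same trial, in Beck Depression
#: Inventory points.
BEAT_THE_BLUES_DELTA = 5.4


def exchangeable_covariance(corr: CorrelationSpec, alloc: AllocationSpec) -> np.ndarray:
    """Build the full (S+T) x (S+T) exchangeable-block covariance matrix."""
    s, t = alloc.s, alloc.t
    sx = math.sqrt(corr.sigma2_x)
    sy = math.sqrt(corr.sigma2_y)
    pre = corr.sigma2_x * ((1 - corr.rho_x) * np.eye(s) + corr.rho_x * np.ones((s, s)))
    post = corr.sigma2_y * ((1 - corr.rho_y) * np.eye(t) + corr.rho_y * np.ones((t, t)))
    cross = corr.rho_xy * sx * sy * np.ones((s, t))
    return np.block([[pre, cross], [cross.T, post]])


def validate_psd(sigma: np.ndarray, what: str = "covariance matrix") -> None:
    """Raise :class:`InvalidCorrelationError` unless ``sigma`` is symmetric PSD."""
    sigma = np.asarray(sigma, dtype=float)
    if sigma.ndim != 2 or sigma.shape[0] != sigma.shape[1]:
        raise ValueError(f"{what} must be square; got shape {sigma.shape}")
    if not np.allclose(sigma, sigma.T, atol=1e-8):
        raise InvalidCorrelationError(f"{what} must be symmetric")
    if np.linalg.eigvalsh(sigma)[0] < _PSD_TOL:
        raise InvalidCorrelationError(
            f"{what} is not positive semi-definite "
            f"(min eigenvalue {np.linalg.eigvalsh(sigma)[0]:.3e})"
        )


def _block_means(sigma: np.ndarray, s: int, t: int) -> tuple[float, float, float]:
    pre = sigma[:s, :s]
    post = sigma[s:, s:]
    cross = sigma[:s, s:]
    return float(pre.mean()), float(post.mean()), float(cross.mean())


def variance_general(
    sigma: np.ndarray, alloc: AllocationSpec, n0: int, n1: int
) -> float:
    """Treatment-effect variance for an arbitrary covariance matrix.

    The ANCOVA estimator contrasts the arm means of the subject-level
    follow-up average ``Ybar`` after adjusting for the baseline average
    ``Xbar``; its large-sample variance is

    ``(1/n0 + 1/n1) * (mean(Sigma_post) - mean(Sigma_pre_post)^2 / mean(Sigma_pre))``

    where each ``mean`` is the arithmetic mean of all elements of the
    corresponding block of ``sigma``.
    """
    sigma = np.asarray(sigma, dtype=float)
    s, t = alloc.s, alloc.t
    if sigma.shape != (s + t, s + t):
        raise ValueError(
            f"covariance matrix has shape {sigma.shape}, expected ({s + t}, {s + t})"
        )
    validate_psd(sigma)
    pre_bar, post_bar, cross_bar = _block_means(sigma, s, t)
    if pre_bar <= 0:
        raise DegeneratePreBlockError(
            f"mean of the pre-treatment block must be positive; got {pre_bar:.3e}"
        )
    return (1.0 / n0 + 1.0 / n1) * (post_bar - cross_bar**2 / pre_bar)


def variance_bracket(corr: CorrelationSpec, alloc: AllocationSpec) -> float:
    """The dimensionless bracket ``(1+(T-1)rho_y)/T - rho_xy^2 S/(1+(S-1)rho_x)``.

    Multiplying by ``(1/n0 + 1/n1) * sigma2_y`` gives the treatment-effect
    variance; the bracket alone drives sample-size ratios and the visit
    allocation problem.
    """
    s, t = alloc.s, alloc.t
    validate_psd(
        exchangeable_covariance(corr, alloc),
        what=f"implied covariance for S={s}, T={t}",
    )
    bracket = (1 + (t - 1) * corr.rho_y) / t - corr.rho_xy**2 * s / (
        1 + (s - 1) * corr.rho_x
    )
    if bracket < 0:
        raise InvalidCorrelationError(
            f"correlation parameters give a negative variance bracket ({bracket:.3e})"
        )
    return bracket


def variance_structured(
    corr: CorrelationSpec, alloc: AllocationSpec, n0: int, n1: int
) -> float:
    """Treatment-effect variance under the exchangeable-block structure."""
    return (1.0 / n0 + 1.0 / n1) * corr.sigma2_y * variance_bracket(corr, alloc)


@dataclass(frozen=True)
class SampleSizeResult:
    """Per-group sample size with its unrounded value and variance bracket."""

    n: int
    n_exact: float
    bracket: float

    def __int__(self) -> int:
        return self.n


def sample_size_per_group(
    corr: CorrelationSpec, alloc: AllocationSpec, design: DesignInputs
) -> SampleSizeResult:
    """Per-group sample size (equal allocation) for the pre-post ANCOVA.

    ``n = ceil( 2 (z_{1-alpha/2} + z_{power})^2 sigma_y^2 / delta^2 * bracket )``
    with the exchangeable-block variance bracket of :func:`variance_bracket`.
    The unrounded value is exposed alongside the ceiling.
    """
    if design.delta == 0:
        raise ValueError("sample size is undefined for delta = 0")
    z = norm.ppf(1 - design.alpha / 2) + norm.ppf(design.power)
    bracket = variance_bracket(corr, alloc)
    n_exact = 2 * z**2 * corr.sigma2_y / design.delta**2 * bracket
    return SampleSizeResult(n=math.ceil(n_exact), n_exact=n_exact, bracket=bracket)


def sample_size_ratio(
    corr: CorrelationSpec, alloc_a: AllocationSpec, alloc_b: AllocationSpec
) -> float:
    """Ratio of unrounded sample sizes ``n(alloc_a) / n(alloc_b)``.

    The normal quantiles, variance and effect size cancel, leaving the ratio
    of the two variance brackets.  Values above 1 mean ``alloc_a`` requires
    more subjects.
    """
    denom = variance_bracket(corr, alloc_b)
    if denom == 0:
        raise ZeroDivisionError("denominator allocation has a zero variance bracket")
    return variance_bracket(corr, alloc_a) / denom
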