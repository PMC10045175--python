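"""Synthetic two-arm pre-post trial generators.

Continuous endpoints are drawn from a multivariate normal with the
exchangeable-block covariance; the treatment arm shifts the post-treatment
means by the effect ``delta``.  Binary endpoints are produced by a Gaussian
copula: a latent multivariate normal with correlation matrix ``R`` (``rho_x``
within pre, ``rho_y`` within post, ``rho_xy`` across) is mapped through the
standard normal CDF to uniform margins, which are dichotomized at the success
probability — ``p`` everywhere in the control arm, ``p`` for pre and the
log-odds-shifted ``p'`` for post columns in the treatment arm.

Note the correlations parameterize the *latent normal* scale; the induced
correlations among the 0/1 variables are attenuated relative to ``R``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any

import numpy as np
from scipy.stats import norm

from .design import AllocationSpec, CorrelationSpec, validate_psd

__all__ = ["TrialDataset", "BinaryModelSpec", "simulate_continuous", "simulate_binary"]


@dataclass
class TrialDataset:
    """One simulated two-arm trial.

    ``pre`` is n x S, ``post`` n x T, ``arm`` a length-n 0/1 indicator
    (0 control, 1 treatment); control rows come first.  ``meta`` records the
    generator parameters and seed.
    """

    pre: np.ndarray
    post: np.ndarray
    arm: np.ndarray
    meta: dict[str, Any] = field(default_factory=dict)

    @property
    def n(self) -> int:
        return self.arm.shape[0]

    @property
    def alloc(self) -> AllocationSpec:
        return AllocationSpec(s=self.pre.shape[1], t=self.post.shape[1])


@dataclass(frozen=True)
class BinaryModelSpec:
    """Success probabilities of the binary-endpoint model.

    ``p`` is the control-arm success probability; ``beta1`` shifts the
    log-odds in the treatment arm, giving the treated post-treatment success
    probability ``p' = p e^{beta1} / (1 - p + p e^{beta1})``.
    """

    p: float
    beta1: float

    def __post_init__(self) -> None:
        if not 0.0 < self.p < 1.0:
            raise ValueError(f"p must be in (0, 1); got {self.p}")

    @property
    def p_prime(self) -> float:
        e = math.exp(self.beta1)
        return self.p * e / (1 - self.p + self.p * e)


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _latent_correlation(corr: CorrelationSpec, alloc: AllocationSpec) -> np.ndarray:
    s, t = alloc.s, alloc.t
    pre = (1 - corr.rho_x) * np.eye(s) + corr.rho_x * np.ones((s, s))
    post = (1 - corr.rho_y) * np.eye(t) + corr.rho_y * np.ones((t, t))
    cross = corr.rho_xy * np.ones((s, t))
    return np.block([[pre, cross], [cross.T, post]])


def simulate_continuous(
    n0: int,
    n1: int,
    alloc: AllocationSpec,
    corr: CorrelationSpec,
    delta: float,
    seed=None,
) -> TrialDataset:
    """Draw a continuous-endpoint trial from the multivariate normal model.

    Control subjects have mean zero at every visit; treatment subjects have
    mean zero at the ``S`` pre visits and ``delta`` at the ``T`` post visits.
    The covariance is the exchangeable-block matrix implied by ``corr``
    (unit variances by default).
    """
    rng = _as_rng(seed)
    s, t = alloc.s, alloc.t
    sigma = _latent_correlation(corr, alloc)
    scale = np.concatenate(
        [np.full(s, math.sqrt(corr.sigma2_x)), np.full(t, math.sqrt(corr.sigma2_y))]
    )
    sigma = sigma * np.outer(scale, scale)
    validate_psd(sigma, what=f"implied covariance for S={s}, T={t}")
    chol = np.linalg.cholesky(sigma + 1e-12 * np.eye(s + t))
    n = n0 + n1
    z = rng.standard_normal((n, s + t)) @ chol.T
    arm = np.repeat([0, 1], [n0, n1])
    z[n0:, s:] += delta
    return TrialDataset(
        pre=z[:, :s],
        post=z[:, s:],
        arm=arm,
        meta={
            "kind": "continuous",
            "n0": n0,
            "n1": n1,
            "s": s,
            "t": t,
            "corr": corr,
            "delta": delta,
        },
    )


def simulate_binary(
    n0: int,
    n1: int,
    alloc: AllocationSpec,
    corr: CorrelationSpec,
    bspec: BinaryModelSpec,
    seed=None,
) -> TrialDataset:
    """Draw a binary-endpoint trial via the Gaussian copula.

    Latent normals with correlation ``R`` are mapped to uniforms by the
    standard normal CDF; entries become 1 when the uniform is at or below
    the success probability (``p`` everywhere for controls; ``p`` pre /
    ``p'`` post for treated subjects).
    """
    rng = _as_rng(seed)
    s, t = alloc.s, alloc.t
    r = _latent_correlation(corr, alloc)
    validate_psd(r, what=f"copula correlation matrix for S={s}, T={t}")
    chol = np.linalg.cholesky(r + 1e-12 * np.eye(s + t))
    n = n0 + n1
    u = norm.cdf(rng.standard_normal((n, s + t)) @ chol.T)
    thresh = np.full((n, s + t), bspec.p)
    thresh[n0:, s:] = bspec.p_prime
    x = (u <= thresh).astype(np.int8)
    arm = np.repeat([0, 1], [n0, n1])
    return TrialDataset(
        pre=x[:, :s],
        post=x[:, s:],
        arm=arm,
        meta={
            "kind": "binary",
            "n0": n0,
            "n1": n1,
            "s": s,
            "t": t,
            "corr": corr,
            "p": bspec.p,
            "beta1": bspec.beta1,
        },
    )
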