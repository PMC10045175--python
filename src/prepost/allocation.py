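"""Optimal split of a fixed visit budget between baselines and follow-ups.

With the total number of visits ``M = S + T`` fixed, the per-group sample
size of the pre-post ANCOVA is proportional to

    f(S) = (1 + rho_y (M - S - 1)) / (M - S) - rho_xy^2 S / (1 + rho_x (S - 1)),

so the most efficient design takes ``S`` minimizing ``f`` over the integers
in ``[1, M-1]``.  When ``0 < rho_x, rho_y < 1``, ``rho_xy != 0`` and
``rho_x rho_y >= rho_xy^2``, ``f`` has a unique interior minimum whenever
``M >= sqrt((1-rho_y) / ((1-rho_x) rho_xy^2)) + 1``; otherwise a single
baseline (``S = 1``) is optimal.  Outside those assumptions the integer
optimum is found by exhaustive search.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

from .design import CorrelationSpec

__all__ = [
    "ObjectiveDecomposition",
    "AllocationSolution",
    "objective_f",
    "objective_decomposition",
    "m_threshold",
    "s_opt_continuous",
    "s_opt_integer",
    "s_opt_equal_correlation",
]


@dataclass(frozen=True)
class ObjectiveDecomposition:
    """Coefficients of ``f(S) = A/(M-S) + B/(1 + rho_x (S-1)) + C``."""

    a_coef: float
    b_coef: float
    c_coef: float


@dataclass(frozen=True)
class AllocationSolution:
    """Result of the integer allocation search.

    ``s_real`` is the real-valued minimizer of ``f`` (clipped to 1 when the
    visit budget is below the interior-optimum threshold), ``s_int`` the
    integer optimum, ``f_floor``/``f_ceil`` the objective at the two integers
    bracketing ``s_real``, ``feasible`` whether the interior-optimum
    threshold on ``M`` is met, and ``method`` how the optimum was obtained.
    """

    s_real: float
    s_int: int
    f_floor: float
    f_ceil: float
    feasible: bool
    method: str  # "closed_form" | "brute_force"


def objective_f(s: float, m: float, corr: CorrelationSpec) -> float:
    """Allocation objective ``f(S)``; proportional to sample size at fixed M."""
    if not 1 <= s < m:
        raise ValueError(f"need 1 <= s < m; got s={s}, m={m}")
    denom = 1 + corr.rho_x * (s - 1)
    if denom <= 0:
        raise ValueError(f"1 + rho_x (s-1) must be positive; got {denom:.3e}")
    return (1 + corr.rho_y * (m - s - 1)) / (m - s) - corr.rho_xy**2 * s / denom


def objective_decomposition(corr: CorrelationSpec) -> ObjectiveDecomposition:
    """Partial-fraction form of the objective; requires ``rho_x != 0``."""
    if corr.rho_x == 0:
        raise ValueError("the A/B/C decomposition requires rho_x != 0")
    a = 1 - corr.rho_y
    b = corr.rho_xy**2 * (1 - corr.rho_x) / corr.rho_x
    c = corr.rho_y - corr.rho_xy**2 / corr.rho_x
    return ObjectiveDecomposition(a_coef=a, b_coef=b, c_coef=c)


def _check_theorem_assumptions(corr: CorrelationSpec) -> bool:
    return (
        0 < corr.rho_x < 1
        and 0 < corr.rho_y < 1
        and corr.rho_xy != 0
        and corr.rho_x * corr.rho_y - corr.rho_xy**2 >= 0
    )


def m_threshold(corr: CorrelationSpec) -> float:
    """Smallest visit budget admitting an interior optimum.

    Returns ``sqrt((1-rho_y) / ((1-rho_x) rho_xy^2)) + 1``.  For smaller
    ``M`` the optimum sits at the boundary ``S = 1``.
    """
    if corr.rho_xy == 0:
        raise ValueError(
            "threshold undefined for rho_xy = 0 (baselines are uninformative; S_opt = 1)"
        )
    if not (0 < corr.rho_x < 1 and 0 < corr.rho_y < 1):
        raise ValueError("threshold requires 0 < rho_x, rho_y < 1")
    return math.sqrt((1 - corr.rho_y) / ((1 - corr.rho_x) * corr.rho_xy**2)) + 1


def _s_root(m: float, corr: CorrelationSpec) -> float:
    # Stationary point of f from sqrt(A)/(M-S) = sqrt(B rho_x)/(1+rho_x(S-1)).
    # Algebraically identical to the rationalized closed form but the
    # denominator sqrt(B rho_x) + sqrt(A) rho_x is strictly positive, so no
    # special-casing of a vanishing rationalized denominator is needed.
    a = 1 - corr.rho_y
    b_rho = corr.rho_xy**2 * (1 - corr.rho_x)  # B * rho_x
    sqrt_a, sqrt_b = math.sqrt(a), math.sqrt(b_rho)
    return (m * sqrt_b - sqrt_a * (1 - corr.rho_x)) / (sqrt_b + sqrt_a * corr.rho_x)


def s_opt_continuous(m: float, corr: CorrelationSpec) -> float:
    """Real-valued optimal number of baselines for a budget of ``m`` visits.

    Under the interior-optimum assumptions returns the stationary point of
    ``f`` when ``m`` meets :func:`m_threshold`, else 1.  With
    ``rho_xy = 0`` baselines carry no information and 1 is returned.
    """
    if corr.rho_xy == 0:
        return 1.0
    if not _check_theorem_assumptions(corr):
        raise ValueError(
            "closed-form optimum requires 0 < rho_x, rho_y < 1, rho_xy != 0 and "
            "rho_x rho_y >= rho_xy^2; use s_opt_integer for other regimes"
        )
    if m < m_threshold(corr):
        return 1.0
    return _s_root(m, corr)


def _brute_force(m: int, corr: CorrelationSpec) -> int:
    best_s, best_f = 1, objective_f(1, m, corr)
    for s in range(2, m):
        fs = objective_f(s, m, corr)
        if fs < best_f:
            best_s, best_f = s, fs
    return best_s


def s_opt_integer(m: int, corr: CorrelationSpec) -> AllocationSolution:
    """Integer-optimal number of baselines, with exhaustive verification.

    Under the closed-form assumptions the objective is evaluated at the two
    integers bracketing the real optimum and the smaller value wins (ties go
    to the smaller ``S``: fewer baselines at equal efficiency).  The result
    is always verified against — and outside the assumptions obtained by —
    exhaustive search over ``S in [1, M-1]``.
    """
    if m < 2:
        raise ValueError(f"need m >= 2 to allocate at least one pre and one post visit; got {m}")
    if corr.rho_xy != 0 and _check_theorem_assumptions(corr):
        s_real = s_opt_continuous(m, corr)
        feasible = m >= m_threshold(corr)
        method = "closed_form"
    elif corr.rho_xy == 0:
        s_real, feasible, method = 1.0, False, "closed_form"
    else:
        warnings.warn(
            "correlation parameters violate the closed-form assumptions; "
            "falling back to exhaustive search",
            stacklevel=2,
        )
        s_real = float(_brute_force(m, corr))
        feasible = False
        method = "brute_force"

    lo = min(max(math.floor(s_real), 1), m - 1)
    hi = min(max(math.ceil(s_real), 1), m - 1)
    f_lo = objective_f(lo, m, corr)
    f_hi = objective_f(hi, m, corr)
    s_int = lo if f_lo <= f_hi else hi

    exhaustive = _brute_force(m, corr)
    if objective_f(exhaustive, m, corr) < objective_f(s_int, m, corr) - 1e-12:
        # The bracketing argument failed (possible only outside the theorem's
        # assumptions); trust the exhaustive answer.
        s_int = exhaustive
        method = "brute_force"

    return AllocationSolution(
        s_real=float(s_real),
        s_int=int(s_int),
        f_floor=f_lo,
        f_ceil=f_hi,
        feasible=feasible,
        method=method,
    )


def s_opt_equal_correlation(m: float, rho: float) -> float:
    """Real-valued optimum when ``rho_x = rho_y = rho_xy = rho``.

    Reduces to ``M/2 - (1-rho)/(2 rho)`` once ``M >= 1 + 1/rho``; below that
    budget a single baseline is best.
    """
    if rho <= 0:
        raise ValueError("the equal-correlation optimum requires rho > 0")
    if rho >= 1:
        raise ValueError("rho must be below 1")
    if m < 1 + 1 / rho:
        return 1.0
    return m / 2 - (1 - rho) / (2 * rho)
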