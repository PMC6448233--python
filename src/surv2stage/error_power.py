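"""Type I error, power, and critical-value solving for the two-stage design.

The trial stops for futility at the interim when ``Z1 >= c1`` and rejects the
null at the final analysis when it continued and ``Z <= c``; small statistics
favour better-than-historical survival.  Asymptotically ``(Z1, Z)`` is
bivariate normal, so::

    TIE   = P(Z1 <= c1, Z <= c | H0) = Phi2(c, c1; rho0)
    Power = Phi2(c_tilde, c1_tilde; rho1)

where ``Phi2`` is the standard bivariate normal CDF and the tilde boundaries
shift and rescale (c1, c) by the alternative-hypothesis moments::

    c1_tilde = (sigma01/sigma11) * (c1 - omega1*sqrt(n1)/sigma01)
    c_tilde  = (sigma02/sigma12) * (c  - omega *sqrt(n) /sigma02)

``Phi2`` is evaluated through Owen's T function, which is vectorized and
accurate to ~1e-15; an explicit quadrature of the textbook single-integral
form is kept as an independent cross-check.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import integrate
from scipy.special import ndtr, owens_t
from scipy.stats import norm

from .moments import AltMoments, NullMoments

__all__ = [
    "BoundaryPair",
    "bvn_cdf",
    "type_one_error",
    "type_one_error_quad",
    "attained_power",
    "solve_final_critical",
    "InfeasibleBoundaryError",
]


class InfeasibleBoundaryError(ValueError):
    """No finite final critical value can attain the requested level."""


@dataclass(frozen=True)
class BoundaryPair:
    """Interim and final critical values on the standard-normal scale."""

    c1: float
    c: float


def _owen_term(h, a):
    """T(h, a) extended to a = +/-inf and h = 0."""
    h = np.asarray(h, dtype=float)
    a = np.asarray(a, dtype=float)
    finite = np.isfinite(a)
    t = np.where(finite, owens_t(h, np.where(finite, a, 0.0)), 0.0)
    # T(h, +/-inf) = +/- (1 - Phi(|h|)) / 2
    inf_val = np.sign(a) * 0.5 * ndtr(-np.abs(h))
    return np.where(finite, t, inf_val)


def bvn_cdf(h, k, rho: float):
    """Standard bivariate normal CDF ``P(X <= h, Y <= k)`` with correlation rho.

    Vectorized over ``h`` and ``k`` (broadcast together); ``rho`` is a scalar
    with ``|rho| <= 1`` (the limits are handled exactly).
    """
    h = np.asarray(h, dtype=float)
    k = np.asarray(k, dtype=float)
    h, k = np.broadcast_arrays(h, k)
    if not -1.0 <= rho <= 1.0:
        raise ValueError(f"rho must be in [-1, 1], got {rho!r}")
    if rho == 1.0:
        return ndtr(np.minimum(h, k))
    if rho == -1.0:
        return np.maximum(0.0, ndtr(h) + ndtr(k) - 1.0)

    denom = math.sqrt(1.0 - rho * rho)
    hs = np.where(h == 0.0, 1.0, h)  # placeholders; zero rows patched below
    ks = np.where(k == 0.0, 1.0, k)
    with np.errstate(divide="ignore", invalid="ignore"):
        a_h = (k - rho * h) / (hs * denom)
        a_k = (h - rho * k) / (ks * denom)
    # h == 0: the Owen slope degenerates to +/-inf with the sign of k
    # (the h = k = 0 corner is handled by its own closed form below)
    a_h = np.where(h == 0.0, np.where(k >= 0.0, np.inf, -np.inf), a_h)
    a_k = np.where(k == 0.0, np.where(h >= 0.0, np.inf, -np.inf), a_k)

    both_zero = (h == 0.0) & (k == 0.0)
    hk = h * k
    beta = np.where((hk < 0.0) | ((hk == 0.0) & (h + k < 0.0)), 0.5, 0.0)
    val = (
        0.5 * (ndtr(h) + ndtr(k))
        - _owen_term(h, a_h)
        - _owen_term(k, a_k)
        - beta
    )
    val = np.where(both_zero, 0.25 + math.asin(rho) / (2.0 * math.pi), val)
    # infinite boundaries: one vacuous constraint, or an empty region
    val = np.where(np.isneginf(h) | np.isneginf(k), 0.0, val)
    val = np.where(np.isposinf(h), ndtr(k), val)
    val = np.where(np.isposinf(k), ndtr(h), val)
    val = np.clip(val, 0.0, 1.0)
    return val if val.ndim else float(val)


def type_one_error(c1: float, c: float, rho0: float) -> float:
    """P(Z1 <= c1, Z <= c) under H0 for correlation rho0 (bivariate normal)."""
    if math.isinf(c1) and c1 > 0:
        return float(ndtr(c))
    if rho0 >= 1.0:
        return float(ndtr(min(c1, c)))
    return float(bvn_cdf(c, c1, rho0))


def type_one_error_quad(c1: float, c: float, rho0: float) -> float:
    """Cross-check evaluation of the type I error by direct quadrature of

    ``int_{-inf}^{c} phi(t) Phi((c1 - rho0 t)/sqrt(1-rho0^2)) dt``.
    """
    if rho0 >= 1.0:
        return float(ndtr(min(c1, c)))
    denom = math.sqrt(1.0 - rho0 * rho0)

    def integrand(t: float) -> float:
        return norm.pdf(t) * ndtr((c1 - rho0 * t) / denom)

    val, _ = integrate.quad(integrand, -np.inf, c, epsabs=1e-12, epsrel=1e-12)
    return float(val)


def transformed_boundaries(
    c1, c, n1: int, n: int, null_m: NullMoments, alt_m: AltMoments
):
    """Map null-scale boundaries (c1, c) to the alternative scale (c1~, c~)."""
    c1t = (null_m.sigma01 / alt_m.sigma11) * (
        np.asarray(c1, dtype=float) - alt_m.omega1 * math.sqrt(n1) / null_m.sigma01
    )
    ct = (null_m.sigma02 / alt_m.sigma12) * (
        np.asarray(c, dtype=float) - alt_m.omega * math.sqrt(n) / null_m.sigma02
    )
    return c1t, ct


def attained_power(
    c1, c, n1: int, n: int, null_m: NullMoments, alt_m: AltMoments
):
    """Asymptotic power of the design (n1, n, c1, c); vectorized over (c1, c)."""
    if alt_m.sigma11 <= 0 or alt_m.sigma12 <= 0:
        raise ArithmeticError("alternative standard deviations must be positive")
    c1t, ct = transformed_boundaries(c1, c, n1, n, null_m, alt_m)
    return bvn_cdf(ct, c1t, alt_m.rho1)


def solve_final_critical(
    c1: float, rho0: float, alpha: float, tol: float = 1e-8
) -> float:
    """Largest final critical value c with ``type_one_error(c1, c, rho0) <= alpha``.

    The type I error is strictly increasing in c with supremum ``Phi(c1)``, so
    a finite solution requires ``Phi(c1) >= alpha``; otherwise an
    :class:`InfeasibleBoundaryError` is raised.  Bisection on [-10, 10].
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must be in (0, 1), got {alpha!r}")
    if math.isinf(c1) and c1 > 0:
        return float(norm.ppf(alpha))
    if ndtr(c1) < alpha:
        raise InfeasibleBoundaryError(
            f"Phi(c1)={float(ndtr(c1)):.6g} < alpha={alpha}: TIE is capped below alpha"
        )
    lo, hi = -10.0, 10.0
    if type_one_error(c1, hi, rho0) < alpha:  # supremum Phi(c1) == alpha edge
        raise InfeasibleBoundaryError(
            f"type I error cannot reach alpha={alpha} for c1={c1}"
        )
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if type_one_error(c1, mid, rho0) <= alpha:
            lo = mid
        else:
            hi = mid
    return lo


def solve_final_critical_grid(
    c1_grid: np.ndarray, rho0: float, alpha: float, tol: float = 1e-8
) -> np.ndarray:
    """Vectorized bisection of :func:`solve_final_critical` over a c1 grid.

    Entries whose interim boundary cannot attain the level (Phi(c1) < alpha)
    come back as NaN rather than raising.
    """
    c1_grid = np.asarray(c1_grid, dtype=float)
    lo = np.full_like(c1_grid, -10.0)
    hi = np.full_like(c1_grid, 10.0)
    n_iter = int(math.ceil(math.log2(20.0 / tol)))
    for _ in range(n_iter):
        mid = 0.5 * (lo + hi)
        below = bvn_cdf(mid, c1_grid, rho0) <= alpha
        lo = np.where(below, mid, lo)
        hi = np.where(below, hi, mid)
    out = np.asarray(lo, dtype=float)
    return np.where(ndtr(c1_grid) >= alpha, out, np.nan)
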