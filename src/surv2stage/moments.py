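"""Exact moments of the one-sample log-rank numerator with restricted follow-up.

Let ``W1`` and ``W`` denote the normalized log-rank numerators at the interim
analysis (first-stage patients only, calendar time ``t1``) and at the final
analysis (all patients, every one followed to ``t_c``).  With administrative
censoring at the clinically meaningful time ``t_c``, the final censoring
survivor function is ``G(t) = I(t <= t_c)``.  At the interim look a patient
accrued uniformly on ``(0, t1)`` has been followed for a Uniform(0, t1) time,
so the stage-1 censoring survivor function is
``G1(t) = max(0, 1 - t/t1) * I(t <= t_c)``.

Null moments::

    sigma01^2 = Var(W1) = -int_0^tc G1(t) dS0(t)
    sigma02^2 = Var(W)  = -int_0^tc G(t)  dS0(t) = 1 - S0(t_c)
    rho0      = sigma01 / sigma02

Alternative moments (events counted against the null cumulative hazard
``Lambda0`` while times are generated under the alternative ``S1``)::

    p1  = int G  S1 dLambda1       p0  = int G  S1 dLambda0
    p00 = int G  S1 Lambda0 dLambda0
    p01 = int G  S1 Lambda0 dLambda1
    omega = p1 - p0,   E(W) = sqrt(n) * omega

and the exact variance

    sigma12^2 = p1 - p1^2 - p0^2 + 2 p0 p1 + 2 p00 - 2 p01,

with stage-1 analogues (``p1f``, ``p0f``, ``p00f``, ``p01f``, ``omega1``,
``sigma11^2``) obtained by replacing ``G`` with ``G1``; the correlation under
the alternative is ``rho1 = sigma11 / sigma12``.

Normalization convention: ``W1`` is scaled by ``sqrt(n1)`` so that
``E(W1) = sqrt(n1) * omega1`` and ``Var(W1) = sigma01^2``; the correlations
are exactly the variance ratios above, without an additional ``sqrt(n1/n)``
information-fraction factor (see docs/methods.md for discussion).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import integrate

from .survival_model import HypothesisPair, WeibullSurvival

__all__ = [
    "CensoringProfile",
    "NullMoments",
    "AltMoments",
    "null_moments",
    "alt_moments",
    "monte_carlo_moment_oracle",
]

_QUAD_TOL = 1e-10


@dataclass(frozen=True)
class CensoringProfile:
    """Administrative-censoring survivor function for one analysis time.

    ``interim_time=None`` marks the final analysis, where every patient has
    completed the full ``t_c`` of follow-up: ``G(t) = I(t <= t_c)``.  A finite
    ``interim_time = t1`` gives the stage-1 profile
    ``G1(t) = max(0, 1 - t/t1) * I(t <= t_c)``.
    """

    t_c: float
    interim_time: float | None = None

    def __post_init__(self) -> None:
        if self.t_c <= 0:
            raise ValueError(f"t_c must be > 0, got {self.t_c!r}")
        if self.interim_time is not None and self.interim_time <= 0:
            raise ValueError(f"interim_time must be > 0, got {self.interim_time!r}")

    def __call__(self, t: float) -> float:
        if t > self.t_c:
            return 0.0
        if self.interim_time is None:
            return 1.0
        return max(0.0, 1.0 - t / self.interim_time)

    @property
    def upper_limit(self) -> float:
        """Smallest time beyond which the profile vanishes."""
        if self.interim_time is None:
            return self.t_c
        return min(self.t_c, self.interim_time)


@dataclass(frozen=True)
class NullMoments:
    """Variances and correlation of (W1, W) under the null hypothesis."""

    sigma01_sq: float
    sigma02_sq: float
    rho0: float

    @property
    def sigma01(self) -> float:
        return math.sqrt(self.sigma01_sq)

    @property
    def sigma02(self) -> float:
        return math.sqrt(self.sigma02_sq)


@dataclass(frozen=True)
class AltMoments:
    """Mean scale factors, exact variances and correlation under H1.

    ``omega`` and ``omega1`` are the per-sqrt-patient drifts: E(W) =
    sqrt(n)*omega and E(W1) = sqrt(n1)*omega1; both are negative when the
    alternative survival dominates the null (fewer events than expected).
    """

    p1: float
    p0: float
    p00: float
    p01: float
    p1f: float
    p0f: float
    p00f: float
    p01f: float
    sigma11_sq: float
    sigma12_sq: float
    rho1: float

    @property
    def omega(self) -> float:
        return self.p1 - self.p0

    @property
    def omega1(self) -> float:
        return self.p1f - self.p0f

    @property
    def sigma11(self) -> float:
        return math.sqrt(self.sigma11_sq)

    @property
    def sigma12(self) -> float:
        return math.sqrt(self.sigma12_sq)


def _quad(f, upper: float, t1: float | None) -> float:
    """Adaptive quadrature on [0, upper] with a breakpoint at the interim kink."""
    points = None
    if t1 is not None and 0.0 < t1 < upper:
        points = [t1]
    val, err = integrate.quad(
        f, 0.0, upper, points=points, epsabs=_QUAD_TOL, epsrel=1e-10, limit=200
    )
    if not math.isfinite(val) or err > 1e-6:
        raise ArithmeticError(
            f"quadrature failed to converge (value={val!r}, abserr={err!r})"
        )
    return val


def null_moments(pair: HypothesisPair, t1: float) -> NullMoments:
    """Exact null variances of (W1, W) and their correlation.

    ``sigma02^2`` telescopes to ``1 - S0(t_c)``; ``sigma01^2`` is computed by
    quadrature of ``int G1(t) f0(t) dt``.
    """
    profile1 = CensoringProfile(pair.t_c, t1)
    s0: WeibullSurvival = pair.null
    sigma02_sq = 1.0 - s0.survival(pair.t_c)
    upper = profile1.upper_limit
    sigma01_sq = _quad(lambda t: profile1(t) * s0.density(t), upper, t1)
    if not (0.0 < sigma01_sq <= sigma02_sq + 1e-12):
        raise ArithmeticError(
            f"invalid null variances sigma01^2={sigma01_sq}, sigma02^2={sigma02_sq}"
        )
    rho0 = math.sqrt(sigma01_sq / sigma02_sq)
    return NullMoments(sigma01_sq, sigma02_sq, min(rho0, 1.0))


def _p_quantities(pair: HypothesisPair, profile: CensoringProfile):
    """The four p-integrals for a given censoring profile.

    Integration is with respect to ``dLambda1 = h1(t) dt`` or
    ``dLambda0 = h0(t) dt`` where ``h`` is the Weibull hazard.
    """
    s1, s0 = pair.alt, pair.null
    upper = profile.upper_limit
    t1 = profile.interim_time

    def g_s1(t: float) -> float:
        return profile(t) * s1.survival(t)

    p1 = _quad(lambda t: g_s1(t) * s1.hazard(t), upper, t1)
    p0 = _quad(lambda t: g_s1(t) * s0.hazard(t), upper, t1)
    p00 = _quad(lambda t: g_s1(t) * s0.cumhaz(t) * s0.hazard(t), upper, t1)
    p01 = _quad(lambda t: g_s1(t) * s0.cumhaz(t) * s1.hazard(t), upper, t1)
    return p1, p0, p00, p01


def _wu_variance(p1: float, p0: float, p00: float, p01: float) -> float:
    """Exact variance of the normalized log-rank numerator."""
    return p1 - p1**2 - p0**2 + 2.0 * p0 * p1 + 2.0 * p00 - 2.0 * p01


def alt_moments(pair: HypothesisPair, t1: float) -> AltMoments:
    """Exact alternative-hypothesis moments of (W1, W)."""
    final = CensoringProfile(pair.t_c, None)
    interim = CensoringProfile(pair.t_c, t1)
    p1, p0, p00, p01 = _p_quantities(pair, final)
    p1f, p0f, p00f, p01f = _p_quantities(pair, interim)
    sigma12_sq = _wu_variance(p1, p0, p00, p01)
    sigma11_sq = _wu_variance(p1f, p0f, p00f, p01f)
    if sigma12_sq <= 0 or sigma11_sq <= 0:
        raise ArithmeticError(
            f"non-positive variance: sigma11^2={sigma11_sq}, sigma12^2={sigma12_sq}"
        )
    rho1 = math.sqrt(sigma11_sq / sigma12_sq)
    return AltMoments(
        p1=p1, p0=p0, p00=p00, p01=p01,
        p1f=p1f, p0f=p0f, p00f=p00f, p01f=p01f,
        sigma11_sq=sigma11_sq, sigma12_sq=sigma12_sq, rho1=min(rho1, 1.0),
    )


def monte_carlo_moment_oracle(
    pair: HypothesisPair,
    t1: float,
    n1: int,
    n: int,
    theta: float,
    reps: int = 100_000,
    seed: int | None = None,
    hypothesis: str = "alt",
):
    """Empirical moments of (W1, W) by direct simulation of the counting processes.

    Draws ``reps`` trials: stage-1 entry times uniform on (0, t1), stage-2
    uniform on (t1, n/theta); event times Weibull from the null or alternative
    model.  Each patient contributes ``delta_i - Lambda0(O_i)`` to the sums;
    W1 = sum over the first n1 patients at the interim divided by sqrt(n1),
    W = sum over all n patients at the final analysis divided by sqrt(n).

    Returns a dict with means, variances and the correlation of (W1, W),
    each accompanied by a Monte-Carlo standard error where meaningful.
    """
    if reps < 10_000:
        raise ValueError("reps must be >= 10000 for a usable oracle")
    if n > n1 and n / theta < t1:
        raise ValueError(
            f"accrual window inconsistent: total accrual time {n / theta} "
            f"precedes the interim time {t1}"
        )
    rng = np.random.default_rng(seed)
    model = pair.alt if hypothesis == "alt" else pair.null
    t_c = pair.t_c
    t_a = n / theta

    tau = np.empty((reps, n))
    tau[:, :n1] = rng.uniform(0.0, t1, size=(reps, n1))
    if n > n1:
        tau[:, n1:] = rng.uniform(t1, t_a, size=(reps, n - n1))
    T = model.scale * rng.weibull(model.shape, size=(reps, n))

    lam0, k0 = pair.null.scale, pair.null.shape

    # interim: first n1 patients, censored at min(t_c, follow-up so far)
    cens1 = np.minimum(t_c, np.maximum(0.0, t1 - tau[:, :n1]))
    O1 = np.minimum(T[:, :n1], cens1)
    d1 = T[:, :n1] <= cens1
    U1 = d1.sum(axis=1) - ((O1 / lam0) ** k0).sum(axis=1)
    W1 = U1 / math.sqrt(n1)

    # final: all n patients followed through t_c
    O = np.minimum(T, t_c)
    d = T <= t_c
    U = d.sum(axis=1) - ((O / lam0) ** k0).sum(axis=1)
    W = U / math.sqrt(n)

    out = {}
    for name, x in (("W1", W1), ("W", W)):
        out[f"mean_{name}"] = float(x.mean())
        out[f"se_mean_{name}"] = float(x.std(ddof=1) / math.sqrt(reps))
        out[f"var_{name}"] = float(x.var(ddof=1))
        # SE of a sample variance: sqrt((m4 - m2^2)/reps)
        c = x - x.mean()
        m2, m4 = float((c**2).mean()), float((c**4).mean())
        out[f"se_var_{name}"] = math.sqrt(max(m4 - m2**2, 0.0) / reps)
    out["corr"] = float(np.corrcoef(W1, W)[0, 1])
    out["reps"] = reps
    return out
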