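"""Weibull survival models for single-arm trial design.

The survival time ``T`` is assumed Weibull with shape ``k > 0`` and scale
``lambda > 0``::

    S(t) = exp(-(t / lambda)**k)

so the cumulative hazard is ``Lambda(t) = (t/lambda)**k`` and the hazard is
``h(t) = k t**(k-1) / lambda**k``.  The exponential model is the special case
``k = 1``.  Design problems are stated through a null (historical) model and
an alternative (hoped-for) model together with the clinically meaningful
follow-up time ``t_c`` at which the survival probability is judged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "WeibullSurvival",
    "HypothesisPair",
    "scale_from_probability",
    "hazard_ratio",
]


def _check_positive(name: str, value: float) -> None:
    if not (math.isfinite(value) and value > 0):
        raise ValueError(f"{name} must be finite and > 0, got {value!r}")


@dataclass(frozen=True)
class WeibullSurvival:
    """A Weibull survival distribution parameterized by (shape, scale).

    Parameters
    ----------
    shape : float
        Weibull shape parameter ``k > 0``; ``k = 1`` is exponential.
    scale : float
        Weibull scale parameter ``lambda > 0`` in time units.
    """

    shape: float
    scale: float

    def __post_init__(self) -> None:
        _check_positive("shape", self.shape)
        _check_positive("scale", self.scale)

    @classmethod
    def from_probability(
        cls, surv_prob: float, t: float, shape: float = 1.0
    ) -> "WeibullSurvival":
        """Build the model whose survival probability at time ``t`` is ``surv_prob``."""
        return cls(shape=shape, scale=scale_from_probability(surv_prob, t, shape))

    def survival(self, t: float) -> float:
        """S(t) = exp(-(t/scale)**shape)."""
        if t < 0:
            raise ValueError(f"t must be >= 0, got {t!r}")
        return math.exp(-((t / self.scale) ** self.shape))

    def cumhaz(self, t: float) -> float:
        """Cumulative hazard Lambda(t) = (t/scale)**shape = -log S(t)."""
        if t < 0:
            raise ValueError(f"t must be >= 0, got {t!r}")
        return (t / self.scale) ** self.shape

    def hazard(self, t: float) -> float:
        """Hazard function h(t) = shape * t**(shape-1) / scale**shape."""
        if t <= 0:
            if self.shape == 1.0 and t == 0:
                return 1.0 / self.scale
            raise ValueError(f"t must be > 0 for the hazard, got {t!r}")
        return self.shape * t ** (self.shape - 1.0) / self.scale**self.shape

    def density(self, t: float) -> float:
        """Density f(t) = S(t) * h(t)."""
        return self.survival(t) * self.hazard(t) if t > 0 else self.hazard(t)


def scale_from_probability(surv_prob: float, t: float, k: float) -> float:
    """Invert ``S(t) = surv_prob`` for the Weibull scale parameter.

    Returns ``lambda = t / (-log(surv_prob))**(1/k)``; round-trips through
    :meth:`WeibullSurvival.survival` to ``surv_prob`` within 1e-12.
    """
    if not (math.isfinite(surv_prob) and 0.0 < surv_prob < 1.0):
        raise ValueError(f"surv_prob must be in (0, 1), got {surv_prob!r}")
    _check_positive("t", t)
    _check_positive("k", k)
    return t / (-math.log(surv_prob)) ** (1.0 / k)


@dataclass(frozen=True)
class HypothesisPair:
    """A null/alternative pair of Weibull models with a follow-up horizon.

    The one-sided test is H0: S(t_c) <= S0(t_c) against H1: S(t_c) > S0(t_c);
    with a common shape this is H0: HR >= 1 against H1: HR < 1 where
    HR = (lambda0/lambda1)**k.
    """

    null: WeibullSurvival
    alt: WeibullSurvival
    t_c: float

    def __post_init__(self) -> None:
        _check_positive("t_c", self.t_c)

    @classmethod
    def from_probabilities(
        cls,
        s0: float,
        s1: float,
        t_c: float,
        k0: float = 1.0,
        k1: float | None = None,
    ) -> "HypothesisPair":
        """Construct from survival probabilities at ``t_c`` (convenience only;
        the (shape, scale) pairs are the stored truth)."""
        if k1 is None:
            k1 = k0
        return cls(
            null=WeibullSurvival.from_probability(s0, t_c, k0),
            alt=WeibullSurvival.from_probability(s1, t_c, k1),
            t_c=t_c,
        )

    @classmethod
    def from_hazard_ratio(
        cls, s0: float, hr: float, t_c: float, k: float = 1.0
    ) -> "HypothesisPair":
        """Construct from S0(t_c) and a constant hazard ratio (common shape)."""
        if not (0 < hr):
            raise ValueError(f"hazard ratio must be > 0, got {hr!r}")
        null = WeibullSurvival.from_probability(s0, t_c, k)
        # HR = (lambda0/lambda1)**k  =>  lambda1 = lambda0 / HR**(1/k)
        alt = WeibullSurvival(shape=k, scale=null.scale / hr ** (1.0 / k))
        return cls(null=null, alt=alt, t_c=t_c)

    @property
    def constant_hazard_ratio(self) -> float:
        """(lambda0/lambda1)**k for equal shapes; raises otherwise."""
        if self.null.shape != self.alt.shape:
            raise ValueError("hazard ratio is time-dependent when shapes differ")
        return (self.null.scale / self.alt.scale) ** self.null.shape


def hazard_ratio(pair: HypothesisPair, t: float) -> float:
    """Hazard ratio h1(t)/h0(t) with the lambda0-numerator convention.

    For a common shape ``k`` this is the constant ``(lambda0/lambda1)**k``
    (< 1 when the alternative survival is better).  For unequal shapes it is
    the time-dependent ratio
    ``(lambda0**k0 / lambda1**k1) * (k1 t**(k1-1)) / (k0 t**(k0-1))``.
    """
    k0, l0 = pair.null.shape, pair.null.scale
    k1, l1 = pair.alt.shape, pair.alt.scale
    if k0 == k1:
        return (l0 / l1) ** k0
    if t <= 0:
        raise ValueError("hazard ratio undefined at t<=0 when shapes differ")
    return (l0**k0 / l1**k1) * (k1 * t ** (k1 - 1.0)) / (k0 * t ** (k0 - 1.0))
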