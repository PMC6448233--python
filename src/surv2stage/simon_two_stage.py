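"""Simon's exact two-stage designs for a binary endpoint.

A design (n1, r1, n, r) stops for futility after stage 1 when the response
count X1 <= r1 and rejects the null response rate p0 when X1 > r1 and the
total count X > r.  All operating characteristics are exact binomial sums:

    PET(p)    = P(X1 <= r1 | p)
    reject(p) = sum_{x1=r1+1}^{n1} b(x1; n1, p) * P(X2 > r - x1 | n2, p)
    ESS0      = n1 + (1 - PET(p0)) * n2

With an accrual rate theta and a response-assessment window t_c the expected
total study length under the null is

    ETSL0 = (t1 + t_c) + (1 - PET) * (t2 + t_c),      t_i = n_i / theta,

for the classical design (accrual suspends while stage-1 patients complete
their t_c of observation), or, when accrual continues during the interim
assessment,

    ESS0  = n1 + theta*t_c + (1 - PET) * (n2 - theta*t_c)
    ETSL0 = (t1 + t_c) + (1 - PET) * t2.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import binom

__all__ = [
    "SimonDesign",
    "exact_operating_characteristics",
    "search_simon",
    "study_length_metrics",
    "InfeasibleSimonError",
]

logger = logging.getLogger(__name__)


class InfeasibleSimonError(RuntimeError):
    """No two-stage binomial design satisfies the error constraints."""


@dataclass(frozen=True)
class SimonDesign:
    """A two-stage binomial design (n1, r1, n, r) with its null metrics."""

    n1: int
    r1: int
    n: int
    r: int
    p0: float
    p1: float
    pet: float
    ess0: float
    type_i_error: float
    power: float

    @property
    def n2(self) -> int:
        return self.n - self.n1


def exact_operating_characteristics(
    n1: int, r1: int, n: int, r: int, p: float
) -> tuple[float, float]:
    """(rejection probability, PET) of the design at response rate p."""
    if not 0.0 < p < 1.0:
        raise ValueError(f"p must be in (0,1), got {p!r}")
    if not (0 <= r1 <= n1 < n and r1 <= r <= n):
        raise ValueError(f"invalid design ({n1},{r1},{n},{r})")
    n2 = n - n1
    pet = float(binom.cdf(r1, n1, p))
    x1 = np.arange(r1 + 1, n1 + 1)
    if x1.size == 0:
        return 0.0, pet
    pmf1 = binom.pmf(x1, n1, p)
    tail2 = binom.sf(r - x1, n2, p)  # P(X2 > r - x1); sf of negative arg is 1
    return float(np.sum(pmf1 * tail2)), pet


def _reject_matrix(n1: int, n2: int, p: float) -> np.ndarray:
    """reject[r1, r] = P(X1 > r1, X1 + X2 > r) for r1 in 0..n1, r in 0..n.

    Built as a reverse cumulative sum over x1 of pmf(x1) * sf(r - x1).
    """
    n = n1 + n2
    x1 = np.arange(n1 + 1)
    pmf1 = binom.pmf(x1, n1, p)
    # sf_vals[j] = P(X2 > j) for j in -n1..n  (1 for j < 0, 0 for j >= n2)
    j = np.arange(-n1, n + 1)
    sf_vals = np.where(j < 0, 1.0, binom.sf(np.clip(j, 0, None), n2, p))
    # M[x1, r] = pmf1[x1] * P(X2 > r - x1)
    r_idx = np.arange(n + 1)
    M = pmf1[:, None] * sf_vals[(r_idx[None, :] - x1[:, None]) + n1]
    # reject[r1, r] = sum_{x1 > r1} M[x1, r]
    tail = np.flip(np.cumsum(np.flip(M, axis=0), axis=0), axis=0)
    reject = np.zeros((n1 + 1, n + 1))
    reject[:n1, :] = tail[1:, :]
    return reject


def search_simon(
    p0: float,
    p1: float,
    alpha: float,
    beta: float,
    n_cap: int = 150,
) -> dict[str, SimonDesign]:
    """Exhaustive search for Simon's minimax and optimal two-stage designs.

    The minimax design has the smallest total n (ESS0 tie-break); the optimal
    design minimizes the null expected sample size ESS0 across all feasible
    designs with n <= n_cap.  For the reported design at a given (n1, r1) the
    final boundary r is the smallest value with exact type I error <= alpha
    (which maximizes power among alpha-feasible choices).
    """
    if not 0.0 < p0 < p1 < 1.0:
        raise ValueError(f"need 0 < p0 < p1 < 1, got p0={p0!r}, p1={p1!r}")
    minimax: SimonDesign | None = None
    optimal: SimonDesign | None = None
    for n in range(2, n_cap + 1):
        best_at_n: SimonDesign | None = None
        for n1 in range(1, n):
            n2 = n - n1
            pet0 = binom.cdf(np.arange(n1 + 1), n1, p0)
            pet1 = binom.cdf(np.arange(n1 + 1), n1, p1)
            # power <= 1 - PET(p1): r1 values with PET(p1) > beta are hopeless
            r1_ok = pet1 <= beta
            if not r1_ok.any():
                continue
            rej0 = _reject_matrix(n1, n2, p0)
            rej1 = _reject_matrix(n1, n2, p1)
            feasible = (rej0 <= alpha) & (rej1 >= 1.0 - beta) & r1_ok[:, None]
            if not feasible.any():
                continue
            ess0 = n1 + (1.0 - pet0) * n2
            for r1 in np.nonzero(feasible.any(axis=1))[0]:
                if best_at_n is not None and ess0[r1] >= best_at_n.ess0:
                    continue
                # smallest alpha-feasible r maximizes power among valid r
                # (both TIE and power are decreasing in r)
                r_alpha = int(np.argmax(rej0[r1] <= alpha))
                if not feasible[r1, r_alpha]:
                    continue
                best_at_n = SimonDesign(
                    n1=n1, r1=int(r1), n=n, r=r_alpha,
                    p0=p0, p1=p1,
                    pet=float(pet0[r1]), ess0=float(ess0[r1]),
                    type_i_error=float(rej0[r1, r_alpha]),
                    power=float(rej1[r1, r_alpha]),
                )
        if best_at_n is None:
            continue
        if minimax is None:
            minimax = best_at_n
        if optimal is None or best_at_n.ess0 < optimal.ess0:
            optimal = best_at_n
    if minimax is None or optimal is None:
        raise InfeasibleSimonError(
            f"no feasible Simon design with n <= {n_cap} for "
            f"(p0={p0}, p1={p1}, alpha={alpha}, beta={beta})"
        )
    return {"minimax": minimax, "optimal": optimal}


def study_length_metrics(
    design: SimonDesign,
    theta: float,
    t_c: float,
    interim_accrual: bool = False,
) -> tuple[float, float]:
    """(ESS0, ETSL0) of a Simon design under an accrual rate theta.

    ``interim_accrual=True`` lets enrolment continue while the stage-1
    patients complete their t_c of observation; the printed formulas are
    applied as-is, with a warning when n2 < theta*t_c (more patients would
    accrue during the wait than the second stage needs).
    """
    if theta <= 0:
        raise ValueError(f"theta must be > 0, got {theta!r}")
    n1, n2, pet = design.n1, design.n2, design.pet
    t1, t2 = n1 / theta, n2 / theta
    if not interim_accrual:
        ess0 = n1 + (1.0 - pet) * n2
        etsl0 = (t1 + t_c) + (1.0 - pet) * (t2 + t_c)
        return ess0, etsl0
    if n2 < theta * t_c:
        logger.warning(
            "interim accrual overshoots stage 2 (n2=%d < theta*t_c=%.2f); "
            "formulas applied as printed", n2, theta * t_c,
        )
    ess0 = n1 + theta * t_c + (1.0 - pet) * (n2 - theta * t_c)
    etsl0 = (t1 + t_c) + (1.0 - pet) * t2
    return ess0, etsl0
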