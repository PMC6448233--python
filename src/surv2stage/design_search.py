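"""Grid search for two-stage minimax and optimal designs with survival endpoint.

For a design problem (alpha, beta, hypothesis pair, accrual rate theta) the
search enumerates, for each total sample size ``n``, every first-stage size
``n1`` in 1..n-1 and every interim boundary ``c1`` on a grid (default -0.3 to
1.6 in steps of 0.005).  For each (n1, c1) the final boundary ``c`` is the
largest value keeping the asymptotic type I error at or below alpha; the
candidate is kept when the asymptotic power reaches 1-beta.  The best
candidate at each ``n`` minimizes the null expected sample size

    ESS0 = n1 + (1 - PET) * (n - n1),      PET = 1 - Phi(c1),

the minimax design is the first feasible ``n``, the optimal design the global
ESS0 minimizer, and the scan stops once ESS0(n) exceeds 110% of the best seen.
Null expected total study length:

    ETSL0 = t1 + (1 - PET) * (t2 + t_c),   t1 = n1/theta, t2 = (n-n1)/theta

(an early stop ends the study at the interim; a continued trial runs through
accrual plus the full follow-up of the last patient).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import ndtr

from . import error_power, moments
from .survival_model import HypothesisPair

__all__ = [
    "C1Grid",
    "DesignProblem",
    "SurvivalTwoStageDesign",
    "SearchResult",
    "best_design_for_n",
    "search_designs",
    "design_metrics",
    "InfeasibleProblemError",
]

logger = logging.getLogger(__name__)


class InfeasibleProblemError(RuntimeError):
    """No design attains the requested power below the sample-size cap."""


@dataclass(frozen=True)
class C1Grid:
    """Inclusive grid of interim critical values."""

    lo: float = -0.3
    hi: float = 1.6
    step: float = 0.005

    def __post_init__(self) -> None:
        if not (self.lo < self.hi and self.step > 0):
            raise ValueError(f"invalid c1 grid {self!r}")

    def values(self) -> np.ndarray:
        count = int(round((self.hi - self.lo) / self.step)) + 1
        return self.lo + self.step * np.arange(count)


@dataclass(frozen=True)
class DesignProblem:
    """One design search: error rates, hypothesis pair and accrual rate."""

    alpha: float
    beta: float
    pair: HypothesisPair
    theta: float
    c1_grid: C1Grid = field(default_factory=C1Grid)
    n_start: int = 5
    stop_factor: float = 1.10
    n_cap: int = 500

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must be in (0,1), got {self.alpha!r}")
        if not 0.0 < self.beta < 1.0:
            raise ValueError(f"beta must be in (0,1), got {self.beta!r}")
        if self.theta <= 0:
            raise ValueError(f"theta must be > 0, got {self.theta!r}")

    @property
    def t_c(self) -> float:
        return self.pair.t_c


@dataclass(frozen=True)
class SurvivalTwoStageDesign:
    """A two-stage survival-endpoint design and its operating characteristics."""

    n1: int
    n: int
    c1: float
    c: float
    pet: float
    ess0: float
    etsl0: float
    power: float

    @property
    def n2(self) -> int:
        return self.n - self.n1


@dataclass(frozen=True)
class SearchResult:
    minimax: SurvivalTwoStageDesign
    optimal: SurvivalTwoStageDesign
    candidates: dict[int, SurvivalTwoStageDesign]


def design_metrics(
    n1: int, n: int, c1: float, theta: float, t_c: float
) -> tuple[float, float, float]:
    """(PET, ESS0, ETSL0) under the null for a survival two-stage design."""
    pet = float(1.0 - ndtr(c1))
    ess0 = n1 + (1.0 - pet) * (n - n1)
    t1, t2 = n1 / theta, (n - n1) / theta
    etsl0 = t1 + (1.0 - pet) * (t2 + t_c)
    return pet, ess0, etsl0


class _MomentCache:
    """Per-n1 moments and boundary solutions, shared across total sizes n.

    Everything that depends on n1 does so only through the interim calendar
    time t1 = n1/theta, so it is computed once per n1 for the whole search.
    """

    def __init__(self, problem: DesignProblem):
        self.problem = problem
        self.grid = problem.c1_grid.values()
        self._per_n1: dict[int, tuple] = {}
        # final-analysis alternative moments do not depend on n1; take them
        # from any alt_moments call (they use G, not G1)
        self._final: tuple[float, float] | None = None  # (omega, sigma12)
        self.sigma02_sq = 1.0 - problem.pair.null.survival(problem.t_c)

    def for_n1(self, n1: int):
        cached = self._per_n1.get(n1)
        if cached is not None:
            return cached
        p = self.problem
        t1 = n1 / p.theta
        null_m = moments.null_moments(p.pair, t1)
        alt_m = moments.alt_moments(p.pair, t1)
        c_grid = error_power.solve_final_critical_grid(self.grid, null_m.rho0, p.alpha)
        c1t, _ = error_power.transformed_boundaries(
            self.grid, 0.0, n1, 1, null_m, alt_m
        )
        cached = (null_m, alt_m, c_grid, c1t)
        self._per_n1[n1] = cached
        return cached


def _best_for_n(cache: _MomentCache, n: int) -> SurvivalTwoStageDesign | None:
    p = cache.problem
    grid = cache.grid
    target = 1.0 - p.beta
    pet_grid = 1.0 - ndtr(grid)
    best: SurvivalTwoStageDesign | None = None
    for n1 in range(1, n):
        null_m, alt_m, c_grid, c1t = cache.for_n1(n1)
        valid = np.isfinite(c_grid)
        if not valid.any():
            continue
        ct = (null_m.sigma02 / alt_m.sigma12) * (
            c_grid - alt_m.omega * math.sqrt(n) / null_m.sigma02
        )
        power = error_power.bvn_cdf(ct, c1t, alt_m.rho1)
        feasible = valid & (power >= target)
        if not feasible.any():
            continue
        # ESS0 is strictly increasing in c1 at fixed n1, so the first feasible
        # grid point (smallest c1) minimizes ESS0 and settles the c1 tie-break
        idx = int(np.argmax(feasible))
        ess0 = n1 + (1.0 - pet_grid[idx]) * (n - n1)
        if best is None or ess0 < best.ess0:  # strict < keeps the smaller n1 on ties
            pet, ess0, etsl0 = design_metrics(n1, n, float(grid[idx]), p.theta, p.t_c)
            best = SurvivalTwoStageDesign(
                n1=n1, n=n, c1=float(grid[idx]), c=float(c_grid[idx]),
                pet=pet, ess0=ess0, etsl0=etsl0, power=float(power[idx]),
            )
    return best


def best_design_for_n(problem: DesignProblem, n: int) -> SurvivalTwoStageDesign | None:
    """The ESS0-minimizing feasible design B(n) at total size n, or None."""
    if n < 2:
        raise ValueError(f"n must be >= 2, got {n!r}")
    return _best_for_n(_MomentCache(problem), n)


def search_designs(problem: DesignProblem) -> SearchResult:
    """Scan n upward for the minimax and optimal two-stage designs.

    Raises :class:`InfeasibleProblemError` when no design attains the power
    requirement before ``problem.n_cap``.
    """
    cache = _MomentCache(problem)
    candidates: dict[int, SurvivalTwoStageDesign] = {}
    minimax: SurvivalTwoStageDesign | None = None
    best_ess0 = math.inf
    n = max(problem.n_start, 2)
    while n <= problem.n_cap:
        design = _best_for_n(cache, n)
        if design is not None:
            candidates[n] = design
            if minimax is None:
                minimax = design
                logger.info("minimax design found at n=%d (ESS0=%.2f)", n, design.ess0)
            best_ess0 = min(best_ess0, design.ess0)
            if design.ess0 >= problem.stop_factor * best_ess0 and n > minimax.n:
                break
            logger.debug("n=%d ESS0=%.3f", n, design.ess0)
        n += 1
    else:
        if minimax is None:
            raise InfeasibleProblemError(
                f"no feasible design with n <= {problem.n_cap}"
            )
    if minimax is None:
        raise InfeasibleProblemError(f"no feasible design with n <= {problem.n_cap}")
    optimal = min(candidates.values(), key=lambda d: (d.ess0, d.n, d.n1, d.c1))
    return SearchResult(minimax=minimax, optimal=optimal, candidates=candidates)


def search_with_beta(problem: DesignProblem, beta: float) -> SearchResult:
    """Re-run the search at a tightened nominal type-II error."""
    return search_designs(replace(problem, beta=beta))
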