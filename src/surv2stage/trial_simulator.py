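"""Monte-Carlo verification of two-stage survival designs.

Each replicate draws a full single-arm trial: entry times uniform over the
accrual period (the first n1 patients over (0, t1), the rest over (t1, t_a)
with t1 = n1/theta and t_a = n/theta), Weibull event times from the null or
alternative model, administrative censoring at the clinically meaningful
follow-up time t_c.  The interim one-sample log-rank statistic Z1 uses the
first n1 patients at calendar time t1 (each censored at min(t_c, time on
study)); the trial continues iff Z1 < c1, and rejects at the final analysis
(calendar time t_a + t_c, all n patients censored at t_c) iff Z <= c.

The statistic is the classical one-sample log-rank form

    Z = (O - E) / sqrt(E),   O = number of events,  E = sum_i Lambda0(O_i),

with Lambda0 the null cumulative hazard and O_i the observed times.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace as dc_replace

import numpy as np

from .design_search import DesignProblem, SearchResult, SurvivalTwoStageDesign, search_designs
from .survival_model import WeibullSurvival

__all__ = [
    "TrialData",
    "SimSummary",
    "one_sample_logrank",
    "simulate_operating_characteristics",
    "replicate_interval",
    "power_adjustment_loop",
]

logger = logging.getLogger(__name__)

_CHUNK = 20_000  # replicates simulated per numpy block


@dataclass(frozen=True)
class TrialData:
    """Patient-level data of one simulated trial (times from study entry)."""

    entry: np.ndarray       # calendar entry times tau_i
    event_time: np.ndarray  # latent event times T_i
    observed: np.ndarray    # O_i at the analysis in question
    event: np.ndarray       # delta_i = 1 iff O_i == T_i

    def __post_init__(self) -> None:
        n = len(self.entry)
        if not (len(self.event_time) == len(self.observed) == len(self.event) == n):
            raise ValueError("patient arrays must share one length")


@dataclass(frozen=True)
class SimSummary:
    """Monte-Carlo estimate of a design's rejection and early-stop rates."""

    rejection_rate: float
    early_stop_rate: float
    reps: int
    seed: int | None
    interval: tuple[float, float] | None = None


def one_sample_logrank(data: TrialData, null_model: WeibullSurvival) -> float:
    """Z = (O - E)/sqrt(E) with E the expected events under the null model."""
    observed_events = float(np.sum(data.event))
    expected = float(np.sum((data.observed / null_model.scale) ** null_model.shape))
    if expected <= 0.0:
        raise ZeroDivisionError("no expected events: log-rank statistic undefined")
    return (observed_events - expected) / math.sqrt(expected)


def _simulate_block(
    rng: np.random.Generator,
    reps: int,
    design: SurvivalTwoStageDesign,
    problem: DesignProblem,
    model: WeibullSurvival,
) -> tuple[int, int]:
    """(number of rejections, number of early stops) among `reps` trials."""
    n1, n = design.n1, design.n
    theta, t_c = problem.theta, problem.t_c
    t1 = n1 / theta
    lam0, k0 = problem.pair.null.scale, problem.pair.null.shape

    tau1 = rng.uniform(0.0, t1, size=(reps, n1))
    T1 = model.scale * rng.weibull(model.shape, size=(reps, n1))

    # interim analysis at calendar time t1 on the first n1 patients
    cens1 = np.minimum(t_c, t1 - tau1)  # tau1 < t1 so follow-up is positive
    O1 = np.minimum(T1, cens1)
    E1 = ((O1 / lam0) ** k0).sum(axis=1)
    O1_events = (T1 <= cens1).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        Z1 = (O1_events - E1) / np.sqrt(E1)
    undefined = E1 <= 0.0
    if undefined.any():
        logger.warning(
            "%d interim analyses had zero expected events; treated as continue",
            int(undefined.sum()),
        )
    stop = (Z1 >= design.c1) & ~undefined
    cont = ~stop

    n_cont = int(cont.sum())
    rejections = 0
    if n_cont:
        # Stage-2 entries are uniform on (t1, t_a); the final analysis waits
        # until calendar t_a + t_c, so every patient reaches the full t_c of
        # follow-up and the entry times drop out of the final statistic.
        T2 = model.scale * rng.weibull(model.shape, size=(n_cont, n - n1))
        T_all = np.concatenate([T1[cont], T2], axis=1)
        O = np.minimum(T_all, t_c)
        E = ((O / lam0) ** k0).sum(axis=1)
        events = (T_all <= t_c).sum(axis=1)
        Z = (events - E) / np.sqrt(E)
        rejections = int((Z <= design.c).sum())
    return rejections, int(stop.sum())


def simulate_operating_characteristics(
    design: SurvivalTwoStageDesign,
    problem: DesignProblem,
    hypothesis: str = "null",
    reps: int = 100_000,
    seed: int | None = None,
) -> SimSummary:
    """Rejection and early-termination rates of a design by simulation.

    ``hypothesis`` selects the event-time model: ``"null"`` estimates the
    type I error, ``"alt"`` the power.  Reproducible given ``seed``.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    if hypothesis not in ("null", "alt"):
        raise ValueError(f"hypothesis must be 'null' or 'alt', got {hypothesis!r}")
    model = problem.pair.null if hypothesis == "null" else problem.pair.alt
    rng = np.random.default_rng(seed)
    rejections = stops = 0
    done = 0
    while done < reps:
        block = min(_CHUNK, reps - done)
        r, s = _simulate_block(rng, block, design, problem, model)
        rejections += r
        stops += s
        done += block
    return SimSummary(
        rejection_rate=rejections / reps,
        early_stop_rate=stops / reps,
        reps=reps,
        seed=seed,
    )


def replicate_interval(
    design: SurvivalTwoStageDesign,
    problem: DesignProblem,
    hypothesis: str = "null",
    outer: int = 1000,
    inner: int = 10_000,
    seed: int | None = None,
) -> SimSummary:
    """Empirical 95% interval of the rejection rate over repeated estimates.

    Runs ``outer`` independent simulations of ``inner`` replicates each and
    reports the 2.5th/97.5th percentiles of the outer estimates around the
    pooled point estimate.
    """
    if outer < 2:
        raise ValueError("outer must be >= 2")
    seeds = np.random.SeedSequence(seed).spawn(outer)
    rates = np.empty(outer)
    stop_rates = np.empty(outer)
    for i, ss in enumerate(seeds):
        rng = np.random.default_rng(ss)
        model = problem.pair.null if hypothesis == "null" else problem.pair.alt
        r, s = _simulate_block(rng, inner, design, problem, model)
        rates[i] = r / inner
        stop_rates[i] = s / inner
    lo, hi = np.percentile(rates, [2.5, 97.5])
    return SimSummary(
        rejection_rate=float(rates.mean()),
        early_stop_rate=float(stop_rates.mean()),
        reps=outer * inner,
        seed=seed,
        interval=(float(lo), float(hi)),
    )


def power_adjustment_loop(
    problem: DesignProblem,
    reps: int = 100_000,
    seed: int | None = None,
    max_adjust: int = 20,
) -> tuple[SearchResult, int]:
    """Search, verify power by simulation, tighten beta by 1% until both pass.

    The asymptotic bivariate-normal power can overstate the finite-sample
    power; when the simulated power of the minimax or the optimal design falls
    below the original nominal level 1 - beta, the search is repeated at
    (alpha, beta - 0.01*j) for j = 1, 2, ... .  Returns the final search
    result and the number of adjustments j.
    """
    nominal_power = 1.0 - problem.beta
    ss = np.random.SeedSequence(seed)
    for j in range(max_adjust + 1):
        beta_j = problem.beta - 0.01 * j
        if beta_j <= 0.0:
            raise InfeasibleAdjustmentError(
                f"beta - 0.01*{j} <= 0: power cannot be guaranteed"
            )
        result = search_designs(dc_replace(problem, beta=beta_j))
        child = ss.spawn(2)
        ok = True
        for design, child_seed in zip((result.minimax, result.optimal), child):
            summary = simulate_operating_characteristics(
                design, problem, hypothesis="alt", reps=reps,
                seed=int(child_seed.generate_state(1)[0] % (2**31)),
            )
            if summary.rejection_rate < nominal_power:
                ok = False
                break
        if ok:
            return result, j
    raise InfeasibleAdjustmentError(
        f"power not guaranteed after {max_adjust} beta adjustments"
    )


class InfeasibleAdjustmentError(RuntimeError):
    """The beta-tightening loop cannot reach the nominal power."""
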