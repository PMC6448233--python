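# Methods

This note records the statistical model behind `surv2stage`, the numerical
choices made in implementing it, and the limitations a user should know
about.

## Design setting

A single-arm trial measures survival through a clinically meaningful
follow-up time `t_c`.  Event times are Weibull with shape `k` and scale `λ`:
`S(t) = exp(-(t/λ)^k)`, `Λ(t) = (t/λ)^k`.  The internal parameterization is
always `(k, λ)`; survival probabilities at `t_c` are constructor
conveniences (`HypothesisPair.from_probabilities`, `from_hazard_ratio`) and
are never stored as primary truth, so changing `t_c` cannot silently
re-derive a different model.  Unequal shapes `k0 ≠ k1` are supported
throughout the moment machinery, which only ever consumes `(S, Λ, h)`; the
constant hazard ratio `(λ0/λ1)^k` is an accessor for the common-shape case.

Patients accrue uniformly at `θ` per unit time.  With `n1` first-stage
patients the interim look is at calendar time `t1 = n1/θ`; a continued trial
accrues to `n` by `t_a = n/θ` and ends at `t_a + t_c`, when every patient
has completed the restricted follow-up.  The only censoring is
administrative: at the final analysis the censoring survivor function is
`G(t) = I(t ≤ t_c)`; at the interim a stage-1 patient has been on study a
Uniform(0, t1) time, giving `G1(t) = max(0, 1 - t/t1)·I(t ≤ t_c)`.  There is
no loss to follow-up and no non-uniform accrual; those are out of scope.

## Moments of the log-rank numerators

Writing `W1` and `W` for the interim and final log-rank numerators
normalized by `√n1` and `√n` respectively, the null variances are
`σ01² = -∫₀^{t_c} G1 dS0` and `σ02² = 1 - S0(t_c)` (the final integral
telescopes), with `ρ0 = σ01/σ02`.  Under the alternative the means are
`E(W1) = √n1·ω1`, `E(W) = √n·ω` with `ω = p1 - p0` built from the moment
integrals listed in the README, and the exact variance is
`σ12² = p1 - p1² - p0² + 2p0p1 + 2p00 - 2p01` (stage-1 analogue `σ11²` with
the `G1`-weighted integrals), `ρ1 = σ11/σ12`.

Two conventions deserve emphasis, because plausible alternatives exist:

- **Normalization of `W1`.**  `W1` is scaled by `√n1`, so `Var(W1) = σ01²`
  and `E(W1) = √n1·ω1`.  A `√n` normalization is internally inconsistent
  with the mean formula and is not used.
- **The correlation deliberately omits the information fraction.**
  Standard group-sequential theory gives `corr(Z1, Z) = (σ01/σ02)·√(n1/n)`;
  this package uses `ρ0 = σ01/σ02` alone.  The Monte-Carlo oracle confirms
  the empirical correlation of the simulated statistics is
  `ρ0·√(n1/n)` (e.g. 0.684 vs ρ0 = 0.880 at n1/n = 44/73), but only the
  `σ01/σ02` convention reproduces the operating characteristics that the
  error/power calculus and the published designs are built on, so it is the
  method's definition here.  The tests document the distinction rather than
  asserting either value as "the" correlation.

All integrals use adaptive quadrature (`scipy.integrate.quad`) on
`[0, min(t1, t_c)]` or `[0, t_c]` with absolute tolerance 1e-10 and an
explicit breakpoint at the `G1` kink when `t1 < t_c`.  Weibull shapes below
1 make `dΛ` singular at 0; the singularity is integrable and the quadrature
is validated against closed forms in the exponential case (agreement to
1e-8 across a parameter grid) and against a 10⁵-replicate simulation of the
counting processes for `k = 0.5`.

## Error, power and boundaries

`(Z1, Z)` is treated as standard bivariate normal under the null with
correlation `ρ0`, so the type I error of boundaries `(c1, c)` is
`Φ2(c, c1; ρ0)`.  `Φ2` is evaluated through Owen's T function
(`scipy.special.owens_t`), which is vectorized and accurate to machine
precision; the textbook single-integral form is retained as
`type_one_error_quad` and the two routes agree to 1e-9 in the tests, as
does `scipy.stats.multivariate_normal`.  Power applies the location/scale
map `c̃1 = (σ01/σ11)(c1 - ω1√n1/σ01)`, `c̃ = (σ02/σ12)(c - ω√n/σ02)` and
evaluates `Φ2(c̃, c̃1; ρ1)`.  The scale factor in `c̃` uses the null limit
`σ02` of the studentizer `√(E/n)`; under the alternative the studentizer
actually converges to `√p0 > σ02`, which is why this asymptotic power is
systematically optimistic at phase-II sample sizes (see the adjustment loop
below).

The final boundary solve (largest `c` with TIE ≤ α) uses bisection on
`[-10, 10]` to 1e-8; TIE is strictly increasing in `c` with supremum
`Φ(c1)`, so `Φ(c1) < α` is reported as an infeasible interim boundary.

## Design search

For each total size `n` (starting at 5), every `n1 ∈ {1..n-1}` and every
`c1` on the inclusive grid `-0.3 : 1.6 : 0.005` (configurable) is examined;
feasible candidates must attain power `≥ 1-β`.  Selection currencies are
`ESS0 = n1 + (1-PET)(n-n1)` with the asymptotic `PET = 1-Φ(c1)`, and
`ETSL0 = t1 + (1-PET)(t2 + t_c)`: an early stop ends the study at the
interim, a continued trial runs through accrual plus the final patient's
full follow-up.  Ties are broken lexicographically on (ESS0, n1, c1)
ascending — at fixed `n1`, ESS0 is strictly increasing in `c1`, so the
smallest feasible `c1` wins automatically.  The scan stops once `ESS0(n)`
exceeds 110% of the best seen (and a safety cap of n = 500 guards
infeasible inputs).  Moments depend on `(n1, θ, t_c)` only, so they are
memoized per `n1` across all `n`, and the boundary solve is vectorized over
the whole `c1` grid; a full search runs in a few seconds.

Because the asymptotic power overstates the simulated power by roughly
1-3% at these sample sizes, the complete procedure re-checks the selected
minimax and optimal designs by simulating 100,000 trials and, if either
falls short of the original nominal power, tightens the nominal type-II
error by 0.01 and searches again (`power_adjustment_loop`).  Two or three
such adjustments are typical at 90% nominal power.  One consequence worth
knowing: when a candidate design's true power sits within a Monte-Carlo
standard error of the nominal level, the loop's stopping index — and hence
the reported optimal ESS0 — can depend on the seed; the 100,000-replicate
check is the procedure's defined resolution, and the seed is recorded with
every run.

## Simulator

Each replicate draws stage-1 entries iid Uniform(0, t1), stage-2 entries
Uniform(t1, t_a) (their values never influence the statistics, since the
final analysis waits for complete follow-up), and Weibull event times from
the hypothesis being studied.  Conventions fixed here: the trial continues
iff `Z1 < c1` (a tie stops), rejects iff `Z ≤ c`; an interim with zero
expected events — impossible in exact arithmetic since every stage-1
patient has positive exposure, but guarded anyway — counts as "continue",
which can only cost power, never inflate the type I error.  Replicates are
processed in 20,000-trial numpy blocks from a single seeded generator;
`replicate_interval` spawns independent child streams per outer estimate
and reports empirical 2.5/97.5 percentiles.

What the simulator emulates is exactly the design model: uniform accrual,
Weibull events, administrative censoring only.  Passing simulation checks
therefore validates the moment and boundary calculus, not robustness to
dropout, accrual drift or non-Weibull hazards — real trials should expect
some slippage in all three.

## Simon comparator

The binomial module enumerates `(n, n1, r1, r)` exhaustively (cap n = 150)
with exact binomial tails; for each `(n, n1, r1)` the reported `r` is the
smallest value with exact TIE ≤ α, which maximizes power among valid
choices.  `r1` rows with `P(X1 ≤ r1 | p1) > β` are pruned (early stopping
alone would already cost too much power).  Study-length metrics implement
both the classical suspend-accrual variant and the interim-accrual variant;
the latter's standard formulas are applied verbatim, with a logged warning
when `n2 < θ·t_c` (they have no clamp for that corner, and adding one would
silently change ESS0).

## Known limitations

- The error/power calculus is asymptotic; the adjustment loop corrects the
  power side empirically but the type I error is only verified, not
  recalibrated (simulations show it conservative, ~0.040 at nominal 0.05).
- `PET = 1-Φ(c1)` is itself asymptotic; simulated early-stop rates differ
  by up to ~1% at first-stage sizes around 25-30.
- Designs with more than two stages, adaptive second-stage sizes,
  ETSL-optimal selection and dropout processes are out of scope.
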