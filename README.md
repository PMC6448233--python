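# surv2stage

Two-stage single-arm phase II trial designs with a **survival endpoint under
restricted follow-up**, built on the one-sample log-rank test with exact
moment calculations, together with Simon's exact binomial two-stage designs
as comparators.

## Who this is for

Biostatisticians designing early-phase oncology trials in which the primary
outcome is survival through a clinically meaningful time `t_c` (say,
one-year progression-free survival) rather than a binary response.  Unlike a
binomial two-stage design, a survival-endpoint design needs no accrual
suspension at the interim: patients keep only the follow-up they have
accumulated by the interim look, which shortens the expected total study
length.

## The model and test

Survival times are Weibull, `S(t) = exp(-(t/λ)^k)`, with a null (historical)
model `(k, λ0)` and an alternative `(k, λ1)`; for a common shape the hazard
ratio `Δ = (λ0/λ1)^k` is constant and the one-sided test is
`H0: S(t_c) ≤ S0(t_c)` vs `H1: S(t_c) > S0(t_c)`.

Patients accrue uniformly at rate `θ`.  The interim analysis happens at
calendar time `t1 = n1/θ` using the first `n1` patients, each
administratively censored at `min(t_c, time on study)`; the final analysis
uses all `n` patients followed through `t_c`.  Both analyses use the
one-sample log-rank statistic

```
Z = (O - E) / sqrt(E),    O = # events,    E = Σ_i Λ0(O_i),
```

small values favouring better-than-historical survival.  The trial stops for
futility when `Z1 ≥ c1`, and rejects `H0` when it continued and `Z ≤ c`.

The joint law of `(Z1, Z)` is treated as bivariate normal.  Its exact
ingredients come from the censoring survivor functions `G(t) = I(t ≤ t_c)`
(final) and `G1(t) = max(0, 1 - t/t1)·I(t ≤ t_c)` (interim, reflecting
uniform accrual): null variances `σ01² = -∫G1 dS0`, `σ02² = 1 - S0(t_c)`,
correlation `ρ0 = σ01/σ02`, and under the alternative the drifts
`E(W) = √n·ω` with `ω = p1 - p0` and the exact variance

```
σ12² = p1 - p1² - p0² + 2·p0·p1 + 2·p00 - 2·p01
```

built from the moment integrals `p1 = ∫G·S1 dΛ1`, `p0 = ∫G·S1 dΛ0`,
`p00 = ∫G·S1·Λ0 dΛ0`, `p01 = ∫G·S1·Λ0 dΛ1` (stage-1 analogues use `G1`).

The search enumerates `(n1, c1)` over a grid, solves for the largest final
boundary `c` holding the type I error at `α`, keeps power-feasible
candidates, and selects the **minimax** design (smallest `n`) and the
**optimal** design (smallest null expected sample size
`ESS0 = n1 + (1-PET)(n-n1)`, `PET = 1-Φ(c1)`).  Because the bivariate-normal
approximation can overstate finite-sample power, a final verification step
simulates 100,000 trials and, if either selected design misses the nominal
power, tightens the nominal level by 1% and repeats.

## Worked example

A resectable pancreatic cancer trial: null one-year survival 35%, promising
survival 50%, 90% power at one-sided 10%, accrual 24 patients/year.

```
$ surv2stage search --alpha 0.10 --beta 0.10 --tc 1 --s0 0.35 --s1 0.50 \
      --accrual 24 --seed 0 --adjust
power adjustments: 2
 design  n1  n     c1         c      PET      ESS0    ETSL0    power
minimax  44 73  0.240 -1.281290 0.405165 61.250211 3.146927 0.920016
optimal  41 79 -0.085 -1.278569 0.533869 58.712966 2.912504 0.920011
```

The minimax design enrols 44 patients, looks at calendar time 44/24 ≈ 1.83
years, stops for futility when `Z1 ≥ 0.240` (40.5% probability under the
null), and otherwise continues to 73 patients, rejecting when `Z ≤ -1.281`.
Under the null it costs 61.3 patients and 3.15 years on average; the
`--adjust` flag reports that the nominal power level had to be tightened
twice (to 92%) before the simulated power cleared 90%.

The binomial comparator for the same trial:

```
$ surv2stage simon --p0 0.35 --p1 0.50 --alpha 0.10 --beta 0.10 --accrual 24 --tc 1
 design  n1  r1  n  r      PET      ESS0  type_i_error    power    ETSL0
minimax  43  14 72 30 0.436526 59.340744      0.095083 0.900013 4.036005
optimal  34  12 81 33 0.591942 53.178724      0.099335 0.901789 3.623838
```

Simon's minimax design needs a similar number of patients (ESS0 59.3 vs
61.3) but, because accrual suspends while stage-1 patients complete their
year of follow-up, a materially longer expected study: 4.04 vs 3.15 years.

Operating characteristics of any design can be verified by simulation:

```
$ surv2stage simulate --alpha 0.05 --beta 0.10 --tc 1 --s0 0.5 --hr 0.5 \
      --accrual 15 --design 28,52,-0.10,-1.64 --hypothesis alt --seed 1
```

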