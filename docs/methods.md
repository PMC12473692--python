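# Methods

## The demographic model

`agestage` implements the age-stage, two-sex life table of Chi & Liu for
cohorts followed by daily census from oviposition to death. The raw datum is
one row per individual per day: developmental stage, alive/dead, sex
(assigned morphologically at pupation; individuals dying earlier are retained
as *undetermined*), and eggs laid that day for adult females. Unlike
female-only life tables, both sexes and all pre-adult deaths stay in the
denominator, so the parameters describe the whole cohort of N eggs.

With `s_xj = n_xj / N` the probability that a newborn is alive and in stage
`j` at age `x` (the adult stage split into female and male columns):

- age-specific survival `l_x = Σ_j s_xj`;
- age-stage fecundity `f_xj` = mean eggs laid per individual in `(x, j)`
  (nonzero only in the adult-female column), and
  `m_x = Σ_j s_xj f_xj / Σ_j s_xj`;
- net reproductive rate `R0 = Σ_x l_x m_x`;
- intrinsic rate of increase `r` solving the Euler–Lotka equation
  `Σ_x exp(−r (x+1)) l_x m_x = 1` with ages indexed from 0 and an end-of-day
  census, i.e. the Goodman/Chi `(x+1)` exponent convention — **not**
  `exp(−r x)`;
- finite rate `λ = e^r`; mean generation time `T = ln(R0)/r`.

Life expectancy `e_xj` and reproductive value `v_xj` propagate a unit of
survival mass forward from `(x, j)` through the empirical age-stage
transition frequencies (stay / develop / die, with the pupa→adult transition
branching by sex):

- `e_xj = Σ_{i≥x} Σ_y s'_iy`, counting the current day plus expected future
  days, so that `e_{0,egg}` equals the mean observed lifespan **exactly**;
- `v_xj = exp(r(x+1)) Σ_{i≥x} exp(−r(i+1)) Σ_y s'_iy f_iy`, which satisfies
  the algebraic identity `v_{0,egg} = λ` on any cohort in which every
  individual starts in the first stage at age 0.

Because the transition frequencies are the empirical conditional
frequencies, forward propagation from `(0, egg)` reproduces the marginal
`s_xj` exactly; the identities above (together with
`R0 = (adult females / N) × mean lifetime eggs per adult female`) therefore
hold to machine precision on every cohort and are enforced by the test
suite. Cells never occupied are reported masked, not zero-filled. Ages
beyond the last death are truncated; there is no tail extrapolation.

### Numerical choices

The Euler left-hand side is strictly decreasing in `r`, so the root is
unique whenever `R0 > 0`. The solver works on the *logarithm* of the sum
(max-shifted), which cannot overflow for any bracket; the bracket starts at
[−1, 1] and doubles outward as needed, and Brent's method polishes the root
to `xtol = 1e−14`. The residual at the returned root is checked against
1e−10 (tests assert < 1e−9 end to end). `r` is undefined at `R0 = 0` (error
or NaN depending on the entry point); `r < 0` is legitimate for declining
cohorts (`0 < R0 < 1`); `T` is flagged undefined at `r = 0`.

The engine is stage-list agnostic: collapsing the four larval instars into
one stage relabels rows of the same individual histories, leaves `l_x` and
`m_x` unchanged, and therefore leaves R0, r, λ and T bit-identical (tested).

## Bootstrap inference

The resampling unit is the individual (the egg), keeping each life history
intact, which is the standard two-sex bootstrap: parameters are functionals
of individual histories. Replicate `b` draws its N-with-replacement indices
from the sub-seeded stream `(seed, b)`, so runs on different cohorts of equal
N with the same seed have aligned replicate streams. The default is
B = 100 000 replicates, the convention of large published life-table
analyses; tests and the analysis scripts use B = 1000–2000, at which SEs are
stable to a few percent (CI widths scale as expected with B). Reported SEs
are the standard deviations of the replicate distributions (the usual
TWOSEX-style convention; whether published ± values are SDs of replicates or
SEs of means is rarely stated, so this choice is documented rather than
claimed). Replicates with no surviving reproducing female have `R0 = 0` and
undefined `r`, `λ`, `T`; they are recorded as missing, counted, and excluded
from the affected summaries.

The paired bootstrap test compares two cohorts on the aligned replicate
differences `d_b = a_b − b_b`:
`p = 2 · min(P(d ≤ 0), P(d ≥ 0))` estimated with add-one smoothing
`(k+1)/(n+1)` and capped at 1. The construction is percentile-based because
the reference implementation's internal formula is unpublished; it is
antisymmetric under order swap and gives `d ≡ 0, p = 1` for self-comparison.
For more than two groups, all pairwise tests are Holm-adjusted at α = 0.05
and summarised as a compact letter display (letters = maximal cliques of the
non-significance graph, ordered by descending mean).

## Bioassay statistics

- **Abbott's correction** `100·(p_t − p_c)/(1 − p_c)` adjusts treatment
  mortality for natural control mortality; negative values (treatment below
  control) are reported as-is with a warning. The pipeline corrects
  replicate-mean daily series and restores cumulativity with a running
  maximum, since day-wise correction can wobble when control deaths
  fluctuate.
- **Time–mortality** uses the three-parameter logistic
  `Y = K/(1 + exp(a − bX))` fitted by bounded nonlinear least squares
  (`K ∈ (0, 100]`), initialised from the observed maximum and a
  log-linearised interior regression. `LT50 = (a − ln(K/50 − 1))/b` exists
  only when the asymptote K exceeds 50%; lower-plateau fits return an
  undefined result carrying the reason (the "—" convention of bioassay
  tables), never an exception. The LT50 CI is a delta-method interval on the
  (K, a, b) covariance — published CIs of this kind rarely state their
  method, so no numerical agreement with any published interval is claimed.
- **Dose–response** uses maximum-likelihood probit regression on
  log10(concentration) (statsmodels GLM), `LC50 = 10^(−intercept/slope)`,
  with a Fieller 95% CI for the ratio and a Pearson χ² heterogeneity
  statistic. All-or-nothing response at every dose raises a separation
  error; a non-positive slope is returned flagged invalid.
- **Group comparison** applies the arcsine-square-root transform to
  percentage data (0% and 100% map to 0 and π/2), one-way ANOVA, all-pairs
  LSD t-tests on the transformed scale, Holm correction, and letters.

## The synthetic cohort generator

No individual-level rearing records of the motivating study system
(*Tuta absoluta* on control vs *Beauveria bassiana*-colonized tomato) are
public, so the generator produces cohorts with the statistical structure the
analysis assumes, parameterised from the published treatment-level summaries:

- **Stage durations** (egg, four instars, pupa) and **adult longevities**:
  discretized gamma (round to nearest day, floor 1 day), means set to the
  published stage means; individual-level CVs are back-derived from
  published SEs (`SD ≈ SE·√n`) — SEs describe means, not individuals, so
  these CVs are declared defaults, not facts.
- **Daily survival** per pre-adult stage: stage-level survival allocated as
  egg 0.95 × larva × pupa 0.95 (0.93 in the treatments, which concentrate
  extra mortality in the larval window, reproducing the published sharp
  survival decline at days 5–15), constrained so the product equals the
  published probabilities of reaching adulthood (0.6267 control, 0.36
  foliar-spray, 0.3714 root-irrigation), then converted to per-day rates via
  `s^(1/mean duration)`. Mortality acts on each occupied day after the
  development draw, so realized durations are censoring-consistent.
- **Sex** is Bernoulli(0.5) at pupation (≈1:1 published sex ratio).
- **Fecundity**: lifetime totals are negative binomial with the published
  means (147.82 / 112.07 / 124.79 eggs per female) and dispersion
  back-derived from the published SEs (k ≈ 35 control, ≈ 10 treatments);
  laying starts one day after emergence and follows a triangular daily
  profile with a finite tail, calibrated so the population fecundity `m_x`
  peaks near days 24 / 23 / 25 as published. A female lays her entire drawn
  total before death (all-eggs-before-death simplification), which gives the
  generative process a closed-form net reproductive rate
  `R0 = P(female) · E[eggs] · Π_s E[p_s^{D_s}]`, evaluated exactly by
  `analytic_r0` from the discretized duration laws — the ground truth used
  in bootstrap-coverage tests.

What the generator does **not** emulate: correlations between development
speed, longevity and fecundity within individuals; age-dependent adult
mortality interacting with laying (eggs are never censored by early death);
density or maternal effects; observation error in the daily census. Passing
tests therefore demonstrate the correctness of the estimators and the
qualitative treatment contrasts under the published magnitudes, not the
numerical values of any real cohort's parameters — with N = 100 per
treatment, a single cohort's R0 has a sampling SE near 7, so published point
values are not reproducible targets even in expectation.

The bioassay generator draws binomial final mortality from a probit
dose-response combined independently with control mortality, and spreads
each replicate's deaths over the 14 daily censuses along a logistic-in-time
CDF.

## Problem sizes

Analysis scripts and tests use N = 100 cohorts and B = 1000–2000 bootstrap
replicates; coverage checks use 200 simulation repetitions, probit recovery
100 assays, and ordering checks 40 paired seeds. These sizes keep each check
to seconds-to-a-minute on one CPU while leaving Monte-Carlo error well
inside the asserted bands.

## Known limitations

- The percentile paired-test p-value is one specific construction; a
  normal-approximation variant would differ in the far tails.
- Fieller intervals are undefined when the slope is not distinguishable from
  zero (`g ≥ 1`); the fit then reports no CI rather than an unbounded one.
- `e_xj`/`v_xj` are conditional on the empirical transition table and hence
  undefined (masked) in never-occupied cells; they are descriptive, not
  model-smoothed.
- Censoring (escaped or removed individuals) is reserved in the data model
  but rejected by the default validator, matching studies that follow every
  individual to death.
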