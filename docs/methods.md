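# Methods

## The life-cycle model

Polar bears reproduce on an approximately three-year cycle: cubs stay
with their mother for about two and a half years, so a successful
mother is unavailable to breed for two seasons after whelping. The
model makes this cycle explicit rather than collapsing it into a
one-year Leslie matrix. The state space is

- independent bears by sex and whole-year age 0–30, and
- family units by mother age, litter age *y* ∈ {0 = cub-of-year,
  1 = yearling, 2 = two-year-old} and litter composition
  (*k_f*, *k_m*) with 1 ≤ *k_f* + *k_m* ≤ 3.

Age 30 is an absorbing "30+" class sharing the adult rates; this makes
survival 1 imply growth exactly 1 and matches the usual terminal-class
convention of age-structured models. Survival is parameterized by sex
and age class — cub-of-year (0), yearling (1), subadult (2–4), adult
(5+) — the granularity at which such rates are typically estimated
from mark–recapture studies; a "natural" variant excludes and a
"total" variant includes human-caused mortality.

### Annual event order

The census is taken just after the birth pulse. Within each year:

1. **Survival.** Every bear survives with its class rate. A dead
   mother's dependent young die with her (orphans of dependent age do
   not survive alone). Surviving dependent young die or persist
   independently of one another, giving a binomial
   composition-transition for each litter.
2. **Litter fate.** A mother whose entire litter has died returns to
   the available pool, but only from the following census — she does
   not breed in the same year she lost the litter.
3. **Aging and dispersal.** Ages advance one year. Two-year-old young
   disperse, entering the independent population at age three, and
   their mother rejoins the breeding pool immediately — this is the
   "female with dispersing two-year-old cubs" case of the
   litter-production definition, so she can whelp in this year's birth
   pulse.
4. **Reproduction.** Each available female of age *x* produces a
   litter with probability LPR(*x*). Litter size is drawn from the
   minimal two-point distribution on {1, 2, 3} bracketing the mean;
   cub sexes are independent Bernoulli (female probability 0.5 by
   default).
5. **Harvest** (stochastic engine only; see below).

The within-year placement of harvest after reproduction, and the
one-year wait after whole-litter loss, are conventions: the biology
constrains neither strongly, and both are documented here so results
are interpretable. The dependency rules themselves (orphan death,
mother released by litter loss or dispersal) are what make the cycle a
three-year cycle.

### Deterministic quantities

The expectation of the cycle is linear in the state, so the
deterministic growth rate λ is the dominant eigenvalue of the expanded
state-transition matrix. It is computed by power iteration on the
annual map (L1 tolerance 1e-10, cap 10,000 iterations; failure to
converge signals degenerate rates such as all-zero survival). A dense
matrix built by pushing unit vectors through the map is exposed for
cross-checks and agrees with the power iteration to better than 1e-6
in the test suite; the stable age distribution likewise matches the
dominant eigenvector.

## The stochastic engine

### Uncertainty model

Each rate estimate θ̂ with standard error SE is realized per iteration
and year as

    θ = θ̂ + √p·SE·z_run + √(1−p)·SE·z_year

where *p* (default 0.75) is the fraction of total variance treated as
parameter uncertainty (how wrong the estimated mean may be — one draw
per Monte Carlo iteration) and 1−*p* as environmental variance
(year-to-year fluctuation — redrawn annually). Under correlation mode
R0, deviates are independent per parameter (and per parameter-year for
the environmental component); under R1 a single standard-normal
deviate is shared by all parameters at each level. Realized
probabilities are clipped to [0, 1] and litter size to [1, 3]; clip
events are tallied per run so the bias introduced by clipping (which
grows with SE) is observable rather than silent. The normal-with-
clipping form is the minimal distributional reading of a mean/SE
table; no distribution beyond that is assumed.

### Demographic stochasticity and harvest

Counts evolve by per-class binomial and multinomial draws, which are
distributionally identical to per-individual Bernoulli trials.
The initial abundance is a rounded normal deviate N(N̂, SE) (exact
when SE = 0), allocated to state cells by drawing whole family units
from the initial distribution and balancing to the exact total with
single independent bears.

Annual removals may be fractional (multi-year means): the integer part
is removed and the remainder with matching Bernoulli probability,
which is unbiased. The total is split binomially into a female share
(with the observed female proportion of the kill) and a male share;
within each sex, victims are drawn without replacement proportional to
standing numbers (multivariate hypergeometric), with an optional
(sex, age-class) selectivity table. By default **family groups are
protected**: only independent bears of age ≥ 1 are vulnerable,
mirroring the standard harvest regulation that exempts females with
dependent cubs. With protection disabled, mothers and their dependent
yearlings/two-year-olds join the pool and a harvested mother's young
die as orphans (not counted against the quota) — under that rule
effective removals exceed the quota whenever mothers are taken, which
measurably depresses growth below the nominal sustainable-yield
balance.

### Truncation

A run is truncated — N set to zero for the remainder of the horizon —
when (i) the initial deviate is nonpositive, (ii) all individuals die,
or (iii) either sex cannot supply its share of the quota. Causes are
recorded per run but pooled into a single truncation proportion for
reporting. The fraction of initial-deviate truncations equals
Φ(−N̂/SE) in expectation; the test suite checks this across a grid.

### Reproducibility

Each iteration runs on its own generator spawned from the master seed
(`numpy` SeedSequence), so an ensemble is bitwise-reproducible from
(inputs, seed) and independent of iteration order.

## Derived metrics

- **Growth estimators.** λ_G is the geometric mean over runs of each
  run's annual growth (N_T/N_0)^(1/T); the N-based estimator solves
  λᵗ = N̄_t/N̄₀ over ensemble means. Both are withheld whenever any
  run truncated, because zero-clamped trajectories bias them. The
  reported SE of λ_G is the run-to-run standard deviation of per-run
  growth — the spread of plausible growth rates given rate
  uncertainty — not the Monte Carlo standard error of the mean, which
  is smaller by √n. The two estimators measure different functionals
  of the growth distribution (the N-based one up-weights large runs
  and exceeds λ_G by roughly exp((T−1)σ²/2) for run-level spread σ),
  so they agree tightly only when rate uncertainty is small.
- **Probability of decline.** The fraction of runs whose final N is
  below that run's own realized initial N, truncated runs counting as
  declined, with binomial SE √(p(1−p)/n). Comparing against the run's
  realized start (rather than the published point estimate) keeps the
  metric a property of trajectories; with SE = 0 starts the two
  coincide. Empirically the metric tracks the normal approximation
  Φ((1−λ_G)/SD(λ)) closely for truncation-free ensembles.
- **Viability experiment.** Zero harvest, stable-age start,
  N₀ = 10,000 with SE = 0, 20-year horizon, 5000 iterations; run on
  natural-survival rates (a warning is issued for the total variant).
  The 20-year horizon is long enough for the standing age distribution
  to respond to sex-selective harvest in the harvested companion runs.
- **Reference-year projection.** An ensemble from the estimate year to
  the reference year under an interval-wise harvest schedule (stepwise
  regime changes supported). The projected estimate is the ensemble
  mean and SD of N at the reference year with truncated runs
  contributing zero — so a chronically overharvested population
  projects toward zero rather than conditioning on survival — plus the
  mean standing age distribution of surviving runs for onward
  simulation and a depletion flag (mean below one bear, or no
  survivors).

## Statistics layer

- **Fisher exact 2×2** (two-sided): sum of hypergeometric
  probabilities, over all tables with the observed margins, not
  exceeding the observed table's probability (minimum-likelihood
  rule); degenerate margins give p = 1.
- **Mann–Whitney U** (two-sided, exact): mid-ranks for ties; the U
  null distribution is built by enumerating all C(n_a+n_b, n_a)
  labelings when that count is ≤ 10⁶, with p = 2·min(tail
  probabilities) capped at 1; larger problems fall back to the
  tie-corrected normal approximation with continuity correction.
- **Two-sample z**: |N_a − N_b|/√(SE_a² + SE_b²), p = 2(1 − Φ(z)).
- **Percent difference**: 100·(higher − lower)/lower.
- **Ward clustering** of (unharvested λ_G, harvested p_decline) status
  points on squared Euclidean distance, tree cut at two clusters.
  Features are deliberately left unscaled, so the decline probability
  (range ≈ 0.8 across subpopulations) dominates the growth rate
  (range ≈ 0.09) — this is the convention under which the published
  memberships reproduce, and the test suite verifies the merge
  sequence against a Lance–Williams agglomeration oracle.
- **Within-cluster slopes**: OLS slope of p_decline on λ with the
  t-test p-value; a two-point cluster has no residual degrees of
  freedom and returns a flagged undefined p.

For the 13-subpopulation analysis, KB is excluded from both U tests
(source–sink dynamics invalidate its closed-population estimates) and
BB additionally from the decline-probability U test (disputed harvest
reporting); KB enters the clustering with decline probability 1.0 (it
projects to depletion before the post-2013 window).

## Synthetic data

The generator emits vital-rate tables with the structure of the
published supplementary estimates: class survival means with standard
errors, age-specific litter production (first breeding at age 5), a
mean litter size, an abundance estimate with sampling error, and a
removals series with a female fraction. Adult female survival is the
solved free parameter (bisection to a requested deterministic λ,
tolerance 1e-4): it dominates growth in long-lived, slowly reproducing
species, so fixing the other rates at interpretable values and solving
the one that matters keeps tables realistic. Defaults (cub survival
0.65, yearling 0.86, subadult 0.92, adult male 0.93, LPR 0.90, litter
size 1.7, survival SE 0.04, N̂ = 2000 with SE 200, female proportion
of the kill 0.35 — the customary two-thirds-male split) sit in the
middle of the published ranges for healthy subpopulations.

Synthetic harvest schedules remove a constant fraction *h* of the
self-consistent harvested expectation N_{t+1} = N_t(λ − h), so
*h* = λ − 1 is sustainable by construction; the simulation holds
within Monte Carlo error of λ_G = 1 under that schedule with the
default sex split and family-group protection.

What the generator does **not** emulate: immigration and source–sink
structure, density dependence, time trends in rates (e.g. sea-ice
effects), individual heterogeneity beyond age/sex/status, and
non-normal estimation error. Passing tests on synthetic data therefore
demonstrate that the pipeline recovers known truth under the model's
own assumptions — not that those assumptions hold for any particular
wild subpopulation.

## Problem sizes and numerical choices

The test suite runs reduced ensembles (150–400 iterations) for
distributional checks and one full 5000-iteration viability ensemble;
the acceptance script uses 5000 iterations for the viability
experiment, 2000 for the initial-deviate check and 1000 for parameter
recovery. These sizes put Monte Carlo standard errors well below the
tolerances being asserted. Power iteration tolerance is 1e-10;
bisection runs at most 60 halvings; comp-transition probability rows
are renormalized before multinomial sampling to absorb floating-point
drift; harvest draws that collide with concurrently removed family
members are dropped with counts kept consistent (a rare event that
slightly under-harvests in the unprotected mode).

## Known limitations

- No immigration/emigration: chronically overharvested sink
  subpopulations are projected to depletion even where immigration
  sustains them in reality; the depletion flag marks, not models,
  this.
- Covariance between rates is limited to the two bracketing cases
  R = 0 and R = 1.
- The mechanics of partial mark–recapture sampling (the hypothesis the
  comparison layer probes) is not itself modeled; the package takes
  the published estimates at face value and quantifies their
  consequences.
- Growth estimators are undefined under truncation by design; status
  under heavy harvest rests on the decline probability alone.
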