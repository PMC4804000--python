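# polarpva

Population viability analysis (PVA) for harvested polar bear
subpopulations, built around an explicit stochastic simulation of the
species' three-year reproduction cycle, plus the statistics used to
compare PVA status calls with sampling protocols and community
(traditional ecological knowledge, TEK) trend assessments for the 13
Canadian subpopulations.

It is written for quantitative wildlife biologists who need to
reproduce or extend harvested-population risk assessments: project an
abundance estimate forward under observed removals, measure the
probability of decline, test whether a subpopulation's vital rates can
sustain any harvest at all, and ask whether disagreements between
assessment methods track how the underlying data were collected.

## The model

The population state tracks independent bears by sex and whole-year age
(0-30, terminal class absorbing) and family units — a mother with her
dependent litter — by mother age, litter age (cubs-of-year, yearlings,
two-year-olds) and litter sex composition (1-3 cubs). Each simulated
year applies, in order: survival (a dead mother's litter dies with her;
a female whose whole litter dies returns to the breeding pool the next
year), aging (two-year-olds disperse and their mother becomes
available), reproduction (each available female of age *x* whelps with
litter-production probability LPR(*x*)), then harvest.

Deterministic quantities come from the expectation of that cycle: the
stable age distribution **w** and growth rate λ satisfy
*A* **w** = λ **w**, where *A* is the expanded state-transition matrix,
computed by power iteration.

Each Monte Carlo iteration realizes every uncertain rate as

    θ = θ̂ + √p · SE(θ̂) · z_run + √(1−p) · SE(θ̂) · z_year

with parameter fraction *p* = 0.75 by default, `z_run` fixed per
iteration, `z_year` redrawn annually, and a toggle between independent
(R = 0) and fully correlated (R = 1) deviates. Demographic
stochasticity is binomial at the individual level; annual removals are
split into female/male shares and taken from the standing population.
A run is truncated to zero when the initial normal deviate for N₀ is
nonpositive, the population hits zero, or a sex cannot fill its share
of the quota.

From an ensemble the package reports two geometric growth estimators —
the geometric mean of per-run annual growth λ_G, and the λ solving
λᵗ = N̄_t / N̄₀ — (both withheld when any run truncated), and the
probability of decline: the fraction of runs ending below their own
realized starting abundance.

The statistics layer provides exact tests (Fisher 2×2 by hypergeometric
enumeration; Mann–Whitney U by full labeling enumeration with
mid-ranks), a two-sample z comparison of abundance estimates, percent
difference, Ward clustering of (λ_H=0, p_decline) status points on
squared Euclidean distance, and within-cluster least-squares slopes.

## Worked example

```python
from polarpva import SubpopulationPVA, SyntheticSpec, generate_vital_rates

rates = generate_vital_rates(SyntheticSpec(target_lambda=1.03))
result = SubpopulationPVA.viability(rates).fit(n_iterations=5000, seed=101)
print(result.summary())
```

```
Population Viability Analysis Results
=====================================================
Subpopulation:        SYN (natural survival)
Initial N (SE):       10000.0 (0.0)   year 0
Harvest:              none
Iterations / horizon: 5000 / 20 yr
Variance partition:   75% parameter / 25% environmental (R0)
-----------------------------------------------------
Deterministic lambda: 1.0300
Stochastic lambda_G:  1.0313 (SE 0.0288)
N-based lambda:       1.0391
p(decline):           0.1402 (SE 0.0049)
Truncated runs:       0.0000
Final N mean (SD):    21521.1 (12003.4)   year 20
=====================================================
```

The synthetic table was calibrated so its deterministic growth rate is
1.03/yr; the stochastic geometric mean (1.0313) agrees within its
run-to-run spread (SE 0.0288 here is the SD of per-run growth, driven
almost entirely by the rate uncertainty), and even this healthy
population declines in ~14% of 20-year futures once parameter and
environmental uncertainty are propagated. No runs truncate at
N₀ = 10,000.

The published status tables for the 13 Canadian subpopulations ship in
`polarpva.datasets`; the comparison layer runs directly on them:

```python
from polarpva import fisher_exact_2x2
from polarpva.datasets import tek_by_trend_table
print(fisher_exact_2x2(tek_by_trend_table()))   # 0.004662...
```

A thin CLI mirrors the library (`polarpva viability`, `project`,
`status-stats`, `cluster`, `synth`); see `polarpva --help`.

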