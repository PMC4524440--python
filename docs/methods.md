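# Methods

## Model

Tumour growth is modelled as a discrete-time multitype Galton–Watson
branching process. Cells carry two heritable labels: the number of
extra driver mutations `i ∈ {0, …, N}` and a resistance flag
`j ∈ {0, 1}`. Cells neither compete nor interact; each subclone evolves
independently, which is what makes the expectation dynamics exactly
linear (see *Mean-field oracle* below).

Each time step represents one cell cycle of `T` days. Every cell either
divides or dies; the per-cycle fitness

```
f_ij = s·(i + 1) − σ·(1 − j) − c·j
```

is interpreted as the difference between the division and death
probabilities, which together with "every cell divides or dies each
step" (b + d = 1) forces

```
b = (1 + f)/2,   d = (1 − f)/2.
```

Expected offspring per cell per step is `2b = 1 + f`. Driver fitness is
additive; for `s` of a few tenths of a percent this is indistinguishable
from multiplicative fitness. Treatment is purely a per-cycle fitness
reduction `σ` on sensitive cells — it deliberately does not distinguish
cytostatic from cytotoxic action.

On division, the daughter cell mutates with probability `u` (one extra
driver) or `v` (resistance), mutually exclusively; the parent's copy
never mutates, and there is no back mutation. At the lattice boundary
(`i = N`, or `j = 1` for `v`) the mutation is *wasted*: its probability
mass folds back into plain division, keeping the four per-cell fate
probabilities normalised exactly.

The population update is a single batched multinomial draw per step:
for each subclone with `n` cells, the numbers of deaths, plain
divisions, driver divisions and resistance divisions are multinomially
distributed, and offspring are routed to `(i, j)`, `(i+1, j)` and
`(i, 1)` accordingly. Counts are 64-bit integers throughout; multinomial
sampling is exact at any population size (including 10¹¹ cells), so no
Gaussian approximation is used anywhere.

## Parameters

| symbol | meaning | default | unit |
|---|---|---|---|
| `T` | cell-cycle length (one step) | 4 | days |
| `s` | selective advantage per driver | 0.004 | per cycle |
| `c` | cost of resistance | 0.001 | per cycle |
| `u` | driver mutation probability per division | 3.4 × 10⁻⁵ | — |
| `v` | resistance mutation probability per division | 10⁻⁶ | — |
| `N` | max extra drivers | 5 (preformed-lesion prevention) / 9 (grown-tumour protocols) | — |
| `M` | detection threshold | 10⁹ | cells |
| `M₀` | lesion size when a measure starts | 10⁶ | cells |
| `κ` | initial resistant fraction (preformed lesion) | 10⁻⁴ | — |
| `σ` | treatment intensity | scenario-specific | per cycle |

`σ` is stored per cycle; the daily arrest level often quoted alongside
it is `σ/T` (0.375%/day ≙ σ = 1.5% at T = 4 d). Config files must name
the unit in the key (`sigma_per_cycle` vs `sigma_daily`); values accept
a `%` suffix, and bare numbers ≥ 0.5 are rejected as almost certainly a
forgotten percent sign. The driver cap `N` has no default in config
files because the published cohorts alternate between 5 and 9 and a
silent default would invite misreproduction.

Calendar conversion uses 365 days/year, i.e. 91.25 steps/year; times are
reported in years as `steps × T / 365`. A useful anchor: an untreated
single-type population grows by `1 + s` per step, so 10⁶ → 10⁹ takes
`ln 1000 / ln 1.004` ≈ 1731 steps ≈ 19.0 years.

`σ_crit = s·(N + 1)` (`critical_intensity`) is the intensity above which
even the fittest sensitive subclone is subcritical; beyond it, dynamics
are governed entirely by resistant lineages, whose fitness `s(i+1) − c`
is independent of `σ`.

## Protocols and conventions

* Detection/relapse is checked after each completed step; detection
  means total ≥ `M`.
* Growth phases from a single founder cell condition on non-extinction:
  attempts that die out (probability ≈ (1−s)/(1+s) ≈ 0.992 per attempt)
  are discarded and redrawn within the replicate's RNG stream. Replicate
  counts therefore refer to surviving tumours.
* Resection keeps exactly the requested residual count, allocated by
  one multinomial draw proportional to the pre-resection composition.
  (True sampling without replacement would be hypergeometric; at
  residual ≪ total the difference is negligible and the multinomial is
  cheaper.)
* Relapse distributions are run uncapped (hard safety cap 150 years),
  because their 95th percentiles extend beyond the 50-year horizon used
  for success metrics. Success-probability metrics and the second-chance
  protocol use a 50-year horizon, clocked from the start of the measure
  (the pre-`M₀` growth period is not counted).
* The second-chance protocol resects back to exactly `M₀` cells
  (proportional sampling of the failed tumour, not a fresh naive
  lesion) and continues at the same `σ`.
* The resistant burden "4 years into treatment" is recorded at step 365
  of the treatment phase; replicates that end earlier (detection or
  extinction) record their end-state resistant count, so extinct
  tumours count as trivially below 100 resistant cells.
* Per-replicate RNG: `default_rng(base_seed + replicate_index)`.
  Outcome sets are bit-reproducible and independent of execution order;
  sweeps give each grid point a disjoint seed block.
* Negative or >1 fitness is clipped to [−1, 1] with a warning; baseline
  parameters never approach the bound.
* The metronomic policy applies `σ` only on steps where sensitive cells
  outnumber resistant cells, and 0 otherwise — the trigger rule only,
  with the resistance cost held constant (dose-dependent costs are out
  of scope).

## Mean-field oracle

The expected counts of the exact same process satisfy
`E[n(t+1)] = A·E[n(t)]` with

```
A[(i,j)→(i,j)]   = b_ij (2 − u′ − v′)
A[(i,j)→(i+1,j)] = b_ij u′
A[(i,0)→(i,1)]   = b_i0 v′
```

(`u′`, `v′` are the boundary-adjusted mutation probabilities). Each
source column sums to `1 + f_ij`, the expected offspring number — a
structural identity the tests assert exactly. The recursion is iterated
with per-step renormalisation and an accumulated log-scale factor, so
expectation trajectories remain finite far beyond floating-point
overflow of the raw counts. Because `A` is the exact first moment of the
implemented stochastic update, Monte-Carlo subclone means must match it
within sampling error; this internal-consistency check (2000 replicates,
250 steps, 3 SE) is part of the suite. Closed-form analytic solutions
of the master equations are intentionally not implemented; the matrix
recursion plays that role and is guaranteed consistent with the engine.
`deterministic_detection_time` declares a configuration "never detected"
when the spectral radius of `A` restricted to the types reachable from
the initial support is ≤ 1.

## What the simulated cohorts do and do not show

The generator *is* the study design: cohorts start from the stated
initial conditions (preformed lesions of identical cells, or tumours
grown from one founder), with no patient heterogeneity in rates, no
spatial structure, no competition between subclones, no
pharmacokinetics, and resistance to all measures assumed identical.
Agreement of the reproduced statistics therefore validates the
branching-process machinery and protocol logic, not the clinical realism
of any particular parameter choice.

Replicate counts are scaled down from the reference cohorts of 10⁶ to
500–2000 per statistic, chosen so that the Monte-Carlo standard error
of each reported median is well under the comparison tolerances;
medians and success probabilities are stable at these sizes.

One known systematic remains: with the conventions above (additive
fitness, single-daughter mutation at `u = 3.4 × 10⁻⁵`,
`b = (1+f)/2`), a tumour grown from one cell reaches 10⁹ cells with
dominant subclones carrying 1–2 extra drivers (cell-weighted mean
≈ 1.7), which is fewer than the 4–5 the source cohorts report for the
same size. Statistics dominated by post-resection dynamics of small
residuals inherit a ~10–15% downward shift in relapse times from this
difference; large-residual and prevention statistics agree within a few
percent. Plausible alternative conventions (e.g. letting both daughters
mutate) shift results in the wrong direction, so the documented
single-daughter rule is kept.

## Numerical and degenerate-input choices

* Percentiles use linear interpolation between order statistics; the
  "90% confidence interval" of a cohort is its 5th–95th percentile band,
  not a standard-error band.
* Detection-time histograms use exact 3-month (0.25-year) bins that
  partition the time axis and are normalised over detected cases.
* Zero detected events → distributional statistics are null while
  success metrics remain defined; empty populations propagate as empty
  states; a start already at/above target returns in zero steps.
* The exponential relapse-vs-drivers regression `y = a·e^(−bx)` is fit
  by nonlinear least squares (initial guess `a = max y`, `b = 0.3`),
  with R² reported as `1 − SS_res/SS_tot` on the original scale so it is
  directly comparable to the linear fit's R².

## Limitations

Spatial growth, subclone competition, multidrug resistance,
dose-dependent resistance costs, explicit cytotoxic/cytostatic
mechanisms, and metastatic seeding as a spatial process are all out of
scope; residual cells after resection stand in for residual disease and
micro-metastases collectively. Fitness is additive in drivers; at the
parameter magnitudes used this is a second-order approximation to the
multiplicative case.
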