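# Methods

## The fragility model

The package treats a two-arm 1:1 randomized trial's dichotomous outcome as
a 2×2 contingency table (arm × event/non-event) and asks how many
single-patient outcome changes the statistical significance of that table
can absorb. The analysis is exact and conditional: given the observed
margins, the experimental-arm event count follows a hypergeometric
distribution, and significance is judged by Fisher's exact test. The time
dimension of survival endpoints is deliberately discarded — the method sees
only end-of-study counts, which is both its simplicity and its main
limitation.

### Fisher's exact test

`fisher_two_sided` enumerates the full conditional support and sums the
probabilities of every table no more probable than the observed one (the
minimum-likelihood two-sided convention used by the major statistical
packages; the alternative "double the one-sided tail" convention is not
offered). Implementation choices:

- All binomial coefficients are accumulated as log-gamma sums and
  exponentiated only at the end, so trial-scale sample sizes cannot
  overflow. Normalization over the support holds to 1e-9 for N up to 400.
- A table's probability counts as "no more probable" than the observed one
  if it is ≤ the observed probability times (1 + 1e-7). Mathematically
  tied tables (e.g. symmetric extremes) can differ in their floating-point
  log-gamma evaluations; the relative tolerance re-merges those ties and
  matches mainstream implementations.
- Before enumeration the table is mapped to a canonical representative of
  its four-element symmetry orbit (arm swap × outcome-column swap), so the
  test is invariant under those swaps *bitwise*, not merely to rounding.
- Degenerate tables (zero events anywhere, or events in every patient)
  admit a single conditional table; they return p = 1.0 with a logged
  warning instead of raising, so the FI iteration can terminate gracefully.

### The FI iteration

Significance means p < alpha (default alpha = 0.05); a result is nullified
at the first step where p ≥ alpha, with exact equality counting as
nullified. If the baseline p is already ≥ alpha the FI is 0 — no iteration
runs. Otherwise one non-event is converted to an event per step, holding
arm totals fixed, and the FI is the step count at nullification. The
result object carries the full trace (arm, table, p per step), so the
minimality property — p < alpha at every step before the last, p ≥ alpha at
the last — is directly inspectable and is asserted across the test suite on
the built-in cohort and on hundreds of random tables.

Events go to the arm with the **fewer** events (`fewest_events`, the
convention of the widely used web calculators). Adding events to the
larger-count arm widens the observed contrast and can never nullify it;
with the built-in cohort the experimental arm is sometimes the
larger-count arm, so a literal "always experimental" rule could not
reproduce the published FIs. Fixed `experimental`/`control` conventions
remain available for sensitivity analyses. Under `fewest_events` the
target arm is re-selected after every step; for real trial tables the
smaller-count arm cannot overtake the other before p crosses alpha, so
re-selection is observationally equivalent to fixing the arm at step 0,
but it is the safer definition for adversarial inputs.

If the target arm saturates (every patient an event) before significance
is lost, the result is returned with `converged=False` and the steps taken
so far, plus a warning — batch runs survive pathological rows. This arises
mainly under the fixed-arm conventions or for tiny synthetic tables; a
non-converged result's FI is a lower bound, not a fragility index.

### Fragility quotient

FQ = 100·FI/N with N the grand total. The internal value is unrounded;
report formatting rounds half-up to 2 decimals (`0.1969 → "0.20%"`,
`3.4146 → "3.41%"`) — half-up, not banker's rounding, because the
published 2-dp cells follow that convention.

## Cohort aggregation

Medians and quartiles use the (n+1)-position linear-interpolation order
statistic (Hyndman & Fan type 6, `numpy.quantile(..., method="weibull")`,
positions clamped to the extremes). For six sorted values the quartiles
interpolate at positions 1.75 and 5.25; this is the only common quantile
definition that reproduces both published quartiles of the built-in cohort
(FI upper quartile 10; sample-size lower quartile 220.75), which is why it
is pinned rather than left to a default. The cohort summary also counts
primary-endpoint trials with FI = 0 and refuses records whose allocation
ratio is not 1:1, naming the offending trial — the FI as defined here has
no meaning for unequal allocation.

The built-in cohort (`data/table1.csv`, loaded by `builtin_table1()`)
contains the six 1:1-randomized phase-3 hepatocellular-carcinoma trials
with their published arm sizes and event counts. The `reported_p` column
is the p-value each trial itself published — usually a stratified log-rank
on the time-to-event data, not a Fisher p — and is carried as metadata
only; no computation reads it. CSV is the single exchange format
(documented schema, row-level error messages with line numbers); summaries
are written as per-trial CSV or a JSON document.

## The synthetic-trial generator

`simulate_trial` draws per-arm event counts as independent
Binomial(n_per_arm, rate) variables for a 1:1 two-arm trial. This matches
exactly the structure the fragility analysis assumes — end-of-study
dichotomous outcomes with fixed arm sizes — and deliberately omits what
the analysis itself ignores: censoring, variable follow-up, covariates,
stratified randomization, and any time axis. Passing tests on simulated
data therefore validate the count-based machinery, not the adequacy of
collapsing survival data to counts.

Every draw derives from `(seed, trial index)` via numpy's seeded
generator, so a single trial is reproducible without generating its
predecessors and whole experiments are bit-identical across runs. The seed
is mandatory — there is no implicit entropy. Only within-implementation
reproducibility is promised, not stability across numpy versions.

The FI-vs-p experiment defaults to event rates 0.5 vs 0.3 at 100
patients/arm over 1000 trials: that contrast gives well over 50% power, so
several hundred trials land in the significant subset and the Spearman
rank correlation between FI and baseline p over that subset is stable. The
experiment asserts direction only (the correlation is negative — in
practice near −1, since both quantities are monotone summaries of the same
table); no magnitude is claimed. It raises rather than returning a number
when fewer than 10 trials are significant or when FI or p has no variance
across them.

## Problem sizes and runtime

Everything is desk-scale: the cohort reproduction is six tables; property
checks use a few hundred random tables with arm sizes ≤ 80 and simulations
of 200–1000 trials at 100/arm. The full test suite runs in a few seconds
on one CPU; the acceptance script in under ten.

## Known limitations

- Only two-arm 1:1 dichotomous outcomes; no reverse FI for non-significant
  trials, no survival-aware fragility variants, no mid-p or one-sided
  tests, no meta-analytic pooling.
- The FI inherits every criticism of fixed-alpha significance testing; an
  FI = 0 trial is not "negative", it merely was not significant by this
  particular test on these particular counts.
- For unequal-arm-size tables the package computes the FI if asked at the
  single-table level, but cohort entry enforces the 1:1 label, mirroring
  the method's stated scope.
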