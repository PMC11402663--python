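# Methods

## Scope and data model

`faersig` implements a complete spontaneous-report signal-detection workflow
for the FDA Adverse Event Reporting System (FAERS): reading the quarterly
"$"-delimited ASCII extracts (DEMO, DRUG, REAC, THER; INDI/OUTC/RPSR are
read and carried but unused), collapsing report versions to patient cases,
building per-drug 2x2 contingency tables against one MedDRA preferred term,
computing four disproportionality statistics with signal criteria, and
fitting Weibull time-to-onset distributions.

The unit of analysis is the **deduplicated case**: a FAERS case (CASEID) can
appear as several report versions (PRIMARYID), and the retained version is
the one with the greatest FDA receipt date, ties broken by the greatest
PRIMARYID (numerically when both ids are integers).  This is the common
FAERS-community convention; the choice is deterministic and idempotent.  A
report-level sensitivity mode (`dedup=False`) treats every version as its
own unit.

Drug exposure is restricted to **primary-suspect** (role code PS) mentions;
secondary-suspect, concomitant and interacting mentions are dropped, with
per-reason counts exposed so that every input row reconciles to retained +
dropped.  Drug names and preferred terms are normalised by trimming,
upper-casing and whitespace collapsing; an optional exact-match synonym map
folds brand/salt variants.  No MedDRA hierarchy expansion is performed: the
target event is a single preferred-term string.

## Disproportionality statistics

All statistics derive from the case-level 2x2 table (a = drug and event,
b = drug only, c = event only, d = neither; N = a+b+c+d):

* **ROR** = ad/bc with the Woolf 95% CI, exp(ln ROR ± 1.96·√(1/a+1/b+1/c+1/d)).
* **PRR** = [a/(a+b)] / [c/(c+d)] with the uncorrected Pearson chi-square
  N(ad−bc)²/[(a+b)(c+d)(a+c)(b+d)]; a Yates-corrected variant is available
  behind `yates=True`.
* **RRR** (relative reporting ratio, observed over expected) = aN/[(a+b)(a+c)].
* **MGPS**: `mode="simplified"` (the default for replication runs) reports
  EBGM = RRR with EB05 = exp(ln RRR − 1.64·√(1/a+1/b+1/c+1/d)).  This is the
  variant that reproduces published FAERS signal tables exactly — the
  EB05/EBGM ratio in those tables matches the 1.64-sigma log-normal bound,
  indicating no actual Bayes shrinkage was applied.  `mode="full"` is the
  DuMouchel gamma-Poisson shrinker: a two-component gamma mixture prior on
  the rate ratio is fitted by maximising the negative-binomial mixture
  marginal likelihood over all drug-event cells (5 hyperparameters,
  multi-start L-BFGS-B from the classic start (0.2, 0.1, 2, 4, 1/3) plus
  seeded perturbations, bounded log/logit parameters, Nelder-Mead polish on
  precision-loss terminations); EBGM = 2^E[log2 λ | a] under the posterior
  gamma mixture and EB05 is the posterior 5th percentile found by monotone
  root-finding on the mixture CDF (tolerance 1e-8).  On homogeneous
  (pure-null) cell sets the marginal-likelihood optimum is a near-delta
  prior at 1 — empirical Bayes then shrinks everything to 1, which is the
  correct limit, so the "data swamp the prior" behaviour should be expected
  only when the cell population is genuinely heterogeneous.
* **BCPNN IC**: `mode="paper_compat"` is IC = log2(RRR) with
  IC025 = IC − 1.67.  The constant 1.67 offset matches the published tables
  row-for-row but corresponds to no standard credible-interval formula; its
  provenance is unknown and it is reproduced purely for comparability.
  `mode="noren"` is the principled alternative:
  IC = log2[(a+0.5)/((a+b)(a+c)/N+0.5)] with
  IC025 = IC − 3.3(a+0.5)^(−1/2) − 2.4(a+0.5)^(−1).

**Zero cells** yield typed undefined results (NaN plus a reason) rather than
silent 0.5 continuity corrections; a correction flag exists on the ROR for
exploratory use.  An undefined statistic never raises a signal flag.

**Signal criteria** (defaults, validated against the published 30-drug flag
pattern): ROR — a ≥ 3 and lower CI bound > 1; PRR — a ≥ 3, PRR ≥ 2 and
chi-square ≥ 4; MGPS — EB05 > 2; BCPNN — IC025 > 0; a drug is a signal when
any criterion fires.  All thresholds are configurable.

Products such as a·d reach ~10^11 at FAERS scale; all statistics are
evaluated in double precision (exact for integers to 2^53), with the ROR
computed via logs.

## Reconstructing published tables

Published signal tables print a, N, the event margin and the statistics but
not the drug margin.  `ContingencyTable.from_margins_and_ror` solves
b = a(N−a−c)/(ROR·c+a) so the full table can be rebuilt from a printed ROR;
applied to the strongest-signal drug (a = 2,369; N = 50,659,288;
a+c = 169,897; ROR = 115.51) this reproduces the printed PRR (83.78),
chi-square (191,709.73), EBGM (82.63), EB05 (79.4), IC (6.37) and IC025
(4.70) within 0.1%.  `replicate_from_printed` applies the criteria directly
to printed statistic rows, making the headline classification (26/15/15/11
signals per algorithm, union 26 of 30) a data-free computation; the package
ships that table as a fixture.

## Time-to-onset

TTO = EVENT_DT − START_DT in days, where the start date is the earliest
day-precision START_DT among therapy rows matching the case's
primary-suspect sequences for the drug (first start chosen when several
therapy episodes exist; the alternative — last start — is not
distinguishable from reported data).  Pairs are excluded, with per-reason
accounting, when the event precedes the start, a date is missing, a date has
only month/year precision, or an 8-digit date is not a real calendar date.
Same-day onsets are kept as 0.5 day for fitting (the log-likelihood needs
positive values) and counted as 0 in descriptive medians.  Quartiles use
linear interpolation between order statistics.

The two-parameter Weibull is fitted by maximum likelihood, with no
censoring model (only observed onsets are analysed).  Newton iterations run
on (log α, log β) with analytic gradient and Hessian, step-halving damping,
and convergence when the step max-norm falls below 1e-10; starting values
come from the method of moments on log onsets (Var ln T = π²/6β²).  95% CIs
are Wald intervals from the observed information on the log scale,
back-transformed; a seeded percentile bootstrap (default 1000 resamples) is
available for small samples.  Identical values or n < 3 raise an error
(the shape is unbounded).  The shape CI classifies the hazard: entirely
below 1 → early failure (onset risk decreasing over time), containing 1 →
random, entirely above 1 → wear-out; non-finite bounds → indeterminate.
Simulation checks: estimates within 5% of truth at n = 5000, CI coverage
within [90%, 99%] at n = 500 over 200 replicates, and ≥ 80% "random"
classification for exponential data at n = 1000.

## Synthetic data generator

The generator emits the exact FAERS dialect the readers consume plus a
ground-truth ledger.  Per report: a primary-suspect drug from configured
marginal shares; the target event with probability
min(1, background_event_rate × rrr_target); onset days from the drug's
Weibull realised as EVENT_DT = START_DT + round(onset) (onsets < 0.5 give
the same-day case); FDA dates inside the configured quarters; demographics
from configurable sex/age-band/country mixes (defaults follow the
female-predominant, US-dominated, many-unknowns pattern of large
spontaneous-report cohorts); duplicate versions (same CASEID, fresh
PRIMARYID, later FDA date) at a configurable rate, default 1.4% — the
reduction seen between constipation reports and unique patients at FAERS
scale; date corruption (missing 30%, partial 10%, event-before-start 2% by
default, matching the sparse usable-onset fraction of real reports).
Identical seeds give byte-identical files.

A drug's *measured* relative reporting rate equals its multiplier divided by
the share-weighted mean multiplier; the default configuration keeps that
mean near 1 by giving the associated drugs small shares, and the ledger
records the exact implied value (`rrr_implied`) alongside the target.  The
default size (20,000 reports, 8 quarters, background event rate 2%) makes
every stage run in seconds while leaving the strongly associated drugs with
expected event counts of 20–140 — large enough for all four criteria to
fire on the 20x drug and for 3-SE recovery checks to be meaningful.

What the generator does **not** emulate: drug-name messiness (misspellings,
combination products), reporting-rate drift over calendar time, event-count
heterogeneity across thousands of preferred terms, country-specific
reporting behaviour, or informative missingness of dates.  Passing recovery
tests on synthetic data therefore demonstrates correctness of the
bookkeeping and estimators under the stated generative model, not
robustness to real FAERS data quality.

## Descriptive conventions

Percentages are rounded half-up (2 decimals for ranking/trend shares, 1 for
demographics), matching the convention of published tables; Python's
banker's rounding would disagree at ties.  Trend periods derive from the
retained version's FDA receipt quarter.  Age is converted to years via
AGE_COD (DEC×10, YR×1, MON÷12, WK÷52, DY÷365.25, HR÷8766); bands are <18,
18–39, 40–64, ≥65, unknown.  The country field uses REPORTER_COUNTRY as
reported (upper-cased, trimmed), no ISO normalisation.

The shipped ATC class map is a user-editable fixture, not a computed
classification.  Two published class letters (duloxetine printed as L,
capecitabine as N) are transposed relative to the ATC system; the fixture
follows ATC (duloxetine N, capecitabine L).

## Known limitations

* Raw FAERS-scale results are not reproducible without the full database;
  the package validates against printed-value arithmetic, the reconstructed
  strongest-signal table, and synthetic-data recovery instead.
* No stratified (age/sex/year) MGPS; single-event study design, so no
  multiple-testing control across events.
* The paper-compatibility modes (EBGM = RRR, IC025 = IC − 1.67) reproduce a
  published variant, not the reference methods; use `mode="full"` /
  `mode="noren"` for new analyses.
* Multi-ingredient product decomposition and XML FAERS are out of scope.
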