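# Methods

`faersig` implements a complete disproportionality signal-detection
pipeline for spontaneous adverse-event reports in the FAERS quarterly
ASCII schema, together with a synthetic report generator that provides
ground truth for every downstream stage. This note records the models,
the defaults and why they are what they are, the numerical choices, and
what the synthetic evaluation does and does not establish.

## Data model and cleaning

A *report* is one submission to the reporting system, keyed by
`primaryid`; a *case* (`caseid`) is one patient event that may be
reported several times as follow-ups arrive. The cleaning stages are:

1. **Parsing.** Seven `'$'`-delimited tables (DEMO, DRUG, REAC, OUTC,
   THER, INDI, RPSR), one header line each; a comma dialect is accepted
   for fixtures. `PRIMARYID` is mandatory in every supplied table.
2. **Standardization.** Age is converted to years (`DEC` ×10, `MON` /12,
   `WK` /52.1775, `DY` /365.25, `HR` /8766), weight to kilograms
   (`LBS` ×0.45359237, `GMS` /1000). Values outside plausibility bounds
   (age 0–120 y, weight 1–500 kg) or with unknown unit codes become
   missing and are counted in the cleaning log. Drug names are
   uppercased, characters outside `[A-Z0-9 ]` removed, whitespace runs
   collapsed. Reaction rows are reduced to one per (report, preferred
   term): disproportionality counts reports, not reaction rows.
3. **Deduplication.** One record per case: the latest FDA submission
   date wins; ties are broken by the largest numeric `primaryid`.
   Partial submission dates (`YYYY`, `YYYYMM`) are zero-padded to the
   first day *for ordering only*; they are treated as missing for any
   interval arithmetic. Records without a `caseid` are kept as their own
   group and flagged. Deduplication is idempotent and its output is
   sorted by case id, so repeated runs are identical.
4. **Cohort selection.** Reports whose *primary suspect* drug matches a
   target name. The default match is a whitespace-token substring after
   normalization ("VONOPRAZAN" captures "VONOPRAZAN FUMARATE"); exact
   matching is available.
5. **Seriousness.** A report is serious iff it carries at least one
   outcome code in {DE, LT, HO, DS, CA, RI}; `OT` alone is non-serious.
   This is the conventional reading of the outcome table; the package
   treats it as a definition, configurable only by editing the code
   constant.
6. **Weight imputation.** If the missing fraction of weight is below
   10%, missing values take the median of their (sex, descriptive age
   band) cell; above the threshold nothing is imputed. At the ~80%
   missingness typical of spontaneous reports the rule never triggers,
   which is the expected behaviour, not a defect.

Age bands: descriptive output uses <18, 18–64.9, 65–85, ≥85; stratified
signal analysis uses <18, 18–64.9, ≥65. "18–64.9" is read as the
half-open interval [18, 65), so 64.95 y falls in the middle band and
65.0 y in the elderly band.

## Contingency tables

For a focal cohort F in a database of N deduplicated reports, each
preferred term (PT) yields

|            | event | no event |
|------------|-------|----------|
| focal      | a     | b        |
| all others | c     | d        |

The counting unit is the unique report. Margin identities
(a+b = |F|, a+c = event reports, N = a+b+c+d) are enforced by
construction and re-checked in tests. System-organ-class (SOC) tables
count a report once per SOC by default even when several of its PTs map
there; an occurrence-level mode (margins = (report, PT) pair counts) is
provided because either convention appears in published analyses.
Unmapped PTs are collected under `UNMAPPED`. Stratified tables are
rebuilt with stratum-local margins; the explicit `missing` stratum is
excluded from stratified signal statistics.

## Disproportionality algorithms

With E = (a+b)(a+c)/N the expected a-cell under independence:

* **ROR** = ad/bc with Wald 95% CI `exp(ln ROR ± 1.96·√(1/a+1/b+1/c+1/d))`.
  Positive when ROR ≥ 3 and the CI lower bound exceeds 1. The
  conventional alternative (a ≥ 3 and CI lower > 1) is available; the
  printed-rule default is kept because it is self-consistent with the
  signal tables this pipeline emulates.
* **PRR** = [a/(a+b)]/[c/(c+d)] with the *uncorrected* Pearson χ² on the
  same table and its 1-df p-value. Positive when PRR ≥ 2, χ² ≥ 4 and
  a ≥ 3.
* **BCPNN information component.** Default is the closed-form shrinkage
  IC = log₂((a+0.5)/(E+0.5)) with the credible-bound approximation
  IC025 = IC − 3.3(a+0.5)^(−1/2) − 2(a+0.5)^(−3/2); positive when
  IC025 > 0. Published signal tables sometimes print IC = log₂(EBGM);
  an `ic_from_ebgm` mode mirrors that convention. Neither variant is
  asserted to be "the" BCPNN — the full Bate-style Bayesian network and
  the closed form differ mainly in the credible bound, and the choice is
  exposed in configuration.
* **MGPS / EBGM.** DuMouchel's empirical Bayes gamma-Poisson shrinker:
  a ~ Poisson(λE) with λ ~ P·Gamma(α₁,β₁) + (1−P)·Gamma(α₂,β₂). The
  five prior parameters are fitted by marginal maximum likelihood over
  all PT cells (the marginal of each cell is a two-component negative
  binomial mixture), using bounded L-BFGS-B on log/logit-transformed
  parameters, multi-started from the classical default
  (0.2, 0.1, 2.0, 4.0, 1/3) plus seeded perturbations. Cells are sorted
  before summation so the fit is exactly permutation-invariant. The
  posterior given a is again a two-component gamma mixture with
  components (αₖ+a, βₖ+E) and weights updated by the component marginal
  likelihoods; EBGM = 2^{E[log₂λ | a]} (closed form via digammas,
  verified against numeric integration), and EBGM05 is the 5th posterior
  percentile solved by Brent's method to |CDF−0.05| < 1e−8. Positive
  when EBGM05 > 2 (the companion condition EBGM > 0 holds for every
  gamma posterior and is recorded as vacuous). When a degenerate fitted
  component (shape → 0) places ≥5% posterior mass below 1e−12, EBGM05 is
  reported as 0 — this only occurs in tiny strata where the prior is
  unidentified. Fewer than 50 cells triggers a warning for the same
  reason. A caution on interpretation: with several strong signals of
  different sizes in one database, MGPS can pull a weaker elevated cell
  *up* toward the signal component fitted on the stronger cells; the
  textbook "EBGM between 1 and a/E" bracket is guaranteed only when the
  prior centres near 1 (the usual mostly-null database).
* **Zero cells.** The Haldane–Anscombe correction (0.5 added to all four
  cells) is applied to the ratio estimates only when some cell is zero,
  and corrected results are flagged.

**Tiering.** A PT with all four criteria positive is `cross_validated`;
with at least one but not all four (including a single family firing
alone) it is `hypothesis_generating`; otherwise `negative`.

**Multiplicity.** Benjamini–Hochberg (default) or Bonferroni on the PRR
χ² p-values, over the family of PTs with a ≥ 3. Both procedures are kept
because published tables are not always explicit about which one their
"adjusted p" column used.

**Label comparison.** Positive-tier PTs absent (case-insensitive exact
match) from a user-supplied labeled-event list are reported as unlisted.
The bundled `labeled_pts_synthetic.tsv` is a synthetic stand-in for a
product label, for tests and demos only; real analyses must supply the
actual label list. Likewise `pt_soc_map.tsv` is a small PT→SOC fixture,
not a MedDRA substitute (MedDRA is licensed and is deliberately out of
scope).

## Severity comparison

Per PT, serious and non-serious report groups are compared on a 2×2
table whose margins are the groups' total PT occurrences (not case
counts — occurrence margins are what reproduce published statistics of
this design). The test is the Yates continuity-corrected χ²,

  χ² = N(|ad−bc| − N/2)² / [(a+b)(c+d)(a+c)(b+d)], clamped at 0,

unless the minimum expected cell count (rowᵢ·colⱼ/N) is below 5, in
which case Fisher's exact test (two-sided, sum-of-small-p convention,
no mid-p) is used. Both the threshold-5 selection rule and the
continuity correction are reconstructions validated numerically against
published statistics of this table type (six golden χ² values reproduce
to 3 decimals; all 17 test choices agree); the package documents them as
reconstructions rather than quoted procedure.

## Time to onset and Weibull modelling

TTO = event date − earliest focal-drug start date, in whole days, per
report. Records with a strictly earlier event date, or with either date
missing or partial, are excluded and tallied; same-day onset (0 days) is
retained. `records_in = records_used + Σ exclusions` always holds.

The onset sample is summarized by median and IQR (linear interpolation)
and fitted with a two-parameter Weibull by maximum likelihood. Because
the Weibull support is positive, day counts are offset by +0.5 d for
fitting only (raw-days mode available); dropping day-0 events instead
would bias the shape upward. Optimization is Nelder–Mead refined by BFGS
on (log α, log β); 95% CIs are Wald intervals from the central-difference
observed information on the log scale (a seeded percentile bootstrap is
available, default 1,000 resamples). Failure type follows the CI, not
the point estimate: shape CI entirely below 1 → `early_failure`,
entirely above → `wear_out`, else `random_failure` — the CI rule gives
"β = 1" a testable meaning.

Cumulative onset curves are plain ECDFs (every record is an event;
spontaneous reports have no at-risk denominator, so censoring-aware
survival modelling is explicitly out of scope). The between-sex
comparison is the standard log-rank test with all observations treated
as events.

## Synthetic report generator

The generator emulates the statistical structure the pipeline assumes:

* Each of `n_reports` reports gets the focal drug as primary suspect
  with probability `focal_drug_share`, else a background drug from a
  pool of 200 names.
* Each PT in the panel occurs independently per report with its
  background probability, multiplied by the planted relative reporting
  ratio on focal reports (capped at 1 with a warning), with optional
  male and ≥65 multiplicative tilts.
* Onset for focal reports is Weibull(α, β) in days, rounded to integers
  with 0 retained; event and start dates are written consistently, and
  the FDA date follows the event date.
* Seriousness is the maximum of a baseline rate and the planted per-PT
  serious probability; serious reports draw one outcome code from a
  configured mix, others get `OT`.
* Duplicates (same case, earlier FDA date, smaller primaryid) and
  partial dates are injected at configured rates so the cleaning rules
  are exercised on every run.

Defaults are the study conditions: 20,000 reports, focal share 0.05
(~1,000 focal reports, the scale of a moderate post-approval cohort),
sex mix 62% female / 29.6% male / 8.4% unknown, age-band and country and
reporter mixes matching a typical focal-drug cohort, baseline serious
rate 0.343, onset Weibull(scale 19.73 d, shape 0.49), weight missingness
0.80, duplicate rate 0.05, partial-date rate 0.05. A `truth_table` emits
per-PT generating ratios and exact 2×2 cell probabilities
(p_a = share·bg·ratio etc., ignoring tilts and capping) for recovery
tests.

What the generator does **not** emulate: reporting-behaviour biases
(stimulated reporting, channeling, under-reporting trends), indication
and pregnancy fields, within-report correlation between PTs beyond the
shared seriousness draw, secular trends in reporting volume, and free-text
noise in drug names beyond the normalization classes. Passing recovery
tests therefore shows the estimators are correct under the independence
model they assume — not that real-database signals are unbiased.

## Problem sizes and runtime choices

Replicate-based checks use 100 seeded replicates of 20,000-report
databases (planted-ratio recovery and null-database specificity), 5,000
draws for Weibull recovery, a 200×200 grid for the fit oracle, and full
hypergeometric enumeration for Fisher tables up to N = 60. These sizes
were chosen so that each property has comfortable statistical resolution
while a complete run of the suite plus the reproduction script stays in
the low minutes on one core.

## Known limitations

* The MGPS prior is weakly identified on small PT panels; per-stratum
  fits in small strata can degenerate (handled, but the stratified EBGMs
  are then uninformative).
* The Wald CIs for ROR and the Weibull parameters are asymptotic;
  with very small counts the bootstrap option is preferable.
* The IC credible bound is the closed-form approximation; it is
  slightly conservative for a ≳ 100.
* PT strings are matched exactly (after case-folding); no MedDRA
  hierarchy or synonym resolution is attempted.
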