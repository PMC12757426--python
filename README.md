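# faersig

Disproportionality signal detection for spontaneous adverse-event
reports, with severity contrasts and time-to-onset Weibull modelling.

Spontaneous-reporting databases such as the FDA Adverse Event Reporting
System (FAERS) collect unsolicited reports of suspected adverse drug
reactions. They have no exposure denominator, so drug safety signals are
found by *disproportionality*: for a focal drug and each MedDRA
preferred term (PT), the 2×2 table

|            | event | no event |
|------------|-------|----------|
| focal drug | a     | b        |
| all others | c     | d        |

is screened with four standard statistics (E = (a+b)(a+c)/N):

- **ROR** = ad/bc, 95% CI exp(ln ROR ± 1.96·√(1/a+1/b+1/c+1/d));
  positive if ROR ≥ 3 and CI low > 1
- **PRR** = [a/(a+b)]/[c/(c+d)] with Pearson χ²;
  positive if PRR ≥ 2, χ² ≥ 4, a ≥ 3
- **BCPNN IC** = log₂((a+½)/(E+½)) with closed-form lower credible bound
  IC025; positive if IC025 > 0
- **MGPS EBGM**: DuMouchel's empirical-Bayes gamma-Poisson shrinker,
  λ ~ P·Γ(α₁,β₁) + (1−P)·Γ(α₂,β₂) fitted by marginal maximum
  likelihood; positive if the 5th posterior percentile EBGM05 > 2

PTs positive on all four are *cross-validated* signals; any-but-not-all
are *hypothesis-generating*. The pipeline also deduplicates raw
quarterly tables (latest FDA date per case, largest primaryid on ties),
compares serious vs non-serious event frequencies (Yates χ², or Fisher's
exact when an expected cell is below 5), stratifies by sex and age band,
flags signals absent from a product-label list, and models time to onset
with a two-parameter Weibull whose shape β classifies the hazard trend
(β < 1 early failure, β ≈ 1 random, β > 1 wear-out).

A bundled synthetic-report generator emits the same table schema with
known planted effect sizes, Weibull onset times and demographic strata,
so every stage is testable without access to the real database.

Intended users: pharmacovigilance analysts and methods researchers who
want a tested, scriptable reference implementation of the standard
signal-detection stack.

## Worked example

Run the full pipeline on a synthetic database of 20,000 reports
(~1,000 with the focal drug as primary suspect; five PTs planted with
reporting ratios 2–10):

```bash
faersig run-all --synthetic-n 20000 --seed 1 --out run1
```

`run1/signals.tsv` then contains one row per PT; the positive tiers at
this seed are:

```
label                             n_cases   ror   ror_ci        ebgm  ebgm05  tier
GASTROOESOPHAGEAL REFLUX DISEASE       69  12.78  (9.37–17.42)  6.80    6.11  cross_validated
ABDOMINAL DISTENSION                   51   8.12  (5.81–11.33)  6.33    5.66  cross_validated
BLOOD GASTRIN INCREASED                 6   4.63  (1.89–11.34)  2.97    1.00  hypothesis_generating
```

Reading the first row: the planted ratio for this PT was 10; among 1,030
focal reports it occurred in 69, against a background rate that makes
the reporting odds ratio 12.8 (the ROR overshoots the reporting-rate
ratio slightly for common events). The empirical-Bayes estimate shrinks
it to 6.8, still far above the EBGM05 > 2 criterion, so all four
algorithms agree — a cross-validated signal. The weakly planted
BLOOD GASTRIN INCREASED (6 cases) clears the frequentist criteria but
not EBGM05 > 2: hypothesis-generating, exactly the behaviour the
conjunction rule is designed to have at small counts.

`run1/manifest.json` records every stage count (21,000 raw reports →
1,000 duplicates removed → 20,000 cases → 1,030 focal), and
`run1/onset_summary.tsv` holds the onset analysis: 912 evaluable
records, median 10 d (IQR 2–41), fitted Weibull scale 24.9 d
(95% CI 22.1–28.2) and shape 0.56 (0.53–0.59) — shape CI entirely below
1, labelled `early_failure`, i.e. the hazard of a new adverse event is
highest right after treatment start and declines thereafter.

The same pipeline runs on real quarterly tables with
`faersig run-all --input-dir <dir> --out <dir>` or a YAML config
(annotated example in `docs/example_config.yaml`). See `docs/methods.md`
for the statistical details and design decisions.

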