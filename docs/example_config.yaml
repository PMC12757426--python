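# Annotated run configuration for `faersig run-all --config <this file>`.
#
# Exactly one of `input_paths` / `synthetic` must be present.

# --- input: real quarterly tables ------------------------------------------
# input_paths:
#   demo: data/demo.txt      # '$'-delimited FAERS ASCII tables
#   drug: data/drug.txt
#   reac: data/reac.txt
#   outc: data/outc.txt
#   ther: data/ther.txt
# delimiter: "$"

# --- input: synthetic database with known ground truth ----------------------
synthetic:
  n_reports: 20000           # total reports in the database
  focal_drug_share: 0.05     # fraction with the focal drug as primary suspect
  duplicate_rate: 0.05       # stale case versions injected for dedup to remove
  partial_date_rate: 0.05    # YYYYMM dates injected; excluded from onset

target_drugs: [VONOPRAZAN]   # normalized names; token-substring match
match_mode: substring        # or: exact

# signal criteria
ror_rule: point              # point: ROR >= 3 & CI low > 1; cases: a >= 3 & CI low > 1
ror_threshold: 3.0
ic_mode: noren               # or: ic_from_ebgm
fdr_method: bh               # or: bonferroni

# onset modelling
onset_offset: 0.5            # half-day shift so day-0 events stay in the fit
onset_ci_method: wald        # or: bootstrap
n_boot: 1000                 # bootstrap resamples (seeded), if selected

seed: 0                      # single seed for all randomness in the run
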