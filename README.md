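# rdci

Confidence intervals for the risk difference of two independent binomial
proportions, and a trial-level pipeline for comparing five interval methods
in non-inferiority settings.

## What it does

* **Five estimators** (`rdci.intervals`): Wald, Agresti–Caffo (add one
  success and one failure per arm), Newcombe (Wilson square-and-add),
  Miettinen–Nurminen (score inversion with restricted-MLE variance and the
  N/(N−1) inflation), and the skewness-corrected asymptotic score (SCAS).
  The score intervals are inverted by bracketed bisection; the constrained
  MLE uses the closed-form cubic with a bounded-likelihood fallback.
* **Trial-table IO** (`rdci.study_io`): a canonical CSV schema with one row
  per treatment-vs-control comparison, success- or failure-reported counts
  (failure rows are re-oriented to successes on load), primary-analysis
  selection (designated primary → ITT → PP), validated reads with
  row-numbered diagnostics, and full-precision result output.
* **Comparison pipeline** (`rdci.comparison`): per-comparison widths,
  width differences vs Wald, strict non-inferiority conclusions
  (lower limit > −margin), widest-method attribution, median/IQR
  summaries, five-method concordance, and a margin sweep (0–20% by 1%).
* **Subgroups and sensitivity** (`rdci.subgroups`): stratification by
  smallest-arm size and pooled success rate, the small-n/high-success
  subgroup, loess width-vs-n curves, and the subsampling sensitivity
  analysis that shrinks trials with smallest arm > 200 to random sizes in
  {50, 100, 150, 200} at the observed rates.
* **Coverage engine** (`rdci.coverage`): exact enumeration and seeded
  Monte-Carlo coverage/expected-width for any of the five methods.
* **Synthetic cohorts** (`rdci.synthetic`): log-normal arm sizes and
  logit-normal success rates calibrated to a target median/IQR, plus a
  fixed six-row fixture covering the pipeline's edge cases.

## CLI

```bash
rdci compute-ci --x1 8 --n1 10 --x2 6 --n2 10 --json
rdci simulate --n-studies 213 --seed 1 --out synth.csv
rdci compare --input synth.csv --out results.csv --summary summary.json
rdci sweep --input synth.csv --margins 0:20:1 --out sweep.csv
rdci subgroup --input synth.csv --max-arm-n 100 --min-rate 0.90 --out sub.json
rdci sensitivity --input synth.csv --seed 1 --out sweep_sub.csv
rdci coverage --method mn --n1 50 --n2 50 --p1 0.95 --p2 0.95
```

Method aliases: `wald`, `ac`, `newcombe`, `mn`, `scas`.

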