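# tsmr

Two-sample Mendelian randomization (MR) from GWAS summary statistics.

`tsmr` implements the complete analysis chain for estimating the causal
effect of an exposure on an outcome from two independent GWAS:

- **gwas_io** — read/validate/filter delimited summary-statistic tables
  (TSV/CSV, configurable column maps), genome-wide significance filtering
  (default p < 5e-8, strict).
- **instruments** — greedy lowest-p-first LD clumping (defaults r² 0.01,
  window 10,000 kb), LD-proxy lookup for SNPs absent from the outcome table,
  per-SNP F-statistics.
- **harmonization** — aligns exposure and outcome effects onto a shared
  effect allele: allele swaps, strand complementation, and
  frequency-based inference for palindromic SNPs (discarded when minor
  allele frequency exceeds 0.42 on either side).
- **estimators** — inverse-variance-weighted (fixed-effect by default,
  multiplicative random-effects optional), MR-Egger, weighted median,
  simple mode, weighted mode, single-SNP Wald ratio; odds ratios and 95% CIs.
- **sensitivity** — Cochran's Q (IVW) and the Egger-fit Q, Egger intercept
  pleiotropy test, leave-one-out, funnel-plot coordinates with a weighted
  asymmetry statistic, Bonferroni thresholds.
- **evalue** — E-value for unmeasured confounding from an observed risk
  ratio (inverting ratios below 1).
- **synthetic** — generator of paired exposure/outcome summary statistics
  under a known causal model with pleiotropy, LD blocks, palindromic
  alleles, and harmonization corruptions, plus a ground-truth record. Every
  statistical claim in the test suite is validated against this generator.
- **pipeline / CLI** — orchestrates read → filter → clump → proxy →
  harmonize → estimate → sensitivity with full per-SNP provenance.

## CLI

```
# full analysis
tsmr run --exposure exposure.tsv --outcome outcome.tsv --ld ld.tsv \
    --seed 1 --out-dir results/
# writes estimates.tsv (long-format table), sensitivity.json,
# provenance.tsv, run.json

# synthetic benchmark data with known truth
tsmr simulate --nsnp 50 --theta 0.5 --frac-allele-swapped 0.3 \
    --ld-blocks "3:0.5" --seed 1 --out-dir sim/

# E-values
tsmr evalue 2.93 0.95

# individual stages
tsmr clump --input sig.tsv --ld ld.tsv --out clumped.tsv
tsmr harmonize --exposure exp.tsv --outcome out.tsv --out harmonized.tsv
```

Input tables are TSV/CSV with headers
`SNP chr pos effect_allele other_allele eaf beta se pval n`; other dialects
are mapped with a JSON column map (`--exposure-columns`). LD is supplied as
a three-column pairs TSV (`snp_a snp_b r2`); it is never computed from
genotypes. Exit codes: 0 success, 2 configuration error, 3 degenerate data.

## Tests

```
python -m pytest -q tests/
```

The suite covers formula-level oracles (IVW vs. weighted-least-squares
through the origin, exact Egger fits, weighted-median interpolation,
dense-grid mode density), statistical calibration (chi-square distribution
of Q under the null, Egger intercept type-I error, IVW coverage/bias), the
harmonization truth table, and end-to-end determinism.

Three tests in `tests/test_acceptance.py`
(`TestCriterion4PaperValueReproduction`) reproduce published per-cancer MR
estimates and **require per-SNP instrument tables that are not bundled**
(they come from a journal supplement). Without those files under `data/`
they fail with instructions; all other tests pass in a clean checkout.

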