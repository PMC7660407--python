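# unres-screen

Detection of **UN**expectedly **RES**istant cell lines — and their putative
resistance biomarkers — in cell-line pharmacogenomic screens and CRISPR
gene-effect datasets.

Given a cell line × drug table of natural-log IC50 values, a binary cancer
functional event (CFE) matrix with metadata, and cell-line annotations, the
pipeline:

1. **Discovers drug-sensitivity associations** per cancer type with a
   covariate-adjusted ANOVA (MSI status, culture medium, growth property)
   and a signed Cohen's d, under the filters ≥4 mutant lines, ≤50%
   extrapolated IC50s, driver-gene CFEs only; retained at p < 0.001 and
   d < −1.
2. **Detects UNRES cell lines** inside each sensitive subpopulation via the
   change in sample SD when the i = 1..min(⌊n/2⌋, 5) highest IC50s are
   removed, with a bootstrap null (B = 10,000 resamples of n values from the
   drug's tissue-wide pool), add-one p-values, a pooled Benjamini–Hochberg
   pass at α = 0.15, and a normalized SD-decrease magnitude.
3. **Controls the two-level hierarchy** (associations → UNRES tests) with
   hierarchical FDR selection and the closed-form bound
   [(D + F)/(D + 1)]·α·δ, and estimates chance discovery rates with a
   within-tissue permutation study.
4. **Proposes resistance biomarkers** per UNRES case: second mutations in
   the sensitivity gene unique to the UNRES lines, mutually exclusive CFEs
   (either direction), and Fisher-exact-enriched CFEs, optionally filtered
   to a cancer gene list.
5. **Ranks resistance mechanisms** on CRISPR gene-effect matrices with a
   differential-essentiality score: per-comparison z-standardized gene-effect
   differences averaged over comparator cell lines, with ±4 highlight sets
   and an optional wt-like classification.

A fully-tested synthetic-screen generator with planted ground truth
(associations, UNRES lines, resistance CFEs, differential genes) makes every
stage testable without external data.

## Test

```bash
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (statistic oracles,
null calibration, planted-truth recovery, hierarchy contract). Two
assertions there are intentionally red: they encode recovery thresholds that
are statistically unattainable under the stated generative model (see the
NOTE comments in the tests for the analysis).

## CLI

```bash
# write a synthetic screen bundle with planted ground truth
unres-screen simulate --seed 1 --out bundle/ --n-unres 1 --plant-resistance

# run every stage (discover → UNRES → HFDR → biomarkers → essentiality)
unres-screen run \
  --drug-response bundle/drug_response.csv \
  --cfe-matrix bundle/cfe_matrix.csv \
  --cfe-metadata bundle/cfe_metadata.csv \
  --annotations bundle/annotations.csv \
  --gene-effect bundle/gene_effect.csv \
  --seed 1 --out results/

# permutation study of the full workflow
unres-screen permute --config run.yaml --n-perm 100 --out results/perm/

# one differential-essentiality contrast
unres-screen essentiality --gene-effect gene_effect.csv \
  --index-cell CL-A --comparators CL-B,CL-C --out results/ess/
```

Subcommands: `simulate`, `discover`, `unres`, `permute`, `biomarkers`,
`essentiality`, `run`. All thresholds can come from a YAML config
(`--config run.yaml`) with CLI flags overriding; defaults are the published
constants (p < 0.001, d < −1, ≥4 mutants, ≤50% extrapolated, α = 0.15,
B = 10,000, i ≤ 5, 100 permutations, Fisher p < 0.05, |Δess| > 4, label at
normalized SD decrease > 0.5). Exit codes: 0 success, 2 validation error,
1 runtime error.

Each run writes stage TSVs (`associations.tsv`, `unres_cases.tsv`,
`biomarkers.tsv`, `delta_ess.tsv`), an `hfdr.json` report with the FDR
bound, and a `manifest.json` recording parameters, seed and SHA-256 input
digests. Reruns with the same seed and inputs are byte-identical.

## Package layout

```
src/unres_screen/
  data_model_io.py         # types + readers/writers for all tabular formats
  synthetic_data.py        # planted-ground-truth screen generators
  sensitivity_assoc.py     # candidate filters, ANOVA, Cohen's d, discovery
  unres_detect.py          # SD-decrease statistic, bootstrap null, BH
  error_control.py         # permutation study, hierarchical FDR, FDR bound
  resistance_biomarkers.py # uniqueness / exclusivity / enrichment routes
  diff_essentiality.py     # pairwise z, delta-essentiality, highlights
  cli_pipeline.py          # RunConfig, stage orchestration, manifests
  cli.py                   # click command-line interface
```
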