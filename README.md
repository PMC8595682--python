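# scpower

Analytic power analysis and experimental-design optimization for
multi-sample single-cell RNA-seq studies.

The package fits a cell-type-specific *expression prior* from pilot count
data (per-gene negative binomial fits, a censored three-component gamma
mixture over gene means, a mean–dispersion trend and linear depth curves
tying the mixture parameters, UMI counts and read depth together). Given
that prior, a ranked *effect-size prior* (log2 fold changes for DE studies,
R² values for eQTL studies) and a candidate design — number of samples
`n_s`, cells captured per sample `n_c`, reads sequenced per cell `r` — it
computes:

- the probability that each gene passes a configurable expressed-gene
  threshold under a pseudobulk analysis, and the expected number of
  expressed genes;
- per-gene significance power (analytic two-rate negative binomial test for
  DE; noncentral-F or, for low pseudobulk means, a discrete count simulation
  for eQTLs), with Bonferroni (FWER) or analytic FDR-inverted thresholds;
- the overall detection power (expression probability × significance power,
  averaged over the prior genes);
- the probability of capturing enough cells of a rare cell type;
- budget-constrained grid optimization of `(n_s, n_c, r)` with a 10x-style
  kit/flowcell cost model, including doublet/overloading and mapping-rate
  adjustments.

Everything runs offline: a synthetic-fixtures module generates pilot counts
and effect priors with known ground truth, and Monte-Carlo oracles back the
test suite.

## CLI

The console script `scpower` exposes the main operations:

```sh
# fit an expression prior from pilot data (repeat --counts for subsampled depths)
scpower fit-prior --counts run.mtx --cells cells.tsv --cell-type "CD4 T" \
    --technology umi-droplet-10x --out prior.json

# expected expressed genes for a design
scpower expressed-genes --prior prior.json --samples 14 --cells-per-type 500 \
    --reads 25000 --min-count 10 --frac-individuals 0.5

# overall detection power
scpower power --prior prior.json --effects effects.tsv --kind de \
    --samples 20 --cells 1500 --reads 20000 --freq 0.25 --mt fdr --alpha 0.05

# budget-constrained design optimization
scpower optimize --budget 10000 --prior prior.json --effects effects.tsv \
    --kind de --freq 0.25 --grid-cells 400:3000:200 --grid-reads 10000:50000:10000

# rare cell type detection
scpower detect-celltype --freq 0.01 --min-cells 10 --samples 20 --target-prob 0.95

# simulated effect-size priors
scpower simulate-priors --kind de --n 250 --rank-max 10000 --seed 7 --out effects.tsv
```

File formats: count matrices as Matrix Market (`.mtx`, genes × cells) or
dense TSV (gene ids in the first column, cell ids in the header); cell
annotations as TSV with columns `cell_id`, `sample_id`, `cell_type`
(optional `batch`); effect priors as TSV with columns `rank` and `log2fc`
(DE) or `r2` / `beta`,`se`,`n` (eQTL), optionally `gene_length`; fitted
expression priors as schema-versioned JSON. For Matrix Market input without
a barcodes file, columns are named `cell_0 .. cell_{n-1}` in file order.

## Package layout

| module | contents |
| --- | --- |
| `scpower.data_model` | shared dataclasses (priors, designs, thresholds, cost model, results) |
| `scpower.io` | count/annotation/effect-prior readers, prior JSON (de)serialization |
| `scpower.prior_fit` | size factors, per-gene NB fits, censored gamma-mixture EM, depth curves |
| `scpower.expression` | depth-specific mixture, rank→mean mapping, expression probabilities |
| `scpower.significance` | DE/eQTL power, dispersion matching, Bonferroni and FDR thresholds |
| `scpower.detection` | overall detection power, threshold helpers and optimization |
| `scpower.design` | doublet model, cost model, rare-cell detection, budget grid search |
| `scpower.simulate` | synthetic priors/counts and Monte-Carlo oracles |
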