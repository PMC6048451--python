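# rewirekit

Transcriptional network-rewiring analysis for gene-expression cohorts:

- **Unsupervised**: diagonal Gaussian mixture clustering of samples, with
  simulation-based significance of the group structure (mean-equality t,
  Steiger correlation-equality chi-square, log-likelihood ratio, delta
  AIC/BIC, all with `(count+1)/(S+1)` empirical p-values).
- **Supervised**: Steiger and Jennrich correlation-matrix equivalence
  tests between mutation-defined groups, with label-permutation nulls.
- **Network architecture**: thresholded correlation networks (edge kept
  iff the Spearman p-value is at most alpha, weight `r^2`), four
  centralities (weighted degree, Wasserman–Faust closeness, unnormalized
  betweenness, eigenvector), consensus-hub calling, and drug candidate
  lookup against a local DGIdb-style table.
- **Modules**: WGCNA-style topological-overlap modules at fixed k,
  maximum-overlap module matching across groups, permutation overlap
  nulls, and per-module rewiring tests.
- **Synthetic data**: cohort generators that plant rewiring (equal group
  means, unequal correlation matrices), correlation hubs, and mutation
  labels with a configurable cluster association — so every stage is
  testable without external data.

## CLI

All commands live under a single `rewirekit` entry point; inputs and
outputs are plain TSV/YAML.  Expression matrices are genes x samples TSV
with a `gene_id` first column; annotations are TSV with a `sample_id`
first column.

```sh
# simulate a cohort with a planted 10-gene rewired block
rewirekit simulate --genes 50 --group-sizes 100,100 --block-r 0.8 --seed 1 demo

# cluster samples and test the group structure
rewirekit cluster --k 2 --restarts 10 --seed 1 demo_expr.tsv demo
rewirekit rewire-test --k 2 --sims 1000 --seed 1 demo_expr.tsv report.tsv

# supervised equivalence tests, networks, modules, associations, drugs
rewirekit matequiv --labels demo_labels.tsv --column label --perms 10000 --seed 1 demo_expr.tsv equiv.tsv
rewirekit network --alpha 0.05 demo_expr.tsv net.tsv centrality.tsv
rewirekit modules --k 10 --labels demo_labels.tsv --column label --perms 1000 --seed 1 demo_expr.tsv mods
rewirekit assoc --clusters demo_labels.tsv --predictors ann.tsv assoc.tsv
rewirekit drugs genes.txt drugs.tsv

# full pipeline from a YAML config
rewirekit run --config run.yaml --mode unsupervised
```

Python API highlights: `rewirekit.fit_mixture`, `rewirekit.delta_criteria`,
`rewirekit.omnibus_rewiring_test`, `rewirekit.steiger_test`,
`rewirekit.jennrich_test`, `rewirekit.permutation_equivalence_test`,
`rewirekit.build_network` / `centralities` / `consensus_hub`, and
`rewirekit.detect_modules`.

## Conventions

- Empirical p-values are `(1 + #{null > observed}) / (S + 1)`; with
  S = 1000 the attainable floor is `1/1001 ~ 9.99e-4`.
- The homogeneity null for the omnibus test defaults to random
  orthogonal rotation of the centered data, which preserves the sample
  mean and covariance exactly and gives exactly calibrated p-values
  under a Gaussian null (`null="parametric"` selects fresh
  multivariate-normal draws from the estimated covariance instead).
- Spearman correlation is the default everywhere; Pearson is available
  for Gaussian calibration work.
- Randomness is PCG64 (`numpy.random.default_rng`) seeded through
  `numpy.random.SeedSequence`; identical seeds give identical results.
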