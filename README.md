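# medibench

Benchmark of time-series network-inference methods on simulated microbial
communities whose interactions are either **chemically mediated** (species
interact only through produced/consumed chemicals) or **direct** (pairwise
Lotka–Volterra terms), with or without competition for a shared resource
pool.

The package simulates stochastic community dynamics under four model
variants (`M`, `Mprime`, `D`, `Dprime`), selects diverse coexisting
communities by an evolutionary search, derives ground-truth directed
interaction networks, runs five inference methods on resampled abundance
series, and scores detection quality with ROC-AUC and precision on the
top-five-abundance subnetwork.

## Layout

| module | role |
| --- | --- |
| `medibench.mediator_sim` | model definitions, parameter sampling, Euler–Maruyama integration, tail resampling, TSV/JSON serialization |
| `medibench.ground_truth` | analytic Jacobian blocks, effective interaction matrix, structural presence patterns |
| `medibench.community_search` | community score, swap mutation, evolutionary search, benchmark dataset assembly/persistence |
| `medibench.inference` | Pearson/Spearman, local similarity analysis (LSA), convergent cross mapping (CCM), sparse stepwise-bagging regression (LIMITS-style) |
| `medibench.evaluation` | top-k species selection, midrank ROC-AUC, precision at half, Mann–Whitney summaries |
| `medibench.fixtures` | synthetic generators with known truth (discrete gLV, coupled logistic maps, correlated Gaussians) |
| `medibench.benchmark` | generate → infer → evaluate orchestration |

Conventions: matrix entry `(i, j)` always means "effect of species *j* on
species *i*"; statistics are ranked by magnitude and p-values ascending
when used as interaction classifiers.

## CLI

```sh
# search accepted communities and write a dataset directory per condition
medibench generate --model Mprime --n-communities 5 --tau 40 --sigma 1.0 \
    --seed 0 --out data/

# run one method on a series TSV
medibench infer --method limits --in data/Mprime_tau40_sigma1/community_0/series.tsv \
    --out result.json --seed 1 --option n_bags 200

# score every community of a stored dataset
medibench evaluate --dataset data/Mprime_tau40_sigma1 --method pearson \
    --method limits --seed 2 --out eval/

# end-to-end benchmark from a YAML/JSON config
medibench benchmark --config bench.yaml --out bench_out/

# regenerate synthetic test fixtures
medibench fixtures --generator glv --seed 0 --out fixtures/glv/
```

A minimal benchmark config:

```yaml
models: [Mprime, Dprime]
methods: [pearson, spearman, lsa, ccm, limits]
n_communities: 10
tau: 40
sigma: 1.0
seed: 0
search: {Tmax: 30}
method_kwargs:
  limits: {n_bags: 200}
```

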