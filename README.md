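# cyanoniche

Strain-level niche-partitioning analysis for amplicon time series of
bloom-forming cyanobacteria. The package decomposes aligned reads into exact
sequence variants by positional-entropy splitting, quantifies conditionally
rare taxa, infers taxon-environment responses with a latent variable model,
infers co-occurrence with compositional (SparCC-style) correlation, and
tests how niche similarity decays with pairwise genetic distance. A
synthetic-study generator makes every stage testable offline.

## Modules

| Module | Purpose |
| --- | --- |
| `cyanoniche.datamodel` | count/environment/sequence tables, TSV/FASTA I/O, depth filtering |
| `cyanoniche.med` | entropy-based decomposition of reads into variant nodes (`-M` noise filter) |
| `cyanoniche.compositional` | multiplicative zero replacement, clr at inter-/intra-genus grain |
| `cyanoniche.crt` | bimodality-coefficient detection of conditionally rare taxa, Fisher enrichment |
| `cyanoniche.sparcc` | log-ratio-variance basis correlations, Dirichlet resampling, permutation p-values, network export |
| `cyanoniche.lvm` | latent variable niche model, environmental/residual correlation matrices, AIC polynomial fits |
| `cyanoniche.decay` | p-distance, co-occurrence and niche-similarity decay regressions, partner divergence |
| `cyanoniche.simulate` | synthetic studies: trees, sequences, GP niche coefficients, logistic-normal-multinomial counts, planted bursts |
| `cyanoniche.cli` | `cyanoniche` executable with per-stage subcommands and a full pipeline |

## CLI

Each stage is a subcommand; `all` runs the pipeline from one config:

```sh
# generate a synthetic study
cyanoniche simulate --seed 1 --out study/

# single stages
cyanoniche med reads.fasta -M 500 --out med/
cyanoniche crt study/counts.tsv --group-map genus_map.tsv --out crt/
cyanoniche sparcc study/counts.tsv --n-resample 20 --bootstraps 500 --out sparcc/

# everything, from a YAML/JSON config
cyanoniche all --config pipeline.yaml --out results/
```

A minimal pipeline config:

```yaml
seed: 7
simulate:
  n_samples: 135
  n_background_taxa: 60
sparcc:
  n_resample: 20
  n_bootstrap: 100
lvm:
  n_latent: 2
  prevalence: 0.70
```

The run writes per-stage outputs (TSV/FASTA/JSON) plus a check-summed
`manifest.json`; identical config and seed reproduce identical checksums.

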