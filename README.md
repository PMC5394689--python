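# omiclust

Condition clustering of multi-omics (mRNA / protein) count data, built
around a permutation z-score test on mean cophenetic distances, plus
doubling-time estimation from OD600 growth curves and flux-ratio trend
regressions with FDR correction. A seeded synthetic-data generator makes
every stage testable without external downloads.

## What it does

1. **I/O & validation** (`omiclust.io_model`) — gene-by-sample count TSVs
   (protein counts rounded half-away-from-zero, blanks zero-filled),
   sample metadata, growth curves, flux-ratio tables; JSON result
   serialization with lossless round-trips.
2. **Preprocessing** (`omiclust.preprocess`) — replicate-consistency QC on
   log2 count differences; median-of-ratios size factors computed on the
   +1-pseudocounted matrix and applied to the raw counts; log transform.
3. **Clustering** (`omiclust.clustering`) — Euclidean sample distances,
   complete-linkage agglomeration with deterministic tie-breaking, the
   cophenetic matrix of the dendrogram, Newick export.
4. **Permutation test** (`omiclust.permtest`) — for each experimental
   variable (growth phase, carbon source, Na+/Mg2+ level, batch), the mean
   cophenetic distance over same-label sample pairs is compared against a
   reshuffled-label null and reported as a z-score (z < −1.96: the
   variable clusters samples significantly).
5. **Growth** (`omiclust.growth`) — doubling times via OLS of log OD600
   over the 0.05–0.75×max exponential window; replicate t-intervals.
6. **Flux statistics** (`omiclust.flux_stats`) — per-ratio OLS trends
   against Na+, log Mg2+, or doubling time; Benjamini–Hochberg FDR across
   the 13 ratios.
7. **Synthetic data** (`omiclust.synthetic_data`) — negative-binomial
   count matrices with planted condition/batch effects ("mrna-like",
   "protein-like", "null" presets), noisy growth curves, flux tables.

## CLI

```sh
# synthetic dataset with a dominant growth-phase effect
omiclust simulate --preset mrna-like --n-genes 1000 --seed 7 --out-dir sim/

# individual stages
omiclust qc --counts sim/counts.tsv --metadata sim/meta.tsv --out qc.json
omiclust normalize --counts sim/counts.tsv --omics mrna --out norm.tsv
omiclust cluster --norm norm.tsv --out-coph coph.tsv --out-newick tree.nwk
omiclust permtest --coph coph.tsv --metadata sim/meta.tsv \
    --variables growth_phase,carbon_source,na_level,mg_level,batch \
    --n-perm 10000 --seed 42 --out ztable.json
omiclust growth --curves growth.tsv --out doubling.json
omiclust flux --table flux.tsv --covariate doubling_time_min --out flux.json

# everything end-to-end from one config
omiclust run --config run.yaml
```

Minimal `run.yaml`:

```yaml
out_dir: run/
seed: 42
simulate_preset: mrna-like   # or: counts: counts.tsv / metadata: meta.tsv
n_perm: 10000
```

The run writes every intermediate artifact (normalized matrix, cophenetic
TSV, Newick dendrogram, permutation-test JSON, ...) plus a
`manifest.json` with seed, stage timings and sha256 checksums; reruns
with the same config and seed are byte-identical.

## Conventions worth knowing

- Size factors use the median of `(count+1)/geometric-mean reference`
  ratios; the raw (un-pseudocounted) counts are then divided.
- The clustering input is `log2(normalized + 1)` by default; pseudocount
  and base are configurable.
- The per-variable "overall" statistic pools all same-label pairs
  (pair-weighted); a per-level-mean variant is available via
  `method="level_mean"`.
- Na+ levels bin at ≥100 mM → "high"; Mg2+ at 0.8 mM → "base" (below:
  "low", above: "high"); thresholds are user-editable
  (`permtest.VariableBinning`).
- The FDR procedure is Benjamini–Hochberg; correction is applied across
  the 13 ratios within one covariate family.
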