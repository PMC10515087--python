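# thermevol

Phylogenetic comparative analysis of evolutionary rates for plant
physiological thermal tolerance (cold tolerance `T_min`, heat tolerance
`T_max`) versus climatic-niche temperatures (`MTCM` = coldest-month
minimum / Bio6, `MTWM` = warmest-month maximum / Bio5), on a
time-calibrated phylogeny.

The package provides:

- **`thermevol.phylo`** — Newick I/O, tip pruning that preserves
  root-to-tip depths, phylogenetic shared-path covariance matrices, and
  branch-length/covariance transforms for BM, single-optimum OU
  (fixed-root convention), Pagel's λ, and white noise.
- **`thermevol.models`** — maximum-likelihood fits of the four trait
  evolution models (σ², root state, α or λ, lnL, AIC) with AIC model
  selection.
- **`thermevol.ratecomp`** — the core statistic: a χ²(1) likelihood-ratio
  test of a common-rate model against a separate-rates model for two
  traits on the same tree (independent BM processes with separate means).
- **`thermevol.ancrates`** — GLS ancestral state reconstruction on the
  best-model covariance, per-species absolute rates
  `|tip − ancestor| / branch time`, and paired t-tests on ln rates.
- **`thermevol.niche`** — species-level niche summaries from
  occurrence-climate records (mean, 90th/10th-percentile tails, local
  site values), trait-measurement averaging, hardening/group strata,
  ESRI-ASCII climate-grid lookup.
- **`thermevol.pgls`** — phylogenetic GLS regression (fixed or ML λ) and
  the six tolerance~niche panels across hardening strata.
- **`thermevol.simulate`** — Yule trees, correlated BM / OU / λ trait
  simulation, and a full synthetic scenario generator so every stage is
  testable without downloads.
- **`thermevol.pipeline` / CLI** — orchestration across the four trait
  comparisons × taxonomic groups × hardening strata.

## CLI

```sh
# generate a synthetic scenario (tree, raw traits, occurrences, grids)
thermevol simulate --out scen/ --seed 1 --n-species 200

# summarize occurrences into species-level niches
thermevol niche --occurrences scen/occurrences.csv --out niche.csv \
    --sites scen/sites.csv --bio5 scen/bio5.asc --bio6 scen/bio6.asc

# overall-rate LRTs, absolute rates, PGLS — or everything at once
thermevol rates    --tree scen/tree.nwk --traits scen/traits_raw.csv \
    --occurrences scen/occurrences.csv --out results/
thermevol absrates --tree scen/tree.nwk --traits scen/traits_raw.csv \
    --occurrences scen/occurrences.csv --out results/
thermevol pgls     --tree scen/tree.nwk --traits scen/traits_raw.csv \
    --occurrences scen/occurrences.csv --out results/
thermevol run-all  --tree scen/tree.nwk --traits scen/traits_raw.csv \
    --occurrences scen/occurrences.csv --out results/
```

All commands also accept `--config FILE` with flat `key = value` lines
(keys mirror `thermevol.pipeline.AnalysisConfig`), plus
`--niche-variant {mean,tail,local}`, `--lambda-mode {fixed,ml}`, and
`--seed`.  Each result table is written rounded to 2 decimals and as a
`*_full.csv` companion at full precision, with a `run_manifest.json`
recording versions, seed, options, and input checksums.

## Conventions

- Rates are ML estimates with divisor *n* (REML optional); AIC is
  `2k − 2 lnL` with k = 2 (BM, WN) or 3 (OU, λ).
- The OU covariance uses the fixed-root, non-stationary convention on an
  ultrametric tree; WN is realized as `T·I` (T = tree height) so σ² is
  commensurate across models.
- Percentiles use linear interpolation between order statistics.
- Absolute-rate divisors default to the terminal branch length
  (`--time-mode depth` divides by tip age instead); zero-rate species are
  excluded from ln-scale paired tests and counted.
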