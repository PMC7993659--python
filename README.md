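# omicstrata

Integrative genomic / epigenomic / transcriptomic subtyping pipeline: from raw
copy-number segments, methylation probes, expression matrices and mutation
calls to molecular subtypes and their clinical characterization. Every stage
is exercised end-to-end against a synthetic multi-omics generator that plants
the statistical structure the analysis assumes, so the whole pipeline is
testable offline.

## Stages

1. **synthetic_data** — coupled multi-omics simulator: planted subtypes,
   positive CNV→expression and negative promoter-methylation→expression
   coupling, correlated per-sample event burdens, per-subtype survival
   hazards. One seed, byte-identical output.
2. **ingest_preprocess** — SEG/MAF/TSV readers; segment merging (reciprocal
   50% overlap, <5-probe filter), gene-level CNV mapping, methylation probe
   filtering (>70% missing dropped) + KNN imputation, promoter-window probe
   mapping (TSS −2000/+200, strand-aware), zero-fraction expression filter,
   silent/intron mutation filter.
3. **event_stats** — per-sample Gain/Loss (|log-ratio| > 0.3) and
   MetHyper/MetHypo (β > 0.8 / < 0.2) tallies and their six pairwise Pearson
   concordance correlations.
4. **gene_stratification** — per-gene omics–expression Pearson screen with
   Fisher z = ln((1+r)/(1−r)) and p < 1e-5 gene sets (CNV-G / MET-G);
   median-split log-rank prognostic screen; set intersection.
5. **nmf_subtyping** — KL-divergence ("brunet") NMF consensus clustering over
   random restarts; cophenetic coefficient, dispersion and silhouette for
   rank selection (K = 2–10, minimum cluster size 10).
6. **icluster_integration** — lasso-penalized Gaussian latent-variable model
   shared across data types (EM; k−1 latent dimensions; k-means on posterior
   latent means); 101-point lambda screening; 20-repeat stability report for
   K = 2, 3, 4.
7. **subtype_characterization** — exact 2×2/2×3 contingency tests (full
   enumeration, Monte-Carlo above 200 observations), NB Wald differential
   expression (median-of-ratios size factors, method-of-moments dispersion;
   2-fold + FDR < 0.05 rule), mutation-frequency Fisher tests, Kaplan–Meier +
   log-rank survival comparisons, L1/L2/L3 expression-tier marker
   stratification, Kruskal–Wallis / rank-sum score comparisons, and
   hypergeometric over-representation against GMT gene sets.
8. **pipeline_cli** — orchestrates all stages from one YAML config with a
   run manifest (parameters, output hashes, warnings).

## CLI

```sh
# full pipeline from a config
omicstrata run --config config.yaml

# or stage by stage
omicstrata simulate --out data/ --seed 7 --n-samples 159 --n-genes 2000
omicstrata preprocess --seg data/cnv_segments.seg --beta data/beta.tsv \
    --probe-anno data/probe_annotation.tsv --gene-anno data/gene_annotation.tsv \
    --expr data/expression_fpkm.tsv --maf data/mutations.maf --out pre/
omicstrata events --cnv pre/cnv_gene.tsv --beta pre/met_gene.tsv --out ev/
omicstrata stratify --cnv pre/cnv_gene.tsv --met pre/met_gene.tsv \
    --expr pre/fpkm.tsv --clinical data/clinical.tsv --out strat/
omicstrata nmf --expr pre/fpkm.tsv --genes strat/genes_cnv.txt --out nmf/
omicstrata icluster --cnv pre/cnv_gene.tsv --met pre/met_gene.tsv \
    --expr pre/fpkm.tsv --genes-cnv strat/genes_cnv.txt \
    --genes-met strat/genes_met.txt --k 3 --out ic/
```

Example YAML config (all sections optional; `enabled: false` skips a stage):

```yaml
outdir: run/
seed: 7
simulate: {n_samples: 159, n_genes: 2000, n_subtypes: 3,
           hazard_ratios: [1.0, 2.0, 4.0]}
nmf: {kmin: 2, kmax: 10, nrun: 50}
icluster: {k_values: [2, 3, 4], lambdas: [0.1, 0.1, 0.1], repeats: 20, k: 3}
```

## Notes

- All file formats are plain TSV (SEG-like segments, gene × sample matrices,
  MAF-like mutations, GMT gene sets). Coordinates in files are 1-based
  inclusive.
- The expression scale for correlation, NMF and integrative clustering is
  log2(FPKM+1); β values are logit-transformed before integrative
  clustering.
- The published lambda vectors for K=2 and K=3 are shipped as documented
  presets (`icluster_integration.PRESET_LAMBDAS`), not defaults.
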