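# toxscore

Toxicogenomic integration for tumor transcriptomes: does a curated
chemical-exposure gene set (e.g., the lead/Pb interaction genes curated in
CTD) sit non-randomly inside the differential-expression signal of a
tumor-vs-normal cohort, and does a tumor-level composite of that overlap
carry prognostic information?

The package implements the full analysis chain for TCGA-style bulk RNA-seq
cohorts (the motivating application is bladder urothelial carcinoma with
412 primary tumors and 19 solid-tissue normals over 20,530 genes):

1. **Differential expression** (`toxscore.dge`) — per-gene Welch's *t* on
   log2 expression, Benjamini–Hochberg FDR over the retained universe,
   significance at FDR < 0.05 with an optional |log2FC| ≥ 1 sensitivity
   threshold, and top-candidate selection by lowest FDR.
2. **Exposure-set enrichment** (`toxscore.enrichment`) — the exact
   right-tailed hypergeometric test on the sufficient statistics
   (M, K, n, k): universe size, exposure genes in the universe, DEG-set
   size, overlap size;

   p = Σ_{j=k}^{min(n,K)} C(K,j) C(M−K,n−j) / C(M,n)

   summed exactly in log space (log-gamma binomials), with configurable
   background universes (all measured genes, protein-coding only, or genes
   expressed in ≥ 80 % of tumors).
3. **Pathway over-representation** (`toxscore.ora`) — hypergeometric ORA of
   the exposure–DEG overlap against GMT collections, 10–500 member size
   filter applied before testing, BH FDR within each collection, GeneRatio
   (k/n) reporting.
4. **Exposure-response score** (`toxscore.pb_score`) — per tumor, the
   signed z-composite S_i = (1/|G|) Σ_g sign(log2FC_g) · z_{gi}, with
   z-standardization across tumors only, standardized to SD units; plus an
   ssGSEA-style rank-weighted single-sample score for concordance checks.
5. **Survival association** (`toxscore.survival`) — from-scratch
   Kaplan–Meier, log-rank, and Cox proportional hazards with Breslow tie
   handling (Newton–Raphson on the partial likelihood), hazard ratios per
   1 SD with Wald 95 % CIs, adjustment for age (per 10 y), sex, and
   pathological stage (ordinal or categorical), median/tertile splits, a
   cross-validated maximally-selected log-rank cutpoint, restricted-cubic-
   spline linearity tests, and Schoenfeld-type PH diagnostics.
6. **Robustness suite** (`toxscore.robustness`) — leave-one-gene-out score
   stability, tumor bootstrap of the adjusted HR, size- and
   abundance-matched random-gene-set negative controls, and stage/sex
   subgroup models.
7. **Synthetic cohorts** (`toxscore.synthetic_data`) — a generator with
   known ground truth (true DE genes and directions, true exposure-set
   enrichment, true score–hazard coefficient) emulating the TCGA-BLCA data
   structure, so every stage is testable without any download.

## Worked example

Run the whole pipeline on a simulated desk-scale cohort (60 tumors,
10 normals, 500 genes, an 80-gene exposure set whose genes are
differentially expressed at 4× the background rate, and a protective
composite effect of −0.5 log-hazard per SD):

```yaml
# run.yaml
seed: 42
simulate:
  n_tumor: 60
  n_normal: 10
  m_genes: 500
  k_exposure: 80
  frac_de: 0.2
  enrichment_rho: 4.0
  effect_size_log2: 1.5
  beta_score: -0.5
  censor_rate: 0.5
robustness:
  bootstrap_B: 100
  null_sets: 200
```

```bash
toxscore all --config run.yaml --out demo
# pipeline complete: k=23 overlap genes, enrichment p=8.398e-07
```

`demo/report.json` then contains (seed 42):

- `n_deg = 55` significant genes at FDR < 0.05, `n_deg_strict = 51` after
  adding |log2FC| ≥ 1 — the planted 20 % DE fraction is recovered at the
  power this sample size affords;
- enrichment tuple `(M=500, K=80, n=55, k=23)` with right-tail
  `p = 8.40e-07`: the planted 4× exposure enrichment is detected;
- `score_ssgsea_concordance = 0.945` — the signed z-composite and the
  ssGSEA-style score rank tumors nearly identically;
- adjusted Cox model for overall survival: HR per SD = 0.63
  (95 % CI 0.43–0.93, p = 0.019, 60 patients / 30 events), recovering the
  protective generating coefficient (true HR e^{−0.5} ≈ 0.61);
- median-split log-rank p = 5.8e-04; bootstrap HR CI (0.40, 0.87); the
  observed enrichment beats all 200 size-matched random gene sets
  (`null_enrichment_quantile = 0.0`).

Individual stages are also available as `toxscore simulate`,
`toxscore dge`, and `toxscore enrich`, or directly as library calls
(`run_dge`, `enrich_overlap`, `fit_score`, `cox_fit`, ...).

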