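# Methods

## Analysis model

The package treats a toxicogenomic integration analysis as five linked
inferences on a gene × sample log2-expression matrix with a tumor/normal
partition derived from TCGA-style barcodes ("01" primary tumor, "11"
solid-tissue normal; all other sample-type codes are dropped).

**Differential expression.** Per gene, Welch's unequal-variance *t*-test
compares tumors with normals; the log2 fold change is the difference of
group means of the already-log2 values (tumor − normal), so positive
values mean higher expression in tumor. BH step-up adjustment runs over
exactly the post-QC gene universe (duplicate symbols mean-collapsed,
zero-variance genes removed), not only over genes with finite statistics.
Significance is FDR < 0.05; a "strict" flag adds |log2FC| ≥ 1. Output
rows are totally ordered by (q, p, −|log2FC|, symbol) so files reproduce
byte-identically. Degenerate genes with zero variance in both groups get
p = 1 when the means agree and a p = 0 sentinel (with a warning) when
they differ.

**Exposure-set enrichment.** The test statistic is the exact right tail
P(X ≥ k) of Hypergeometric(M, K, n): M genes in the background universe,
K exposure genes inside it, n DEGs inside it, k in the overlap. Terms
are evaluated through log-gamma binomial coefficients and combined with
logsumexp — no normal or saddlepoint approximation — because at
M ≈ 20,000 the interesting p-values live at 1e-9 to 1e-15, where an
approximation's relative error would dominate. Both sets are clipped to
the universe before counting; K = 0 or n = 0 is an error (the test is
uninterpretable), distinct from k = 0 (a valid p = 1). A single a priori
chemical set is a single hypothesis; no multiplicity correction is
applied across chemicals. Background choices: all measured genes
(default), a supplied protein-coding list, or genes above the expression
floor (the matrix's global minimum by default) in at least 80 % of
tumors.

**Pathway ORA.** Same hypergeometric machinery per term. Term size is
measured after intersection with the universe (a flag restores raw
membership) and the 10–500 window is applied *before* testing, so the BH
family within each collection contains only tested terms. Adjustment is
per collection, never pooled. An optional greedy Jaccard collapse
(threshold 0.5) thins redundant terms for display only; it replaces
semantic-similarity consolidation and is labeled non-canonical.

**Exposure-response score.** For each overlap gene, expression is
z-standardized across primary tumors only (mean 0, SD 1); the composite
is the mean of signed z-scores, the sign being the direction of the
gene's tumor-vs-normal log2FC from the same run; scores are then
standardized to SD units over the fitting cohort. Genes with zero tumor
SD or log2FC exactly 0 are excluded with a log message. A fitted model
applied to new samples reuses the stored gene means/SDs — required for
honest resampling. The ssGSEA-style alternative ranks each sample's
genes (ascending, ties broken by symbol), walks from the top rank down,
and accumulates the rank^α-weighted in-set ECDF minus the unweighted
out-set ECDF (α = 0.25, the conventional exponent, exposed as a flag);
scores are cohort range-normalized to [0, 1] and centered.

**Survival.** Kaplan–Meier, the two-group log-rank test, and Cox
regression are implemented directly on their estimating equations. The
Cox fitter maximizes the Breslow partial likelihood by Newton–Raphson
with step-halving; convergence at max |score| < 1e-9 or relative log-PL
change < 1e-12, hard stop at 100 iterations. Monotone likelihood
(perfect separation) is diagnosed by a scale-aware check
(|β|·sd(x) > 15). Wald CIs use z = 1.959964. Continuous predictors are
standardized to SD 1 over the per-endpoint complete-case analysis set,
so HRs are per 1 SD; adjustment covariates are age/10, male sex
indicator, and stage coded ordinal 1–4 (default) or as indicators with
the lowest *present* stage as reference (so a stratum without Stage I
patients cannot produce a likelihood-invariant direction). Complete-case
filtering is per endpoint; sample sizes legitimately differ across
endpoints and are always reported. Median splits send ties to "low".
The maxstat cutpoint searches distinct values inside the 10–90 %
quantile range, picks the log-rank-maximizing cut per training fold of a
10-fold CV, reports the median of fold-optimal cuts plus held-out
log-rank p-values. The spline linearity test uses the restricted
(natural) cubic basis with knots at the 10/50/90 % predictor quantiles
and a likelihood-ratio test with df = knots − 2 against the nested
linear model. PH diagnostics correlate Schoenfeld residuals (observed
minus risk-set-weighted expected covariate at each event time, tied
events sharing the full risk set) with event rank and report a z-test.

**Robustness.** Leave-one-gene-out refits the composite (re-standardized)
and the adjusted Cox model per deletion. The tumor bootstrap resamples
tumors with replacement and, by default, refits the score's
z-parameters inside each replicate (full-pipeline bootstrap; a
frozen-parameter mode exists) before refitting the Cox model; the CI is
the 2.5/97.5 percentile interval, and more than 10 % non-converged
replicates is an error. Negative controls draw size-matched random gene
sets from the universe, or stratified draws matching the observed set's
decile profile of mean tumor expression (deciles on the universe;
per-draw bin histograms are returned so matching is checkable).
Subgroup fits follow the published adjustment sets: stage strata
(I–II vs III–IV) adjust for age only; sex strata adjust for age and
ordinal stage.

## Synthetic cohorts

The generator is the test bed for every stage, so its defaults are the
study conditions of the motivating cohort: 412 tumors + 19 normals over
20,530 genes, a 2,618-gene exposure set, age ~ Normal(69, 10) truncated
to [30, 95], 73.8 % male, stage distribution (I, II, III, IV, missing) =
(0.5, 31.8, 34.2, 33.0, 0.5) %, censoring fraction 0.56, and a weak
protective score effect (β = −0.078 per SD, HR ≈ 0.93). The marginal DE
fraction defaults to 0.557 (the full-scale DEG fraction) with exposure
genes DE at ρ = 1.09 times the background rate — the relative risk
implied by the published (M, K, n, k) tuple.

Generative law: per-gene baseline μ_g ~ Uniform(3, 12) on the log2
scale with residual noise SD 1 (typical of log RSEM values); a fraction
`frac_de` of genes is truly DE, exposure genes at ρ× the renormalized
background probability so the marginal stays at `frac_de`; effect sizes
|δ_g| ~ Exponential(mean = `effect_size_log2`), direction up with
probability 0.55 (tumor cohorts are predominantly up-shifted; with mean
1.0 the implied fraction of |log2FC| ≥ 1 among DE genes, e^{-1} ≈ 0.37,
matches the full-scale strict/primary DEG ratio). Each tumor carries a
latent program-activity factor a_i ~ Normal(1, 0.3) multiplying its DE
shifts: real cohorts show coherent between-tumor variation in signature
activity, and this factor is precisely what single-sample scores
measure — without it the composite would be averaging independent noise
and no scoring method could agree with any other. Survival is
exponential with hazard h0·exp(β_score·S_i + 0.18·age/10 + 0.10·male +
0.45·(stage−2.5)), where S_i is the realized signed composite over the
exposure ∩ true-DE genes with true directions; censoring is independent
exponential with its rate solved by bisection so the expected censoring
fraction hits the target exactly under the model. Random streams are
split per component (expression, clinical, survival, pathways) from one
seed, so changing, say, the survival coefficients cannot perturb the
expression draw.

The desk-scale fixture (500 genes, 60 + 10 samples) uses a deliberately
strong planted signal — DE fraction 0.2 at ρ = 4, mean effect 1.5,
β_score = −0.5 — because recovery-style tests (sign of the fitted HR,
enrichment detection) need adequate power at 30 events; the full-scale
default β of −0.078 is a ~1-SE effect even at 412 tumors and is
deliberately weak, mirroring the motivating cohort's non-significant
composite.

What the generator does **not** emulate: negative-binomial count noise,
gene–gene correlation beyond the single program factor, batch effects,
molecular subtype structure, informative censoring, or non-proportional
hazards. Tests passing on these cohorts therefore certify the
statistical machinery and the pipeline plumbing, not robustness to those
real-data pathologies.

## Numerical and design notes

- BH is the step-up transform q(i) = min_{j≥i} min(1, p(j)·m/j) computed
  in O(m log m); verified against an independent O(m²) double loop and
  statsmodels.
- The hypergeometric right tail saturates in double precision: successive
  tails near p = 1 differ by less than one ulp, and deep tails underflow
  below ~1e-308. Monotonicity is therefore asserted strictly only in the
  resolvable mid-range.
- Welch–Satterthwaite p-values are anticonservative in the far tail when
  one group is very small: with a 10-sample normal arm under exact
  normality, the measured P(p < 1e-4) is ≈ 3e-4. Genome-wide BH puts the
  rejection boundary exactly in that tail, so global-null FDR calibration
  is verified at the study's arm sizes (412/19), where the measured mean
  false-discovery proportion is ≈ 0.055 at the nominal 0.05. This is a
  property of Welch's approximation, not of the BH implementation (which
  is oracle-exact).
- The Cox fitter's information matrix uses cumulative sums over the
  descending-time sort, giving O(n·p²) per Newton iteration; tied event
  times share the full-risk-set denominator (Breslow). Efron/exact ties,
  time-varying covariates, competing risks, and frailty are out of scope.
- log2FC is difference-of-log-means. Published tables from the motivating
  analysis imply two different fold-change conventions in different
  tables; this package fixes one convention and documents it rather than
  guessing which table is canonical.
- The bootstrap refits z-parameters per replicate by default because the
  frozen-parameter variant understates score-estimation uncertainty; both
  modes are exposed since the original description does not say which was
  used.
- The synonym table for symbol harmonization is a user-supplied
  two-column file; full HGNC reconciliation is out of scope, and legacy
  symbols are left unmapped unless the user provides mappings (the
  motivating analysis itself reports a legacy symbol among its top
  genes).
- Pipeline outputs carry a `#` provenance header (version, seed, config
  hash, no timestamps) and all floats are written as %.17g with
  round-trip parsing, so a rerun with the same config and seed is
  byte-identical.
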