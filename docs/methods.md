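# Methods

This note documents the models, estimators, parameters and design choices
behind each stage of `atlaskit`, and what the synthetic-data tests do and
do not establish about behavior on real data.

## Data model and normalization

A `CellMatrix` holds nonnegative-integer sparse counts (cells × genes,
optionally cells × ADT markers) with per-cell metadata (donor, tissue,
coarse tissue group, lineage, subset, age group, sex, CMV serostatus,
processing site, chemistry) and per-gene nuisance-list flags.  Fine
sampling sites map onto six coarse tissue groups (blood; bone marrow;
spleen; the three lymph-node stations pooled; airway lavage + lung
parenchyma pooled; jejunum epithelium + lamina propria pooled); the
mapping is configuration, not code.

Normalization is `ln(scale · c / T + 1)` with `scale = 10,000` for gene
expression and `1,000` for ADTs, where `T` is the cell's total count in
that modality.  Natural log is a fixed package convention (the dominant
single-cell choice).  Zero counts remain exactly zero, so sparsity is
preserved.

Depth equalization across groups thins each cell binomially at rate
`target / group_mean_depth`, with the target being the minimum group mean.
Binomial thinning is the default because it is exactly mean-matching in
expectation and embarrassingly vectorizable; an exact multinomial
subsample per cell (`method="multinomial"`) is available when the
per-cell total must be hit exactly.

## Synthetic atlas generator

The generator is the package's study-condition definition, not a test
fixture.  Defaults: 24 donors (14 male / 10 female, half over 40 years,
CMV ~50%, two processing sites, two chemistries), six tissue groups, a
lineage → subset hierarchy, 800 genes, 80 cells per donor × tissue sample,
mean depth 1,500 with log-normal spread (σ = 0.25).

Counts are gamma-Poisson: each cell carries nonnegative activities over a
set of programs (a baseline program on all genes, one per lineage, one per
subset, optional tissue-resident programs active ~5× in their home tissue,
and five nuisance programs drawn from the heat-shock / ribosomal /
metallothionein / hemoglobin / dissociation-stress gene lists); the rate
vector is `depth · (A L)ᵀ` row-normalized, multiplied by a
`Gamma(θ, 1/θ)` factor with θ = 10, giving NB variance `μ + μ²/θ`.
Planted age effects multiply either a program's activity or named genes'
rates by `2^log2FC` for old donors in scope; planted tissue effects do the
same per tissue group.

Composition per donor × tissue is Dirichlet within lineage.  The
concentration default (10 per subset) gives a donor-to-donor coefficient
of variation near 0.3 for a subset at 1/6 of its lineage, matching typical
human immune-frequency spread; planted shifts multiply the Dirichlet
parameter of the target subset (per tissue, or for old donors).

Contaminants: doublets are sums of two random cells' counts and receive
high doublet probabilities (Beta(8,2)); erythrocytes are hemoglobin-program
profiles with a 95%-sensitive predicted-erythrocyte flag.  ADTs are
two-component log-normal mixtures per marker with additive per-site shifts
on the log scale (σ = 0.4), so landmark registration has true peaks to
find.  Clonotypes follow a power law whose exponent is tuned by bisection
against a Monte-Carlo estimate of the subsampled clonality score.

What the generator does **not** emulate: transcriptome-wide correlation
structure beyond shared programs, ambient RNA, sequence-level V(D)J
structure, batch effects in gene expression, or continuous age.  Passing
the planted-recovery suites therefore shows the algorithms are correct and
calibrated under the stated generative model, not that their thresholds
are optimal for any particular real dataset.

### Compositional coupling

Because per-cell rates are normalized (as are CPM values downstream),
boosting one program in one tissue *depresses the relative expression of
every other gene there*.  Small negative background fold changes in
tissue contrasts on planted data are genuine signal of this coupling, not
miscalibration; the null-simulation suites (no planted effects) are the
calibration reference.

## Composite QC

The per-cell score is a plain sum: Scrublet-style doublet probability +
hashing doublet probability + erythrocyte-gene fraction (0–1 scale; a
0–100 scale would dominate the sum) + indicator flags for dual TCR+BCR,
predicted erythrocyte, `< 2,000` UMIs, `< 1,200` genes, `< 200` ADT
counts, and `> 20%` mitochondrial counts.  The mitochondrial indicator is
included by default and excludable by flag, since its role in the sum is a
judgment call.  Filtering is cluster-level: any labeling is accepted (a
k-means helper on an embedding is bundled); a cluster is removed when its
median score ≥ 1.0 **or** mean score ≥ 0.3, with per-tissue mean-cutoff
overrides and (subset, tissue) rescue rules taking precedence.  The
absolute UMI/gene/ADT floors are full-scale-data values; the demo pipeline
scales them to the synthetic depth (median depth / 3, n_genes / 10, 0).

## Pseudobulk differential expression

Counts are summed per (donor, tissue group, unit) where the unit is a
lineage or subset.  Representation filters: samples need ≥ 50 cells
(relaxed mode: ≥ 10; counterfactual validation mode: ≥ 5 cells and ≥ 1,000
counts); genes need ≥ 5 counts in ≥ 40% of retained samples (relaxed: 10%;
validation: ≥ 3 total counts), boundaries inclusive.  A contrast is
skipped when an arm has fewer than 3 (tissue) or 4 (age) samples.

The response is `log2((count + 0.5) / (libsize + 1) · 10⁶)`.  Each gene is
fit with intercept + contrast indicator + fixed covariates (aliased
columns dropped by a greedy rank check), with a random intercept for the
grouping factor (donor for tissue contrasts; batch factors for age
contrasts).  The random-intercept model is estimated by method of moments:
the grouping variance component comes from the one-way ANOVA of the OLS
residuals (clamped at zero, where the model reduces exactly to OLS, per
gene and flagged as such), and fixed effects are re-estimated by GLS using
the Woodbury block inverse of the compound-symmetric covariance.  This is
orders of magnitude faster than per-gene iterative REML at pseudobulk
sample sizes and targets the same estimand; it differs from
precision-weighted LMM packages in not carrying per-observation precision
weights, so equivalence is claimed at the level of calibration and
sign/rank agreement, never per-gene p-values.

Residual variances are moderated across genes with the standard
scaled-inverse-chi-square empirical-Bayes shrinkage (prior df estimated by
trigamma inversion); moderated t statistics use `df_residual + df_prior`.
BH adjustment is applied within one (unit, contrast, tissue) result set.
Sign convention: positive log2FC = higher in the named tissue / older
group.

Variance decomposition is a sequential (type-I) ANOVA partition of the
log2-CPM variance over the covariates in the given order plus a residual;
fractions are clipped to [0, 1] and renormalized to sum to exactly 1.
A crossed-random-effects partition would need a multi-grouping REML
fitter; the ANOVA partition satisfies the same invariants and recovers
planted structure, at the cost of mild order dependence for correlated
covariates (covariates in the atlas design are near-orthogonal).

## Signatures, GSEA and disentanglement

Signature genes pass adjusted p < 0.05, log2FC > 1 and mean expression > 2
in at least one tissue × lineage combination; the per-combination **mean
expression** matrix (computed from the pseudobulk table, not from the
contrast-invariant `ave_expr` column) is z-scored per gene and clustered
with Ward linkage on Euclidean distance, cut to exactly `n_clusters`
(maxclust semantics).  The cluster count is a required parameter here; in
the full-scale study it was chosen from the dendrogram.

Pre-ranked GSEA is the classic weighted Kolmogorov–Smirnov running sum
(weight `p = 1` by default, `p = 0` selectable): hits advance the running
sum by `|score|^p` normalized over set members, misses retreat by
`1/(n − |set|)`; ES is the extremum.  The null is gene-label permutation
(random same-size sets); NES divides ES by the mean |null ES| of the same
sign and the nominal p is the same-sign exceedance fraction with an
add-one correction.  FDR across terms is BH on nominal p-values (the
pooled-null GSEA q is not reimplemented).  The implementation is tested
for exact equality with a brute-force running-sum oracle.

The composition-vs-expression summary emits, per subset × tissue, the
within-lineage frequency, its log2 fold change versus other tissues, the
within-subset cluster-expression shift, and the cluster's NES — and flags
"composition-driven" (frequency log2FC ≥ 1 and |expression shift| < 0.25)
or "expression-driven" (significant positive NES and frequency
log2FC < 0.5).  These thresholds are explicit artifact heuristics for a
decision the original evidence presented visually; the raw evidence is
always emitted.

ADT differential abundance runs per donor: groups are subsampled to equal
cell numbers, depth-equalized, log-normalized (scale 1,000) and compared
per marker with a two-sided Wilcoxon rank-sum test (tie-corrected
asymptotic); donors under 50 cells are excluded and analyses with fewer
than 4 donors are skipped.  Note that with few markers the depth
normalization couples markers compositionally, so per-marker p-values
within one donor are not independent.

## Consensus Poisson factorization

The factor model is Poisson NMF, `X[g,c] ~ Poisson((W H)[g,c])`, fit by
multiplicative updates that monotonically decrease the generalized
Kullback–Leibler deviance (asserted per iteration); convergence is a
relative deviance change below 1e-5.  Gene scores are column-normalized to
sum 1, resolving the scale invariance; genes must be detected in ≥ 1% of
cells (prefilter helper).  This is a deliberate simplification of
hierarchical Poisson factorization: no Bayesian hierarchy, no variational
uncertainty; acceptance is planted-structure recovery, not numerical
equality with any HPF implementation.

Consensus: for each K in the requested range (full-scale default 15–30;
desk scale 4–8), `runs_per_K` restarts are ranked by final deviance and
the top `top_models_per_K` kept.  All retained factors form a similarity
graph (Pearson correlation of gene-score columns, edges above 0.6);
communities come from igraph's walktrap when available, otherwise a
deterministic average-linkage agglomerative cut at the same threshold.
Communities containing factors from at least two distinct models become
consensus factors (asserted); their medoids (max within-cluster
similarity) seed a final refit at the consensus rank.  Final-deviance
ranking stands in for the unspecified "convergence criteria" used to pick
top models.

Nuisance factors: a factor is flagged when its top-30 genes contain
strictly more than 1 heat-shock, 10 ribosomal, 1 metallothionein, 0
hemoglobin, or 7 dissociation-stress genes.  Tissue-specific factors: mean
cell score per tissue group ≥ 1.8 × the mean of the remaining groups
(inclusive boundary).  Cross-lineage modules: pairwise Pearson
correlations of gene-score vectors over M genes, thresholded at the
two-sided Fisher-z null bound `tanh(z₀.₉₇₅ / √(M − 3))`; factors with ≥ 2
super-threshold partners are retained and Ward-clustered on the Euclidean
distance of their correlation rows into a requested number of modules.

Covariate association fits, per factor, cell score ~ covariate + fixed
covariates + two tissue-type dummies (mucosal and lymph-node versus
blood-rich) with a donor random intercept (statsmodels MixedLM; lbfgs,
then the default optimizer, then an OLS fallback when the donor variance
sits on the boundary — flagged per factor).  The reference level is the
young group, so positive coefficients mean higher scores in older donors.
Covariate-adjusted scores (the covariate's fitted contribution plus the
residual) are emitted for plotting.  Projection of external cells holds
gene scores fixed and runs the same multiplicative updates on cell scores
only; gene overlap below 50% of the model's genes is an error.

## Compositional analysis and ADT registration

Subset frequencies are tabulated within lineage per donor × tissue;
donor × tissue × lineage combinations under 50 cells are excluded, and
subset × tissue units with fewer than 4 donors are ineligible.  The shift
test is a binomial/logit GLM on (subset count, lineage total) with the
effect indicator plus donor covariates; because donor-level proportions
are overdispersed relative to multinomial sampling, a quasi-binomial
dispersion (Pearson X²/df, floored at 1) rescales the standard errors.
The covariate-aware log2FC is the log2 ratio of predicted proportions at
reference covariates with the effect on versus off.  Percent-positivity
responses use a Gaussian model on the logit of the percentage (a logit
GLM is selectable).  BH is applied across units.

The majority-vote wrapper runs any compositional backend once per choice
of reference subset; a subset is credible only when flagged in strictly
more than half of the runs in which it was a candidate (a backend failure
shrinks that denominator).  The built-in backend is an additive-log-ratio
linear model with BH at FDR 0.05; a Bayesian backend can be plugged in
unchanged.

Landmark registration is a two-landmark simplification: per batch and
marker, a Gaussian KDE on a 512-point grid, peaks by prominence (up to 2);
two-peak batches get the monotone piecewise-linear map (negative peak → 0,
positive peak → 1, linear extrapolation with the interior slope beyond the
landmarks); single-peak batches are shifted; constant markers get the
identity warp, flagged.  Ranks within a batch are preserved exactly.
Acceptance is cross-batch peak alignment (within 0.05), not equality with
any GUI-assisted registration.

## Counterfactual effect modules

Input is a dense cells × genes matrix of predicted per-cell log2 fold
changes for one covariate plus a cell embedding.  Gene filters: raw mean
expression ≥ 0.01 and 95th percentile of |log2FC| ≥ 0.1; cells in fewer
than 3 samples are dropped.  Smoothing: `S = 2 · A · E` with A the
row-stochastic 15-NN affinity (self included); the literal factor 2 is
kept (a `scale` argument disables it) since downstream thresholds are
calibrated on the scores anyway.  Co-clustering uses spectral
co-clustering (equal grid) or spectral biclustering (unequal), after
shifting the signed matrix to nonnegative (`X − min`), which the
bistochastic normalization requires and which preserves block structure.

Module markers are the top 50 genes by |mean log2FC| across the module's
cells (sign retained; zero-mean genes dropped — a module with no
informative marker is skipped).  Scores: `sum_lfc` (sum over up-markers
minus sum over down-markers; the default) and `weighted_sign_mean` (mean
of sign-weighted lfc) are both provided.  When an assignment already
carries markers, scoring re-uses them, which is how a module fit in one
tissue scores cells from another.  The module-positive cutoff maximizes
Youden's J over midpoints of sorted unique scores with the orientation
chosen to maximize J, and the *same* cutoff is applied to all target
tissues; a named-gene override (e.g. predicted log2FC of one gene below a
constant) covers cases where other tissues have no positive cells.
Validation restricts to module-positive cells and reruns pseudobulk age
DE in validation mode, then tests the module's markers by pre-ranked GSEA
against the resulting log2FC ranking.

## Repertoire clonality

Clonotype grouping applies, in order: identical V and J genes and CDR3
length on every chain; then 100% CDR3 nucleotide identity (TCR) or ≥ 85%
CDR3 amino-acid identity (normalized Hamming, inclusive boundary) with
single-linkage connected components (BCR).  Both chains of a paired cell
must satisfy their rule.  Records whose nucleotide length is not 3× the
amino-acid length are rejected and logged.

Clonality of a group is `1 − H_s / log2(C)` on a 100-cell subsample drawn
without replacement, where H_s is the Shannon entropy (bits) of clone
counts in the subsample and C the number of distinct clonotypes in it.
The default averages 25 draws (Monte-Carlo SD < 0.02 on generator
fixtures); `n_draws=1` reproduces the literal single-subsample procedure.
C = 1 yields clonality 1 by convention (the limit of total clonal
dominance) and is flagged.  Groups smaller than the subsample are skipped.

## Pipeline, seeds and problem sizes

`atlas-kit run` executes the stages in dependency order from one YAML
config (schema-validated; unknown keys rejected).  Per-stage seeds derive
from the global seed as `sha256(stage_name:seed) mod 2³¹`, so stages rerun
independently and deterministically; every artifact directory carries a
manifest (stage, config hash, seed, package version).

Test and demo problem sizes — hundreds of genes, tens of cells per
donor × tissue, rank ranges of 4–8 — are the package's desk-scale study
conditions: large enough for every planted structure to be recoverable
and every calibration check to be informative, small enough that the full
suite and the demo pipeline run in minutes on one CPU.  Full-scale
defaults (filters, rank range 15–30, absolute QC floors) are kept wherever
a value is scale-free.

## Known limitations

- The DE estimator is unweighted GLS; very unbalanced cell numbers per
  pseudobulk sample are handled only through the count filters, not
  through precision weights.
- Variance fractions are order-dependent for strongly correlated
  covariates.
- GSEA FDR is BH on permutation p-values, which is conservative relative
  to the pooled-null q-value for many overlapping sets.
- The effect-matrix producer (the counterfactual generative model itself)
  is out of scope; `EffectMatrix` is an input contract, and the bundled
  generator plants modules directly rather than decoding them from a
  latent model.
- BCR similarity is computed per chain with both chains required to match;
  heavy-chain-only grouping, allele correction and mutation calling are
  not implemented.
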