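# Methods

## Study design and data model

The pipeline operates on a matched-tetrad, multi-region case–control design:
T tetrads, each holding one CTRL, SCZ, BD and MDD subject matched for sex
and approximately for age, with every subject profiled in DLPFC,
hippocampus and striatum. Inputs are a complete, finite, log10-scale
expression matrix per region (genes x samples, TSV), one metadata row per
sample (subject x region) with the covariates age, sex, tobacco use, manner
of death (accidental/natural/suicide), PMI and pH, and GMT gene sets.
Missing values are rejected at input — the pipeline assumes a complete
matrix (as produced by detection-filtered array normalisation); users with
missing data must impute upstream. Gene identifiers are opaque strings; no
probe/symbol mapping layer is provided.

## Mixed-model ANCOVA

For each gene the log10 response is modelled with fixed effects for
diagnosis (CTRL reference), optionally region (pooled scope), and the six
covariates (continuous covariates centred; categorical factors
dummy-coded), plus a tetrad random intercept. Because the fixed-effects
design matrix is shared by all genes within a region, the model is fitted by
rotating into the eigenbasis of Z Z' (the tetrad incidence Gram matrix),
which diagonalises the marginal covariance sigma^2 (I + lambda Z Z') with
lambda = tau^2/sigma^2. The restricted likelihood profiled over beta and
sigma^2 is then a one-dimensional function of lambda, minimised on a log
grid (lambda in {0} U [1e-4, 1e3], 70 points) followed by ~35 vectorised
ternary-search refinements per gene. lambda is bounded below at 0; a zero
tetrad variance degenerates gracefully to OLS. Constant responses
short-circuit to zero effects and zero variance components. The fitter
matches `statsmodels` MixedLM REML to ~1e-6 where the latter converges, and
(being an exact 1-D profile search) attains a lower restricted deviance in
boundary cases where the general-purpose optimiser stalls.

Contrasts are differences of least-squares means — covariates at their
means, categorical factors at equal weights — which for disease-vs-control
reduce to the diagnosis dummy coefficients. Tests are two-tailed t with
containment degrees of freedom n − rank(X) − T + 1, a simple, conservative
and reproducible choice (Kenward–Roger/Satterthwaite are out of scope).
Tukey–Kramer adjusted p-values for all diagnosis pairs use the
studentized-range distribution with unequal-n standard errors; with two
groups this reduces exactly to the t test. The omnibus-first gating
(contrasts only when the diagnosis Wald F is significant at 0.05) is
available as a switch, default off: DE selection uses the FDR-adjusted
disease-vs-control p directly.

Fold change is defined as 10^|LS-mean difference| since the response is
log10; DE selection requires fold > 1.2 (strict) and BH-FDR < 0.05, with
the FDR family per (region x diagnosis contrast) across genes, matching
per-region, per-diagnosis DE reporting. qPCR normalized quantities and
cytokine concentrations reuse the identical machinery on log10 values, with
folds reported relative to the control LS mean.

## Pathway enrichment and net scores

Enrichment is the one-sided hypergeometric tail of the DE-list/gene-set
overlap over a declared universe (default: all genes in the expression
matrix); both lists are intersected with the universe first. Directional
analysis re-tests the up- and down-regulated lists separately;
net = −log10(p_up) + log10(p_down), so sets driven by up-regulation score
positive, down-regulation negative, balanced sets near zero. Enriched sets
are declared at p < 0.05, and cross-disorder agreement is a one-sided
Fisher's exact on the 2x2 classification of all tested pathways by
enrichment in either condition. The top-N export ranks pathways by maximum
|net score| in the reference condition (a single diagnosis/region cell or a
diagnosis's maximum across regions), ties broken lexicographically.
A commercial pathway engine's proprietary scoring is deliberately not
emulated; Fisher's exact over user GMTs keeps the pipeline internally
consistent with the module-level enrichment test.

## Consensus network

Per region, signed adjacency a = ((1+r)/2)^beta with beta = 12; the power
targets approximate scale-free topology, checked by the binned log-log
regression R^2 of the connectivity distribution (10 equal-width bins, empty
bins dropped). TOM is computed from the signed adjacency directly
(the adjacency already encodes sign). Consensus: per-region TOMs are scaled
by the ratio of their off-diagonal quantiles (default q = 0.95) to the
first region's, then the elementwise minimum is taken and clipped to [0,1].
The reference region is the input order's first; both q and the reference
are configurable.

Genes are pre-clustered into blocks (default 4) by projective k-means —
distance 1 − |r| on per-region-standardised concatenated profiles, centres
the dominant principal direction of their members. Clustering runs with a
finer set of centres (4x the block count) that are then packed into the
blocks by average-linkage clustering of centre similarity; this keeps small
correlated families in one block, which a direct k-centre run at the block
count does not guarantee. Consensus TOMs are computed within block only,
bounding memory.

Module detection is an average-linkage tree on 1 − TOM with a dynamic
hybrid cut. The dendrogram is truncated at 0.995 of the top joining height;
only branches fully formed below the truncation are candidates — a
featureless dissimilarity matrix (all joins within a hair of the top)
therefore yields no modules. Candidate branches must be large enough
(>= 50 genes), internally tight and separated: with core scatter = mean
within-branch dissimilarity and joins normalised to the spread between the
5th-percentile joining height and the cut height, a branch is distinct when
its normalised scatter is below the deepSplit threshold (0.64/0.73/0.82/
0.91/0.95 for deepSplit 0–4) and the normalised gap between its merging
height and its scatter exceeds (1 − threshold) * 3/4. A second (hybrid)
stage attaches each unlabelled gene to its closest module when the mean
dissimilarity falls below the midpoint between that module's core scatter
and the cut height. The published tree-cut implementation's internal
constants are not reproduced bit for bit; planted-structure recovery, not
label-for-label agreement with any external package, is the correctness
contract.

Module eigengenes are first principal components of the standardised
within-module expression over the region-concatenated samples, unit length,
oriented so the mean member kME is positive. Refinement follows, in order:
genes with own-module kME < 0.3 removed; modules with fewer than 17 genes
at kME > 0.5 disbanded; eigengenes recomputed; then a single reassignment
pass (after all blocks) moving genes whose Fisher-z kME p-value to another
eigengene beats their own module's by a factor of 1e-4 — computed in log
space, since these p-values underflow ordinary doubles. Note the rule order
means a gene below the 0.3 own-kME threshold is removed rather than
reassigned, even if strongly correlated with another module; the
reassignment rule acts on retained genes only. Finally, eigengenes are
clustered by 1 − correlation (signed, not |r|) and branches below 0.15
merged, repeating to a fixed point (termination guaranteed: the module
count strictly decreases). Modules are renumbered by decreasing size, ties
by smallest member identifier, making labels invariant to gene input order.

ME–trait association is Pearson correlation with the two-tailed Fisher-z
asymptotic p (z = atanh(r) sqrt(n−3)) and BH-FDR over the reported grid.
Diagnosis is coded one-vs-rest by default (one-vs-control switchable).
Because each subject contributes one sample per region, correlations are
computed per region by default in the drivers (n = subjects), avoiding
pseudo-replication of subjects across regions; the un-grouped variant over
all samples is available. Module DE enrichment delegates to the same
Fisher's-exact routine as pathway enrichment, with module memberships as
gene sets.

## Validation statistics

Reference-gene stability follows the model-based (NormFinder-style)
variance decomposition on log, sample-centred quantities: per gene and
group, an intergroup deviation shrunken toward zero by its sampling
variance (shrinkage factor tau^2/(tau^2 + v/n), with tau^2 the excess
variance of the deviations over their mean sampling variance) combines with
the intragroup sampling deviation into
stability = mean_g sqrt(d_shrunk^2 + v/n); lower is more stable, ties
broken by lower intragroup variance. Sample centring makes the ranking
exactly invariant to per-sample loading artifacts. The two-step candidate
screen (e.g. 16 -> 6 -> 3) is a configurable funnel. Quadruplicate wells
are collapsed to their mean quantity before normalization (the collapse
rule is a package choice). NQ divides the gene of interest by the geometric
mean of the selected references.

## Synthetic data generator

On the log10 scale, expression is baseline_g + tetrad_{g,t,region} +
diagnosis effect + covariate effects + sum_m lambda_gm f_m(subject) +
N(0, residual_sd). Defaults (the simulated study conditions):

* 19 tetrads, 2000 genes, 3 regions; residual sd 0.10, tetrad sd 0.05
  (per gene, within region), baseline N(2.5, 0.3).
* Planted DE fractions: SCZ 9%/3%/2% of genes in HIP/STR/DLPFC (the graded
  regional burden), BD 1.2%/0.8%/1.0%, MDD 0.4%/0.3%/0.35%. Observed
  cohort-scale BD/MDD burdens would translate to fewer than ten genes per
  region at n = 2000 — too few to measure ordering recovery — so the BD/MDD
  fractions are set an order of magnitude below SCZ while keeping the
  orderings testable at desk scale. Effect magnitudes are
  U(0.6, 1.4) x mean |log10 effect| (0.15–0.18) with random sign.
* Five planted modules, sizes 300/200/122/80/60, within-module target
  correlations 0.55–0.65; module signal is a rank-one factor (per-subject
  score, shared across regions, times a positive per-gene loading
  lambda = residual_sd sqrt(c/(1−c)) jittered ±20%). The 122-gene module is
  inflammation-like: its factor score is shifted by +1.5 SD for SCZ
  subjects, so its genes are up-regulated in SCZ in every region and its
  eigengene correlates with the SCZ indicator. Module genes and
  independently planted DE genes are disjoint; the ground truth records
  module-induced shifts as DE separately from the independent effects,
  because all genes of one module share a single factor realisation (their
  common sampling deviation makes per-module mean bias a poor estimator
  check — bias is therefore assessed on the independently planted genes).
* Covariates: age drawn per tetrad ±2y jitter, sex constant within tetrad
  (the matching structure); tobacco, manner, PMI, pH per subject. Per-gene
  covariate coefficients are small Gaussians (e.g. sd 0.002/year for age,
  0.05/pH unit), giving the ANCOVA real confounding to absorb.
* Randomness: one named counter-based stream per ingredient
  (covariates, baselines, coefficients, effects, modules, tetrad effects,
  per-region noise, decoys), all derived from a single seed, so changing
  the gene count does not reshuffle subject covariates.

What the generator does not emulate: probe-level/array noise, batch
effects, RNA-degradation artifacts, heavy-tailed or heteroscedastic genes,
correlated module factors, or diagnosis-covariate confounding beyond what
random sampling produces. Passing recovery tests therefore demonstrates the
pipeline's correctness and calibration under the declared generative model,
not robustness to every pathology of real array data.

## Experiment sizes and numerical choices

The calibration and recovery experiments run at the full design size
(2000 genes x 76 subjects x 3 regions) with 10 replicate seeds for the
ordering and module-recovery fractions; a full acceptance run takes a few
minutes on one CPU. KS uniformity is tested per contrast pooled across
regions (n = 6000) at alpha = 0.01. Decoy gene sets (50 genes drawn from
non-module genes) provide the conservative-enrichment check. The adjusted
Rand index between recovered and planted labels is computed over genes that
are planted in a module and assigned by the network, per the
unassigned-excluded convention. p-values are clamped to (0, 1]; kME
p-values are handled in log space; TOM and consensus matrices are clipped
to [0, 1] and symmetrised against floating-point drift.

## Known limitations

Per-gene variance components are estimated independently (no empirical-
Bayes shrinkage), so very small designs give noisy tetrad variances.
Containment df is conservative. The tree cut is a faithful re-derivation of
the dynamic hybrid scheme, not a port; on data with very weak or nested
module structure its branch decisions can differ from other
implementations (the eigengene merge step absorbs over-splitting). The
cross-block TOM is never materialised, so modules split across blocks can
only be reunited by the eigengene merge. Pooled-scope fitting uses a single
tetrad intercept across regions rather than a subject-level nested effect.
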