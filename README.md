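# tetranet

Cross-region, cross-disorder analysis of tetrad-matched postmortem brain
transcriptomes, as a tested, reusable pipeline exercised end to end on a
synthetic study generator.

The study design it targets: matched tetrads of subjects — one unaffected
control (CTRL) and one subject each with schizophrenia (SCZ), bipolar
disorder (BD) and major depressive disorder (MDD), matched for sex and
approximately for age — profiled in three connected brain regions
(dorsolateral prefrontal cortex DLPFC, hippocampus HIP, associative striatum
STR). The pipeline asks which genes are differentially expressed per
disorder and region, which pathways those genes implicate and in which
direction, whether disorders share enriched pathways, and which co-expression
modules track diagnosis consistently across regions.

## What it computes

**Differential expression** (`tetranet.differential_expression`). Per gene,
a mixed-model ANCOVA on the log10 response

```
y = X beta + Z u + eps,   u ~ N(0, tau^2 I_T),   eps ~ N(0, sigma^2 I_n)
```

with diagnosis (and region, when pooled) as fixed factors, tetrad as a
random intercept, and age, sex, tobacco use, manner of death, PMI and pH as
covariates. Variance components by REML (profiled, vectorised across
genes); disease-vs-control contrasts of least-squares means, two-tailed t
tests with containment degrees of freedom, Tukey–Kramer adjusted pairwise
p-values, BH-FDR per (region x diagnosis) family, and DE selection at
fold change > 1.2 (fold = 10^|LS-mean difference|) and FDR < 0.05.

**Directional pathway enrichment** (`tetranet.pathway_enrichment`).
One-sided Fisher's exact (hypergeometric tail) over-representation of DE
lists in user-supplied GMT gene sets; up- and down-regulated lists scored
separately, with the net enrichment score
`-log10(p_up) + log10(p_down)` (positive = driven by up-regulated genes);
cross-disorder overlap of enriched-pathway sets by Fisher's exact over all
tested pathways; top-N net-score matrix export.

**Signed consensus co-expression network** (`tetranet.consensus_network`).
Per block and region: signed adjacency `((1 + r)/2)^beta` (beta = 12),
topological overlap; per-region TOMs single-quantile scaled and the
elementwise minimum retained as the consensus; average-linkage clustering of
1 − TOM with a dynamic hybrid tree cut (min module size 50, deepSplit 4);
module eigengenes (first principal components); refinement — kME < 0.3
removal, disbanding modules with fewer than 17 genes at kME > 0.5, 1e-4
kME-p-value reassignment; eigengene merging at height 0.15; ME–trait Pearson
correlations with Fisher-z p and FDR; module DE-gene enrichment.

**Validation statistics** (`tetranet.validation_stats`). NormFinder-style
reference-gene stability ranking, normalized quantities
`NQ = GOI / geomean(3 refs)`, and the same mixed ANCOVA applied to log10 NQ
or cytokine values.

**Synthetic data** (`tetranet.synthetic_data`). A generator for the full
design — 19 tetrads x 3 regions, graded planted DE burden (SCZ >> BD > MDD;
within SCZ, HIP > STR > DLPFC at 9%/3%/2% of genes), five planted
co-expression modules including a 122-gene inflammation-like module
up-regulated in SCZ in all regions, covariate and tetrad effects — plus the
ground truth needed to score recovery.

## Worked example

The numbered scripts under `analysis/` run the full study on the synthetic
fixture and write their tables under `results/`:

```bash
python analysis/01_simulate_study.py --seed 1
python analysis/02_differential_expression.py
python analysis/03_pathway_enrichment.py
python analysis/04_consensus_network.py
python analysis/05_validation_qpcr.py
```

`02` prints the recovered DE counts, reproducing the planted burden
orderings (SCZ >> BD > MDD in every region; HIP > STR > DLPFC within SCZ):

```
DE genes (>1.2-fold, FDR < 0.05) per condition:
diagnosis  BD  MDD  SCZ
region
DLPFC      18    3  117
HIP        18    4  277
STR        10    4  158
```

`04` recovers exactly the five planted modules; only the planted
inflammation-like module (recovered as module 3, all 122 genes) is
FDR-significantly correlated with SCZ, positively and in every region:

```
consensus modules: 5 (sizes 60-300); 1287 genes unassigned
  module 3:  122 genes | ME-SCZ DLPFC: r=+0.59*  HIP: r=+0.58*  STR: r=+0.59*
```

and `03` shows the same module's gene set with large positive net
enrichment scores in all three SCZ conditions (93.5 / 105.7 / 113.7 in
DLPFC/HIP/STR) and near-zero scores elsewhere. `05` recovers a planted
14.2-fold analyte increase as 14.7-fold (FDR p = 5.3e-35) after
reference-gene normalization.

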