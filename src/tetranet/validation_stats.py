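"""qRT-PCR / cytokine validation statistics.

Reference-gene selection follows the model-based (NormFinder-style) variance
decomposition: on log-scale, sample-centred quantities, each candidate gene
gets a per-group intergroup bias estimate (shrunken toward zero by its
sampling variance) and an intragroup variance; these combine into a single
stability value, lower = more stable.  Sample-centring makes the ranking
invariant to sample-loading artifacts (multiplying every quantity of one
sample by a constant).

Normalized quantities divide a gene of interest by the geometric mean of the
chosen reference genes.  Group comparisons of NQ or cytokine values reuse the
mixed-model ANCOVA from :mod:`tetranet.differential_expression` on log10
values, with fold changes reported relative to the control least-squares
mean.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .data_model import SampleTable, make_contrast_table
from .differential_expression import bh_fdr, fit_region_contrasts
from .data_model import ExpressionStudy

PLATE_COLUMNS = ("sample_id", "gene", "replicate", "quantity", "group")
MAX_REPLICATES = 4


def read_qpcr_plate(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in PLATE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"plate table missing columns: {missing}")
    return validate_plate(df)


def validate_plate(df: pd.DataFrame) -> pd.DataFrame:
    if (df["quantity"] <= 0).any():
        bad = df.loc[df["quantity"] <= 0].iloc[0]
        raise ValueError(
            f"nonpositive quantity for sample {bad['sample_id']!r}, "
            f"gene {bad['gene']!r}")
    reps = df.groupby(["sample_id", "gene"]).size()
    if (reps > MAX_REPLICATES).any():
        sid, gene = reps.idxmax()
        raise ValueError(
            f"more than {MAX_REPLICATES} replicates for sample {sid!r}, "
            f"gene {gene!r}")
    return df


def collapse_replicates(plate: pd.DataFrame) -> pd.DataFrame:
    """Mean quantity per (sample, gene); carries group (and region) along."""
    keep = [c for c in ("group", "region") if c in plate.columns]
    agg = (plate.groupby(["sample_id", "gene"] + keep, as_index=False)
           ["quantity"].mean())
    return agg


def stability_rank(quantities: pd.DataFrame, groups: pd.Series) -> pd.Series:
    """NormFinder-style stability values, ascending = more stable.

    ``quantities``: samples x candidate genes, positive, replicate-collapsed.
    ``groups``: per-sample group labels aligned to the rows.  Works on
    log-transformed, sample-centred values.
    """
    if quantities.shape[1] < 2:
        raise ValueError("need at least 2 candidate genes")
    groups = pd.Series(groups).reindex(quantities.index)
    if groups.isna().any():
        raise ValueError("group label missing for some samples")
    if groups.nunique() < 2:
        raise ValueError("need at least 2 groups")
    if (quantities <= 0).to_numpy().any():
        raise ValueError("quantities must be positive")

    X = np.log(quantities.to_numpy(float))
    X = X - X.mean(axis=1, keepdims=True)          # remove sample loading
    genes = list(quantities.columns)
    glabels = sorted(groups.unique())

    means, varis, ns = [], [], []
    for g in glabels:
        rows = (groups == g).to_numpy()
        sub = X[rows]
        if sub.shape[0] < 2:
            raise ValueError(f"group {g!r} has fewer than 2 samples")
        if np.isnan(sub).any():
            raise ValueError("missing quantities in a group")
        means.append(sub.mean(axis=0))
        varis.append(sub.var(axis=0, ddof=1))
        ns.append(sub.shape[0])
    means = np.array(means)          # (G groups, J genes)
    varis = np.array(varis)
    ns = np.array(ns, float)[:, None]

    grand = (means * ns).sum(axis=0) / ns.sum()
    d = means - grand[None, :]       # intergroup deviation per (group, gene)
    # shrink bias by its sampling variance (empirical-Bayes style)
    samp_var = varis / ns
    tau2 = max(float(d.var()) - float(samp_var.mean()), 0.0)
    d_shrunk = d * (tau2 / (tau2 + samp_var)) if tau2 > 0 else d * 0.0
    stability = np.sqrt(d_shrunk**2 + samp_var).mean(axis=0)
    order_key = stability + 1e-12 * varis.mean(axis=0)   # tie-break: lower var
    out = pd.Series(stability, index=genes, name="stability")
    return out.iloc[np.argsort(order_key, kind="stable")]


def select_reference_genes(plate: pd.DataFrame, n_final: int = 3,
                           funnel: tuple = (16, 6, 3)) -> list:
    """Two-step stability funnel over candidate reference genes.

    Mirrors the screening design: rank all candidates, keep the top of each
    funnel stage, and return the ``n_final`` most stable genes overall.
    """
    collapsed = collapse_replicates(plate)
    wide = collapsed.pivot(index="sample_id", columns="gene",
                           values="quantity")
    groups = (collapsed.drop_duplicates("sample_id")
              .set_index("sample_id")["group"])
    keep = list(wide.columns)
    for stage in list(funnel[1:]) + [n_final]:
        ranking = stability_rank(wide[keep].dropna(), groups)
        keep = list(ranking.index[:stage])
        if len(keep) <= n_final:
            break
    return keep[:n_final]


def normalized_quantity(goi, refs):
    """NQ = gene-of-interest quantity / geometric mean of reference quantities.

    ``goi`` may be scalar or array; ``refs`` is a sequence of (arrays of)
    reference quantities, typically three.
    """
    goi = np.asarray(goi, float)
    refs = np.asarray(refs, float)
    if (goi <= 0).any() or (refs <= 0).any():
        raise ValueError("quantities must be positive")
    gm = np.exp(np.log(refs).mean(axis=0))
    out = goi / gm
    return float(out) if out.ndim == 0 else out


def nq_table(plate: pd.DataFrame, reference_genes) -> pd.DataFrame:
    """Per-sample normalized quantities for every non-reference gene.

    Returns analytes x samples (positive values, linear scale)."""
    collapsed = collapse_replicates(plate)
    wide = collapsed.pivot(index="sample_id", columns="gene",
                           values="quantity")
    missing = [g for g in reference_genes if g not in wide.columns]
    if missing:
        raise ValueError(f"reference gene(s) absent from plate: {missing}")
    refs = wide[list(reference_genes)].to_numpy().T
    gois = [g for g in wide.columns if g not in set(reference_genes)]
    out = {g: normalized_quantity(wide[g].to_numpy(), refs) for g in gois}
    return pd.DataFrame(out, index=wide.index).T


def analyze_validation(values: pd.DataFrame, meta: SampleTable,
                       fdr_max: float = 0.05) -> pd.DataFrame:
    """Mixed ANCOVA of validation measurements (NQ or cytokine levels).

    ``values`` is analytes x samples, positive, linear scale; each analyte is
    log10-transformed and fitted with the same tetrad-random-intercept model
    as the expression data.  The returned contrast table reports the fold
    change of each disease group relative to the control least-squares mean;
    BH-FDR is applied per diagnosis across analytes.
    """
    if (values.to_numpy() <= 0).any():
        raise ValueError("validation values must be positive")
    study = ExpressionStudy(np.log10(values), meta)
    region = meta.df["region"].iloc[0]
    raw = fit_region_contrasts(study, region=region)
    adj = np.full(len(raw), np.nan)
    for dx, grp in raw.groupby("diagnosis"):
        adj[grp.index] = bh_fdr(grp["p_raw"].to_numpy())
    raw["p_adj"] = adj
    table = make_contrast_table(raw)
    table["significant"] = table["p_adj"] < fdr_max
    table = table.rename(columns={"gene": "analyte"})
    table["fold_vs_control"] = np.power(10.0, table["estimate"])
    return table
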