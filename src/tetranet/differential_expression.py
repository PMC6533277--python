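"""Per-gene mixed-model ANCOVA with a tetrad random intercept.

The model for one gene (log10 response) is

    y = X beta + Z u + eps,    u ~ N(0, tau^2 I_T),  eps ~ N(0, sigma^2 I_n)

with fixed effects for diagnosis (CTRL reference), optionally brain region
(pooled scope), and the covariates age, sex, tobacco use, manner of death,
PMI and pH; Z is the tetrad incidence matrix.  Variance components are
estimated by REML: rotating by the eigenvectors of Z Z' diagonalises the
marginal covariance, so the profile REML criterion in lambda = tau^2/sigma^2
is a cheap one-dimensional objective, evaluated on a grid and polished by
golden section -- vectorised across genes because the design matrix is shared
within a region.

Disease-vs-control contrasts are differences of least-squares means
(covariates at their means, categorical factors at equal weights), tested
two-tailed against a t distribution with containment degrees of freedom
n - rank(X) - T + 1.  Tukey-Kramer adjusted p-values for all diagnosis pairs
use the studentized-range distribution.  DE selection applies the
>1.2-fold-change and FDR-adjusted p < 0.05 rule, with the FDR family taken
per (region x diagnosis contrast) across genes.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .data_model import (
    DIAGNOSES,
    DISEASE_DIAGNOSES,
    ExpressionStudy,
    SampleTable,
    make_contrast_table,
)

logger = logging.getLogger(__name__)

_CONSTANT_TOL = 1e-24


# ---------------------------------------------------------------------------
# design matrix
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Design:
    X: np.ndarray
    columns: list
    tetrad_codes: np.ndarray
    n_tetrads: int
    diag_levels: list            # levels present, CTRL first if present
    ls_rows: dict                # diagnosis level -> LS-mean row vector
    n_per_diagnosis: pd.Series

    @property
    def rank(self) -> int:
        return np.linalg.matrix_rank(self.X)

    @property
    def df_containment(self) -> int:
        return self.X.shape[0] - self.rank - self.n_tetrads + 1


def build_design(meta: SampleTable, scope: str = "region") -> Design:
    """Build the shared fixed-effects design for one region (or pooled).

    ``scope='region'`` drops region from the fixed effects and requires a
    single region in the metadata; ``scope='pooled'`` adds region dummies.
    """
    if scope not in ("region", "pooled"):
        raise ValueError("scope must be 'region' or 'pooled'")
    df = meta.df
    if scope == "region" and df["region"].nunique() > 1:
        raise ValueError("scope='region' requires metadata from one region")

    diag_levels = [d for d in DIAGNOSES if d in set(df["diagnosis"])]
    if len(diag_levels) < 2:
        raise ValueError("need >= 2 diagnosis levels to fit the ANCOVA")
    diag_ref = "CTRL" if "CTRL" in diag_levels else diag_levels[0]

    cols: dict = {"Intercept": np.ones(len(df))}
    ls_template: dict = {"Intercept": 1.0}

    for d in diag_levels:
        if d != diag_ref:
            cols[f"diag_{d}"] = (df["diagnosis"] == d).to_numpy(float)
    if scope == "pooled":
        region_levels = sorted(df["region"].unique())
        for r in region_levels[1:]:
            cols[f"region_{r}"] = (df["region"] == r).to_numpy(float)
            ls_template[f"region_{r}"] = 1.0 / len(region_levels)

    def add_categorical(name, series, levels, weight_name):
        present = [lv for lv in levels if lv in set(series)]
        for lv in present[1:]:
            cols[f"{weight_name}_{lv}"] = (series == lv).to_numpy(float)
            ls_template[f"{weight_name}_{lv}"] = 1.0 / len(present)

    add_categorical("sex", df["sex"], ["M", "F"], "sex")
    add_categorical("tobacco", df["tobacco"], ["no", "yes"], "tobacco")
    add_categorical("manner", df["manner_of_death"],
                    ["accidental", "natural", "suicide"], "manner")

    for cov in ("age", "pmi", "ph"):
        centered = df[cov].to_numpy(float) - df[cov].to_numpy(float).mean()
        if centered.std() > 0:
            cols[f"{cov}_c"] = centered
            ls_template[f"{cov}_c"] = 0.0
        else:
            logger.info("covariate %s constant; dropped from design", cov)

    columns = list(cols)
    X = np.column_stack([cols[c] for c in columns])

    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        from scipy.linalg import qr as _qr
        _, _, piv = _qr(X, mode="economic", pivoting=True)
        aliased = [columns[piv[i]] for i in range(rank, X.shape[1])]
        raise ValueError(f"design is rank-deficient; aliased columns: {aliased}")

    ls_rows = {}
    for d in diag_levels:
        row = np.zeros(len(columns))
        for i, c in enumerate(columns):
            if c in ls_template:
                row[i] = ls_template[c]
            elif c == f"diag_{d}":
                row[i] = 1.0
        ls_rows[d] = row

    tetrads = sorted(df["tetrad_id"].unique())
    tet_index = {t: i for i, t in enumerate(tetrads)}
    tetrad_codes = df["tetrad_id"].map(tet_index).to_numpy()
    # put reference level first for reporting
    diag_levels = [diag_ref] + [d for d in diag_levels if d != diag_ref]
    n_per = df["diagnosis"].value_counts().reindex(diag_levels)
    return Design(X=X, columns=columns, tetrad_codes=tetrad_codes,
                  n_tetrads=len(tetrads), diag_levels=diag_levels,
                  ls_rows=ls_rows, n_per_diagnosis=n_per)


# ---------------------------------------------------------------------------
# REML machinery
# ---------------------------------------------------------------------------

class _RemlWorkspace:
    """Shared quantities for the rotated random-intercept REML problem."""

    def __init__(self, design: Design):
        X, codes = design.X, design.tetrad_codes
        n = X.shape[0]
        Z = np.zeros((n, design.n_tetrads))
        Z[np.arange(n), codes] = 1.0
        d, U = np.linalg.eigh(Z @ Z.T)
        d[d < 1e-10] = 0.0
        self.d = d                      # eigenvalues of ZZ' (n,)
        self.U = U
        self.Xt = U.T @ X               # rotated design (n, p)
        self.n, self.p = X.shape
        self.rank = design.rank
        self.df = n - self.rank

    def rotate(self, Y: np.ndarray) -> np.ndarray:
        return self.U.T @ Y

    def objective_grid(self, Yt: np.ndarray, lams: np.ndarray) -> np.ndarray:
        """Negative restricted log-likelihood (up to constant) on a shared
        lambda grid; ``Yt`` is (n, G) rotated responses.  Returns (L, G)."""
        n, p, df = self.n, self.p, self.df
        out = np.empty((len(lams), Yt.shape[1]))
        y2 = Yt**2
        for j, lam in enumerate(lams):
            w = 1.0 / (1.0 + lam * self.d)
            A = self.Xt.T @ (w[:, None] * self.Xt)
            B = self.Xt.T @ (w[:, None] * Yt)
            beta = np.linalg.solve(A, B)
            rss = np.maximum((w[:, None] * y2).sum(0) - (B * beta).sum(0),
                             1e-300)
            _, logdetA = np.linalg.slogdet(A)
            out[j] = df * np.log(rss) + np.log1p(lam * self.d).sum() + logdetA
        return out

    def objective_vec(self, Yt: np.ndarray, lam_g: np.ndarray) -> np.ndarray:
        """Objective with a gene-specific lambda vector (G,)."""
        w = 1.0 / (1.0 + lam_g[None, :] * self.d[:, None])      # (n, G)
        A = np.einsum("ip,ig,iq->gpq", self.Xt, w, self.Xt)
        B = np.einsum("ip,ig->gp", self.Xt, w * Yt)
        beta = np.linalg.solve(A, B[..., None])[..., 0]
        rss = np.maximum((w * Yt**2).sum(0) - (B * beta).sum(1), 1e-300)
        _, logdetA = np.linalg.slogdet(A)
        sumlog = np.log1p(lam_g[None, :] * self.d[:, None]).sum(0)
        return self.df * np.log(rss) + sumlog + logdetA

    def gls_at(self, Yt: np.ndarray, lam_g: np.ndarray):
        """GLS solution and covariance factors at gene-specific lambda."""
        w = 1.0 / (1.0 + lam_g[None, :] * self.d[:, None])
        A = np.einsum("ip,ig,iq->gpq", self.Xt, w, self.Xt)
        B = np.einsum("ip,ig->gp", self.Xt, w * Yt)
        Ainv = np.linalg.inv(A)
        beta = np.einsum("gpq,gq->gp", Ainv, B)
        rss = np.maximum((w * Yt**2).sum(0) - (B * beta).sum(1), 0.0)
        sigma2 = rss / self.df
        return beta, Ainv, sigma2


_LAM_GRID = np.concatenate([[0.0], np.logspace(-4.0, 3.0, 70)])


def _fit_lmm_batch(Y: np.ndarray, design: Design, n_golden: int = 35):
    """REML-fit the random-intercept model for G genes at once.

    ``Y`` is (n, G).  Returns a dict of per-gene arrays: ``beta`` (G, p),
    ``cov`` (G, p, p), ``sigma2``, ``tau2``.
    """
    ws = _RemlWorkspace(design)
    Yt = ws.rotate(np.asarray(Y, float))
    G = Yt.shape[1]

    obj = ws.objective_grid(Yt, _LAM_GRID)
    jstar = obj.argmin(axis=0)
    lo = _LAM_GRID[np.maximum(jstar - 1, 0)]
    hi = _LAM_GRID[np.minimum(jstar + 1, len(_LAM_GRID) - 1)]

    # vectorised ternary search on [lo, hi] per gene
    a, b = lo.copy(), hi.copy()
    for _ in range(n_golden):
        m1 = a + (b - a) / 3.0
        m2 = b - (b - a) / 3.0
        left = ws.objective_vec(Yt, m1) < ws.objective_vec(Yt, m2)
        b = np.where(left, m2, b)
        a = np.where(left, a, m1)
    lam_hat = np.maximum((a + b) / 2.0, 0.0)

    beta, Ainv, sigma2 = ws.gls_at(Yt, lam_hat)
    cov = Ainv * sigma2[:, None, None]
    tau2 = lam_hat * sigma2

    # degenerate (constant) genes: everything zero, OLS-free answer
    total_var = np.asarray(Y, float).var(axis=0)
    const = total_var < _CONSTANT_TOL
    if const.any():
        beta[const] = 0.0
        beta[const, 0] = np.asarray(Y, float).mean(0)[const]  # Intercept first
        cov[const] = 0.0
        sigma2 = np.where(const, 0.0, sigma2)
        tau2 = np.where(const, 0.0, tau2)
    return {"beta": beta, "cov": cov, "sigma2": sigma2, "tau2": tau2,
            "lam": lam_hat, "constant": const}


# ---------------------------------------------------------------------------
# single-gene interface
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AncovaFit:
    """Fitted per-gene mixed ANCOVA: coefficients, variance components and
    the least-squares means needed for contrasts."""

    coefficients: pd.Series
    cov_beta: np.ndarray
    tetrad_var: float
    resid_var: float
    ls_means: pd.Series
    df_resid: int
    design: Design

    def contrast(self, row: np.ndarray):
        est = float(row @ self.coefficients.to_numpy())
        se = float(np.sqrt(max(row @ self.cov_beta @ row, 0.0)))
        return est, se


def fit_gene_ancova(y, meta: SampleTable, scope: str = "region",
                    design: Design | None = None) -> AncovaFit:
    """Fit the mixed ANCOVA for one gene's per-sample log10 response.

    ``y`` may be a pandas Series indexed by sample_id (aligned to the
    metadata) or an array in metadata row order.
    """
    if design is None:
        design = build_design(meta, scope=scope)
    if isinstance(y, pd.Series):
        y = y.reindex(meta.df["sample_id"]).to_numpy(float)
    else:
        y = np.asarray(y, float)
    if y.shape[0] != design.X.shape[0]:
        raise ValueError("response length does not match design")
    if not np.isfinite(y).all():
        raise ValueError("response contains non-finite values")

    res = _fit_lmm_batch(y[:, None], design)
    beta = pd.Series(res["beta"][0], index=design.columns)
    cov = res["cov"][0]
    ls = pd.Series({d: float(design.ls_rows[d] @ beta.to_numpy())
                    for d in design.diag_levels})
    return AncovaFit(coefficients=beta, cov_beta=cov,
                     tetrad_var=float(res["tau2"][0]),
                     resid_var=float(res["sigma2"][0]),
                     ls_means=ls, df_resid=design.df_containment,
                     design=design)


def _t_pvalue(est, se, df):
    est, se = np.asarray(est, float), np.asarray(se, float)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, est / np.where(se > 0, se, 1.0), 0.0)
    p = 2.0 * stats.t.sf(np.abs(t), df)
    # zero-variance fits: estimate 0 -> p = 1, nonzero -> p = 0
    zero_se = se <= 0
    p = np.where(zero_se, np.where(np.abs(est) < 1e-12, 1.0, 0.0), p)
    return np.minimum(p, 1.0)


def disease_contrasts(fit: AncovaFit) -> pd.DataFrame:
    """Disease-vs-CTRL LS-mean differences with two-tailed t p-values."""
    design = fit.design
    if "CTRL" not in design.diag_levels:
        raise ValueError("CTRL level required for disease contrasts")
    rows = []
    for dx in DISEASE_DIAGNOSES:
        if dx not in design.diag_levels:
            logger.warning("diagnosis %s absent; contrast omitted", dx)
            continue
        c = design.ls_rows[dx] - design.ls_rows["CTRL"]
        est, se = fit.contrast(c)
        p = float(_t_pvalue(est, se, fit.df_resid))
        rows.append({"diagnosis": dx, "estimate": est, "se": se,
                     "df": fit.df_resid, "p_raw": p})
    return pd.DataFrame(rows)


def tukey_kramer(fit: AncovaFit) -> pd.DataFrame:
    """Tukey-Kramer adjusted p-values for every diagnosis pair.

    Uses the studentized-range distribution with the unequal-n Tukey-Kramer
    standard error; with two groups this reduces to the two-sample t test.
    """
    design = fit.design
    levels = design.diag_levels
    if len(levels) < 2:
        return pd.DataFrame(columns=["level_a", "level_b", "estimate", "se",
                                     "p_raw", "p_adj"])
    k, df = len(levels), fit.df_resid
    rows = []
    for a, b in itertools.combinations(levels, 2):
        c = design.ls_rows[a] - design.ls_rows[b]
        est, se = fit.contrast(c)
        p_raw = float(_t_pvalue(est, se, df))
        if se > 0:
            q = abs(est) * np.sqrt(2.0) / se
            p_adj = float(stats.studentized_range.sf(q, k, df))
        else:
            p_adj = 1.0 if abs(est) < 1e-12 else 0.0
        rows.append({"level_a": a, "level_b": b, "estimate": est, "se": se,
                     "p_raw": p_raw, "p_adj": min(max(p_adj, p_raw), 1.0)})
    return pd.DataFrame(rows)


def omnibus_diagnosis_p(fit: AncovaFit) -> float:
    """Wald F test of the diagnosis main effect (all diagnosis dummies = 0)."""
    design = fit.design
    idx = [i for i, c in enumerate(design.columns) if c.startswith("diag_")]
    if not idx:
        return 1.0
    b = fit.coefficients.to_numpy()[idx]
    V = fit.cov_beta[np.ix_(idx, idx)]
    if np.allclose(V, 0):
        return 1.0 if np.allclose(b, 0) else 0.0
    F = float(b @ np.linalg.solve(V, b)) / len(idx)
    return float(stats.f.sf(F, len(idx), fit.df_resid))


def bh_fdr(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvals, float)
    if p.size == 0:
        return p
    if np.isnan(p).any():
        raise ValueError("NaN p-value passed to bh_fdr")
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# study-level pipeline
# ---------------------------------------------------------------------------

def fit_region_contrasts(study: ExpressionStudy, region: str | None = None,
                         omnibus_gate: bool = False) -> pd.DataFrame:
    """All-gene disease-vs-CTRL contrasts for one region (vectorised).

    Returns one row per (gene, diagnosis) with estimate, se, df, p_raw and,
    when ``omnibus_gate`` is set, the per-gene omnibus diagnosis F p-value.
    """
    meta = study.metadata
    if region is None:
        regions = meta.df["region"].unique()
        if len(regions) != 1:
            raise ValueError("study spans multiple regions; pass region=")
        region = regions[0]

    design = build_design(meta, scope="region")
    Y = study.expr.reindex(columns=meta.df["sample_id"]).to_numpy(float).T
    res = _fit_lmm_batch(Y, design)
    beta, cov = res["beta"], res["cov"]
    df = design.df_containment

    diag_idx = {}
    for dx in DISEASE_DIAGNOSES:
        if dx in design.diag_levels:
            c = design.ls_rows[dx] - design.ls_rows["CTRL"]
            diag_idx[dx] = c

    frames = []
    genes = study.gene_ids
    for dx, c in diag_idx.items():
        est = beta @ c
        se = np.sqrt(np.maximum(np.einsum("p,gpq,q->g", c, cov, c), 0.0))
        p = _t_pvalue(est, se, df)
        frames.append(pd.DataFrame({
            "gene": genes, "region": region, "diagnosis": dx,
            "estimate": est, "se": se, "df": df, "p_raw": p,
        }))
    out = pd.concat(frames, ignore_index=True)

    if omnibus_gate:
        idx = [i for i, col in enumerate(design.columns)
               if col.startswith("diag_")]
        b = beta[:, idx]
        V = cov[:, idx][:, :, idx]
        ok = ~np.all(np.isclose(V, 0), axis=(1, 2))
        F = np.zeros(len(b))
        F[ok] = np.einsum("gp,gp->g", b[ok],
                          np.linalg.solve(V[ok], b[ok][..., None])[..., 0]) / len(idx)
        p_omni = np.where(ok, stats.f.sf(F, len(idx), df), 1.0)
        out = out.merge(pd.DataFrame({"gene": genes, "p_omnibus": p_omni}),
                        on="gene")
    return out


def run_differential_expression(studies: dict, fold_min: float = 1.2,
                                fdr_max: float = 0.05,
                                omnibus_gate: bool = False) -> pd.DataFrame:
    """Per-region DE pipeline: mixed ANCOVA contrasts, BH-FDR per
    (region x diagnosis) family, fold change and the selection flag."""
    pieces = []
    for region, study in studies.items():
        pieces.append(fit_region_contrasts(study, region=region,
                                           omnibus_gate=omnibus_gate))
    raw = pd.concat(pieces, ignore_index=True)

    adj = np.full(len(raw), np.nan)
    for (region, dx), grp in raw.groupby(["region", "diagnosis"]):
        if omnibus_gate:
            keep = grp["p_omnibus"] < 0.05
            idx = grp.index[keep]
        else:
            idx = grp.index
        if len(idx):
            adj[idx] = bh_fdr(raw.loc[idx, "p_raw"].to_numpy())
    raw["p_adj"] = adj
    table = make_contrast_table(raw)
    if omnibus_gate:
        table.loc[table["p_adj"].isna(), "significant"] = False
    # selection thresholds may differ from the constructor defaults
    table["significant"] = (table["fold_change"] > fold_min) & \
        (table["p_adj"] < fdr_max)
    return table


def select_de_genes(contrasts: pd.DataFrame, fold_min: float = 1.2,
                    fdr_max: float = 0.05) -> dict:
    """Split significant genes into up/down lists per (diagnosis, region).

    Strict inequality on fold change (>1.2 excluded at exactly 1.2) and the
    FDR threshold (<0.05); direction from the sign of the LS-mean difference.
    """
    sel = contrasts[(contrasts["fold_change"] > fold_min)
                    & (contrasts["p_adj"] < fdr_max)]
    out: dict = {}
    for (dx, region), grp in contrasts.groupby(["diagnosis", "region"]):
        hit = sel[(sel["diagnosis"] == dx) & (sel["region"] == region)]
        out[(dx, region)] = {
            "up": sorted(hit.loc[hit["direction"] == "up", "gene"]),
            "down": sorted(hit.loc[hit["direction"] == "down", "gene"]),
        }
    return out
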