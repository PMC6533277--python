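"""Signed consensus weighted gene co-expression network analysis.

Pipeline, per block of pre-clustered genes and per region:

1. signed adjacency a_ij = ((1 + cor_ij) / 2)^beta (beta = 12 by default,
   chosen for approximate scale-free topology, model-fit R^2 > 0.8);
2. topological overlap TOM_ij = (sum_u a_iu a_uj + a_ij)
   / (min(k_i, k_j) + 1 - a_ij), the shared-neighbourhood similarity;
3. consensus TOM: per-region TOMs are single-quantile scaled to the first
   region and the elementwise minimum retained -- a pair of genes is similar
   only if similar in every region;
4. average-linkage clustering of 1 - TOM and a dynamic hybrid tree cut
   (minimum module size 50, deepSplit sensitivity 0-4, plus a second stage
   attaching unlabelled genes to sufficiently close clusters);
5. eigengene-based refinement: genes with own-module kME < 0.3 are removed,
   modules with fewer than 17 genes at kME > 0.5 are disbanded, and genes
   whose correlation p-value to another module eigengene beats their own by a
   factor of 1e-4 are reassigned (one pass after all blocks);
6. modules whose eigengenes cluster below height 0.15 (1 - cor) are merged,
   repeating until a fixed point.

Module eigengenes (MEs) are first principal components of the standardized
within-module expression, unit length and oriented so the mean member kME is
positive.  ME-trait association uses Pearson correlation with Fisher's
asymptotic z p-value and BH-FDR across the module x trait grid; module DE
enrichment delegates to the Fisher's-exact machinery in
:mod:`tetranet.pathway_enrichment`.

The tree-cut stage follows the published dynamic hybrid scheme in spirit
(branch size, core scatter and gap criteria mapped from deepSplit) without
aiming at bit-compatibility with any existing implementation; recovery of
planted structure is the correctness contract.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from . import pathway_enrichment
from .data_model import SampleTable
from .differential_expression import bh_fdr

# deepSplit 0..4 -> maximum normalised core scatter of a distinct branch
_MAX_CORE_SCATTER = {0: 0.64, 1: 0.73, 2: 0.82, 3: 0.91, 4: 0.95}


@dataclass(frozen=True)
class NetworkConfig:
    power: float = 12.0
    n_blocks: int = 4
    min_module_size: int = 50
    deep_split: int = 4
    scale_quantile: float = 0.95
    me_cor_min: float = 0.3
    disband_count: int = 17
    disband_cor: float = 0.5
    reassign_factor: float = 1e-4
    merge_cut: float = 0.15
    # dendrogram truncation for the tree cut; None -> 0.995 * top join height
    cut_height: float | None = None

    def __post_init__(self) -> None:
        if self.power < 1:
            raise ValueError("power must be >= 1")
        if not 0.0 < self.scale_quantile < 1.0:
            raise ValueError("scale_quantile must be in (0, 1)")
        if self.deep_split not in _MAX_CORE_SCATTER:
            raise ValueError("deep_split must be an integer in 0..4")
        if not 0.0 <= self.me_cor_min <= 1.0 or not 0.0 <= self.disband_cor <= 1.0:
            raise ValueError("kME thresholds must be in [0, 1]")
        if not 0.0 < self.merge_cut < 2.0:
            raise ValueError("merge_cut must be in (0, 2)")
        if self.reassign_factor <= 0 or self.reassign_factor > 1:
            raise ValueError("reassign_factor must be in (0, 1]")


# ---------------------------------------------------------------------------
# network primitives
# ---------------------------------------------------------------------------

def _as_array(expr):
    if isinstance(expr, pd.DataFrame):
        return expr.to_numpy(float), list(expr.index)
    return np.asarray(expr, float), None


def signed_adjacency(expr, power: float = 12.0):
    """Signed adjacency ((1 + r) / 2)^beta from gene-wise Pearson correlation.

    ``expr`` is genes x samples.  Perfect positive correlation maps to 1,
    perfect negative correlation to 0; the diagonal is set to 1.
    """
    X, genes = _as_array(expr)
    sd = X.std(axis=1)
    if (sd == 0).any():
        i = int(np.argmax(sd == 0))
        name = genes[i] if genes else i
        raise ValueError(f"zero-variance gene: {name!r}")
    r = np.corrcoef(X)
    np.clip(r, -1.0, 1.0, out=r)
    a = ((1.0 + r) / 2.0) ** power
    np.fill_diagonal(a, 1.0)
    if genes is not None:
        return pd.DataFrame(a, index=genes, columns=genes)
    return a


def scale_free_fit(adjacency, n_bins: int = 10) -> float:
    """R^2 of the log-log regression of p(k) on k over binned connectivity.

    Connectivity k_i excludes the diagonal; k is split into equal-width bins,
    empty bins dropped, and log10 frequency regressed on log10 mean k.
    """
    A, _ = _as_array(adjacency)
    n = A.shape[0]
    if n < 50:
        raise ValueError("scale-free fit needs >= 50 genes")
    A0 = A.copy()
    np.fill_diagonal(A0, 0.0)
    k = A0.sum(axis=1)
    if k.max() - k.min() < 1e-10:
        raise ValueError("degenerate network: all connectivities equal")
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    which = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    ks, ps = [], []
    for b in range(n_bins):
        mask = which == b
        if mask.sum() == 0:
            continue
        km = k[mask].mean()
        if km <= 0:
            continue
        ks.append(km)
        ps.append(mask.sum() / n)
    if len(ks) < 3:
        raise ValueError("too few occupied connectivity bins for a fit")
    fit = stats.linregress(np.log10(ks), np.log10(ps))
    return float(fit.rvalue ** 2)


def topological_overlap(adjacency):
    """Topological overlap matrix of a symmetric adjacency.

    TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij) for
    i != j, with connectivity k excluding the diagonal; TOM_ii = 1.
    """
    A, genes = _as_array(adjacency)
    if not np.allclose(A, A.T, atol=1e-10):
        raise ValueError("adjacency must be symmetric")
    A0 = A.copy()
    np.fill_diagonal(A0, 0.0)
    k = A0.sum(axis=1)
    num = A0 @ A0 + A0
    den = np.minimum.outer(k, k) + 1.0 - A0
    with np.errstate(invalid="ignore", divide="ignore"):
        tom = num / den
    tom = np.clip(np.nan_to_num(tom, nan=0.0), 0.0, 1.0)
    np.fill_diagonal(tom, 1.0)
    tom = (tom + tom.T) / 2.0
    if genes is not None:
        return pd.DataFrame(tom, index=genes, columns=genes)
    return tom


def consensus_tom(toms, quantile: float = 0.95):
    """Quantile-scaled elementwise-minimum consensus of per-region TOMs.

    Each region's off-diagonal values are multiplied by
    Q_q(reference) / Q_q(region), reference being the first region; the
    consensus is the elementwise minimum, clipped to [0, 1].
    """
    mats, genes = [], None
    for t in toms:
        m, g = _as_array(t)
        if mats and m.shape != mats[0].shape:
            raise ValueError("TOMs have mismatched gene sets")
        if genes is not None and g is not None and g != genes:
            raise ValueError("TOMs have mismatched gene order")
        genes = genes or g
        mats.append(m)
    if not mats:
        raise ValueError("no TOMs supplied")
    iu = np.triu_indices_from(mats[0], k=1)
    q_ref = np.quantile(mats[0][iu], quantile)
    scaled = []
    for m in mats:
        q = np.quantile(m[iu], quantile)
        s = m * (q_ref / q if q > 0 else 1.0)
        np.fill_diagonal(s, 1.0)
        scaled.append(s)
    cons = np.clip(np.minimum.reduce(scaled), 0.0, 1.0)
    np.fill_diagonal(cons, 1.0)
    if genes is not None:
        return pd.DataFrame(cons, index=genes, columns=genes)
    return cons


# ---------------------------------------------------------------------------
# block pre-clustering (consensus projective k-means)
# ---------------------------------------------------------------------------

def _projective_kmeans(Xn: np.ndarray, k: int, rng, max_iter: int = 50):
    """Projective k-means on row-standardised profiles: distance 1 - |r|,
    centres the dominant principal direction of their members."""
    n = Xn.shape[0]
    # k-means++-style seeding under the projective distance
    centers = [Xn[rng.integers(n)]]
    for _ in range(k - 1):
        d = 1.0 - np.abs(Xn @ np.array(centers).T).max(axis=1)
        probs = np.maximum(d, 1e-12) ** 2
        centers.append(Xn[rng.choice(n, p=probs / probs.sum())])
    C = np.array(centers)

    assign = np.full(n, -1)
    for _ in range(max_iter):
        sim = np.abs(Xn @ C.T)
        new_assign = sim.argmax(axis=1)
        for b in range(k):            # re-seed empty clusters with outliers
            if not (new_assign == b).any():
                far = (1.0 - sim.max(axis=1)).argmax()
                new_assign[far] = b
        if (new_assign == assign).all():
            break
        assign = new_assign
        for b in range(k):
            M = Xn[assign == b]
            v = C[b]
            for _ in range(15):       # power iteration for the top direction
                v = M.T @ (M @ v)
                nv = np.linalg.norm(v)
                if nv == 0:
                    break
                v = v / nv
            C[b] = v
    return assign, C


def preassign_blocks(X, k: int, seed: int = 0, max_iter: int = 50,
                     n_centers: int | None = None) -> np.ndarray:
    """Split genes into k blocks by projective k-means.

    ``X`` is genes x samples (profiles concatenated across regions).  The
    distance is 1 - |r| between a gene and a centre, so a profile and its
    negation land in the same block (separation is by shape, not sign).  To
    keep small correlated families intact, clustering runs with a finer set
    of centres (4k by default) which are then packed into the k blocks by
    average-linkage clustering of centre similarity.  Deterministic given
    the seed.
    """
    X = np.asarray(X, float)
    n = X.shape[0]
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > n:
        raise ValueError(f"k={k} exceeds number of genes ({n})")
    if k == 1:
        return np.zeros(n, dtype=int)

    Xc = X - X.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(Xc, axis=1)
    norms[norms == 0] = 1.0
    Xn = Xc / norms[:, None]

    rng = np.random.default_rng(seed)
    if n_centers is None:
        n_centers = min(4 * k, n)
    n_centers = max(n_centers, k)
    assign, C = _projective_kmeans(Xn, n_centers, rng, max_iter=max_iter)
    if n_centers == k:
        return assign

    # pack centres into k blocks by shape similarity
    Cc = C - C.mean(axis=1, keepdims=True)
    Cn = Cc / np.maximum(np.linalg.norm(Cc, axis=1, keepdims=True), 1e-12)
    d = np.clip(1.0 - np.abs(Cn @ Cn.T), 0.0, None)
    np.fill_diagonal(d, 0.0)
    Z = linkage(squareform(d, checks=False), method="average")
    groups = fcluster(Z, t=k, criterion="maxclust") - 1
    return groups[assign]


# ---------------------------------------------------------------------------
# dynamic hybrid tree cut
# ---------------------------------------------------------------------------

def cut_dendrogram(tom, config: NetworkConfig) -> np.ndarray:
    """Average-linkage clustering of 1 - TOM with a dynamic hybrid cut.

    The dendrogram is truncated at a cut height (0.995 of the top joining
    height unless configured): only branches fully formed below it are
    module candidates, which already leaves featureless (pure-noise)
    dendrograms -- whose joins all happen within a hair of the top --
    unclustered.  Stage 1 then decomposes candidate branches into modules
    that are large enough (>= min_module_size), internally tight and
    separated from their surroundings; the core-scatter and gap thresholds
    are mapped from deepSplit (0-4) and normalised to the spread of joining
    heights, following the published dynamic hybrid scheme.  Stage 2 attaches
    each unlabelled gene to the closest module when its mean dissimilarity is
    below the midpoint between that module's core scatter and the cut
    height.  Returns integer labels, 0 = unassigned.
    """
    T, _ = _as_array(tom)
    n = T.shape[0]
    labels = np.zeros(n, dtype=int)
    if n < config.min_module_size:
        warnings.warn("fewer genes than min_module_size; nothing assigned")
        return labels
    D = 1.0 - T
    np.fill_diagonal(D, 0.0)
    Z = linkage(squareform(D, checks=False), method="average")

    heights_all = Z[:, 2]
    cut_h = config.cut_height
    if cut_h is None:
        cut_h = 0.995 * heights_all.max()
    ref_h = np.quantile(heights_all, 0.05)
    h_range = max(cut_h - ref_h, 1e-12)

    n_nodes = 2 * n - 1
    left = np.full(n_nodes, -1)
    right = np.full(n_nodes, -1)
    height = np.zeros(n_nodes)
    size = np.ones(n_nodes)
    pair_sum = np.zeros(n_nodes)      # sum of within-branch dissimilarities
    parent_h = np.full(n_nodes, np.inf)
    for i in range(n - 1):
        node = n + i
        l, r = int(Z[i, 0]), int(Z[i, 1])
        left[node], right[node] = l, r
        height[node] = Z[i, 2]
        size[node] = size[l] + size[r]
        # average linkage: merge height is the mean cross-pair dissimilarity
        pair_sum[node] = pair_sum[l] + pair_sum[r] + Z[i, 2] * size[l] * size[r]
        parent_h[l] = parent_h[r] = Z[i, 2]

    with np.errstate(invalid="ignore", divide="ignore"):
        scatter = np.where(size > 1,
                           2.0 * pair_sum / (size * (size - 1.0)), 0.0)

    mcs = _MAX_CORE_SCATTER[config.deep_split]
    min_gap = (1.0 - mcs) * 3.0 / 4.0

    def distinct(node: int) -> bool:
        if size[node] < config.min_module_size or height[node] > cut_h:
            return False
        merge_h = min(parent_h[node], cut_h)
        scatter_norm = (scatter[node] - ref_h) / h_range
        gap_norm = (merge_h - scatter[node]) / h_range
        return scatter_norm <= mcs and gap_norm >= min_gap

    # post-order harvest of maximal distinct branches below the cut height
    result: dict = {}
    stack = [(n_nodes - 1, False)]
    while stack:
        node, processed = stack.pop()
        if node < n:
            result[node] = []
            continue
        if not processed:
            stack.append((node, True))
            stack.append((left[node], False))
            stack.append((right[node], False))
            continue
        sub = result.pop(left[node]) + result.pop(right[node])
        if sub:
            result[node] = sub
        elif distinct(node):
            result[node] = [node]
        else:
            result[node] = []
    module_nodes = result[n_nodes - 1]

    def leaves(node: int) -> list:
        out, st = [], [node]
        while st:
            v = st.pop()
            if v < n:
                out.append(v)
            else:
                st.extend((left[v], right[v]))
        return out

    members = [leaves(m) for m in module_nodes]
    for lab, mem in enumerate(members, start=1):
        labels[mem] = lab

    if members:
        # hybrid stage: attach close unlabelled genes
        unl = np.where(labels == 0)[0]
        if len(unl):
            mean_d = np.stack([D[np.ix_(unl, mem)].mean(axis=1)
                               for mem in members], axis=1)
            thresh = np.array([
                scatter[m] + 0.5 * (cut_h - scatter[m])
                for m in module_nodes])
            best = mean_d.argmin(axis=1)
            ok = mean_d[np.arange(len(unl)), best] < thresh[best]
            labels[unl[ok]] = best[ok] + 1
    return labels


# ---------------------------------------------------------------------------
# eigengenes and module refinement
# ---------------------------------------------------------------------------

def _fisher_z_logp(r: np.ndarray, n: int) -> np.ndarray:
    """log of the two-tailed Fisher-z asymptotic p-value for Pearson r."""
    r = np.clip(np.asarray(r, float), -1.0 + 1e-15, 1.0 - 1e-15)
    z = np.abs(np.arctanh(r)) * np.sqrt(max(n - 3, 1))
    return np.log(2.0) + stats.norm.logsf(z)


def fisher_z_pvalue(r, n: int):
    """Two-tailed Fisher-z asymptotic p-value for a Pearson correlation."""
    if n < 4:
        raise ValueError("Fisher z p-value requires n >= 4")
    return np.exp(_fisher_z_logp(r, n))


@dataclass
class ModuleSolution:
    """Gene-module assignment with eigengenes and membership correlations.

    ``labels``: gene -> module id (0 = unassigned).  ``mes``: samples x
    modules, each eigengene unit length and oriented so that the mean kME of
    the module's own genes is positive.  ``kme``: genes x modules Pearson
    correlations with the eigengenes.
    """

    labels: pd.Series
    mes: pd.DataFrame
    kme: pd.DataFrame

    @property
    def module_ids(self) -> list:
        return list(self.mes.columns)

    def module_genes(self, module) -> list:
        return list(self.labels.index[self.labels == module])

    def gene_sets(self) -> dict:
        return {m: self.module_genes(m) for m in self.module_ids}


def module_eigengenes(expr: pd.DataFrame, labels) -> ModuleSolution:
    """Compute MEs (first principal components) and kME for given labels.

    ``expr`` is genes x samples on a comparable scale (z-scored per gene
    within region, samples concatenated across regions).
    """
    labels = pd.Series(np.asarray(labels, int), index=expr.index)
    X = expr.to_numpy(float)
    Xc = X - X.mean(axis=1, keepdims=True)
    sd = Xc.std(axis=1)
    sd[sd == 0] = 1.0
    Xs = Xc / sd[:, None]

    mes = {}
    for m in sorted(set(labels) - {0}):
        rows = np.where(labels.to_numpy() == m)[0]
        _, _, vt = np.linalg.svd(Xs[rows], full_matrices=False)
        me = vt[0]
        if (Xs[rows] @ me).mean() < 0:   # orient: mean member kME > 0
            me = -me
        mes[m] = me
    me_df = pd.DataFrame(mes, index=expr.columns)

    if mes:
        M = me_df.to_numpy()
        Mc = M - M.mean(axis=0, keepdims=True)
        Mn = Mc / np.linalg.norm(Mc, axis=0, keepdims=True)
        Xn = Xs / np.linalg.norm(Xs, axis=1, keepdims=True)
        kme = pd.DataFrame(Xn @ Mn, index=expr.index, columns=me_df.columns)
    else:
        kme = pd.DataFrame(index=expr.index)
    return ModuleSolution(labels=labels, mes=me_df, kme=kme)


def refine_modules(expr: pd.DataFrame, labels,
                   config: NetworkConfig) -> ModuleSolution:
    """Eigengene-based module clean-up.

    In order: drop genes with own-module kME below ``me_cor_min``; disband
    modules with fewer than ``disband_count`` genes at kME above
    ``disband_cor``; recompute eigengenes; then a single reassignment pass
    moving genes whose Fisher-z kME p-value to another eigengene is smaller
    than their own module's by ``reassign_factor``.  Removed genes get
    label 0.
    """
    sol = module_eigengenes(expr, labels)
    labels = sol.labels.copy()
    n_samples = expr.shape[1]

    for m in sol.module_ids:
        own = labels == m
        weak = own & (sol.kme[m] < config.me_cor_min)
        labels[weak] = 0
    for m in sol.module_ids:
        own = labels == m
        strong = int((sol.kme.loc[own, m] > config.disband_cor).sum())
        if strong < config.disband_count:
            labels[own] = 0

    sol = module_eigengenes(expr, labels)
    if sol.module_ids:
        logp = pd.DataFrame(
            {m: _fisher_z_logp(sol.kme[m].to_numpy(), n_samples)
             for m in sol.module_ids}, index=sol.kme.index)
        log_factor = np.log(config.reassign_factor)
        new_labels = sol.labels.copy()
        for gene in labels.index[labels > 0]:
            own = labels[gene]
            row = logp.loc[gene]
            best = row.idxmin()
            if best != own and row[best] < row[own] + log_factor:
                new_labels[gene] = best
        labels = new_labels
        sol = module_eigengenes(expr, labels)
    return sol


def merge_modules(expr: pd.DataFrame, solution: ModuleSolution,
                  merge_cut: float = 0.15) -> ModuleSolution:
    """Merge modules whose eigengenes cluster below ``merge_cut`` (1 - cor).

    Average-linkage clustering of MEs is cut at the merge height; all modules
    on a resulting branch are merged and eigengenes recomputed, repeating
    until no merge occurs.  Terminates because the module count strictly
    decreases each round.
    """
    sol = solution
    while len(sol.module_ids) > 1:
        M = sol.mes.to_numpy()
        corr = np.corrcoef(M.T)
        d = np.clip(1.0 - corr, 0.0, None)
        np.fill_diagonal(d, 0.0)
        Z = linkage(squareform(d, checks=False), method="average")
        groups = fcluster(Z, t=merge_cut, criterion="distance")
        if len(set(groups)) == len(sol.module_ids):
            break
        mapping = {}
        for g in set(groups):
            mods = [m for m, grp in zip(sol.module_ids, groups) if grp == g]
            keep = min(mods)
            for m in mods:
                mapping[m] = keep
        labels = sol.labels.map(lambda m: mapping.get(m, 0))
        sol = module_eigengenes(expr, labels)
    return sol


def canonicalize(solution: ModuleSolution) -> ModuleSolution:
    """Renumber modules 1..K by decreasing size (ties by smallest gene id)."""
    sizes = []
    for m in solution.module_ids:
        genes = solution.module_genes(m)
        sizes.append((-len(genes), min(genes), m))
    mapping = {m: i + 1 for i, (_, _, m) in enumerate(sorted(sizes))}
    labels = solution.labels.map(lambda m: mapping.get(m, 0))
    mes = solution.mes.rename(columns=mapping)
    kme = solution.kme.rename(columns=mapping)
    order = sorted(mes.columns)
    return ModuleSolution(labels=labels, mes=mes[order], kme=kme[order])


# ---------------------------------------------------------------------------
# module-trait statistics and DE enrichment
# ---------------------------------------------------------------------------

def trait_matrix(meta: SampleTable, scheme: str = "one_vs_rest",
                 include_covariates: bool = True) -> pd.DataFrame:
    """Numeric per-sample trait coding: 0/1 diagnosis indicators (one column
    per disorder, one-vs-rest by default or one-vs-control) and, optionally,
    the continuous covariates."""
    df = meta.df.set_index("sample_id")
    out = pd.DataFrame(index=df.index)
    for dx in ("SCZ", "BD", "MDD"):
        if scheme == "one_vs_rest":
            out[dx] = (df["diagnosis"] == dx).astype(float)
        elif scheme == "one_vs_control":
            col = pd.Series(np.nan, index=df.index)
            col[df["diagnosis"] == dx] = 1.0
            col[df["diagnosis"] == "CTRL"] = 0.0
            out[dx] = col
        else:
            raise ValueError("scheme must be one_vs_rest or one_vs_control")
    if include_covariates:
        for cov in ("age", "pmi", "ph"):
            out[cov] = df[cov].astype(float)
    return out


def module_trait_stats(solution: ModuleSolution, traits: pd.DataFrame,
                       groups: pd.Series | None = None) -> pd.DataFrame:
    """Pearson ME-trait correlations with Fisher-z p and BH-FDR.

    ``traits`` is samples x traits, aligned to the eigengene sample index;
    rows with missing trait values are dropped pairwise.  When ``groups``
    (sample -> group, typically brain region) is given, one correlation is
    computed per (module, trait, group) over that group's samples -- with
    one sample per subject and region this makes n the number of subjects,
    avoiding pseudo-replication across regions.  BH-FDR runs over the whole
    reported grid.
    """
    traits = traits.reindex(solution.mes.index)
    if groups is None:
        group_iter = [(None, solution.mes.index)]
    else:
        groups = pd.Series(groups).reindex(solution.mes.index)
        group_iter = [(g, groups.index[groups == g])
                      for g in pd.unique(groups.dropna())]
    rows = []
    for m in solution.module_ids:
        me = solution.mes[m]
        for gname, idx in group_iter:
            for trait in traits.columns:
                t = traits.loc[idx, trait]
                mask = t.notna()
                n = int(mask.sum())
                if n < 4:
                    raise ValueError(
                        f"trait {trait!r}: fewer than 4 samples")
                r = float(np.corrcoef(me.loc[idx][mask], t[mask])[0, 1])
                p = float(fisher_z_pvalue(r, n))
                row = {"module": m, "trait": trait, "n": n, "r": r, "p": p}
                if gname is not None:
                    row["group"] = gname
                rows.append(row)
    out = pd.DataFrame(rows)
    if len(out):
        out["p_adj"] = bh_fdr(out["p"].to_numpy())
    return out


def module_de_enrichment(solution: ModuleSolution, de_lists: dict,
                         universe) -> pd.DataFrame:
    """Fisher's exact enrichment of DE genes within each module.

    ``de_lists`` maps (diagnosis, region) -> {'up': [...], 'down': [...]};
    up and down lists are pooled per condition.  Delegates to
    :func:`tetranet.pathway_enrichment.fisher_enrichment`.
    """
    rows = []
    for m in solution.module_ids:
        genes = solution.module_genes(m)
        for (dx, region), lists in sorted(de_lists.items()):
            de = list(lists["up"]) + list(lists["down"])
            overlap, p = pathway_enrichment.fisher_enrichment(
                de, genes, universe)
            rows.append({"module": m, "diagnosis": dx, "region": region,
                         "module_size": len(genes), "de_size": len(de),
                         "overlap": overlap, "p": p})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------

@dataclass
class ConsensusNetworkResult:
    solution: ModuleSolution
    blocks: pd.Series
    config: NetworkConfig
    scale_free_r2: dict = field(default_factory=dict)

    @property
    def labels(self) -> pd.Series:
        return self.solution.labels

    @property
    def mes(self) -> pd.DataFrame:
        return self.solution.mes

    @property
    def kme(self) -> pd.DataFrame:
        return self.solution.kme


def _zscore_within_region(studies: dict) -> pd.DataFrame:
    parts = []
    genes = None
    for region, study in studies.items():
        if genes is None:
            genes = study.gene_ids
        elif study.gene_ids != genes:
            raise ValueError("regions have mismatched gene sets")
        X = study.expr.to_numpy(float)
        mu = X.mean(axis=1, keepdims=True)
        sd = X.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        parts.append(pd.DataFrame((X - mu) / sd, index=genes,
                                  columns=study.sample_ids))
    return pd.concat(parts, axis=1)


def build_consensus_network(studies: dict, config: NetworkConfig | None = None,
                            seed: int = 0,
                            compute_scale_free: bool = False
                            ) -> ConsensusNetworkResult:
    """End-to-end signed consensus network over per-region studies.

    ``studies`` maps region -> :class:`ExpressionStudy` with identical gene
    order; the first region is the quantile-scaling reference.  Deterministic
    given the seed (used only by the block pre-clustering).
    """
    if config is None:
        config = NetworkConfig()
    regions = list(studies)
    Xz = _zscore_within_region(studies)
    genes = list(Xz.index)

    n_blocks = min(config.n_blocks, len(genes))
    blocks = preassign_blocks(Xz.to_numpy(), n_blocks, seed=seed)

    labels = np.zeros(len(genes), dtype=int)
    offset = 0
    r2: dict = {}
    for b in range(n_blocks):
        idx = np.where(blocks == b)[0]
        if len(idx) < 3:
            continue
        toms = []
        for region in regions:
            sub = studies[region].expr.iloc[idx]
            adj = signed_adjacency(sub, config.power)
            if compute_scale_free and len(idx) >= 50:
                try:
                    r2[(region, b)] = scale_free_fit(adj)
                except ValueError:
                    pass
            toms.append(topological_overlap(adj))
        ctom = consensus_tom(toms, config.scale_quantile)
        lab = cut_dendrogram(ctom, config)
        lab = np.where(lab > 0, lab + offset, 0)
        offset = max(offset, lab.max())
        labels[idx] = lab

    sol = refine_modules(Xz, pd.Series(labels, index=genes), config)
    sol = merge_modules(Xz, sol, config.merge_cut)
    sol = canonicalize(sol)
    return ConsensusNetworkResult(solution=sol,
                                  blocks=pd.Series(blocks, index=genes),
                                  config=config, scale_free_r2=r2)
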