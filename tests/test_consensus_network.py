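"""Network primitives against closed forms and brute-force oracles, the
dynamic hybrid cut on planted partitions, and module refinement rules."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from tetranet import consensus_network as cn
from tetranet.synthetic_data import SimulationConfig, simulate_study

CFG = cn.NetworkConfig()


def factor_block(rng, n_genes, n_samples, cor, factor=None):
    """Genes sharing one latent factor at a target pairwise correlation."""
    if factor is None:
        factor = rng.normal(size=n_samples)
    lam = np.sqrt(cor / (1.0 - cor))
    return lam * factor + rng.normal(size=(n_genes, n_samples)), factor


class TestSignedAdjacency:
    def test_closed_forms_at_power_12(self):
        x = np.array([1.0, -1.0, 1.0, -1.0])
        y = np.array([1.0, 1.0, -1.0, -1.0])     # exactly orthogonal to x
        expr = np.vstack([x, x, -x, y])
        a = cn.signed_adjacency(expr, 12.0)
        assert a[0, 1] == pytest.approx(1.0)          # r = +1
        assert a[0, 2] == pytest.approx(0.0)          # r = -1
        assert a[0, 3] == pytest.approx(0.5 ** 12)    # r = 0
        assert np.allclose(np.diag(a), 1.0)

    def test_zero_variance_gene_named(self):
        expr = pd.DataFrame([[1.0, 2.0, 3.0], [5.0, 5.0, 5.0]],
                            index=["ok", "flatgene"])
        with pytest.raises(ValueError, match="flatgene"):
            cn.signed_adjacency(expr, 12.0)


class TestScaleFreeFit:
    def test_power_law_degree_toy_graph_fits_near_one(self):
        counts = {k: max(1, int(600 * k ** -2.0)) for k in range(1, 11)}
        w = np.concatenate([np.full(c, k * 0.02) for k, c in counts.items()])
        A = np.outer(w, w) / w.sum()
        np.fill_diagonal(A, 1.0)
        assert cn.scale_free_fit(np.clip(A, 0, 1)) > 0.95

    def test_equal_weight_complete_graph_is_degenerate(self):
        A = np.full((60, 60), 0.5)
        np.fill_diagonal(A, 1.0)
        with pytest.raises(ValueError, match="degenerate"):
            cn.scale_free_fit(A)

    def test_default_fixture_regions_approximately_scale_free(
            self, default_study):
        """Whole-region signed networks at the default power show the
        approximate scale-free topology the power choice targets."""
        studies, _ = default_study
        r2 = [cn.scale_free_fit(cn.signed_adjacency(st.expr, 12.0))
              for st in studies.values()]
        assert min(r2) >= 0.75
        assert np.mean(r2) > 0.8


class TestTopologicalOverlap:
    def test_no_edges_gives_identity(self):
        tom = cn.topological_overlap(np.eye(5))
        assert np.allclose(tom, np.eye(5))

    def test_isolated_perfect_pair_saturates(self):
        A = np.eye(4)
        A[0, 1] = A[1, 0] = 1.0
        tom = cn.topological_overlap(A)
        assert tom[0, 1] == pytest.approx(1.0)

    def test_matches_brute_force_double_loop(self):
        rng = np.random.default_rng(5)
        for n in (8, 12):
            A = rng.uniform(0, 1, (n, n))
            A = (A + A.T) / 2
            np.fill_diagonal(A, 1.0)
            tom = cn.topological_overlap(A)
            for i in range(n):
                for j in range(n):
                    if i == j:
                        assert tom[i, j] == 1.0
                        continue
                    num = sum(A[i, u] * A[u, j] for u in range(n)
                              if u != i and u != j) + A[i, j]
                    ki = sum(A[i, u] for u in range(n) if u != i)
                    kj = sum(A[j, u] for u in range(n) if u != j)
                    expect = num / (min(ki, kj) + 1 - A[i, j])
                    assert abs(tom[i, j] - expect) < 1e-12

    def test_asymmetric_input_rejected(self):
        A = np.eye(4)
        A[0, 1] = 0.5
        with pytest.raises(ValueError, match="symmetric"):
            cn.topological_overlap(A)


class TestConsensusTom:
    def _random_tom(self, rng, n):
        X = rng.normal(size=(n, 30))
        return cn.topological_overlap(cn.signed_adjacency(X, 6.0))

    def test_identical_regions_are_a_fixed_point(self):
        rng = np.random.default_rng(6)
        t = self._random_tom(rng, 15)
        cons = cn.consensus_tom([t, t, t], 0.95)
        assert np.allclose(cons, t, atol=1e-15)

    def test_uniform_rescaling_is_undone_by_quantile_scaling(self):
        rng = np.random.default_rng(7)
        t = self._random_tom(rng, 15)
        half = t * 0.5
        np.fill_diagonal(half, 1.0)
        for q in (0.5, 0.8, 0.95):
            cons = cn.consensus_tom([t, half], q)
            off = ~np.eye(15, dtype=bool)
            assert np.allclose(cons[off], t[off], atol=1e-12)

    def test_consensus_below_each_scaled_regional_tom(self):
        rng = np.random.default_rng(8)
        toms = [self._random_tom(rng, 20) for _ in range(3)]
        q = 0.95
        cons = cn.consensus_tom(toms, q)
        iu = np.triu_indices(20, k=1)
        q_ref = np.quantile(toms[0][iu], q)
        for t in toms:
            scaled = t * (q_ref / np.quantile(t[iu], q))
            np.fill_diagonal(scaled, 1.0)
            assert (cons <= scaled + 1e-12).all()


class TestPreassignBlocks:
    def test_k_one_is_single_block(self):
        rng = np.random.default_rng(9)
        assert (cn.preassign_blocks(rng.normal(size=(30, 20)), 1) == 0).all()

    def test_k_larger_than_genes_rejected(self):
        with pytest.raises(ValueError):
            cn.preassign_blocks(np.zeros((5, 4)), 6)

    def test_anticorrelated_families_split_by_shape_not_sign(self):
        rng = np.random.default_rng(10)
        f1, f2 = rng.normal(size=40), rng.normal(size=40)
        fam1 = np.vstack([3 * f1 + rng.normal(size=(20, 40)),
                          -3 * f1 + rng.normal(size=(20, 40))])
        fam2 = np.vstack([3 * f2 + rng.normal(size=(20, 40)),
                          -3 * f2 + rng.normal(size=(20, 40))])
        blocks = cn.preassign_blocks(np.vstack([fam1, fam2]), 2, seed=0)
        assert len(set(blocks[:40])) == 1       # family 1 intact (both signs)
        assert len(set(blocks[40:])) == 1
        assert blocks[0] != blocks[40]

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(11)
        X = rng.normal(size=(60, 25))
        b1 = cn.preassign_blocks(X, 3, seed=7)
        b2 = cn.preassign_blocks(X, 3, seed=7)
        assert (b1 == b2).all()


class TestCutDendrogram:
    def test_two_planted_blocks_recovered_exactly(self):
        rng = np.random.default_rng(12)
        b1, _ = factor_block(rng, 100, 40, 0.8)
        b2, _ = factor_block(rng, 100, 40, 0.8)
        tom = cn.topological_overlap(
            cn.signed_adjacency(np.vstack([b1, b2]), 12.0))
        labels = cn.cut_dendrogram(tom, CFG)
        assert (labels > 0).all()
        assert len(set(labels[:100])) == 1 and len(set(labels[100:])) == 1
        assert labels[0] != labels[150]

    @pytest.mark.parametrize("seed", range(5))
    def test_pure_noise_leaves_genes_unassigned(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(300, 76))
        tom = cn.topological_overlap(cn.signed_adjacency(X, 12.0))
        labels = cn.cut_dendrogram(tom, CFG)
        assert (labels == 0).all()

    def test_gene_permutation_permutes_labels(self):
        rng = np.random.default_rng(13)
        b1, _ = factor_block(rng, 80, 40, 0.7)
        b2, _ = factor_block(rng, 60, 40, 0.7)
        X = np.vstack([b1, b2, rng.normal(size=(40, 40))])
        tom = cn.topological_overlap(cn.signed_adjacency(X, 12.0))
        labels = cn.cut_dendrogram(tom, CFG)
        perm = rng.permutation(len(X))
        tom_p = tom[np.ix_(perm, perm)]
        labels_p = cn.cut_dendrogram(tom_p, CFG)
        # identical partitions (as sets of gene indices)
        def parts(lab, idx):
            out = {}
            for g, m in zip(idx, lab):
                out.setdefault(m, set()).add(g)
            return {frozenset(v) for k, v in out.items() if k != 0}, \
                {g for g, m in zip(idx, lab) if m == 0}
        assert parts(labels, range(len(X))) == parts(labels_p, perm)

    def test_fewer_genes_than_min_size_warns_unassigned(self):
        tom = np.eye(10)
        with pytest.warns(UserWarning):
            labels = cn.cut_dendrogram(tom, CFG)
        assert (labels == 0).all()


class TestEigengenesAndRefinement:
    def _solution(self, seed=14, cor=0.8):
        rng = np.random.default_rng(seed)
        b1, _ = factor_block(rng, 60, 50, cor)
        b2, _ = factor_block(rng, 40, 50, cor)
        noise = rng.normal(size=(30, 50))
        expr = pd.DataFrame(np.vstack([b1, b2, noise]),
                            index=[f"G{i}" for i in range(130)])
        labels = np.r_[np.ones(60), np.full(40, 2), np.zeros(30)]
        return expr, labels

    def test_me_unit_norm_and_orientation(self):
        expr, labels = self._solution()
        sol = cn.module_eigengenes(expr, labels)
        for m in sol.module_ids:
            assert np.linalg.norm(sol.mes[m]) == pytest.approx(1.0)
            own = sol.labels == m
            assert sol.kme.loc[own, m].mean() > 0

    def test_me_explains_more_variance_than_any_member_gene(self):
        expr, labels = self._solution()
        sol = cn.module_eigengenes(expr, labels)
        X = expr.to_numpy()
        Xs = (X - X.mean(1, keepdims=True)) / X.std(1, keepdims=True)
        for m in sol.module_ids:
            rows = np.where(sol.labels.to_numpy() == m)[0]
            M = Xs[rows]
            me = sol.mes[m].to_numpy()
            var_me = np.linalg.norm(M @ me) ** 2
            for g in rows[:10]:
                v = Xs[g] / np.linalg.norm(Xs[g])
                assert var_me >= np.linalg.norm(M @ v) ** 2 - 1e-9

    def test_clean_module_keeps_all_genes(self):
        expr, labels = self._solution(cor=0.85)
        sol = cn.refine_modules(expr, labels, CFG)
        assert (sol.labels.to_numpy()[:60] == sol.labels.iloc[0]).all()
        assert sol.labels.iloc[0] != 0

    def test_sixteen_gene_module_disbanded(self):
        rng = np.random.default_rng(15)
        b1, _ = factor_block(rng, 16, 50, 0.9)
        b2, _ = factor_block(rng, 60, 50, 0.8)
        expr = pd.DataFrame(np.vstack([b1, b2]),
                            index=[f"G{i}" for i in range(76)])
        labels = np.r_[np.ones(16), np.full(60, 2)]
        sol = cn.refine_modules(expr, labels, CFG)
        assert (sol.labels.iloc[:16] == 0).all()       # fewer than 17 strong
        assert (sol.labels.iloc[16:] != 0).all()

    def test_gene_loading_stronger_on_other_factor_reassigned(self):
        rng = np.random.default_rng(16)
        b1, f1 = factor_block(rng, 60, 80, 0.7)
        b2, f2 = factor_block(rng, 60, 80, 0.7)
        # last gene of module 1 keeps a real loading on its own factor
        # (so the kME > 0.3 filter retains it) but loads far more strongly
        # on factor 2 -> its kME p-value to module 2 wins by >> 1e4
        b1[-1] = 1.3 * f1 + 3.0 * f2 + 0.5 * rng.normal(size=80)
        expr = pd.DataFrame(np.vstack([b1, b2]),
                            index=[f"G{i}" for i in range(120)])
        labels = np.r_[np.ones(60), np.full(60, 2)]
        sol = cn.refine_modules(expr, labels, CFG)
        assert sol.labels.iloc[59] == sol.labels.iloc[60]

    def test_split_factor_modules_merge_and_merge_is_idempotent(self):
        rng = np.random.default_rng(17)
        block, f = factor_block(rng, 80, 50, 0.8)
        other, _ = factor_block(rng, 50, 50, 0.8)
        expr = pd.DataFrame(np.vstack([block, other]),
                            index=[f"G{i}" for i in range(130)])
        labels = np.r_[np.ones(40), np.full(40, 2), np.full(50, 3)]
        sol = cn.module_eigengenes(expr, labels)
        merged = cn.merge_modules(expr, sol, 0.15)
        assert len(merged.module_ids) == 2        # halves of one factor join
        lab = merged.labels
        assert len(set(lab.iloc[:80])) == 1
        assert lab.iloc[0] != lab.iloc[100]       # independent factor kept
        again = cn.merge_modules(expr, merged, 0.15)
        assert again.labels.equals(merged.labels)


class TestModuleTraitStats:
    def test_fisher_z_closed_form(self):
        p = cn.fisher_z_pvalue(0.5, 28)
        expect = 2 * stats.norm.sf(abs(np.arctanh(0.5)) * 5)
        assert p == pytest.approx(expect, rel=1e-12)
        assert cn.fisher_z_pvalue(0.0, 30) == pytest.approx(1.0)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            cn.fisher_z_pvalue(0.3, 3)

    def test_delegation_to_fisher_enrichment(self):
        rng = np.random.default_rng(18)
        genes = [f"G{i}" for i in range(100)]
        expr = pd.DataFrame(rng.normal(size=(100, 30)), index=genes)
        labels = np.r_[np.ones(40), np.zeros(60)]
        sol = cn.module_eigengenes(expr, labels)
        de_lists = {("SCZ", "HIP"): {"up": genes[:20], "down": genes[90:]}}
        res = cn.module_de_enrichment(sol, de_lists, genes)
        from tetranet.pathway_enrichment import fisher_enrichment
        ov, p = fisher_enrichment(genes[:20] + genes[90:], genes[:40], genes)
        row = res.iloc[0]
        assert row["overlap"] == ov and row["p"] == pytest.approx(p)


class TestFullPipeline:
    def test_deterministic_given_seed(self):
        studies, _ = simulate_study(SimulationConfig(n_genes=900, seed=2))
        r1 = cn.build_consensus_network(studies, seed=3)
        r2 = cn.build_consensus_network(studies, seed=3)
        assert r1.labels.equals(r2.labels)
        pd.testing.assert_frame_equal(r1.mes, r2.mes)

    def test_labels_canonical_by_decreasing_size(self, default_network):
        sizes = default_network.labels[default_network.labels > 0] \
            .value_counts().sort_index()
        assert (sizes.diff().dropna() <= 0).all()
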