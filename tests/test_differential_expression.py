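"""Mixed ANCOVA fitting, contrasts, Tukey-Kramer and DE selection."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import statsmodels.api as sm

from tetranet import data_model as dm
from tetranet import differential_expression as de

from conftest import make_sample_table


@pytest.fixture(scope="module")
def meta4():
    return make_sample_table(n_tetrads=4, seed=1)


@pytest.fixture(scope="module")
def design4(meta4):
    return de.build_design(meta4, scope="region")


class TestDesign:
    def test_columns_and_containment_df(self, design4):
        assert design4.columns[0] == "Intercept"
        assert {"diag_SCZ", "diag_BD", "diag_MDD"} <= set(design4.columns)
        n, p = design4.X.shape
        assert design4.df_containment == n - p - design4.n_tetrads + 1

    def test_rank_deficient_design_names_aliased_columns(self):
        df = make_sample_table(n_tetrads=4, seed=1).df.copy()
        # make tobacco a perfect copy of sex -> aliased dummy columns
        df["tobacco"] = np.where(df["sex"] == "F", "yes", "no")
        with pytest.raises(ValueError, match="aliased.*tobacco|tobacco.*aliased"):
            de.build_design(dm.SampleTable(df), scope="region")

    def test_single_diagnosis_rejected(self):
        table = make_sample_table(n_tetrads=3, diagnoses=("CTRL",))
        with pytest.raises(ValueError, match="2 diagnosis"):
            de.build_design(table, scope="region")


class TestFitGeneAncova:
    def test_constant_response_gives_zero_effects_and_variances(self, meta4):
        y = pd.Series(2.5, index=meta4.df["sample_id"])
        fit = de.fit_gene_ancova(y, meta4)
        assert fit.tetrad_var == 0.0 and fit.resid_var == 0.0
        contr = de.disease_contrasts(fit)
        assert np.allclose(contr["estimate"], 0.0)
        assert (contr["p_raw"] == 1.0).all()
        tk = de.tukey_kramer(fit)
        assert (tk["p_adj"] == 1.0).all()

    def test_noiseless_planted_shift_recovered_exactly(self, meta4):
        delta = 0.37
        y = 1.0 + delta * (meta4.df["diagnosis"] == "SCZ").to_numpy(float)
        fit = de.fit_gene_ancova(y, meta4)
        contr = de.disease_contrasts(fit).set_index("diagnosis")
        assert abs(contr.loc["SCZ", "estimate"] - delta) < 1e-8
        assert abs(contr.loc["BD", "estimate"]) < 1e-8

    def test_fixed_effects_match_explicit_gls_oracle(self, meta4, design4):
        """At the fitted variance components, the coefficients must equal a
        GLS solve against the explicit marginal covariance
        sigma^2 I + tau^2 Z Z'."""
        rng = np.random.default_rng(2)
        for _ in range(5):
            y = rng.normal(2.0, 0.3, len(meta4))
            fit = de.fit_gene_ancova(y, meta4, design=design4)
            Z = np.zeros((len(y), design4.n_tetrads))
            Z[np.arange(len(y)), design4.tetrad_codes] = 1.0
            V = fit.resid_var * np.eye(len(y)) + fit.tetrad_var * (Z @ Z.T)
            Vi = np.linalg.inv(V)
            X = design4.X
            beta = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y)
            assert np.abs(beta - fit.coefficients.to_numpy()).max() < 1e-6

    def test_reml_agrees_with_statsmodels_mixedlm(self):
        meta = make_sample_table(n_tetrads=12, seed=3)
        design = de.build_design(meta, scope="region")
        rng = np.random.default_rng(3)
        tet = design.tetrad_codes
        y = (rng.normal(0, 0.1, len(meta))
             + rng.normal(0, 0.3, design.n_tetrads)[tet] + 2.0)
        fit = de.fit_gene_ancova(y, meta, design=design)
        mf = sm.MixedLM(y, design.X, groups=tet).fit(reml=True)
        assert np.abs(fit.coefficients.to_numpy() - mf.fe_params).max() < 1e-6
        assert abs(fit.resid_var - mf.scale) < 1e-5
        tau_sm = float(np.asarray(mf.cov_re)[0, 0])
        assert abs(fit.tetrad_var - tau_sm) < 1e-5


class TestTukeyKramer:
    def test_two_groups_reduces_to_t_test(self):
        meta = make_sample_table(n_tetrads=12, diagnoses=("CTRL", "SCZ"))
        rng = np.random.default_rng(4)
        y = rng.normal(0, 1, len(meta)) + 0.5 * (
            meta.df["diagnosis"] == "SCZ").to_numpy()
        fit = de.fit_gene_ancova(y, meta)
        tk = de.tukey_kramer(fit).iloc[0]
        assert abs(tk["p_adj"] - tk["p_raw"]) < 1e-6

    def test_adjusted_p_monotone_in_shift(self, meta4):
        prev = 1.1
        rng = np.random.default_rng(5)
        noise = rng.normal(0, 0.5, len(meta4))
        scz = (meta4.df["diagnosis"] == "SCZ").to_numpy(float)
        for shift in (0.0, 0.5, 1.0, 2.0):
            fit = de.fit_gene_ancova(noise + shift * scz, meta4)
            tk = de.tukey_kramer(fit)
            p = float(tk.set_index(["level_a", "level_b"])
                      .loc[("CTRL", "SCZ"), "p_adj"])
            assert p <= prev + 1e-12
            prev = p

    def test_adjusted_never_below_raw_over_random_fits(self, meta4, design4):
        rng = np.random.default_rng(6)
        Y = rng.normal(0, 1, (len(meta4), 1000))
        res = de._fit_lmm_batch(Y, design4)
        df = design4.df_containment
        k = len(design4.diag_levels)
        import itertools
        for a, b in itertools.combinations(design4.diag_levels, 2):
            c = design4.ls_rows[a] - design4.ls_rows[b]
            est = res["beta"] @ c
            se = np.sqrt(np.einsum("p,gpq,q->g", c, res["cov"], c))
            p_raw = 2 * stats.t.sf(np.abs(est / se), df)
            q = np.abs(est) * np.sqrt(2.0) / se
            p_adj = stats.studentized_range.sf(q, k, df)
            assert (p_adj >= p_raw - 1e-10).all()


class TestBhFdr:
    def test_single_p_is_identity(self):
        assert de.bh_fdr([0.05]) == pytest.approx([0.05])

    def test_hand_computed_step_up(self):
        out = de.bh_fdr([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(out, [0.04, 0.04, 0.04, 0.04])

    def test_nan_rejected(self):
        with pytest.raises(ValueError):
            de.bh_fdr([0.1, np.nan])

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1,
                    max_size=40))
    def test_step_up_output_sorted_monotone(self, pvals):
        out = de.bh_fdr(pvals)
        order = np.argsort(pvals)
        assert (np.diff(out[order]) >= -1e-12).all()
        assert (out >= np.asarray(pvals) - 1e-12).all()
        assert (out <= 1.0).all()


class TestSelectDeGenes:
    @pytest.fixture()
    def toy_contrasts(self):
        rows = [
            # fold exactly 1.2 -> excluded by strict inequality
            {"gene": "G1", "region": "HIP", "diagnosis": "SCZ",
             "estimate": np.log10(1.2), "se": 0.01, "df": 40,
             "p_raw": 1e-5, "p_adj": 1e-4},
            # fold 1.5, p_adj 0.049, negative estimate -> down list
            {"gene": "G2", "region": "HIP", "diagnosis": "SCZ",
             "estimate": -np.log10(1.5), "se": 0.01, "df": 40,
             "p_raw": 0.01, "p_adj": 0.049},
            # significant fold but FDR at threshold -> excluded
            {"gene": "G3", "region": "HIP", "diagnosis": "SCZ",
             "estimate": 0.3, "se": 0.01, "df": 40,
             "p_raw": 0.02, "p_adj": 0.05},
        ]
        return dm.make_contrast_table(rows)

    def test_strict_thresholds_and_direction(self, toy_contrasts):
        sel = de.select_de_genes(toy_contrasts)
        lists = sel[("SCZ", "HIP")]
        assert lists["up"] == []
        assert lists["down"] == ["G2"]

    def test_fold_change_consistency(self, toy_contrasts):
        assert np.allclose(toy_contrasts["fold_change"],
                           10 ** toy_contrasts["estimate"].abs())


class TestOmnibusGate:
    def test_gate_runs_and_blanks_nonsignificant_genes(self):
        meta = make_sample_table(n_tetrads=5, seed=8)
        rng = np.random.default_rng(8)
        genes = [f"G{i}" for i in range(30)]
        expr = pd.DataFrame(rng.normal(2, 0.1, (30, len(meta))),
                            index=genes, columns=meta.df["sample_id"])
        # one strongly shifted gene
        expr.iloc[0] += 1.0 * (meta.df["diagnosis"] == "SCZ").to_numpy()
        study = dm.ExpressionStudy(expr, meta)
        tab = de.run_differential_expression({"HIP": study},
                                             omnibus_gate=True)
        g0 = tab[(tab["gene"] == "G0") & (tab["diagnosis"] == "SCZ")]
        assert g0["significant"].iloc[0]
        assert tab["p_adj"].isna().any()  # gated-out genes carry no FDR


class TestPooledScope:
    def test_pooled_fit_includes_region_and_recovers_shift(self):
        meta = make_sample_table(n_tetrads=10, regions=dm.REGIONS, seed=9)
        rng = np.random.default_rng(9)
        delta = 0.25
        y = (rng.normal(2.0, 0.05, len(meta))
             + delta * (meta.df["diagnosis"] == "SCZ").to_numpy()
             + 0.1 * (meta.df["region"] == "HIP").to_numpy())
        design = de.build_design(meta, scope="pooled")
        assert any(c.startswith("region_") for c in design.columns)
        fit = de.fit_gene_ancova(y, meta, scope="pooled", design=design)
        contr = de.disease_contrasts(fit).set_index("diagnosis")
        assert abs(contr.loc["SCZ", "estimate"] - delta) < 0.05

    def test_region_scope_rejects_multi_region_metadata(self):
        meta = make_sample_table(n_tetrads=2, regions=dm.REGIONS)
        with pytest.raises(ValueError, match="one region"):
            de.build_design(meta, scope="region")
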