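"""End-to-end recovery experiments on the synthetic study design.

These drive the full pipeline -- simulate, fit, enrich, build networks --
and score the results against the planted ground truth.  They are the
package's headline checks: statistical calibration under the null, recovery
of the planted DE burden orderings (SCZ >> BD > MDD per region;
HIP > STR > DLPFC within SCZ), recovery of planted co-expression modules,
and the behaviour of the inflammation-like SCZ-up module through the
enrichment and module-trait statistics.
"""

from __future__ import annotations

import numpy as np
from scipy import stats
from sklearn.metrics import adjusted_rand_score

from . import consensus_network as cn
from . import differential_expression as de
from . import pathway_enrichment as pe
from .data_model import GeneSetCollection
from .synthetic_data import (
    SimulationConfig,
    SyntheticTruth,
    combined_sample_table,
    decoy_gene_sets,
    null_config,
    simulate_study,
)

REGION_ORDER = ("HIP", "STR", "DLPFC")
DISEASE_ORDER = ("SCZ", "BD", "MDD")


def _derive_seed(seed: int, k: int) -> int:
    return int((seed * 1_000_003 + k) % (2**31 - 1))


def run_null_calibration(seed: int, n_genes: int = 2000) -> dict:
    """Null-simulation calibration: KS uniformity of raw contrast p-values
    (pooled across regions, per contrast) and the false-positive proportion
    of the fold/FDR selection rule."""
    studies, _ = simulate_study(null_config(n_genes=n_genes, seed=seed))
    contr = de.run_differential_expression(studies)
    ks_p = {}
    for dx, grp in contr.groupby("diagnosis"):
        ks_p[dx] = float(stats.kstest(grp["p_raw"].to_numpy(),
                                      "uniform").pvalue)
    n_tests = len(contr)
    fp = int(contr["significant"].sum())
    return {
        "ks_p": ks_p,
        "ks_p_min": min(ks_p.values()),
        "fp_proportion": fp / n_tests,
        "fp_bound": 0.05 + 3 * np.sqrt(0.05 * 0.95 / n_tests),
        "n_tests": n_tests,
    }


def score_de_recovery(truth: SyntheticTruth, contrasts) -> dict:
    """Sensitivity / observed FDR of DE selection against planted truth, and
    the mean signed estimation bias over the independently planted genes."""
    sel = de.select_de_genes(contrasts)
    tp = fp = fn = 0
    for (dx, region), lists in sel.items():
        found = set(lists["up"]) | set(lists["down"])
        true = set(truth.de_genes.get((dx, region), {}))
        tp += len(found & true)
        fp += len(found - true)
        fn += len(true - found)
    est = contrasts.set_index(["diagnosis", "region", "gene"])["estimate"]
    errors, mags = [], []
    for (dx, region), effects in truth.plan_de_genes.items():
        for g, e in effects.items():
            errors.append(float(est.loc[(dx, region, g)]) - e)
            mags.append(abs(e))
    return {
        "sensitivity": tp / max(tp + fn, 1),
        "observed_fdr": fp / max(tp + fp, 1),
        "mean_signed_bias": float(np.mean(errors)) if errors else 0.0,
        "mean_planted_effect": float(np.mean(mags)) if mags else 0.0,
        "de_counts": {f"{dx}/{region}":
                      len(lists["up"]) + len(lists["down"])
                      for (dx, region), lists in sel.items()},
    }


def check_orderings(de_counts: dict) -> dict:
    """Do the recovered DE counts reproduce the planted burden orderings?"""
    n = {tuple(k.split("/")): v for k, v in de_counts.items()}
    dx_ok = all(n[("SCZ", r)] > n[("BD", r)] > n[("MDD", r)]
                for r in REGION_ORDER)
    reg_ok = (n[("SCZ", "HIP")] > n[("SCZ", "STR")] > n[("SCZ", "DLPFC")])
    return {"diagnosis_ordering": bool(dx_ok),
            "region_ordering": bool(reg_ok)}


def run_ordering_experiment(seed: int, n_repeats: int = 10) -> dict:
    """Replicate DE-burden ordering recovery across simulation seeds."""
    dx_ok = reg_ok = 0
    per_seed = []
    for k in range(n_repeats):
        s = _derive_seed(seed, k)
        studies, truth = simulate_study(SimulationConfig(seed=s))
        contr = de.run_differential_expression(studies)
        rec = score_de_recovery(truth, contr)
        orders = check_orderings(rec["de_counts"])
        dx_ok += orders["diagnosis_ordering"]
        reg_ok += orders["region_ordering"]
        per_seed.append({**orders, **rec})
    return {
        "n_repeats": n_repeats,
        "diagnosis_ordering_fraction": dx_ok / n_repeats,
        "region_ordering_fraction": reg_ok / n_repeats,
        "per_seed": per_seed,
    }


def planted_module_ari(truth: SyntheticTruth, labels) -> dict:
    """Adjusted Rand index between recovered and planted module labels,
    over genes planted in a module and assigned by the network
    (unassigned excluded)."""
    planted = truth.module_membership
    mask = (planted != "") & (labels > 0)
    if mask.sum() == 0:
        return {"ari": 0.0, "n_scored": 0}
    ari = float(adjusted_rand_score(planted[mask], labels[mask]))
    return {"ari": ari, "n_scored": int(mask.sum()),
            "n_planted": int((planted != "").sum())}


def scz_module_report(studies: dict, truth: SyntheticTruth,
                      result: cn.ConsensusNetworkResult,
                      contrasts) -> dict:
    """Score the planted SCZ-up (inflammation-like) module end to end.

    Reports the best-Jaccard recovered module, its ME-SCZ correlation with
    FDR, its DE-gene Fisher enrichment, and its directional net enrichment
    score in every region.
    """
    planted_sets = truth.module_gene_sets()
    scz_name = next(name for name, tl in truth.trait_loadings.items()
                    if tl is not None and tl[0] == "SCZ")
    planted = set(planted_sets[scz_name])
    labels = result.labels

    best_j, best_m = 0.0, None
    for m in result.solution.module_ids:
        mem = set(result.solution.module_genes(m))
        j = len(planted & mem) / len(planted | mem)
        if j > best_j:
            best_j, best_m = j, m

    meta = combined_sample_table(studies)
    traits = cn.trait_matrix(meta)
    regions = meta.df.set_index("sample_id")["region"]
    tstats = cn.module_trait_stats(result.solution, traits, groups=regions)
    rows = tstats[(tstats["module"] == best_m)
                  & (tstats["trait"] == "SCZ")]

    sel = de.select_de_genes(contrasts)
    universe = next(iter(studies.values())).gene_ids
    enr = cn.module_de_enrichment(result.solution, sel, universe)
    enr_scz = enr[(enr["module"] == best_m) & (enr["diagnosis"] == "SCZ")]

    genes = list(next(iter(studies.values())).gene_ids)
    module_set = result.solution.module_genes(best_m)
    net_scores = {}
    for region in studies:
        lists = sel[("SCZ", region)]
        _, _, net = pe.directional_scores(lists["up"], lists["down"],
                                          module_set, genes)
        net_scores[region] = float(net)
    return {
        "module": best_m,
        "jaccard": best_j,
        # conservative over regions: weakest correlation, largest FDR p
        "me_scz_r": float(rows["r"].min()),
        "me_scz_p_adj": float(rows["p_adj"].max()),
        "de_enrichment_p_max": float(enr_scz["p"].max()),
        "net_scores": net_scores,
        "net_score_min": min(net_scores.values()),
    }


def run_structure_recovery(seed: int, n_repeats: int = 10) -> dict:
    """Replicate consensus-module recovery (ARI) across seeds, plus the
    full SCZ-module report at the first derived seed."""
    aris = []
    first = None
    for k in range(n_repeats):
        s = _derive_seed(seed, k)
        studies, truth = simulate_study(SimulationConfig(seed=s))
        result = cn.build_consensus_network(studies, seed=s)
        aris.append(planted_module_ari(truth, result.labels)["ari"])
        if k == 0:
            contr = de.run_differential_expression(studies)
            first = scz_module_report(studies, truth, result, contr)
            first["n_modules"] = len(result.solution.module_ids)
    return {
        "n_repeats": n_repeats,
        "aris": aris,
        "ari_pass_fraction": float(np.mean([a >= 0.8 for a in aris])),
        "scz_module": first,
    }


def run_decoy_calibration(seed: int, n_sets: int = 200) -> dict:
    """Null decoy gene sets vs a real DE condition: enrichment p-values are
    conservative (stochastically >= uniform)."""
    studies, truth = simulate_study(SimulationConfig(seed=seed))
    contr = de.run_differential_expression(studies)
    sel = de.select_de_genes(contr)
    genes = next(iter(studies.values())).gene_ids
    decoys = decoy_gene_sets(truth, genes, n_sets=n_sets, size=50, seed=seed)
    coll = GeneSetCollection(decoys)
    lists = sel[("SCZ", "HIP")]
    res = pe.enrich_collection(coll, lists["up"], lists["down"], genes)
    p = res["p_enrich"].to_numpy()
    return {
        "n_sets": n_sets,
        "frac_below_0.05": float((p < 0.05).mean()),
        "mean_p": float(p.mean()),
    }
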