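"""Tetrad-matched multi-region expression simulator with planted structure.

The generator emulates the study design the pipeline targets: T matched
tetrads (one CTRL, SCZ, BD and MDD subject each, matched for sex and
approximately age), each subject profiled in three brain regions (DLPFC, HIP,
STR).  On the log10 scale, expression is

    y_gs = baseline_g + tetrad_gt + diagnosis effect + covariate effects
           + sum_m lambda_gm * f_ms + eps,   eps ~ N(0, residual_sd)

* Differential expression is planted per (diagnosis, region) as a fraction of
  genes with signed log10 shifts; defaults grade the burden SCZ >> BD > MDD
  and, within SCZ, HIP > STR > DLPFC.
* Co-expression modules enter as rank-one factors: a per-subject score f_ms
  (shared across regions, so consensus structure exists) times a positive
  per-gene loading; the score mean is shifted for the associated diagnosis so
  the module eigengene correlates with that trait.  The target within-module
  correlation c fixes the loading scale via lambda = sd * sqrt(c / (1 - c)).
* Covariates (age, sex, tobacco, manner of death, PMI, pH) get small nonzero
  per-gene coefficients, the confounder structure the ANCOVA must absorb.

Randomness uses one named counter-based stream per ingredient derived from a
single seed, so e.g. adding genes does not reshuffle subject covariates.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .data_model import (
    DIAGNOSES,
    MANNER_LEVELS,
    REGIONS,
    ExpressionStudy,
    GeneSetCollection,
    SampleTable,
    write_expression_matrix,
    write_gmt,
    write_sample_table,
)

_STREAMS = {
    "covariates": 0,
    "baseline": 1,
    "gene_covariate_coefs": 2,
    "de_effects": 3,
    "modules": 4,
    "tetrad_effects": 5,
    "noise": 6,
    "decoys": 7,
}


def _rng(seed: int, stream: str, *extra: int) -> np.random.Generator:
    key = (_STREAMS[stream], *extra)
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=key))


@dataclass(frozen=True)
class ModuleSpec:
    """One planted co-expression module (a rank-one factor)."""

    name: str
    size: int
    cor: float                    # target within-module Pearson correlation
    diagnosis: str | None = None  # trait the factor score is shifted for
    assoc: float = 0.0            # shift of the factor score, in score SDs
    direction: str = "up"         # 'up': associated diagnosis raises the ME

    def signed_assoc(self) -> float:
        return self.assoc if self.direction == "up" else -self.assoc


@dataclass(frozen=True)
class EffectSpec:
    """Planted DE burden for one (diagnosis, region) cell."""

    fraction: float       # fraction of genes shifted
    mean_effect: float    # mean |log10 effect|; magnitudes ~ U(0.6, 1.4) * mean


def default_de_plan() -> dict:
    """Graded burden: SCZ >> BD > MDD; within SCZ, HIP > STR > DLPFC."""
    return {
        "SCZ": {"HIP": EffectSpec(0.09, 0.18),
                "STR": EffectSpec(0.03, 0.16),
                "DLPFC": EffectSpec(0.02, 0.15)},
        "BD": {"HIP": EffectSpec(0.012, 0.15),
               "STR": EffectSpec(0.008, 0.15),
               "DLPFC": EffectSpec(0.010, 0.15)},
        "MDD": {"HIP": EffectSpec(0.004, 0.15),
                "STR": EffectSpec(0.003, 0.15),
                "DLPFC": EffectSpec(0.0035, 0.15)},
    }


def default_modules() -> tuple:
    """Five planted modules, sizes 60-300; one inflammation-like module of 122
    genes is up-regulated in SCZ in every region."""
    return (
        ModuleSpec("M1", 300, 0.55),
        ModuleSpec("M2", 200, 0.55),
        ModuleSpec("M3", 122, 0.60, diagnosis="SCZ", assoc=1.5, direction="up"),
        ModuleSpec("M4", 80, 0.60),
        ModuleSpec("M5", 60, 0.65),
    )


@dataclass(frozen=True)
class SimulationConfig:
    n_tetrads: int = 19
    n_genes: int = 2000
    regions: tuple = REGIONS
    de_plan: dict = field(default_factory=default_de_plan)
    modules: tuple = field(default_factory=default_modules)
    covariate_sd: dict = field(default_factory=lambda: {
        "age": 0.002, "sex": 0.03, "tobacco": 0.03,
        "manner": 0.02, "pmi": 0.003, "ph": 0.05,
    })
    residual_sd: float = 0.10
    tetrad_sd: float = 0.05
    baseline_mean: float = 2.5
    baseline_sd: float = 0.3
    seed: int = 0

    def validate(self) -> None:
        if self.n_tetrads < 2:
            raise ValueError("n_tetrads must be >= 2")
        if self.residual_sd <= 0:
            raise ValueError("residual_sd must be > 0")
        for dx, per_region in self.de_plan.items():
            if dx not in DIAGNOSES or dx == "CTRL":
                raise ValueError(f"de_plan diagnosis {dx!r} invalid")
            for region, spec in per_region.items():
                if region not in self.regions:
                    raise ValueError(f"de_plan region {region!r} not simulated")
                if not 0.0 <= spec.fraction <= 1.0:
                    raise ValueError(
                        f"de_plan fraction {spec.fraction} for ({dx},{region}) "
                        "outside [0,1]")
        if sum(m.size for m in self.modules) > self.n_genes:
            raise ValueError("module sizes sum to more than n_genes")
        for m in self.modules:
            if not 0.0 <= m.cor < 1.0:
                raise ValueError(f"module {m.name}: correlation must be in [0,1)")
            if m.direction not in ("up", "down"):
                raise ValueError(f"module {m.name}: direction must be up/down")


def null_config(**overrides) -> SimulationConfig:
    """A pure-noise configuration: no planted DE, no planted modules."""
    return replace(SimulationConfig(), de_plan={}, modules=(), **overrides)


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth for scoring recovery.

    ``de_genes`` holds every gene whose mean truly differs between a disease
    group and control, including genes shifted through a trait-associated
    module factor; ``plan_de_genes`` holds only the genes given independent
    per-gene effects (the right reference for estimator-bias checks, since
    module genes share one factor realisation).
    """

    de_genes: dict               # (diagnosis, region) -> {gene: signed log10 effect}
    plan_de_genes: dict          # same, independent per-gene effects only
    module_membership: pd.Series  # gene -> module name ('' = none)
    trait_loadings: dict         # module name -> (diagnosis, direction) or None
    module_loadings: dict        # module name -> pd.Series gene -> loading

    def module_gene_sets(self) -> dict:
        out: dict = {}
        for gene, label in self.module_membership.items():
            if label:
                out.setdefault(label, []).append(gene)
        return out


def _simulate_subjects(config: SimulationConfig) -> pd.DataFrame:
    rng = _rng(config.seed, "covariates")
    rows = []
    for t in range(1, config.n_tetrads + 1):
        age_base = rng.uniform(25.0, 70.0)
        sex = "F" if rng.random() < 0.5 else "M"   # matched within tetrad
        for dx in DIAGNOSES:
            rows.append({
                "subject_id": f"S{t:02d}{dx}",
                "tetrad_id": t,
                "diagnosis": dx,
                "age": float(np.clip(age_base + rng.normal(0.0, 2.0), 18, 90)),
                "sex": sex,
                "tobacco": "yes" if rng.random() < 0.4 else "no",
                "manner_of_death": MANNER_LEVELS[
                    rng.choice(3, p=[0.2, 0.6, 0.2])],
                "pmi": float(rng.uniform(5.0, 25.0)),
                "ph": float(np.clip(rng.normal(6.8, 0.25), 6.0, 7.4)),
            })
    return pd.DataFrame(rows)


def _plant_de(config: SimulationConfig, genes: list, module_genes: set) -> dict:
    rng = _rng(config.seed, "de_effects")
    free = np.array([g for g in genes if g not in module_genes])
    de: dict = {}
    for dx in sorted(config.de_plan):
        for region in config.regions:
            spec = config.de_plan[dx].get(region)
            if spec is None or spec.fraction == 0.0:
                continue
            n = int(round(spec.fraction * config.n_genes))
            n = min(n, len(free))
            chosen = rng.choice(free, size=n, replace=False)
            signs = rng.choice([-1.0, 1.0], size=n)
            mags = rng.uniform(0.6, 1.4, size=n) * spec.mean_effect
            de[(dx, region)] = dict(zip(chosen.tolist(), (signs * mags).tolist()))
    return de


def simulate_study(config: SimulationConfig):
    """Generate per-region :class:`ExpressionStudy` objects plus ground truth.

    Returns ``(studies, truth)`` where ``studies`` maps region -> study.
    Deterministic given ``config`` (including its seed).
    """
    config.validate()
    genes = [f"G{i:05d}" for i in range(1, config.n_genes + 1)]

    subjects = _simulate_subjects(config)
    n_subj = len(subjects)

    rng_base = _rng(config.seed, "baseline")
    baseline = rng_base.normal(config.baseline_mean, config.baseline_sd,
                               config.n_genes)

    # per-gene covariate coefficients (small, nonzero nuisance effects)
    rng_cov = _rng(config.seed, "gene_covariate_coefs")
    sd = config.covariate_sd
    coef = {
        "age": rng_cov.normal(0, sd["age"], config.n_genes),
        "sex": rng_cov.normal(0, sd["sex"], config.n_genes),
        "tobacco": rng_cov.normal(0, sd["tobacco"], config.n_genes),
        "manner_natural": rng_cov.normal(0, sd["manner"], config.n_genes),
        "manner_suicide": rng_cov.normal(0, sd["manner"], config.n_genes),
        "pmi": rng_cov.normal(0, sd["pmi"], config.n_genes),
        "ph": rng_cov.normal(0, sd["ph"], config.n_genes),
    }

    # planted modules: leading index blocks, rank-one factors
    rng_mod = _rng(config.seed, "modules")
    membership = pd.Series([""] * config.n_genes, index=genes, dtype=object)
    module_loadings: dict = {}
    trait_loadings: dict = {}
    factor_scores: dict = {}
    pos = 0
    for m in config.modules:
        idx = list(range(pos, pos + m.size))
        pos += m.size
        lam_base = config.residual_sd * np.sqrt(m.cor / (1.0 - m.cor))
        lams = lam_base * rng_mod.uniform(0.8, 1.2, m.size)
        scores = rng_mod.normal(0.0, 1.0, n_subj)
        if m.diagnosis is not None and m.assoc:
            scores = scores + m.signed_assoc() * (
                subjects["diagnosis"].to_numpy() == m.diagnosis)
        membership.iloc[idx] = m.name
        module_loadings[m.name] = pd.Series(lams, index=[genes[i] for i in idx])
        trait_loadings[m.name] = ((m.diagnosis, m.direction)
                                  if m.diagnosis is not None and m.assoc else None)
        factor_scores[m.name] = scores

    module_genes = set(membership.index[membership != ""])
    plan_de = _plant_de(config, genes, module_genes)
    # module factors shift the associated diagnosis: those genes are DE too
    de_genes = {k: dict(v) for k, v in plan_de.items()}
    for m in config.modules:
        if m.diagnosis is None or not m.assoc:
            continue
        shift = m.signed_assoc() * module_loadings[m.name]
        for region in config.regions:
            cell = de_genes.setdefault((m.diagnosis, region), {})
            cell.update(shift.to_dict())

    truth = SyntheticTruth(de_genes=de_genes, plan_de_genes=plan_de,
                           module_membership=membership,
                           trait_loadings=trait_loadings,
                           module_loadings=module_loadings)

    diag_arr = subjects["diagnosis"].to_numpy()
    tetrad_arr = subjects["tetrad_id"].to_numpy()
    gene_pos = {g: i for i, g in enumerate(genes)}

    studies: dict = {}
    for r_i, region in enumerate(config.regions):
        rng_tet = _rng(config.seed, "tetrad_effects", r_i)
        rng_noise = _rng(config.seed, "noise", r_i)

        meta = subjects.copy()
        meta["region"] = region
        meta["sample_id"] = meta["subject_id"] + "." + region

        y = np.tile(baseline[:, None], (1, n_subj))
        tet_eff = rng_tet.normal(0.0, config.tetrad_sd,
                                 (config.n_genes, config.n_tetrads))
        y += tet_eff[:, tetrad_arr - 1]

        y += coef["age"][:, None] * (meta["age"].to_numpy() - 45.0)[None, :]
        y += coef["sex"][:, None] * (meta["sex"] == "F").to_numpy()[None, :]
        y += coef["tobacco"][:, None] * (meta["tobacco"] == "yes").to_numpy()[None, :]
        y += coef["manner_natural"][:, None] * (
            meta["manner_of_death"] == "natural").to_numpy()[None, :]
        y += coef["manner_suicide"][:, None] * (
            meta["manner_of_death"] == "suicide").to_numpy()[None, :]
        y += coef["pmi"][:, None] * (meta["pmi"].to_numpy() - 15.0)[None, :]
        y += coef["ph"][:, None] * (meta["ph"].to_numpy() - 6.8)[None, :]

        for (dx, reg), effects in de_genes.items():
            if reg != region:
                continue
            mask = diag_arr == dx
            for g, eff in effects.items():
                if g in module_genes:
                    continue  # module genes shift through their factor below
                y[gene_pos[g], mask] += eff

        for m in config.modules:
            lams = module_loadings[m.name]
            rows = [gene_pos[g] for g in lams.index]
            y[rows, :] += lams.to_numpy()[:, None] * factor_scores[m.name][None, :]

        y += rng_noise.normal(0.0, config.residual_sd, y.shape)

        expr = pd.DataFrame(y, index=genes, columns=meta["sample_id"])
        studies[region] = ExpressionStudy(expr, SampleTable(meta))
    return studies, truth


def combined_sample_table(studies: dict) -> SampleTable:
    dfs = [studies[r].metadata.df for r in studies]
    return SampleTable(pd.concat(dfs, ignore_index=True))


def decoy_gene_sets(truth: SyntheticTruth, genes, n_sets: int = 20,
                    size: int = 50, seed: int = 0) -> dict:
    """Random decoy sets drawn without replacement from non-module genes."""
    rng = _rng(seed, "decoys")
    module_genes = set(truth.module_membership.index[truth.module_membership != ""])
    free = np.array([g for g in genes if g not in module_genes])
    return {
        f"decoy_{i:02d}": rng.choice(free, size=min(size, len(free)),
                                     replace=False).tolist()
        for i in range(1, n_sets + 1)
    }


def emit_fixture(studies: dict, truth: SyntheticTruth, out_dir,
                 n_decoy_sets: int = 20, decoy_size: int = 50,
                 seed: int = 0) -> dict:
    """Write the TSV/GMT files every downstream module consumes.

    Emits one expression TSV per region, a combined sample metadata TSV, and a
    GMT with the planted modules (named ``planted_<module>``) plus random
    decoy sets.  Byte-identical across re-runs with identical inputs.
    """
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    for region, study in studies.items():
        p = out / f"expr_{region}.tsv"
        write_expression_matrix(study.expr, p)
        paths[f"expr_{region}"] = p
    meta_path = out / "samples.tsv"
    write_sample_table(combined_sample_table(studies), meta_path)
    paths["samples"] = meta_path

    genes = next(iter(studies.values())).gene_ids
    sets = {f"planted_{name}": members
            for name, members in sorted(truth.module_gene_sets().items())}
    sets.update(decoy_gene_sets(truth, genes, n_decoy_sets, decoy_size, seed))
    gmt_path = out / "gene_sets.gmt"
    write_gmt(GeneSetCollection(sets), gmt_path)
    paths["gene_sets"] = gmt_path
    return paths
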