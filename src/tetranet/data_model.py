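"""Core containers and text readers/writers for the pipeline.

Every analysis step consumes one of three plain-text inputs: a log10-scale
expression matrix (genes x samples, TSV), a sample metadata table (one row per
sample = subject x region, TSV), and gene sets (GMT).  Values must be complete
and finite at this layer; real-data users pre-impute upstream.  Gene and sample
identifiers are opaque strings -- no probe/symbol mapping is attempted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

REGIONS = ("DLPFC", "HIP", "STR")
DIAGNOSES = ("CTRL", "SCZ", "BD", "MDD")
DISEASE_DIAGNOSES = ("SCZ", "BD", "MDD")
SEX_LEVELS = ("M", "F")
TOBACCO_LEVELS = ("yes", "no")
MANNER_LEVELS = ("accidental", "natural", "suicide")

SAMPLE_COLUMNS = [
    "sample_id",
    "subject_id",
    "tetrad_id",
    "region",
    "diagnosis",
    "age",
    "sex",
    "tobacco",
    "manner_of_death",
    "pmi",
    "ph",
]

_CATEGORICAL_LEVELS = {
    "region": REGIONS,
    "diagnosis": DIAGNOSES,
    "sex": SEX_LEVELS,
    "tobacco": TOBACCO_LEVELS,
    "manner_of_death": MANNER_LEVELS,
}

_NUMERIC_SAMPLE_COLUMNS = ("age", "pmi", "ph")
# covariates that must be identical for the same subject across regions
_SUBJECT_CONSTANT = ("tetrad_id", "diagnosis", "age", "sex", "tobacco",
                     "manner_of_death", "pmi", "ph")


def _check_unique(values, what: str) -> None:
    values = pd.Index(values)
    if values.has_duplicates:
        dup = values[values.duplicated()][0]
        raise ValueError(f"duplicate {what}: {dup!r}")


@dataclass(frozen=True)
class SampleTable:
    """Validated per-sample metadata; one row per (subject, region)."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.df
        missing = [c for c in SAMPLE_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"sample table missing columns: {missing}")
        _check_unique(df["sample_id"], "sample_id")
        for col, levels in _CATEGORICAL_LEVELS.items():
            bad = set(df[col]) - set(levels)
            if bad:
                raise ValueError(
                    f"unknown {col} level(s) {sorted(bad)}; allowed: {list(levels)}"
                )
        for col in _NUMERIC_SAMPLE_COLUMNS:
            vals = pd.to_numeric(df[col], errors="coerce")
            if vals.isna().any():
                bad_row = df.index[vals.isna()][0]
                raise ValueError(f"non-numeric value in column {col!r}, row {bad_row}")
        # tetrad = matched quartet: at most one subject per diagnosis per tetrad
        per_subject = df.drop_duplicates("subject_id")
        counts = per_subject.groupby(["tetrad_id", "diagnosis"]).size()
        if (counts > 1).any():
            tid, dx = counts[counts > 1].index[0]
            raise ValueError(
                f"tetrad {tid!r} has more than one subject with diagnosis {dx!r}"
            )
        # the same subject carries identical covariates across regions
        for col in _SUBJECT_CONSTANT:
            nun = df.groupby("subject_id")[col].nunique()
            if (nun > 1).any():
                subj = nun.index[nun > 1][0]
                raise ValueError(
                    f"subject {subj!r} has inconsistent {col!r} across regions"
                )
        object.__setattr__(self, "df", df.reset_index(drop=True))

    @property
    def sample_ids(self) -> list[str]:
        return list(self.df["sample_id"])

    def subset(self, sample_ids) -> "SampleTable":
        sub = self.df.set_index("sample_id").loc[list(sample_ids)].reset_index()
        return SampleTable(sub)

    def for_region(self, region: str) -> "SampleTable":
        if region not in REGIONS:
            raise ValueError(f"unknown region {region!r}; allowed: {list(REGIONS)}")
        return SampleTable(self.df[self.df["region"] == region].copy())

    def __len__(self) -> int:
        return len(self.df)


@dataclass(frozen=True)
class ExpressionStudy:
    """A log10-scale expression matrix bound to its sample metadata.

    ``expr`` is genes x samples; columns must match the metadata sample_ids
    exactly (same set, one metadata row each).  Values must be finite.
    """

    expr: pd.DataFrame
    metadata: SampleTable

    def __post_init__(self) -> None:
        _check_unique(self.expr.index, "gene id")
        _check_unique(self.expr.columns, "sample id")
        vals = self.expr.to_numpy()
        if not np.issubdtype(vals.dtype, np.number):
            raise ValueError("expression matrix contains non-numeric values")
        if not np.isfinite(vals).all():
            i, j = np.argwhere(~np.isfinite(vals))[0]
            raise ValueError(
                f"non-finite expression value at gene {self.expr.index[i]!r}, "
                f"sample {self.expr.columns[j]!r}"
            )
        meta_ids = set(self.metadata.sample_ids)
        expr_ids = set(self.expr.columns)
        if meta_ids != expr_ids:
            raise ValueError(
                "expression columns and metadata sample_ids differ: "
                f"{sorted(expr_ids ^ meta_ids)[:5]} ..."
            )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.expr.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.expr.columns)

    @property
    def n_genes(self) -> int:
        return self.expr.shape[0]

    @property
    def n_samples(self) -> int:
        return self.expr.shape[1]


@dataclass(frozen=True)
class GeneSetCollection:
    """Named gene sets (the pathway surrogate) with an optional background."""

    sets: dict
    universe: list | None = None

    def __post_init__(self) -> None:
        clean = {}
        for name, members in self.sets.items():
            uniq = list(dict.fromkeys(members))
            if len(uniq) < len(members):
                logger.info("gene set %s: %d duplicate member(s) dropped",
                            name, len(members) - len(uniq))
            clean[name] = uniq
        object.__setattr__(self, "sets", clean)

    def restricted_to(self, universe) -> "GeneSetCollection":
        uni = set(universe)
        sets = {n: [g for g in m if g in uni] for n, m in self.sets.items()}
        return GeneSetCollection(sets, universe=sorted(uni))

    def __len__(self) -> int:
        return len(self.sets)


# ---------------------------------------------------------------------------
# readers / writers (all plain TSV / GMT text)
# ---------------------------------------------------------------------------

def read_expression_matrix(path) -> pd.DataFrame:
    """Read a genes-x-samples TSV (first column gene ids, header sample ids)."""
    df = pd.read_csv(path, sep="\t", index_col=0, dtype={0: str},
                     float_precision="round_trip")
    _check_unique(df.index, "gene id")
    _check_unique(df.columns, "sample id")
    for col in df.columns:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() & df[col].notna()
        if bad.any() or df[col].isna().any():
            row = df.index[(bad | df[col].isna())][0]
            raise ValueError(
                f"non-numeric expression value at gene {row!r}, sample {col!r}"
            )
        df[col] = vals
    return df


def write_expression_matrix(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index_label="gene_id", float_format="%.17g")


def read_sample_table(path) -> SampleTable:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "subject_id": str},
                     float_precision="round_trip")
    return SampleTable(df)


def write_sample_table(table: SampleTable, path) -> None:
    table.df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_gmt(path) -> GeneSetCollection:
    """Read gene sets in GMT dialect: name <tab> description <tab> members..."""
    sets: dict = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}: line {lineno} has {len(fields)} field(s); "
                    "GMT requires name, description and >=1 member"
                )
            name = fields[0]
            if name in sets:
                raise ValueError(f"{path}: duplicate gene set name {name!r}")
            sets[name] = [g for g in fields[2:] if g]
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, members in collection.sets.items():
            fh.write("\t".join([name, description, *members]) + "\n")


def make_contrast_table(rows) -> pd.DataFrame:
    """Assemble per-(gene, region, diagnosis) contrast rows into a table.

    Expects records with gene/region/diagnosis/estimate/se/df/p_raw/p_adj and
    derives fold_change = 10^|estimate| (>= 1 by construction), direction from
    the sign of the estimate, and the >1.2-fold & FDR<0.05 significance flag.
    """
    df = pd.DataFrame(rows)
    est = df["estimate"].to_numpy(float)
    df["fold_change"] = np.power(10.0, np.abs(est))
    df["direction"] = np.where(est >= 0, "up", "down")
    df["significant"] = (df["fold_change"] > 1.2) & (df["p_adj"] < 0.05)
    return df


def write_contrast_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_contrast_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
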