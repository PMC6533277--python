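#!/usr/bin/env python
"""Tetrad-matched mixed-model differential expression per region.

Reads the study files written by 01_simulate_study.py, fits the per-gene
mixed ANCOVA (tetrad random intercept; age, sex, tobacco, manner of death,
PMI and pH covariates), forms disease-vs-control LS-mean contrasts with
BH-FDR per (region x diagnosis), and selects DE genes at >1.2-fold and
FDR < 0.05.  Writes the full contrast table and the DE count summary.
"""

import argparse
from pathlib import Path

import pandas as pd

from tetranet.data_model import (
    ExpressionStudy,
    REGIONS,
    read_expression_matrix,
    read_sample_table,
    write_contrast_table,
)
from tetranet.differential_expression import (
    run_differential_expression,
    select_de_genes,
)


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--fixture", type=Path, default=Path("results/fixture"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    meta = read_sample_table(args.fixture / "samples.tsv")
    studies = {
        region: ExpressionStudy(
            read_expression_matrix(args.fixture / f"expr_{region}.tsv"),
            meta.for_region(region))
        for region in REGIONS
    }
    contrasts = run_differential_expression(studies)
    args.out.mkdir(parents=True, exist_ok=True)
    write_contrast_table(contrasts, args.out / "contrasts.tsv")

    sel = select_de_genes(contrasts)
    counts = pd.DataFrame(
        [{"diagnosis": dx, "region": region,
          "n_up": len(v["up"]), "n_down": len(v["down"]),
          "n_total": len(v["up"]) + len(v["down"])}
         for (dx, region), v in sorted(sel.items())])
    counts.to_csv(args.out / "de_counts.tsv", sep="\t", index=False)

    print("DE genes (>1.2-fold, FDR < 0.05) per condition:")
    print(counts.pivot(index="region", columns="diagnosis",
                       values="n_total").to_string())
    for (dx, region), v in sorted(sel.items()):
        path = args.out / f"de_{dx}_{region}.tsv"
        pd.DataFrame({
            "gene": v["up"] + v["down"],
            "direction": ["up"] * len(v["up"]) + ["down"] * len(v["down"]),
        }).to_csv(path, sep="\t", index=False)
    print(f"wrote {args.out}/contrasts.tsv, de_counts.tsv and per-condition "
          "gene lists")


if __name__ == "__main__":
    main()
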