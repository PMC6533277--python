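#!/usr/bin/env python
"""Signed consensus co-expression network across the three regions.

Builds the consensus WGCNA (power 12, four pre-clustered blocks, quantile-
scaled minimum consensus TOM, dynamic hybrid tree cut at minimum module
size 50 / deepSplit 4, eigengene-based refinement and 0.15 ME merging),
then correlates module eigengenes with diagnosis indicators and covariates
and tests DE-gene enrichment within each module.  Writes labels, MEs, kME,
module-trait statistics and module DE enrichment.
"""

import argparse
from pathlib import Path

import pandas as pd

from tetranet.consensus_network import (
    NetworkConfig,
    build_consensus_network,
    module_de_enrichment,
    module_trait_stats,
    trait_matrix,
)
from tetranet.data_model import (
    ExpressionStudy,
    REGIONS,
    read_contrast_table,
    read_expression_matrix,
    read_sample_table,
)
from tetranet.differential_expression import select_de_genes


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--fixture", type=Path, default=Path("results/fixture"))
    ap.add_argument("--contrasts", type=Path,
                    default=Path("results/contrasts.tsv"))
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results/network"))
    args = ap.parse_args()

    meta = read_sample_table(args.fixture / "samples.tsv")
    studies = {
        region: ExpressionStudy(
            read_expression_matrix(args.fixture / f"expr_{region}.tsv"),
            meta.for_region(region))
        for region in REGIONS
    }
    result = build_consensus_network(studies, NetworkConfig(), seed=args.seed)
    sol = result.solution

    args.out.mkdir(parents=True, exist_ok=True)
    pd.DataFrame({"gene": sol.labels.index, "block": result.blocks.values,
                  "module": sol.labels.values}) \
        .to_csv(args.out / "labels.tsv", sep="\t", index=False)
    sol.mes.to_csv(args.out / "eigengenes.tsv", sep="\t",
                   index_label="sample_id")
    sol.kme.to_csv(args.out / "kme.tsv", sep="\t", index_label="gene")

    traits = trait_matrix(meta)
    regions = meta.df.set_index("sample_id")["region"]
    tstats = module_trait_stats(sol, traits, groups=regions)
    tstats.to_csv(args.out / "module_trait_stats.tsv", sep="\t", index=False)

    contrasts = read_contrast_table(args.contrasts)
    sel = select_de_genes(contrasts)
    universe = list(sol.labels.index)
    enr = module_de_enrichment(sol, sel, universe)
    enr.to_csv(args.out / "module_de_enrichment.tsv", sep="\t", index=False)

    sizes = sol.labels[sol.labels > 0].value_counts().sort_index()
    print(f"consensus modules: {len(sizes)} "
          f"(sizes {sizes.min()}-{sizes.max()}); "
          f"{int((sol.labels == 0).sum())} genes unassigned")
    scz = tstats[tstats["trait"] == "SCZ"]
    for m, size in sizes.items():
        sub = scz[scz["module"] == m]
        per_region = "  ".join(
            f"{g}: r={r:+.2f}{'*' if p < 0.05 else ' '}"
            for g, r, p in zip(sub["group"], sub["r"], sub["p_adj"]))
        print(f"  module {m}: {size:4d} genes | ME-SCZ {per_region}")
    print(f"wrote module tables under {args.out}/")


if __name__ == "__main__":
    main()
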