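"""Fisher's-exact gene-set enrichment with directional net scores.

Enrichment of a DE list in a gene set is the one-sided (over-representation)
hypergeometric tail over a declared background universe.  Directional scoring
re-tests the up- and down-regulated lists separately and reports

    net_score = -log10(p_up) - ( -log10(p_down) )

so a set driven by up-regulated genes scores net positive, one driven by
down-regulated genes net negative, and a balanced set sits near zero.
Cross-disorder comparison asks whether the *sets of enriched pathways* of two
conditions overlap more than chance, again by one-sided Fisher's exact over
all tested pathways.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import GeneSetCollection

ENRICH_ALPHA = 0.05


def fisher_enrichment(de_genes, gene_set, universe):
    """One-sided over-representation test.

    Both the DE list and the gene set are intersected with the universe
    before testing.  Returns ``(overlap, p)`` with p the upper hypergeometric
    tail P[X >= overlap].
    """
    uni = set(universe)
    if not uni:
        raise ValueError("empty universe")
    de = set(de_genes) & uni
    members = set(gene_set) & uni
    overlap = len(de & members)
    p = float(stats.hypergeom.sf(overlap - 1, len(uni), len(members), len(de)))
    return overlap, min(max(p, np.nextafter(0, 1)), 1.0)


def directional_scores(up, down, gene_set, universe):
    """Separate up/down enrichment scores and their signed difference."""
    up, down = set(up), set(down)
    if up & down:
        raise ValueError(f"gene(s) in both up and down lists: "
                         f"{sorted(up & down)[:5]}")
    _, p_up = fisher_enrichment(up, gene_set, universe)
    _, p_down = fisher_enrichment(down, gene_set, universe)
    score_up = -np.log10(p_up)
    score_down = -np.log10(p_down)
    return score_up, score_down, score_up - score_down


def enriched_pathway_overlap(enriched_a, enriched_b, all_tested):
    """Fisher's exact test for overlap of two enriched-pathway sets.

    2x2 table of membership in A x membership in B over every tested
    pathway; one-sided toward over-enrichment of the overlap.
    """
    tested = set(all_tested)
    if not tested:
        raise ValueError("empty set of tested pathways")
    a, b = set(enriched_a) & tested, set(enriched_b) & tested
    if not set(enriched_a) <= tested or not set(enriched_b) <= tested:
        raise ValueError("enriched pathway outside the tested collection")
    both = len(a & b)
    table = [[both, len(a) - both],
             [len(b) - both, len(tested) - len(a) - len(b) + both]]
    p = float(stats.fisher_exact(table, alternative="greater")[1])
    return both, min(p, 1.0)


def enrich_collection(collection: GeneSetCollection, up, down,
                      universe=None) -> pd.DataFrame:
    """Score every gene set in a collection against one DE condition.

    Returns one row per set with overlap counts, the pooled (up+down)
    enrichment p, the directional scores and the net score.
    """
    if universe is None:
        universe = collection.universe
    if universe is None:
        raise ValueError("a background universe is required")
    uni = set(universe)
    up, down = set(up) & uni, set(down) & uni
    de = up | down
    rows = []
    for name in sorted(collection.sets):
        members = set(collection.sets[name]) & uni
        overlap, p = fisher_enrichment(de, members, uni)
        s_up, s_down, net = directional_scores(up, down, members, uni)
        rows.append({
            "set": name, "set_size": len(members), "de_size": len(de),
            "universe_size": len(uni), "overlap": overlap, "p_enrich": p,
            "score": -np.log10(p), "score_up": s_up, "score_down": s_down,
            "net_score": net, "enriched": p < ENRICH_ALPHA,
        })
    return pd.DataFrame(rows)


def exclude_sets(collection: GeneSetCollection,
                 patterns) -> GeneSetCollection:
    """Drop gene sets whose names match any of the given regex patterns.

    Supports excluding e.g. disease-named pathway categories (which are
    redundant with the core signalling sets they re-package) before
    enrichment testing.
    """
    import re
    compiled = [re.compile(p) for p in patterns]
    keep = {name: members for name, members in collection.sets.items()
            if not any(c.search(name) for c in compiled)}
    return GeneSetCollection(keep, universe=collection.universe)


def enrich_all_conditions(collection: GeneSetCollection, de_lists: dict,
                          universe, exclude_patterns=()) -> pd.DataFrame:
    """Run :func:`enrich_collection` for every (diagnosis, region) DE list.

    ``de_lists`` maps (diagnosis, region) -> {'up': [...], 'down': [...]}
    as produced by ``differential_expression.select_de_genes``;
    ``exclude_patterns`` optionally removes matching set names first.
    """
    if exclude_patterns:
        collection = exclude_sets(collection, exclude_patterns)
    frames = []
    for (dx, region), lists in sorted(de_lists.items()):
        res = enrich_collection(collection, lists["up"], lists["down"],
                                universe)
        res.insert(0, "region", region)
        res.insert(0, "diagnosis", dx)
        frames.append(res)
    return pd.concat(frames, ignore_index=True)


def net_score_matrix(results: pd.DataFrame, reference_condition,
                     top_n: int = 50) -> pd.DataFrame:
    """Pathways x conditions matrix of net enrichment scores.

    Rows are the ``top_n`` pathways ranked by the maximum |net_score| in the
    reference condition -- either one 'DX/REGION' column or, given a bare
    diagnosis, the maximum across that diagnosis's regions -- with ties
    broken lexicographically by set name.  Columns are all conditions
    present, as 'DX/REGION'.
    """
    res = results.copy()
    res["condition"] = res["diagnosis"] + "/" + res["region"]
    ref = "{}/{}".format(*reference_condition) \
        if not isinstance(reference_condition, str) else reference_condition
    wide = res.pivot(index="set", columns="condition", values="net_score")
    if ref in wide.columns:
        key = wide[ref].abs()
    else:
        ref_cols = [c for c in wide.columns if c.startswith(ref + "/")]
        if not ref_cols:
            raise ValueError(f"reference condition {ref!r} not in results")
        key = wide[ref_cols].abs().max(axis=1)
    order = (
        key.to_frame("key").assign(name=wide.index)
        .sort_values(["key", "name"], ascending=[False, True]).index
    )
    if top_n > len(order):
        warnings.warn(f"top_n={top_n} exceeds {len(order)} tested pathways; "
                      "truncating")
        top_n = len(order)
    return wide.loc[order[:top_n]]
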