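"""Two-stage "enrichment of enrichment" immune annotation scoring.

Immunologic signature collections (MSigDB C7-style) are too granular to
read directly, so signatures are grouped into functional categories at
four annotation levels (cell types, cell subsets, activation states,
stimulated myeloid cells). Scoring is two-staged:

1. first stage: ordinary over-representation of the query gene list in
   every signature annotatable at the level, keeping signatures with
   BH-adjusted p <= ``fdr_threshold`` (0.01 throughout);
2. second stage: for each category holding at least one enriched
   signature, a one-sided Fisher test of whether enriched signatures are
   over-represented inside the category, against all signatures tested
   at the level.

The Immune Annotation Score combines both stages::

    score = -log10(median first-stage FDR p over the category's
                   enriched signatures) * -log10(category p)

A category whose signatures just meet the first-stage gate (median FDR
p = 0.01) and whose category-level p is also 0.01 scores exactly 4.0;
because the score is a product of two factors, readings of the
significance boundary range between 2 (one strong factor) and 4 (both
factors at their gate) -- see the package docs.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .datatypes import AnnotationMap, GeneSetCollection
from .diffexpr import benjamini_hochberg
from .enrichment import enrich_collection, fisher_enrichment

logger = logging.getLogger(__name__)

FIRST_STAGE_FDR = 0.01

SCORE_COLUMNS = [
    "level", "category", "n_signatures_in_category", "n_enriched_in_category",
    "signatures_median_fdr_p", "category_p", "category_fdr_p",
    "odds_ratio", "score",
]


def first_stage_enrichment(
    query,
    collection: GeneSetCollection,
    universe,
    fdr_threshold: float = FIRST_STAGE_FDR,
) -> pd.DataFrame:
    """Signature-level ORA; returns the full per-signature table with an
    ``enriched`` flag at the FDR threshold."""
    table = enrich_collection(query, collection, universe)
    table["enriched"] = table["fdr_p"] <= fdr_threshold
    return table


def category_test(category: str, enriched, annotation: AnnotationMap):
    """One-sided Fisher test of enriched-signature over-representation in
    one category.

    The 2x2 table is taken over all signatures annotated at this level:
    rows in-category vs not, columns enriched vs not. Returns
    (p_value, odds_ratio).
    """
    members = annotation.categories().get(category)
    if members is None:
        raise KeyError(f"category {category!r} not present at level {annotation.level}")
    all_sigs = list(annotation.assignments)
    res = fisher_enrichment(
        query=set(enriched),
        target=members,
        universe=all_sigs,
        query_id="enriched_signatures",
        set_name=category,
    )
    return res.p_value, res.odds_ratio


def immune_annotation_score(signatures_median_fdr_p: float, category_p: float) -> float:
    """Product of the negative base-10 logs of the two stage p-values.

    Zero when either p-value is 1; p-values of 0 are clamped at 1e-300
    (with a warning) so the score stays finite.
    """
    vals = []
    for p in (signatures_median_fdr_p, category_p):
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"p-value {p} outside [0, 1]")
        if p == 0.0:
            logger.warning("p-value of 0 clamped to 1e-300 for scoring")
            p = 1e-300
        vals.append(p)
    return float((-np.log10(vals[0])) * (-np.log10(vals[1])))


def run_level(
    query,
    collection: GeneSetCollection,
    annotation: AnnotationMap,
    universe,
    fdr_threshold: float = FIRST_STAGE_FDR,
) -> pd.DataFrame:
    """Full two-stage scoring of one query at one annotation level.

    The collection is restricted to signatures annotatable at the level
    before the first stage; only categories containing at least one
    enriched signature are scored. ``category_fdr_p`` is BH across the
    scored categories and can serve as a standalone category-enrichment
    measure. Rows are sorted by score descending.
    """
    annotatable = [s for s in collection.sets if s in annotation.assignments]
    if not annotatable:
        return pd.DataFrame(columns=SCORE_COLUMNS)
    restricted = collection.restrict(annotatable)
    stage1 = first_stage_enrichment(query, restricted, universe,
                                    fdr_threshold=fdr_threshold)
    enriched = stage1[stage1["enriched"]]
    if enriched.empty:
        return pd.DataFrame(columns=SCORE_COLUMNS)
    enriched_fdr = dict(zip(enriched["set_name"], enriched["fdr_p"]))
    level_map = AnnotationMap(
        level=annotation.level,
        assignments={s: annotation.assignments[s] for s in restricted.sets},
    )
    cat_members = level_map.categories()

    rows = []
    for cat, members in sorted(cat_members.items()):
        hits = [s for s in members if s in enriched_fdr]
        if not hits:
            continue  # only categories with >= 1 enriched signature are reported
        med = float(np.median([enriched_fdr[s] for s in hits]))
        cat_p, orat = category_test(cat, list(enriched_fdr), level_map)
        rows.append(
            {
                "level": annotation.level,
                "category": cat,
                "n_signatures_in_category": len(members),
                "n_enriched_in_category": len(hits),
                "signatures_median_fdr_p": med,
                "category_p": cat_p,
                "category_fdr_p": np.nan,
                "odds_ratio": orat,
                "score": immune_annotation_score(med, cat_p),
            }
        )
    out = pd.DataFrame(rows, columns=SCORE_COLUMNS)
    out["category_fdr_p"] = benjamini_hochberg(out["category_p"].to_numpy())
    return out.sort_values(
        ["score", "category"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
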