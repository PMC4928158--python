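"""Mutation-rate landscape and hotspot sequence-context composition.

Rates are per megabase of coding territory per sample, split by tumor type
and the 20 mutation subtypes. Hotspot composition collapses the subtypes
onto 8 categories (six SNV sequence contexts with the coding classes
concatenated, plus insertion and deletion); a hotspot contributes to every
category observed at its position, so per-tumor-type fractions may sum to
more than 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd
from scipy import stats

from .detection import HotspotCall
from .model import CohortDataset
from .subtypes import ALL_SUBTYPES, CATEGORIES, classify_record, subtype_category


@dataclass
class CompositionMatrix:
    """Per-tumor-type hotspot category composition.

    ``fractions`` and ``counts`` are tumor_type x 8-category frames;
    ``n_hotspots`` the per-type denominators.
    """

    fractions: pd.DataFrame
    counts: pd.DataFrame
    n_hotspots: dict[str, int]


def rate_matrix(dataset: CohortDataset, territory_mb: float = 30.0) -> pd.DataFrame:
    """Tumor-type x subtype mutation rates (mutations / Mb / sample).

    ``territory_mb`` is the coding territory surveyed per sample (default
    30 Mb, a whole-exome scale). Tumor types with zero non-excluded samples
    are omitted with a warning.
    """
    if territory_mb <= 0:
        raise ValueError("territory_mb must be positive")
    subtype_cols = [s.value for s in ALL_SUBTYPES]
    rows = {}
    for t in dataset.tumor_types:
        n = len(dataset.samples_of_type(t))
        if n == 0:
            warnings.warn(f"tumor type {t!r} has no samples after filtering; omitted")
            continue
        counts = dict.fromkeys(subtype_cols, 0)
        for r in dataset.records_of_type(t):
            code = classify_record(r)
            if code is not None:
                counts[code.value] += 1
        rows[t] = {s: c / (n * territory_mb) for s, c in counts.items()}
    out = pd.DataFrame.from_dict(rows, orient="index", columns=subtype_cols)
    out.index.name = "tumor_type"
    return out.sort_index()


def kruskal_heterogeneity(groups: list[list[float]]) -> float:
    """Kruskal-Wallis p-value for rate heterogeneity across groups.

    Tie-corrected. All-tied data (zero rank variance) is defined as p = 1
    with a warning rather than NA.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if any(len(g) < 1 for g in groups):
        raise ValueError("every group needs at least one observation")
    flat = [v for g in groups for v in g]
    if len(set(flat)) == 1:
        warnings.warn("all observations tied; Kruskal-Wallis p defined as 1")
        return 1.0
    return float(stats.kruskal(*groups).pvalue)


def hotspot_composition(
    calls: list[HotspotCall], dataset: CohortDataset
) -> CompositionMatrix:
    """Which sequence-context categories each tumor type's hotspots carry.

    A hotspot counts toward category c iff at least one mutation of that
    category is observed at its amino-acid position in its tumor type.
    """
    per_type_hotspots: dict[str, set] = {}
    cat_counts: dict[str, dict[str, int]] = {}
    # index records once per tumor type
    rec_index: dict[str, dict[tuple, set]] = {}
    for c in calls:
        per_type_hotspots.setdefault(c.tumor_type, set()).add((c.gene, c.aa_position))
    for t in per_type_hotspots:
        idx: dict[tuple, set] = {}
        for r in dataset.records_of_type(t):
            if r.aa_position is None:
                continue
            code = classify_record(r)
            if code is None:
                continue
            idx.setdefault((r.gene, r.aa_position), set()).add(subtype_category(code))
        rec_index[t] = idx
    for t, hotspots in per_type_hotspots.items():
        counts = dict.fromkeys(CATEGORIES, 0)
        for key in hotspots:
            for cat in rec_index[t].get(key, set()):
                counts[cat] += 1
        cat_counts[t] = counts
    counts_df = pd.DataFrame.from_dict(cat_counts, orient="index", columns=list(CATEGORIES))
    counts_df.index.name = "tumor_type"
    counts_df = counts_df.sort_index()
    n_hot = {t: len(h) for t, h in per_type_hotspots.items()}
    fractions = counts_df.div(pd.Series(n_hot), axis=0)
    return CompositionMatrix(fractions=fractions, counts=counts_df, n_hotspots=n_hot)


def category_enrichment(
    comp: CompositionMatrix, tumor_type: str, category: str
) -> float:
    """Is a category more common among one tumor type's hotspots than the rest?

    Two-sided Fisher exact test on the 2x2 table of category-carrying
    hotspots vs not, tumor type vs all other types pooled.
    """
    if tumor_type not in comp.counts.index:
        raise ValueError(f"no hotspots for tumor type {tumor_type!r}")
    if category not in comp.counts.columns:
        raise ValueError(f"unknown category {category!r}")
    a = int(comp.counts.loc[tumor_type, category])
    n_t = comp.n_hotspots[tumor_type]
    if n_t == 0:
        raise ValueError(f"zero hotspots in tumor type {tumor_type!r}")
    c = int(comp.counts[category].sum()) - a
    n_rest = sum(comp.n_hotspots.values()) - n_t
    table = [[a, n_t - a], [c, n_rest - c]]
    return float(stats.fisher_exact(table, alternative="two-sided")[1])
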