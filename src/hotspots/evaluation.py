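"""Evaluating a hotspot set: gene-set overlap, conservation, positions.

Overlap with a reference gene set (e.g. a cancer-gene census) is tested by
two-sided Fisher exact on the 2x2 of set membership vs containing a
hotspot, over a stated gene universe. Conservation compares site-level
rejected-substitution scores between hotspot and non-hotspot mutation
sites with a two-sided Mann-Whitney test. Relative positions place each
hotspot at aa_position / protein_length in [0, 1].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .assoc import mwu_test
from .detection import HotspotCall
from .model import GeneAnnotation
from .prevalence import ContingencyTable2x2, fisher_exact_2x2


@dataclass
class GeneSetOverlap:
    set_name: str
    n_set: int
    n_universe: int
    n_set_hit: int
    n_rest_hit: int
    table: ContingencyTable2x2
    p: float


def gene_overlap_test(
    hotspot_genes: set[str],
    reference_set: set[str],
    universe: set[str],
    set_name: str = "reference",
) -> GeneSetOverlap:
    """Fisher test of hotspot-containing genes against a reference set.

    Genes outside the declared universe are dropped with a warning rather
    than silently intersected, so the stated universe is authoritative.
    """
    if not universe:
        raise ValueError("empty gene universe")
    stray = (hotspot_genes | reference_set) - universe
    if stray:
        warnings.warn(
            f"{len(stray)} gene(s) outside the declared universe dropped: "
            + ", ".join(sorted(stray)[:10])
        )
    hot = hotspot_genes & universe
    ref = reference_set & universe
    a = len(ref & hot)
    b = len(ref - hot)
    c = len(hot - ref)
    d = len(universe) - a - b - c
    table = ContingencyTable2x2(a, b, c, d)
    return GeneSetOverlap(
        set_name=set_name,
        n_set=len(ref),
        n_universe=len(universe),
        n_set_hit=a,
        n_rest_hit=c,
        table=table,
        p=fisher_exact_2x2(table),
    )


def overlap_test_from_counts(
    n_set_hit: int, n_set: int, n_rest_hit: int, n_rest: int,
    set_name: str = "reference",
) -> GeneSetOverlap:
    """Overlap test from printed summary counts (hits/set vs hits/rest)."""
    table = ContingencyTable2x2(
        n_set_hit, n_set - n_set_hit, n_rest_hit, n_rest - n_rest_hit
    )
    return GeneSetOverlap(
        set_name=set_name,
        n_set=n_set,
        n_universe=n_set + n_rest,
        n_set_hit=n_set_hit,
        n_rest_hit=n_rest_hit,
        table=table,
        p=fisher_exact_2x2(table),
    )


def conservation_compare(
    hot_scores, nonhot_scores
) -> tuple[float, float, float]:
    """Two-sided Mann-Whitney comparison of conservation scores.

    Returns (p, median of hotspot scores, median of non-hotspot scores);
    higher scores mean stronger evolutionary constraint.
    """
    hot = np.asarray(hot_scores, dtype=float)
    non = np.asarray(nonhot_scores, dtype=float)
    if hot.size == 0 or non.size == 0:
        raise ValueError("both score sets must be nonempty")
    p = mwu_test(hot, non)
    return p, float(np.median(hot)), float(np.median(non))


def relative_positions(
    calls: list[HotspotCall],
    annotations: dict[str, GeneAnnotation],
    bins: int = 20,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Relative protein positions of calls, with an equal-width histogram.

    Returns (positions in [0, 1], bin counts, bin edges).
    """
    pos = []
    for c in calls:
        ann = annotations.get(c.gene)
        if ann is None:
            raise ValueError(f"gene {c.gene!r} lacks an annotation")
        if c.aa_position > ann.protein_length:
            raise ValueError(
                f"{c.gene} position {c.aa_position} exceeds protein length "
                f"{ann.protein_length}"
            )
        pos.append(c.aa_position / ann.protein_length)
    pos_arr = np.asarray(pos, dtype=float)
    counts, edges = np.histogram(pos_arr, bins=bins, range=(0.0, 1.0))
    return pos_arr, counts, edges
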