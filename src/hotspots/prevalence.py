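"""Tumor-type prevalence and exclusivity of hotspot mutations.

For a hotspot B and tumor type A, the 2x2 table counts A samples carrying
B, A samples not carrying B, non-A carriers, and non-A non-carriers over
the combined cohort. Two-sided Fisher exact p-values are BH-adjusted across
all tested (hotspot, tumor type) pairs; a pair with q < 0.01 is called
highly prevalent. A hotspot seen in exactly one tumor type is exclusive.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass

import pandas as pd
from scipy import stats

from .detection import HotspotCall, bh_adjust
from .model import CohortDataset


@dataclass(frozen=True)
class ContingencyTable2x2:
    a: int  # type-A samples with the mutation
    b: int  # type-A samples without
    c: int  # non-A samples with
    d: int  # non-A samples without

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("table entries must be nonnegative")


@dataclass
class PrevalenceResult:
    gene: str
    aa_position: int
    tumor_type: str
    table: ContingencyTable2x2
    p: float
    q: float
    prevalent: bool
    exclusive: bool


def fisher_exact_2x2(t: ContingencyTable2x2) -> float:
    """Two-sided Fisher exact p (probability-mass rule).

    A zero margin makes the table degenerate; p is 1 by convention.
    """
    if (t.a + t.b == 0 or t.c + t.d == 0 or t.a + t.c == 0 or t.b + t.d == 0):
        warnings.warn("degenerate 2x2 table (zero margin); p = 1")
        return 1.0
    return float(stats.fisher_exact([[t.a, t.b], [t.c, t.d]])[1])


def hotspot_carriers(
    dataset: CohortDataset, gene: str, aa_position: int
) -> set[str]:
    """Samples with >= 1 mutation of any subtype at (gene, aa_position)."""
    return {
        r.sample_id
        for r in dataset.records
        if r.gene == gene
        and r.aa_position == aa_position
        and r.sample_id not in dataset.excluded_samples
    }


def prevalence_scan(
    calls: list[HotspotCall], dataset: CohortDataset, alpha: float = 0.01
) -> list[PrevalenceResult]:
    """Fisher-exact prevalence scan over (hotspot, tumor type) pairs.

    Pairs with at least one carrier in the tumor type are tested; BH
    adjustment is applied jointly across all tested pairs.
    """
    all_samples = {
        s for s in dataset.samples if s not in dataset.excluded_samples
    }
    by_type: dict[str, set[str]] = {}
    for s in all_samples:
        by_type.setdefault(dataset.samples[s], set()).add(s)

    hotspots = sorted({(c.gene, c.aa_position) for c in calls})
    rows = []
    for gene, aa in hotspots:
        carriers = hotspot_carriers(dataset, gene, aa) & all_samples
        types_with_carriers = sorted({dataset.samples[s] for s in carriers})
        for t in types_with_carriers:
            in_type = by_type[t]
            a = len(carriers & in_type)
            b = len(in_type) - a
            c = len(carriers) - a
            d = len(all_samples) - len(in_type) - c
            rows.append(
                {
                    "gene": gene,
                    "aa": aa,
                    "tumor_type": t,
                    "table": ContingencyTable2x2(a, b, c, d),
                    "exclusive": len(types_with_carriers) == 1,
                }
            )
    pvals = [fisher_exact_2x2(r["table"]) for r in rows]
    qvals = bh_adjust(pvals)
    return [
        PrevalenceResult(
            gene=r["gene"],
            aa_position=r["aa"],
            tumor_type=r["tumor_type"],
            table=r["table"],
            p=float(p),
            q=float(q),
            prevalent=bool(q < alpha),
            exclusive=r["exclusive"],
        )
        for r, p, q in zip(rows, pvals, qvals)
    ]


def multiplicity_summary(results: list[PrevalenceResult]) -> dict[int, int]:
    """Histogram of per-hotspot counts of tumor types where it is prevalent."""
    per_hotspot = Counter()
    for r in results:
        if r.prevalent:
            per_hotspot[(r.gene, r.aa_position)] += 1
    return dict(Counter(per_hotspot.values()))


def results_to_frame(results: list[PrevalenceResult]) -> pd.DataFrame:
    rows = [
        {
            "gene": r.gene,
            "aa_position": r.aa_position,
            "tumor_type": r.tumor_type,
            "a": r.table.a,
            "b": r.table.b,
            "c": r.table.c,
            "d": r.table.d,
            "p": r.p,
            "q": r.q,
            "prevalent": r.prevalent,
            "exclusive": r.exclusive,
        }
        for r in results
    ]
    cols = ["gene", "aa_position", "tumor_type", "a", "b", "c", "d",
            "p", "q", "prevalent", "exclusive"]
    return pd.DataFrame(rows, columns=cols)
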