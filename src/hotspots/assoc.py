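"""Mutation-status groups and Mann-Whitney association scans.

Samples are partitioned by their mutation status in a gene — carrying the
hotspot, carrying some other mutation in the gene, or carrying none — and
a sample-by-feature matrix (log2 mRNA, protein array, copy number, drug
activity area) is compared between groups with two-sided Mann-Whitney U
tests. Only hotspots carried by at least ``min_occurrence`` matrix-covered
samples are tested.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .detection import HotspotCall
from .model import CohortDataset

# exact enumeration is used for small groups; above this many splits the
# tie-corrected normal approximation takes over
_MAX_EXACT_SPLITS = 150_000


class Group(enum.Enum):
    HOTSPOT = "hotspot"
    NON_HOTSPOT = "non_hotspot"
    NO_MUTATION = "no_mutation"
    EXCLUDED = "excluded"


class CnEvent(enum.Enum):
    DELETION = "deletion"
    NEUTRAL = "neutral"
    AMPLIFICATION = "amplification"


@dataclass
class AssociationResult:
    gene: str
    aa_position: int
    tumor_type: str
    feature_id: str
    comparison: str  # hotspot_vs_nonhotspot | hotspot_vs_none
    n1: int
    n2: int
    p: float
    direction: str  # higher | lower


def log2_rpkm(values) -> np.ndarray:
    """log2-transform RPKM after replacing zeros by the minimum nonzero.

    The zero-replacement makes the log transform finite while preserving
    the ordering of expressed genes.
    """
    v = np.asarray(values, dtype=float)
    if np.any(v < 0):
        raise ValueError("RPKM values must be nonnegative")
    nonzero = v[v > 0]
    if nonzero.size == 0:
        raise ValueError("all-zero RPKM vector cannot be log-transformed")
    v = np.where(v == 0, nonzero.min(), v)
    return np.log2(v)


def call_cn_events(cn: pd.DataFrame) -> pd.DataFrame:
    """Copy-number calls: < -1 deletion, > 1 amplification, else neutral.

    Both thresholds are strict; boundary values are neutral.
    """
    def call(v: float) -> str:
        if v < -1:
            return CnEvent.DELETION.value
        if v > 1:
            return CnEvent.AMPLIFICATION.value
        return CnEvent.NEUTRAL.value

    return cn.map(call)


def assign_groups(
    dataset: CohortDataset,
    gene: str,
    hotspot_aa: int,
    exclude_cn_deleted: bool = False,
    cn: pd.DataFrame | None = None,
    samples: list[str] | None = None,
) -> dict[str, Group]:
    """Partition samples by mutation status at (gene, hotspot_aa).

    CN-deleted samples are excluded (before grouping) when requested, to
    separate mutation effects from loss of the locus.
    """
    gene_records = [r for r in dataset.records if r.gene == gene]
    if not gene_records:
        raise ValueError(f"gene {gene!r} absent from mutation data")
    if samples is None:
        samples = [s for s in dataset.samples if s not in dataset.excluded_samples]
    mutated = {r.sample_id for r in gene_records}
    at_hotspot = {r.sample_id for r in gene_records if r.aa_position == hotspot_aa}
    deleted: set[str] = set()
    if exclude_cn_deleted:
        if cn is None or gene not in cn.columns:
            raise ValueError("CN matrix with the gene column required for exclusion")
        calls = call_cn_events(cn[[gene]])
        deleted = set(calls.index[calls[gene] == CnEvent.DELETION.value])
    out: dict[str, Group] = {}
    for s in samples:
        if s in deleted:
            out[s] = Group.EXCLUDED
        elif s in at_hotspot:
            out[s] = Group.HOTSPOT
        elif s in mutated:
            out[s] = Group.NON_HOTSPOT
        else:
            out[s] = Group.NO_MUTATION
    return out


def _exact_mwu_p(x: np.ndarray, y: np.ndarray) -> float:
    """Exact two-sided p by enumerating all splits of the pooled sample.

    The statistic is U = #{(i,j): x_i > y_j} + 0.5 #{x_i = y_j}; two-sided
    extremeness is distance from the null mean n1*n2/2, which handles ties
    without a normal approximation.
    """
    pooled = np.concatenate([x, y])
    n1, n = len(x), len(x) + len(y)
    mean_u = len(x) * len(y) / 2.0

    def u_of(idx: tuple) -> float:
        xs = pooled[list(idx)]
        ys = np.delete(pooled, list(idx))
        gt = np.sum(xs[:, None] > ys[None, :])
        eq = np.sum(xs[:, None] == ys[None, :])
        return gt + 0.5 * eq

    obs = abs(u_of(tuple(range(n1))) - mean_u)
    hits = total = 0
    for idx in combinations(range(n), n1):
        total += 1
        if abs(u_of(idx) - mean_u) >= obs - 1e-12:
            hits += 1
    return hits / total


def mwu_test(x, y) -> float:
    """Two-sided Mann-Whitney U p-value.

    Exact split enumeration when either group is small (< 8) and the number
    of splits is tractable; otherwise the tie-corrected normal
    approximation. Identical constant samples give p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be nonempty")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return 1.0
    small = min(x.size, y.size) < 8
    if small and math.comb(x.size + y.size, x.size) <= _MAX_EXACT_SPLITS:
        return _exact_mwu_p(x, y)
    return float(
        stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic").pvalue
    )


def _match_features(
    call: HotspotCall, kind: str, columns, feature_map: dict | None
) -> list[str]:
    if kind in ("mrna_log2", "cn"):
        return [call.gene] if call.gene in columns else []
    if feature_map is None:
        return []
    return [f for f in feature_map.get(call.gene, []) if f in columns]


def association_scan(
    calls: list[HotspotCall],
    dataset: CohortDataset,
    matrix: pd.DataFrame,
    kind: str = "mrna_log2",
    feature_map: dict[str, list[str]] | None = None,
    min_occurrence: int = 2,
) -> list[AssociationResult]:
    """Scan hotspots against a samples x features matrix.

    For each hotspot with >= ``min_occurrence`` carriers among
    matrix-covered samples, compares hotspot vs non-hotspot and hotspot vs
    no-mutation groups per matched feature. mRNA and CN features match the
    hotspot's gene symbol; protein-array and drug features go through an
    explicit ``feature_map`` (gene -> feature ids). Raw two-sided p-values
    are reported (no FDR), with the direction of the hotspot group's shift.
    """
    shared = [s for s in matrix.index if s in dataset.samples
              and s not in dataset.excluded_samples]
    if not shared:
        raise ValueError("no samples shared between matrix and mutation data")
    results: list[AssociationResult] = []
    for call in calls:
        features = _match_features(call, kind, matrix.columns, feature_map)
        if not features:
            continue
        groups = assign_groups(dataset, call.gene, call.aa_position, samples=shared)
        hot = [s for s, g in groups.items() if g == Group.HOTSPOT]
        if len(hot) < min_occurrence:
            continue
        others = {
            "hotspot_vs_nonhotspot": [
                s for s, g in groups.items() if g == Group.NON_HOTSPOT
            ],
            "hotspot_vs_none": [
                s for s, g in groups.items() if g == Group.NO_MUTATION
            ],
        }
        for feat in features:
            col = matrix[feat]
            xv = col.loc[hot].dropna()
            if len(xv) < min_occurrence:
                continue
            for comparison, grp in others.items():
                yv = col.loc[grp].dropna()
                if len(yv) < 1:
                    continue
                p = mwu_test(xv.to_numpy(), yv.to_numpy())
                direction = "higher" if xv.median() >= yv.median() else "lower"
                results.append(
                    AssociationResult(
                        gene=call.gene,
                        aa_position=call.aa_position,
                        tumor_type=call.tumor_type,
                        feature_id=feat,
                        comparison=comparison,
                        n1=len(xv),
                        n2=len(yv),
                        p=float(p),
                        direction=direction,
                    )
                )
    return results


def assoc_to_frame(results: list[AssociationResult]) -> pd.DataFrame:
    cols = ["gene", "aa_position", "tumor_type", "feature_id", "comparison",
            "n1", "n2", "p", "direction"]
    return pd.DataFrame([vars(r) for r in results], columns=cols)
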