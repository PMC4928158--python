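"""Per-amino-acid hotspot detection.

The background model is gene-, tumor-type- and mutation-subtype-specific:
for each (gene, subtype) pair, the total subtype-specific mutation count E
in the tumor-type cohort is spread uniformly over the protein, giving a
per-amino-acid Poisson mean lambda = E / protein_length. Each amino-acid
position with at least one classified mutation is scored by combining the
per-subtype Poisson upper-tail p-values with Fisher's method,

    x = -2 * sum_i log p_i,   x ~ chi-square with 2k df,

where k is the number of subtypes with an observation at that position.
Combined p-values are Benjamini-Hochberg adjusted across all tested
positions within the tumor type; positions with q below ``alpha``
(default 0.001) are reported as hotspots.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .model import CohortDataset, GeneAnnotation
from .subtypes import SubtypeCode, classify_record

_TINY = np.nextafter(0.0, 1.0)


@dataclass(frozen=True)
class SubtypeEvidence:
    """Observed count, background rate and Poisson p for one subtype."""

    subtype: str
    observed: int
    lam: float
    p: float


@dataclass
class HotspotCall:
    """A called hotspot: one amino-acid position in one tumor type."""

    gene: str
    aa_position: int
    tumor_type: str
    k: int
    x: float
    p_combined: float
    q: float
    contributing: tuple[SubtypeEvidence, ...]
    n_carrier_samples: int


def poisson_tail(observed: int, lam: float) -> float:
    """Upper-tail Poisson p-value, P(X >= observed | lambda).

    Equals 1 when ``observed`` is 0 (the empty tail). Clamped away from 0
    so the Fisher log is always finite.
    """
    if observed < 0 or lam < 0:
        raise ValueError("observed and lambda must be nonnegative")
    if observed == 0:
        return 1.0
    p = float(stats.poisson.sf(observed - 1, lam))
    return max(p, _TINY)


def poisson_pmf_score(observed: int, lam: float) -> float:
    """Poisson pmf at the observed count (alternative score, see docs).

    Retained because the combination formula can be read either way; the
    upper tail is the default everywhere.
    """
    if observed < 0 or lam < 0:
        raise ValueError("observed and lambda must be nonnegative")
    return max(float(stats.poisson.pmf(observed, lam)), _TINY)


def combine_fisher(pvals) -> tuple[float, float]:
    """Fisher's method: x = -2 sum(ln p), chi-square survival at 2k df.

    At k = 1 this is the identity on p. Zeros are clamped to the smallest
    positive float with a warning.
    """
    pvals = np.asarray(pvals, dtype=float)
    if pvals.size == 0:
        raise ValueError("need at least one p-value")
    if np.any((pvals < 0) | (pvals > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if np.any(pvals == 0):
        warnings.warn("p-value of 0 clamped to smallest positive float")
        pvals = np.maximum(pvals, _TINY)
    x = float(-2.0 * np.sum(np.log(pvals)))
    p = float(stats.chi2.sf(x, 2 * pvals.size))
    return x, max(p, _TINY)


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, order-preserving with input."""
    pvals = np.asarray(pvals, dtype=float)
    if pvals.size == 0:
        return pvals.copy()
    if np.any((pvals < 0) | (pvals > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(pvals, method="fdr_bh")[1]


def estimate_background(
    counts: pd.DataFrame, annotations: dict[str, GeneAnnotation]
) -> tuple[pd.DataFrame, list[str]]:
    """Per-(gene, subtype) totals E and per-amino-acid rates lambda = E/L.

    ``counts`` is a gene x subtype count matrix. Pairs with E = 0 are
    omitted. Genes lacking an annotation are skipped and reported.
    """
    rows = []
    skipped = []
    for gene, row in counts.iterrows():
        ann = annotations.get(gene)
        if ann is None:
            skipped.append(gene)
            continue
        for subtype, e_total in row.items():
            if e_total > 0:
                rows.append(
                    {
                        "gene": gene,
                        "subtype": subtype,
                        "E_total": int(e_total),
                        "lambda_per_aa": e_total / ann.protein_length,
                    }
                )
    if skipped:
        warnings.warn(
            "genes without annotation skipped: " + ", ".join(sorted(skipped))
        )
    cols = ["gene", "subtype", "E_total", "lambda_per_aa"]
    return pd.DataFrame(rows, columns=cols), sorted(skipped)


def _classified_frame(dataset: CohortDataset, tumor_type: str) -> pd.DataFrame:
    rows = []
    for r in dataset.records_of_type(tumor_type):
        code = classify_record(r)
        if code is None or r.aa_position is None:
            continue
        if r.gene not in dataset.annotations:
            continue
        rows.append(
            {
                "gene": r.gene,
                "aa": r.aa_position,
                "subtype": code.value,
                "sample": r.sample_id,
            }
        )
    return pd.DataFrame(rows, columns=["gene", "aa", "subtype", "sample"])


def score_positions(
    dataset: CohortDataset,
    tumor_type: str,
    p_mode: str = "tail",
    k_mode: str = "observed",
) -> pd.DataFrame:
    """Score every (gene, amino-acid) position with >= 1 classified mutation.

    Returns one row per tested position with columns gene, aa_position, k,
    x, p_combined, q, n_carriers and the packed per-subtype evidence.
    ``p_mode`` selects the Poisson score ("tail" or "pmf"); ``k_mode``
    selects which subtypes enter the combination ("observed": only subtypes
    with O >= 1 at the position; "gene": all subtypes with gene-level
    E > 0).
    """
    if p_mode not in ("tail", "pmf"):
        raise ValueError(f"unknown p_mode: {p_mode!r}")
    if k_mode not in ("observed", "gene"):
        raise ValueError(f"unknown k_mode: {k_mode!r}")
    df = _classified_frame(dataset, tumor_type)
    cols = [
        "tumor_type", "gene", "aa_position", "k", "x",
        "p_combined", "q", "n_carriers", "evidence",
    ]
    if df.empty:
        return pd.DataFrame(columns=cols)

    # Background: E per (gene, subtype); lambda = E / protein length.
    e_tot = df.groupby(["gene", "subtype"]).size().rename("E_total")
    lengths = {g: dataset.annotations[g].protein_length for g in df["gene"].unique()}
    score = poisson_tail if p_mode == "tail" else poisson_pmf_score

    obs = (
        df.groupby(["gene", "aa", "subtype"])
        .agg(O=("sample", "size"), carriers=("sample", lambda s: frozenset(s)))
        .reset_index()
    )
    obs["lambda"] = [
        e_tot[(g, s)] / lengths[g] for g, s in zip(obs["gene"], obs["subtype"])
    ]
    obs["p"] = [score(o, lam) for o, lam in zip(obs["O"], obs["lambda"])]

    rows = []
    for (gene, aa), grp in obs.groupby(["gene", "aa"]):
        evidence = [
            SubtypeEvidence(s, int(o), float(lam), float(p))
            for s, o, lam, p in zip(grp["subtype"], grp["O"], grp["lambda"], grp["p"])
        ]
        pvals = [ev.p for ev in evidence]
        if k_mode == "gene":
            seen = set(grp["subtype"])
            for subtype in e_tot.loc[gene].index:
                if subtype not in seen:
                    lam = e_tot[(gene, subtype)] / lengths[gene]
                    ev = SubtypeEvidence(subtype, 0, lam, score(0, lam))
                    evidence.append(ev)
                    pvals.append(ev.p)
        x, p_comb = combine_fisher(pvals)
        carriers = frozenset().union(*grp["carriers"])
        rows.append(
            {
                "tumor_type": tumor_type,
                "gene": gene,
                "aa_position": int(aa),
                "k": len(pvals),
                "x": x,
                "p_combined": p_comb,
                "n_carriers": len(carriers),
                "evidence": tuple(evidence),
            }
        )
    out = pd.DataFrame(rows)
    out["q"] = bh_adjust(out["p_combined"].to_numpy())
    return out[cols]


def call_hotspots(
    dataset: CohortDataset,
    tumor_type: str,
    alpha: float = 0.001,
    p_mode: str = "tail",
    k_mode: str = "observed",
) -> list[HotspotCall]:
    """Hotspots of one tumor type: tested positions with q < alpha.

    Sorted by q, then gene symbol, then position. Distinct genomic variants
    hitting the same amino acid (e.g. jittered frameshift breakpoints)
    aggregate into a single candidate by construction.
    """
    scored = score_positions(dataset, tumor_type, p_mode=p_mode, k_mode=k_mode)
    hits = scored[scored["q"] < alpha].sort_values(
        ["q", "gene", "aa_position"], kind="mergesort"
    )
    return [
        HotspotCall(
            gene=row.gene,
            aa_position=int(row.aa_position),
            tumor_type=row.tumor_type,
            k=int(row.k),
            x=float(row.x),
            p_combined=float(row.p_combined),
            q=float(row.q),
            contributing=row.evidence,
            n_carrier_samples=int(row.n_carriers),
        )
        for row in hits.itertuples()
    ]


def call_hotspots_all_types(
    dataset: CohortDataset, alpha: float = 0.001, **kwargs
) -> list[HotspotCall]:
    """Union of per-tumor-type hotspot calls (FDR applied within each type)."""
    calls: list[HotspotCall] = []
    for t in dataset.tumor_types:
        calls.extend(call_hotspots(dataset, t, alpha=alpha, **kwargs))
    return calls


def calls_to_frame(calls: list[HotspotCall]) -> pd.DataFrame:
    """Flatten calls to a table; per-subtype evidence packed as strings."""
    rows = [
        {
            "tumor_type": c.tumor_type,
            "gene": c.gene,
            "aa_position": c.aa_position,
            "k": c.k,
            "x": c.x,
            "p_combined": c.p_combined,
            "q": c.q,
            "n_carriers": c.n_carrier_samples,
            "evidence": ";".join(
                f"{ev.subtype}:O={ev.observed}:lambda={ev.lam:.6g}:p={ev.p:.6g}"
                for ev in c.contributing
            ),
        }
        for c in calls
    ]
    cols = [
        "tumor_type", "gene", "aa_position", "k", "x",
        "p_combined", "q", "n_carriers", "evidence",
    ]
    return pd.DataFrame(rows, columns=cols)
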