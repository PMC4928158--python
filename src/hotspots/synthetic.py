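"""Seeded synthetic cohorts with the structure the detector assumes.

The generator draws background mutations per (tumor type, gene, subtype)
from a Poisson with a configurable cohort-level mean, places them uniformly
over amino-acid positions, and writes alleles and flanking bases consistent
with the assigned subtype (sequence context is generated, not looked up in
a genome). On top of the background it can plant recurrent hotspots at
fixed positions — frameshift hotspots receive jittered genomic breakpoints
that still map to one amino acid, mirroring how real indel hotspots present
— and inflate a fraction of samples into hyper-mutated outliers. All
randomness flows from one integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .io import build_dataset, read_annotation_table  # noqa: F401  (CLI convenience)
from .model import CohortDataset, GeneAnnotation, MutationRecord, VariantClass
from .subtypes import Context, SubtypeCode

# per-subtype allele/flank templates: (ref, alt, left choices, right choices)
_CONTEXT_TEMPLATES = {
    Context.ATts: ("A", "G", "ACGT", "ACGT"),
    Context.ATtv: ("A", "T", "ACGT", "ACGT"),
    Context.CpG_CGts: ("C", "T", "ACGT", "G"),
    Context.NoCpG_CGts: ("C", "T", "ACGT", "ACT"),
    Context.CpG_CGtv: ("C", "A", "ACGT", "G"),
    Context.NoCpG_CGtv: ("C", "A", "ACGT", "ACT"),
}

_CLASS_ALT_AA = {"missense": "V", "nonsense": "*", "silent": "="}


@dataclass
class PlantedHotspot:
    tumor_type: str
    gene: str
    aa_position: int
    subtype: str  # SubtypeCode value
    n_carriers: int


@dataclass
class SimulationConfig:
    """Generative description of a synthetic multi-tumor-type cohort."""

    seed: int
    tumor_types: list[str]
    n_samples: dict[str, int]
    genes: list[tuple[str, int]]  # (symbol, protein_length)
    # (tumor_type, gene, subtype value) -> expected cohort-level count
    background_rates: dict[tuple[str, str, str], float] = field(default_factory=dict)
    planted_hotspots: list[PlantedHotspot] = field(default_factory=list)
    hypermutated_fraction: float = 0.0
    hypermutated_multiplier: float = 1.0
    indel_jitter: int = 2

    def validate(self) -> None:
        lengths = dict(self.genes)
        for t in self.tumor_types:
            if self.n_samples.get(t, 0) < 1:
                raise ValueError(f"tumor type {t!r} needs at least 1 sample")
        for (t, g, s), rate in self.background_rates.items():
            if rate < 0:
                raise ValueError(f"negative background rate for {(t, g, s)}")
            if t not in self.tumor_types or g not in lengths:
                raise ValueError(f"background rate refers to unknown {(t, g)}")
            SubtypeCode(s)
        for h in self.planted_hotspots:
            if h.gene not in lengths:
                raise ValueError(f"planted hotspot in unknown gene {h.gene!r}")
            if not 1 <= h.aa_position <= lengths[h.gene]:
                raise ValueError(
                    f"planted position {h.aa_position} beyond protein "
                    f"length of {h.gene}"
                )
            if h.tumor_type not in self.tumor_types:
                raise ValueError(f"planted hotspot in unknown type {h.tumor_type!r}")
            if h.n_carriers > self.n_samples[h.tumor_type]:
                raise ValueError("more planted carriers than samples")
            SubtypeCode(h.subtype)
        if not 0.0 <= self.hypermutated_fraction <= 1.0:
            raise ValueError("hypermutated_fraction must be in [0, 1]")

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        raw["genes"] = [tuple(g) for g in raw["genes"]]
        raw["background_rates"] = {
            (r["tumor_type"], r["gene"], r["subtype"]): float(r["rate"])
            for r in raw.get("background_rates", [])
        }
        raw["planted_hotspots"] = [
            PlantedHotspot(**h) for h in raw.get("planted_hotspots", [])
        ]
        return cls(**raw)


def _gene_index(cfg: SimulationConfig) -> dict[str, int]:
    return {g: i for i, (g, _) in enumerate(cfg.genes)}


def _genomic_pos(gene_idx: int, aa: int, offset: int = 0) -> int:
    # synthetic coordinates: genes on one chromosome, 1 Mb apart, 3 b/codon
    return gene_idx * 1_000_000 + aa * 3 + 1 + offset


def _make_record(
    rng: np.random.Generator,
    sample: str,
    tumor_type: str,
    gene: str,
    gene_idx: int,
    aa: int,
    subtype: SubtypeCode,
    jitter: int = 0,
) -> MutationRecord:
    value = subtype.value
    if value == "insertion":
        offset = int(rng.integers(-jitter, jitter + 1)) if jitter else 0
        return MutationRecord(
            sample_id=sample, tumor_type=tumor_type, gene=gene, chrom="chrS",
            pos=_genomic_pos(gene_idx, aa, offset), ref_allele="-",
            alt_allele="".join(rng.choice(list("ACGT"), size=3)),
            variant_class=VariantClass.INSERTION,
            protein_change=f"p.A{aa}fs" if jitter else f"p.A{aa}_A{aa + 1}insV",
            aa_position=aa,
        )
    if value == "deletion":
        offset = int(rng.integers(-jitter, jitter + 1)) if jitter else 0
        size = int(rng.integers(1, 4)) if jitter else 3
        return MutationRecord(
            sample_id=sample, tumor_type=tumor_type, gene=gene, chrom="chrS",
            pos=_genomic_pos(gene_idx, aa, offset),
            ref_allele="".join(rng.choice(list("ACGT"), size=size)),
            alt_allele="-",
            variant_class=VariantClass.DELETION,
            protein_change=f"p.A{aa}fs" if jitter else f"p.A{aa}del",
            aa_position=aa,
        )
    cls_name, ctx_name = value.split("_", 1)
    ref, alt, lefts, rights = _CONTEXT_TEMPLATES[Context(ctx_name)]
    # half the SNVs are written from the opposite strand to exercise
    # strand-symmetric context classification downstream
    left = str(rng.choice(list(lefts)))
    right = str(rng.choice(list(rights)))
    if rng.random() < 0.5:
        comp = {"A": "T", "T": "A", "C": "G", "G": "C"}
        ref, alt, left, right = comp[ref], comp[alt], comp[right], comp[left]
    alt_aa = _CLASS_ALT_AA[cls_name]
    return MutationRecord(
        sample_id=sample, tumor_type=tumor_type, gene=gene, chrom="chrS",
        pos=_genomic_pos(gene_idx, aa),
        ref_allele=ref, alt_allele=alt,
        variant_class=VariantClass(cls_name),
        protein_change=f"p.A{aa}{alt_aa}",
        aa_position=aa, left_flank=left, right_flank=right,
    )


def simulate_cohort(
    cfg: SimulationConfig,
) -> tuple[list[MutationRecord], dict[str, str], dict[str, GeneAnnotation]]:
    """Draw a cohort: (records, sample table, annotations).

    Background counts per (tumor type, gene, subtype) are Poisson with the
    configured cohort mean (scaled up by the hyper-mutation weights), then
    assigned to samples with probability proportional to each sample's
    weight and to uniform amino-acid positions. Planted hotspots add
    carriers (distinct samples) at their fixed position. Deterministic for
    a given seed.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    lengths = dict(cfg.genes)
    gidx = _gene_index(cfg)

    sample_table: dict[str, str] = {}
    weights: dict[str, np.ndarray] = {}
    samples_by_type: dict[str, list[str]] = {}
    for t in cfg.tumor_types:
        ids = [f"{t}_s{i:03d}" for i in range(cfg.n_samples[t])]
        samples_by_type[t] = ids
        for s in ids:
            sample_table[s] = t
        w = np.ones(len(ids))
        n_hyper = int(round(cfg.hypermutated_fraction * len(ids)))
        if n_hyper:
            hyper_idx = rng.choice(len(ids), size=n_hyper, replace=False)
            w[hyper_idx] = cfg.hypermutated_multiplier
        weights[t] = w

    records: list[MutationRecord] = []
    for (t, g, s), mean in sorted(cfg.background_rates.items()):
        if mean == 0:
            continue
        w = weights[t]
        total = rng.poisson(mean * w.mean())
        if total == 0:
            continue
        ids = samples_by_type[t]
        chosen = rng.choice(len(ids), size=total, p=w / w.sum())
        positions = rng.integers(1, lengths[g] + 1, size=total)
        code = SubtypeCode(s)
        for si, aa in zip(chosen, positions):
            records.append(
                _make_record(rng, ids[si], t, g, gidx[g], int(aa), code)
            )

    for h in cfg.planted_hotspots:
        ids = samples_by_type[h.tumor_type]
        carriers = rng.choice(len(ids), size=h.n_carriers, replace=False)
        code = SubtypeCode(h.subtype)
        jitter = cfg.indel_jitter if code in (
            SubtypeCode.insertion, SubtypeCode.deletion
        ) else 0
        for si in carriers:
            records.append(
                _make_record(
                    rng, ids[si], h.tumor_type, h.gene, gidx[h.gene],
                    h.aa_position, code, jitter=jitter,
                )
            )

    annotations = {g: GeneAnnotation(g, length) for g, length in cfg.genes}
    return records, sample_table, annotations


def simulate_dataset(
    cfg: SimulationConfig, apply_hypermutation_filter: bool = True
) -> CohortDataset:
    """Convenience: simulate and assemble a filtered :class:`CohortDataset`."""
    records, samples, annotations = simulate_cohort(cfg)
    return build_dataset(
        records, samples, annotations,
        apply_hypermutation_filter=apply_hypermutation_filter,
    )


def simulate_feature_matrix(
    group_sizes: dict[str, int],
    effect_size: float,
    n_features: int,
    seed: int,
    n_effect_features: int = 1,
) -> tuple[pd.DataFrame, dict[str, list[str]], list[str]]:
    """Samples x features matrix of standard normals with a planted shift.

    Samples of the first group (insertion order) are shifted by
    ``effect_size`` (in SD units) on the first ``n_effect_features``
    features. Returns (matrix, group -> sample ids, shifted feature ids).
    """
    rng = np.random.default_rng(seed)
    sample_ids: list[str] = []
    members: dict[str, list[str]] = {}
    for name, size in group_sizes.items():
        ids = [f"{name}_{i:03d}" for i in range(size)]
        members[name] = ids
        sample_ids.extend(ids)
    features = [f"F{j:04d}" for j in range(n_features)]
    values = rng.standard_normal((len(sample_ids), n_features))
    mat = pd.DataFrame(values, index=sample_ids, columns=features)
    first = next(iter(group_sizes))
    shifted = features[:n_effect_features]
    mat.loc[members[first], shifted] += effect_size
    return mat, members, shifted


def simulate_site_scores(
    n_hot: int, n_nonhot: int, shift: float, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Normal conservation scores; the hotspot group's mean shifted by ``shift``."""
    if n_hot < 1 or n_nonhot < 1:
        raise ValueError("both groups need at least one site")
    rng = np.random.default_rng(seed)
    hot = rng.standard_normal(n_hot) + shift
    nonhot = rng.standard_normal(n_nonhot)
    return hot, nonhot
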