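"""Core data model for cohort somatic-mutation analysis.

A cohort is a set of tumor samples, each assigned to one tumor type, with a
table of somatic variant calls annotated at the protein level (gene symbol
and affected amino-acid position). Genes carry a protein length so that
per-amino-acid background mutation rates can be formed.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field


class VariantClass(enum.Enum):
    """Normalized variant effect class.

    The background model covers five classes (missense, nonsense, silent,
    insertion, deletion); everything else is ``OTHER`` and is kept for
    per-sample mutation counts but excluded from subtype modelling.
    """

    MISSENSE = "missense"
    NONSENSE = "nonsense"
    SILENT = "silent"
    INSERTION = "insertion"
    DELETION = "deletion"
    OTHER = "other"


class ProteinChangeKind(enum.Enum):
    SUBSTITUTION = "substitution"
    FRAMESHIFT = "frameshift"
    INFRAME_INDEL = "inframe_indel"
    OTHER = "other"


@dataclass(frozen=True)
class ProteinChange:
    """Parsed HGVS p. string: the first affected residue."""

    aa_position: int
    ref_aa: str | None
    kind: ProteinChangeKind


@dataclass
class MutationRecord:
    """One somatic variant call in one sample.

    ``pos`` is 1-based and names the first affected base; pure insertions
    are anchored at the base immediately 5' of the inserted sequence and use
    ``ref_allele == "-"``; pure deletions use ``alt_allele == "-"``.
    ``left_flank``/``right_flank`` are the reference bases immediately 5'
    and 3' of an SNV, used for sequence-context classification.
    """

    sample_id: str
    tumor_type: str | None
    gene: str
    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    variant_class: VariantClass
    protein_change: str | None = None
    aa_position: int | None = None
    left_flank: str | None = None
    right_flank: str | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.is_snv and self.ref_allele == self.alt_allele:
            raise ValueError("SNV with ref == alt")

    @property
    def is_snv(self) -> bool:
        return (
            len(self.ref_allele) == 1
            and len(self.alt_allele) == 1
            and self.ref_allele in "ACGT"
            and self.alt_allele in "ACGT"
        )


@dataclass(frozen=True)
class GeneAnnotation:
    """Protein length (amino acids) and optional coding territory (bases)."""

    gene: str
    protein_length: int
    coding_territory_bases: int | None = None

    def __post_init__(self) -> None:
        if self.protein_length < 1:
            raise ValueError(f"{self.gene}: protein_length must be >= 1")
        if (
            self.coding_territory_bases is not None
            and self.coding_territory_bases < 3 * self.protein_length
        ):
            raise ValueError(
                f"{self.gene}: coding territory smaller than 3 x protein length"
            )


@dataclass
class CohortMutationStats:
    """Per-tumor-type sample mutation-count summary for outlier filtering.

    A sample is flagged hyper-mutated when its total mutation count strictly
    exceeds ``mu + 2 * sigma`` computed over samples of its tumor type.
    """

    tumor_type: str
    per_sample_counts: dict[str, int]
    mu: float
    sigma: float

    @property
    def threshold(self) -> float:
        return self.mu + 2.0 * self.sigma


@dataclass
class CohortDataset:
    """A filtered cohort ready for background estimation and hotspot testing."""

    records: list[MutationRecord]
    samples: dict[str, str]  # sample_id -> tumor_type
    annotations: dict[str, GeneAnnotation]
    excluded_samples: set[str] = field(default_factory=set)
    stats: dict[str, CohortMutationStats] = field(default_factory=dict)

    def __post_init__(self) -> None:
        unknown = {r.sample_id for r in self.records} - set(self.samples)
        if unknown:
            raise ValueError(
                "records reference unknown samples: " + ", ".join(sorted(unknown))
            )

    @property
    def tumor_types(self) -> list[str]:
        return sorted(set(self.samples.values()))

    def samples_of_type(self, tumor_type: str, include_excluded: bool = False) -> list[str]:
        out = [
            s
            for s, t in self.samples.items()
            if t == tumor_type and (include_excluded or s not in self.excluded_samples)
        ]
        return sorted(out)

    def records_of_type(self, tumor_type: str) -> list[MutationRecord]:
        if tumor_type not in set(self.samples.values()):
            raise KeyError(f"unknown tumor type: {tumor_type}")
        return [
            r
            for r in self.records
            if self.samples[r.sample_id] == tumor_type
            and r.sample_id not in self.excluded_samples
        ]

    def protein_length(self, gene: str) -> int | None:
        ann = self.annotations.get(gene)
        return ann.protein_length if ann else None


def sample_sd(values: list[float]) -> float:
    """Sample standard deviation (n-1 denominator); 0.0 for n < 2."""
    n = len(values)
    if n < 2:
        return 0.0
    m = sum(values) / n
    return math.sqrt(sum((v - m) ** 2 for v in values) / (n - 1))
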