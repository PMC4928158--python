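"""The 20-subtype mutation taxonomy and its sequence-context classifier.

SNVs in the three coding classes (missense, nonsense, silent) are split by
dinucleotide sequence context into six bins: A/T transition (ATts), A/T
transversion (ATtv), and C/G transitions/transversions at CpG vs non-CpG
sites. Insertions and deletions are their own subtypes regardless of
context, giving 3 x 6 + 2 = 20 subtypes in total.

A CpG site is the dinucleotide CG on either strand: a reference C whose 3'
neighbour is G, or a reference G whose 5' neighbour is C. Classification is
strand-symmetric: the reverse-complemented variant maps to the same label.
"""

from __future__ import annotations

import enum
import warnings

import pandas as pd

from .model import CohortDataset, MutationRecord, VariantClass

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C", "N": "N"}
TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


class Context(enum.Enum):
    """Six dinucleotide sequence contexts for coding SNVs."""

    ATts = "ATts"
    ATtv = "ATtv"
    CpG_CGts = "CpG_CGts"
    NoCpG_CGts = "NoCpG_CGts"
    CpG_CGtv = "CpG_CGtv"
    NoCpG_CGtv = "NoCpG_CGtv"


_SNV_CLASSES = (VariantClass.MISSENSE, VariantClass.NONSENSE, VariantClass.SILENT)

SubtypeCode = enum.Enum(
    "SubtypeCode",
    [(f"{cls.value}_{ctx.value}", f"{cls.value}_{ctx.value}")
     for cls in _SNV_CLASSES for ctx in Context]
    + [("insertion", "insertion"), ("deletion", "deletion")],
)
SubtypeCode.__doc__ = "One of the 20 mutation subtypes (class x context, or indel)."

ALL_SUBTYPES: tuple = tuple(SubtypeCode)
assert len(ALL_SUBTYPES) == 20

# Eight categories used for hotspot signature composition: the six SNV
# contexts with the three coding classes concatenated, plus the two indels.
CATEGORIES = tuple(c.value for c in Context) + ("insertion", "deletion")


def subtype_category(code: SubtypeCode) -> str:
    """Collapse a subtype onto its 8-way category (context or indel)."""
    if code in (SubtypeCode.insertion, SubtypeCode.deletion):
        return code.value
    return code.value.split("_", 1)[1]


def classify_context(ref: str, alt: str, left: str, right: str) -> Context:
    """Classify a flanked SNV into one of the six sequence contexts.

    An ``N`` flank at a C/G site cannot establish a CpG dinucleotide and is
    conservatively treated as non-CpG (with a warning).
    """
    ref, alt = ref.upper(), alt.upper()
    left, right = left.upper(), right.upper()
    if ref not in "ACGT" or alt not in "ACGT" or ref == alt:
        raise ValueError(f"not a valid SNV: {ref}>{alt}")
    ts = (ref, alt) in TRANSITIONS
    if ref in "AT":
        return Context.ATts if ts else Context.ATtv
    if ref == "C":
        flank, cpg = right, right == "G"
    else:  # ref == "G"
        flank, cpg = left, left == "C"
    if flank == "N":
        warnings.warn("N flank at C/G site: classified as non-CpG")
    if cpg:
        return Context.CpG_CGts if ts else Context.CpG_CGtv
    return Context.NoCpG_CGts if ts else Context.NoCpG_CGtv


def reverse_complement_snv(ref: str, alt: str, left: str, right: str):
    """The same variant read from the opposite strand."""
    return (
        COMPLEMENT[ref.upper()],
        COMPLEMENT[alt.upper()],
        COMPLEMENT[right.upper()],
        COMPLEMENT[left.upper()],
    )


def classify_record(
    r: MutationRecord, flanks: tuple[str, str] | None = None
) -> SubtypeCode | None:
    """Map a mutation record onto its subtype, or ``None`` if unclassifiable.

    Indels map directly; coding SNVs need flanking bases (either passed in
    or carried on the record). Class ``other`` and multi-nucleotide
    substitutions have no slot in the taxonomy and return ``None``.
    """
    vc = r.variant_class
    if vc == VariantClass.INSERTION:
        return SubtypeCode.insertion
    if vc == VariantClass.DELETION:
        return SubtypeCode.deletion
    if vc not in _SNV_CLASSES or not r.is_snv:
        return None
    if flanks is None:
        if r.left_flank is None or r.right_flank is None:
            return None
        flanks = (r.left_flank, r.right_flank)
    ctx = classify_context(r.ref_allele, r.alt_allele, flanks[0], flanks[1])
    return SubtypeCode[f"{vc.value}_{ctx.value}"]


def subtype_count_matrix(dataset: CohortDataset, tumor_type: str) -> pd.DataFrame:
    """Gene x 20-subtype counts over non-excluded samples of one tumor type.

    Each carrying sample contributes one count per record; the same genomic
    variant seen in five samples contributes five.
    """
    records = dataset.records_of_type(tumor_type)
    counts: dict[tuple[str, str], int] = {}
    for r in records:
        code = classify_record(r)
        if code is None:
            continue
        key = (r.gene, code.value)
        counts[key] = counts.get(key, 0) + 1
    genes = sorted({g for g, _ in counts})
    mat = pd.DataFrame(
        0, index=pd.Index(genes, name="gene"),
        columns=[s.value for s in ALL_SUBTYPES], dtype=int,
    )
    for (g, s), n in counts.items():
        mat.loc[g, s] = n
    return mat
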