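"""Reading and writing mutation tables, HGVS parsing, hyper-mutation filter.

Two input dialects are supported: a compact tab-separated layout
(``cosmic_tsv``: sample, tumor, gene, chrom, pos, ref, alt, class, pchange,
optional left_flank/right_flank/aa_position) and standard MAF column names.
A ``column_map`` lets callers rename non-standard headers onto either
dialect.
"""

from __future__ import annotations

import logging
import re
import warnings
from pathlib import Path

import pandas as pd

from .model import (
    CohortDataset,
    CohortMutationStats,
    GeneAnnotation,
    MutationRecord,
    ProteinChange,
    ProteinChangeKind,
    VariantClass,
    sample_sd,
)

logger = logging.getLogger(__name__)

COSMIC_COLUMNS = {
    "sample": "sample",
    "tumor": "tumor",
    "gene": "gene",
    "chrom": "chrom",
    "pos": "pos",
    "ref": "ref",
    "alt": "alt",
    "class": "class",
    "pchange": "pchange",
}
COSMIC_OPTIONAL = ("left_flank", "right_flank", "aa_position")

MAF_COLUMNS = {
    "sample": "Tumor_Sample_Barcode",
    "gene": "Hugo_Symbol",
    "chrom": "Chromosome",
    "pos": "Start_Position",
    "ref": "Reference_Allele",
    "alt": "Tumor_Seq_Allele2",
    "class": "Variant_Classification",
    "pchange": "HGVSp_Short",
}

# Variant-effect vocabulary across MAF and COSMIC-style annotations.
CLASS_MAP = {
    "missense_mutation": VariantClass.MISSENSE,
    "missense": VariantClass.MISSENSE,
    "substitution - missense": VariantClass.MISSENSE,
    "nonsense_mutation": VariantClass.NONSENSE,
    "nonsense": VariantClass.NONSENSE,
    "substitution - nonsense": VariantClass.NONSENSE,
    "silent": VariantClass.SILENT,
    "coding silent": VariantClass.SILENT,
    "substitution - coding silent": VariantClass.SILENT,
    "synonymous": VariantClass.SILENT,
    "in_frame_ins": VariantClass.INSERTION,
    "frame_shift_ins": VariantClass.INSERTION,
    "insertion": VariantClass.INSERTION,
    "insertion - in frame": VariantClass.INSERTION,
    "insertion - frameshift": VariantClass.INSERTION,
    "in_frame_del": VariantClass.DELETION,
    "frame_shift_del": VariantClass.DELETION,
    "deletion": VariantClass.DELETION,
    "deletion - in frame": VariantClass.DELETION,
    "deletion - frameshift": VariantClass.DELETION,
}


def normalize_variant_class(raw: str) -> VariantClass:
    return CLASS_MAP.get(str(raw).strip().lower(), VariantClass.OTHER)


_AA = "ACDEFGHIKLMNPQRSTVWY"
_RE_SUB = re.compile(rf"^(?:p\.)?([{_AA}])(\d+)(?:[{_AA}]|\*|=)(?!.)")
_RE_FS = re.compile(rf"^(?:p\.)?([{_AA}*])(\d+)(?:[{_AA}])?fs")
_RE_INDEL = re.compile(
    rf"^(?:p\.)?([{_AA}])(\d+)(?:_[{_AA}]\d+)?(?:del|ins|dup|delins)"
)
_RE_EXT = re.compile(rf"^(?:p\.)?([{_AA}*])(\d+)")


def parse_protein_change(pchange: str | None) -> ProteinChange | None:
    """Parse an HGVS ``p.`` string to its first affected residue.

    Total: returns ``None`` for anything unparseable or of unknown effect
    (``p.?``, ``p.=``, empty), never raises.
    """
    if pchange is None:
        return None
    s = str(pchange).strip()
    if not s or s in ("p.?", "?", "p.=", "="):
        return None
    m = _RE_SUB.match(s)
    if m:
        return ProteinChange(int(m.group(2)), m.group(1), ProteinChangeKind.SUBSTITUTION)
    m = _RE_FS.match(s)
    if m:
        ref = m.group(1) if m.group(1) != "*" else None
        return ProteinChange(int(m.group(2)), ref, ProteinChangeKind.FRAMESHIFT)
    m = _RE_INDEL.match(s)
    if m:
        return ProteinChange(int(m.group(2)), m.group(1), ProteinChangeKind.INFRAME_INDEL)
    m = _RE_EXT.match(s)
    if m and m.group(1) != "*":
        return ProteinChange(int(m.group(2)), m.group(1), ProteinChangeKind.OTHER)
    return None


def _resolve_columns(df: pd.DataFrame, dialect: str, column_map: dict | None) -> dict:
    if column_map:
        df.rename(columns=dict(column_map), inplace=True)
    if dialect == "cosmic_tsv":
        needed = COSMIC_COLUMNS
    elif dialect == "maf":
        needed = MAF_COLUMNS
    else:
        raise ValueError(f"unknown dialect: {dialect!r}")
    missing = [col for col in needed.values() if col not in df.columns]
    if missing:
        raise ValueError(
            f"{dialect} input is missing mandatory column(s): {', '.join(missing)}"
        )
    return needed


def read_mutation_table(
    path: str | Path,
    dialect: str = "cosmic_tsv",
    column_map: dict | None = None,
    strict: bool = True,
) -> list[MutationRecord]:
    """Read a mutation table into :class:`MutationRecord` objects.

    Rows whose variant class maps to ``other`` are retained (they count
    toward per-sample totals) but are excluded later from subtype modelling.
    Under ``strict`` an unparseable row raises with its line number; else it
    is skipped with a warning.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    cols = _resolve_columns(df, dialect, column_map)
    records: list[MutationRecord] = []
    for idx, row in df.iterrows():
        line_no = idx + 2  # header is line 1
        try:
            aa_pos = None
            if "aa_position" in df.columns and row["aa_position"] != "":
                aa_pos = int(row["aa_position"])
            pchange = row[cols["pchange"]] or None
            if aa_pos is None:
                parsed = parse_protein_change(pchange)
                if parsed is not None:
                    aa_pos = parsed.aa_position
            rec = MutationRecord(
                sample_id=row[cols["sample"]],
                tumor_type=row[cols["tumor"]] if "tumor" in cols else None,
                gene=row[cols["gene"]],
                chrom=row[cols["chrom"]],
                pos=int(row[cols["pos"]]),
                ref_allele=row[cols["ref"]],
                alt_allele=row[cols["alt"]],
                variant_class=normalize_variant_class(row[cols["class"]]),
                protein_change=pchange,
                aa_position=aa_pos,
                left_flank=row.get("left_flank") or None,
                right_flank=row.get("right_flank") or None,
            )
        except (ValueError, KeyError) as exc:
            msg = f"line {line_no}: unparseable row ({exc})"
            if strict:
                raise ValueError(msg) from exc
            warnings.warn(msg)
            continue
        records.append(rec)
    return records


def write_mutation_table(records: list[MutationRecord], path: str | Path) -> None:
    """Write records in the ``cosmic_tsv`` dialect (round-trips with read)."""
    rows = [
        {
            "sample": r.sample_id,
            "tumor": r.tumor_type or "",
            "gene": r.gene,
            "chrom": r.chrom,
            "pos": r.pos,
            "ref": r.ref_allele,
            "alt": r.alt_allele,
            "class": r.variant_class.value,
            "pchange": r.protein_change or "",
            "left_flank": r.left_flank or "",
            "right_flank": r.right_flank or "",
            "aa_position": r.aa_position if r.aa_position is not None else "",
        }
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_sample_table(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"sample_id", "tumor_type"} <= set(df.columns):
        raise ValueError("sample table needs columns: sample_id, tumor_type")
    return dict(zip(df["sample_id"], df["tumor_type"]))


def read_annotation_table(path: str | Path) -> dict[str, GeneAnnotation]:
    df = pd.read_csv(path, sep="\t")
    if not {"gene", "protein_length"} <= set(df.columns):
        raise ValueError("annotation table needs columns: gene, protein_length")
    out = {}
    for _, row in df.iterrows():
        terr = row.get("coding_territory_bases")
        terr = int(terr) if pd.notna(terr) else None
        out[row["gene"]] = GeneAnnotation(row["gene"], int(row["protein_length"]), terr)
    return out


def flag_hypermutated(
    per_sample_counts: dict[str, int], tumor_type: str = ""
) -> tuple[CohortMutationStats, set[str]]:
    """Flag samples whose mutation count strictly exceeds mu + 2*sigma.

    sigma is the sample standard deviation (n-1). Below 3 samples the
    statistic is degenerate and nothing is flagged.
    """
    counts = list(per_sample_counts.values())
    n = len(counts)
    mu = sum(counts) / n if n else 0.0
    sigma = sample_sd(counts)
    stats = CohortMutationStats(tumor_type, dict(per_sample_counts), mu, sigma)
    if n < 3:
        warnings.warn(
            f"tumor type {tumor_type!r}: fewer than 3 samples, hyper-mutation "
            "filter not applied"
        )
        return stats, set()
    flagged = {s for s, c in per_sample_counts.items() if c > stats.threshold}
    return stats, flagged


def build_dataset(
    records: list[MutationRecord],
    sample_table: dict[str, str],
    annotations: dict[str, GeneAnnotation],
    apply_hypermutation_filter: bool = True,
) -> CohortDataset:
    """Assemble a cohort, flagging hyper-mutated samples per tumor type.

    All records (including class ``other``) count toward the per-sample
    totals used by the filter; records of flagged samples are dropped.
    Samples with zero mutations still enter the mu/sigma computation.
    """
    unknown = sorted({r.sample_id for r in records} - set(sample_table))
    if unknown:
        raise ValueError("records reference unknown samples: " + ", ".join(unknown))
    for r in records:
        if r.tumor_type is None:
            r.tumor_type = sample_table[r.sample_id]

    excluded: set[str] = set()
    stats: dict[str, CohortMutationStats] = {}
    if apply_hypermutation_filter:
        by_type: dict[str, dict[str, int]] = {}
        for s, t in sample_table.items():
            by_type.setdefault(t, {})[s] = 0
        for r in records:
            by_type[sample_table[r.sample_id]][r.sample_id] += 1
        for t, counts in by_type.items():
            st, flagged = flag_hypermutated(counts, t)
            stats[t] = st
            excluded |= flagged
        if excluded:
            logger.info("excluded %d hyper-mutated samples", len(excluded))

    kept = [r for r in records if r.sample_id not in excluded]
    return CohortDataset(
        records=kept,
        samples=dict(sample_table),
        annotations=dict(annotations),
        excluded_samples=excluded,
        stats=stats,
    )


def write_exclusions(dataset: CohortDataset, path: str | Path) -> None:
    rows = []
    for s in sorted(dataset.excluded_samples):
        t = dataset.samples[s]
        st = dataset.stats.get(t)
        rows.append(
            {
                "sample_id": s,
                "tumor_type": t,
                "count": st.per_sample_counts.get(s) if st else "",
                "threshold": st.threshold if st else "",
            }
        )
    pd.DataFrame(rows, columns=["sample_id", "tumor_type", "count", "threshold"]).to_csv(
        path, sep="\t", index=False
    )
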