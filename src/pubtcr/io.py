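"""Readers and writers for the file formats the pipeline touches.

Germline V/J segments and sequencing reads travel as FASTA; per-sample
clonotype tables as AIRR-style tab-separated rearrangement files
(``v_call``/``j_call``/``junction_aa`` or ``cdr3_aa``/``duplicate_count``);
cohort membership as a tab-separated sample sheet. Everything is validated
into the domain types on ingest.

IMGT-style gene names are normalised on the way in: en-dashes become ASCII
hyphens and allele suffixes (``*01``) are stripped, so all downstream usage
statistics are at gene level (e.g. ``TRBV12-4``).
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

NT_ALPHABET = frozenset("ACGTN")
COHORTS = frozenset({"case", "tolerant", "healthy"})
TISSUES = frozenset({"blister", "PBMC", "other"})

_GENE_CLASS_RE = re.compile(r"^TR[AB]([VJ])")


class FormatError(ValueError):
    """A file does not parse as the expected format."""


class ValidationError(ValueError):
    """A file parses but violates a domain invariant."""


def normalize_gene_name(name: str) -> str:
    """ASCII-hyphen, allele-stripped gene name (``TRBV12–4*01`` -> ``TRBV12-4``)."""
    name = name.strip().replace("–", "-").replace("—", "-")
    return name.split("*", 1)[0]


def infer_segment_class(name: str) -> str:
    m = _GENE_CLASS_RE.match(name)
    if m is None:
        raise ValidationError(
            f"cannot infer segment class from gene name {name!r}; "
            "expected an IMGT-style TR[AB][VJ] prefix"
        )
    return m.group(1)


@dataclass(frozen=True)
class GermlineSegment:
    """One germline V or J segment with its translation frame.

    ``reading_frame_offset`` is the 0-based nucleotide offset at which
    translation of ``nt_sequence`` is in frame with the segment's conserved
    junction motif (Y[YFLI]C for V, [FW]GXGT for J).
    """

    name: str
    segment_class: str  # "V" or "J"
    nt_sequence: str
    reading_frame_offset: int = 0

    def __post_init__(self):
        if not self.nt_sequence:
            raise ValidationError(f"segment {self.name!r}: empty sequence")
        bad = set(self.nt_sequence) - NT_ALPHABET
        if bad:
            raise ValidationError(
                f"segment {self.name!r}: non-ACGTN characters {sorted(bad)}"
            )
        if self.segment_class not in ("V", "J"):
            raise ValidationError(
                f"segment {self.name!r}: segment_class must be V or J"
            )
        if not 0 <= self.reading_frame_offset <= 2:
            raise ValidationError(
                f"segment {self.name!r}: reading_frame_offset must be 0-2"
            )
        if _GENE_CLASS_RE.match(self.name):
            inferred = infer_segment_class(self.name)
            if inferred != self.segment_class:
                raise ValidationError(
                    f"segment {self.name!r}: name implies class {inferred}, "
                    f"got {self.segment_class}"
                )


@dataclass
class GermlineSet:
    """The V and J segments assignments are made against."""

    v_segments: list[GermlineSegment]
    j_segments: list[GermlineSegment]

    def __post_init__(self):
        if not self.v_segments or not self.j_segments:
            raise ValidationError("germline set needs at least one V and one J")
        names = [s.name for s in self.v_segments + self.j_segments]
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise ValidationError(f"duplicate germline names: {sorted(dupes)}")
        self._by_name = {s.name: s for s in self.v_segments + self.j_segments}

    def __getitem__(self, name: str) -> GermlineSegment:
        return self._by_name[name]

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    def __eq__(self, other) -> bool:
        if not isinstance(other, GermlineSet):
            return NotImplemented
        return (self.v_segments, self.j_segments) == (
            other.v_segments,
            other.j_segments,
        )


@dataclass(frozen=True)
class SequenceRead:
    read_id: str
    nt_sequence: str

    def __post_init__(self):
        if not self.nt_sequence:
            raise ValidationError(f"read {self.read_id!r}: empty sequence")


@dataclass(frozen=True)
class SampleMeta:
    """Cohort assignment of one sample.

    ``cohort`` is the analysis grouping (case / tolerant / healthy);
    ``phenotype`` and ``drug`` are free labels (e.g. "SJS/TEN", "CBZ");
    ``hla_flag`` marks carriers of the index HLA allele.
    """

    sample_id: str
    cohort: str
    phenotype: str = ""
    drug: str = ""
    tissue: str = "other"
    hla_flag: bool = False

    def __post_init__(self):
        if self.cohort not in COHORTS:
            raise ValidationError(
                f"sample {self.sample_id!r}: cohort {self.cohort!r} not in "
                f"{sorted(COHORTS)}"
            )
        if self.tissue not in TISSUES:
            raise ValidationError(
                f"sample {self.sample_id!r}: tissue {self.tissue!r} not in "
                f"{sorted(TISSUES)}"
            )

    @property
    def group_label(self) -> str:
        return "|".join((self.cohort, self.phenotype, self.drug, self.tissue))


@dataclass
class CohortDesign:
    samples: list[SampleMeta]

    def __post_init__(self):
        ids = [s.sample_id for s in self.samples]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise ValidationError(f"duplicate sample_id: {sorted(dupes)}")
        self._by_id = {s.sample_id: s for s in self.samples}

    def __len__(self) -> int:
        return len(self.samples)

    def __getitem__(self, sample_id: str) -> SampleMeta:
        return self._by_id[sample_id]

    def by_cohort(self, cohort: str) -> list[SampleMeta]:
        return [s for s in self.samples if s.cohort == cohort]

    def groups(self) -> dict[str, list[SampleMeta]]:
        out: dict[str, list[SampleMeta]] = {}
        for s in self.samples:
            out.setdefault(s.group_label, []).append(s)
        return out


# ---------------------------------------------------------------------------
# germline FASTA


def read_germline_fasta(path: str | Path) -> GermlineSet:
    """Read a germline V/J FASTA.

    Headers carry the gene name and optional ``key=value`` attributes, e.g.::

        >TRBV12-4 frame=0

    ``frame`` is the reading-frame offset (default 0). Segment class is
    inferred from the IMGT-style name prefix (TRBV/TRAV -> V, TRBJ/TRAJ -> J).
    """
    path = Path(path)
    v_segs: list[GermlineSegment] = []
    j_segs: list[GermlineSegment] = []
    try:
        records = list(SeqIO.parse(str(path), "fasta"))
    except Exception as exc:  # Biopython raises plain ValueError on bad FASTA
        raise FormatError(f"{path}: cannot parse FASTA: {exc}") from exc
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    for rec in records:
        if not str(rec.seq):
            raise FormatError(f"{path}: record {rec.id!r} has no sequence")
        name = normalize_gene_name(rec.id)
        attrs = dict(
            kv.split("=", 1) for kv in rec.description.split()[1:] if "=" in kv
        )
        try:
            frame = int(attrs.get("frame", 0))
        except ValueError as exc:
            raise FormatError(
                f"{path}: record {rec.id!r} has non-integer frame"
            ) from exc
        seg = GermlineSegment(
            name=name,
            segment_class=infer_segment_class(name),
            nt_sequence=str(rec.seq).upper(),
            reading_frame_offset=frame,
        )
        (v_segs if seg.segment_class == "V" else j_segs).append(seg)
    return GermlineSet(v_segments=v_segs, j_segments=j_segs)


def write_germline_fasta(germline: GermlineSet, path: str | Path) -> Path:
    path = Path(path)
    records = [
        SeqRecord(
            Seq(s.nt_sequence),
            id=s.name,
            description=f"frame={s.reading_frame_offset}",
        )
        for s in germline.v_segments + germline.j_segments
    ]
    SeqIO.write(records, str(path), "fasta")
    return path


# ---------------------------------------------------------------------------
# reads FASTA


def read_fasta_reads(path: str | Path) -> list[SequenceRead]:
    path = Path(path)
    reads = [
        SequenceRead(read_id=rec.id, nt_sequence=str(rec.seq).upper())
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not reads:
        raise FormatError(f"{path}: no FASTA records found")
    ids = [r.read_id for r in reads]
    if len(set(ids)) != len(ids):
        raise ValidationError(f"{path}: duplicate read ids")
    return reads


def write_fasta_reads(reads: Iterable[SequenceRead], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f">{r.read_id}\n{r.nt_sequence}\n")
    return path


# ---------------------------------------------------------------------------
# AIRR-style rearrangement TSV

_COUNT_COL = "duplicate_count"


def read_rearrangement_tsv(path: str | Path, meta: SampleMeta | None = None):
    """Read an AIRR-style rearrangement TSV into a :class:`ClonotypeTable`.

    Required columns: ``sample_id``, ``v_call``, ``j_call``,
    ``duplicate_count`` and one of ``cdr3_aa`` / ``junction_aa``. When only
    ``junction_aa`` is present (AIRR convention, with the conserved C and
    F/W anchors) the anchors are stripped to obtain ``cdr3_aa``. Rows with
    identical (V, J, CDR3) keys are merged by summing counts.
    """
    from .cdr3 import ClonotypeTable  # local import to avoid a cycle

    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["sample_id", "v_call", "j_call", _COUNT_COL]
    missing = [c for c in required if c not in df.columns]
    if "cdr3_aa" not in df.columns and "junction_aa" not in df.columns:
        missing.append("cdr3_aa|junction_aa")
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    if df.empty:
        raise FormatError(f"{path}: no rows")

    counts = pd.to_numeric(df[_COUNT_COL], errors="coerce")
    if counts.isna().any() or (counts < 0).any() or (counts % 1 != 0).any():
        raise ValidationError(
            f"{path}: {_COUNT_COL} must be non-negative integers"
        )
    df[_COUNT_COL] = counts.astype(int)

    if "cdr3_aa" in df.columns:
        cdr3 = df["cdr3_aa"].astype(str)
    else:
        cdr3 = df["junction_aa"].astype(str).str.slice(1, -1)
    df = df.assign(
        cdr3_aa=cdr3,
        v_gene=df["v_call"].map(normalize_gene_name),
        j_gene=df["j_call"].map(normalize_gene_name),
    )
    sample_ids = df["sample_id"].unique()
    if len(sample_ids) != 1:
        raise ValidationError(
            f"{path}: expected a single sample per file, got {list(sample_ids)}"
        )
    merged = (
        df.groupby(["v_gene", "j_gene", "cdr3_aa"], as_index=False)[_COUNT_COL]
        .sum()
        .rename(columns={_COUNT_COL: "count"})
    )
    counts_map = {
        (r.v_gene, r.j_gene, r.cdr3_aa): int(r.count)
        for r in merged.itertuples()
    }
    return ClonotypeTable.from_counts(
        counts_map, sample_id=str(sample_ids[0]), meta=meta
    )


def write_rearrangement_tsv(table, path: str | Path) -> Path:
    """Write a :class:`ClonotypeTable` as an AIRR-style TSV."""
    path = Path(path)
    out = table.df.rename(
        columns={"v_gene": "v_call", "j_gene": "j_call", "count": _COUNT_COL}
    ).copy()
    out.insert(0, "sample_id", table.sample_id)
    out[["sample_id", "v_call", "j_call", "cdr3_aa", _COUNT_COL]].to_csv(
        path, sep="\t", index=False
    )
    return path


# ---------------------------------------------------------------------------
# sample sheet

_SHEET_REQUIRED = ["sample_id", "cohort", "phenotype", "drug", "tissue"]
_TRUE_TOKENS = {"1", "true", "yes", "y"}


def read_sample_sheet(path: str | Path) -> CohortDesign:
    """Read a tab-separated sample sheet into a :class:`CohortDesign`."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    missing = [c for c in _SHEET_REQUIRED if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    samples = []
    for row in df.itertuples():
        hla = str(getattr(row, "hla_flag", "")).strip().lower() in _TRUE_TOKENS
        samples.append(
            SampleMeta(
                sample_id=row.sample_id,
                cohort=row.cohort,
                phenotype=row.phenotype,
                drug=row.drug,
                tissue=row.tissue,
                hla_flag=hla,
            )
        )
    return CohortDesign(samples=samples)


def write_sample_sheet(design: CohortDesign, path: str | Path) -> Path:
    path = Path(path)
    rows = [
        {
            "sample_id": s.sample_id,
            "cohort": s.cohort,
            "phenotype": s.phenotype,
            "drug": s.drug,
            "tissue": s.tissue,
            "hla_flag": int(s.hla_flag),
        }
        for s in design.samples
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    return path
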