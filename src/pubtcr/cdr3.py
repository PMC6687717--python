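"""Segment assignment and CDR3 junction extraction.

Each read is assigned its best-matching germline V segment (ungapped
identity of the V 3' suffix slid along the read) and J segment (J 5' prefix
likewise). The read is then translated in the frame propagated from the V
segment, and the CDR3 is taken as all residues strictly between the
conserved Y[YFLI]C motif at the 3' end of the V region and the [FW]GXGT
motif of the J region — anchors excluded on both sides, which is why the
reported clonotypes (e.g. ``ASSLAGELF``) lack the canonical leading
cysteine of AIRR junctions.

The V motif is the rightmost occurrence inside the translated V span (plus
two residues of slack), the J motif the leftmost occurrence after it:
conserved anchors are the innermost motif hits flanking the junction, and
this choice minimises spurious long CDR3s.
"""
from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view

from .io import GermlineSet, SampleMeta, SequenceRead, ValidationError

V_MOTIF = re.compile(r"(?=(Y[YFLI]C))")  # lookahead: overlapping hits allowed
J_MOTIF = re.compile(r"[FW]G.GT")

MIN_READ_LENGTH = 30
DEFAULT_MIN_IDENTITY = 0.9

def translate(nt: str) -> str:
    """Translate a nucleotide string, ignoring any trailing partial codon.

    Codons containing N translate to ``X``; stops appear as ``*``.
    """
    from Bio.Seq import Seq

    n = len(nt) // 3 * 3
    return str(Seq(nt[:n]).translate())


class EmptyRepertoireError(ValueError):
    """No read in the sample yielded a productive, assigned junction."""


@dataclass(frozen=True)
class SegmentAssignment:
    """Best V/J call for one read.

    ``status`` is ``assigned``, ``unassigned`` (no segment reached the
    identity threshold) or ``incoherent`` (V match ends after the J match
    begins). Coordinates are 0-based half-open positions in the read.
    """

    status: str
    v_name: str | None = None
    j_name: str | None = None
    v_score: float = 0.0
    j_score: float = 0.0
    v_end_nt: int = 0
    j_start_nt: int = 0


@dataclass(frozen=True)
class Junction:
    """Extracted CDR3 with its translation frame.

    ``status`` is ``ok`` or a failure reason (``no_v_motif``, ``no_j_motif``,
    ``empty_cdr3``). ``productive`` means the translated span from the V
    motif through the J motif carries no stop codon; frame consistency is
    guaranteed by searching both motifs in the single V-anchored frame.
    """

    cdr3_aa: str
    productive: bool
    frame_offset: int
    status: str = "ok"


@dataclass(frozen=True)
class Clonotype:
    v_gene: str
    j_gene: str
    cdr3_aa: str
    count: int
    frequency: float

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.v_gene, self.j_gene, self.cdr3_aa)


@dataclass
class ClonotypeTable:
    """Per-sample clonotype counts and frequencies.

    ``total_reads`` is the number of productive, assigned reads (the
    frequency denominator); counts sum to it exactly. ``qc`` holds the
    per-read outcome tallies when the table was built from reads.
    """

    sample_id: str
    df: pd.DataFrame  # columns: v_gene, j_gene, cdr3_aa, count, frequency
    total_reads: int
    meta: SampleMeta | None = None
    qc: dict[str, int] | None = None

    def __post_init__(self):
        if self.total_reads <= 0:
            raise ValidationError(
                f"table {self.sample_id!r}: total_reads must be positive"
            )
        if int(self.df["count"].sum()) != self.total_reads:
            raise ValidationError(
                f"table {self.sample_id!r}: counts sum "
                f"{int(self.df['count'].sum())} != total_reads {self.total_reads}"
            )
        keys = list(zip(self.df.v_gene, self.df.j_gene, self.df.cdr3_aa))
        if len(set(keys)) != len(keys):
            raise ValidationError(
                f"table {self.sample_id!r}: duplicate clonotype keys"
            )
        if abs(self.df["frequency"].sum() - 1.0) > 1e-9:
            raise ValidationError(
                f"table {self.sample_id!r}: frequencies do not sum to 1"
            )
        self._freq = dict(zip(keys, self.df["frequency"]))

    @classmethod
    def from_counts(
        cls,
        counts: Mapping[tuple[str, str, str], int],
        sample_id: str,
        meta: SampleMeta | None = None,
        qc: dict[str, int] | None = None,
    ) -> "ClonotypeTable":
        if not counts:
            raise EmptyRepertoireError("empty_repertoire")
        total = int(sum(counts.values()))
        rows = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
        df = pd.DataFrame(
            {
                "v_gene": [k[0] for k, _ in rows],
                "j_gene": [k[1] for k, _ in rows],
                "cdr3_aa": [k[2] for k, _ in rows],
                "count": [int(c) for _, c in rows],
            }
        )
        df["frequency"] = df["count"] / total
        return cls(
            sample_id=sample_id, df=df, total_reads=total, meta=meta, qc=qc
        )

    def keys(self, level: str = "vjcdr3") -> set:
        if level == "cdr3":
            return set(self.df["cdr3_aa"])
        return set(self._freq)

    def frequency_of(self, key, level: str = "vjcdr3") -> float:
        """Frequency of a clonotype key; 0.0 when absent."""
        if level == "cdr3":
            return float(
                self.df.loc[self.df["cdr3_aa"] == key, "frequency"].sum()
            )
        return self._freq.get(tuple(key), 0.0)

    def count_of(self, key, level: str = "vjcdr3") -> int:
        if level == "cdr3":
            return int(self.df.loc[self.df["cdr3_aa"] == key, "count"].sum())
        f = self._freq.get(tuple(key))
        return 0 if f is None else int(round(f * self.total_reads))

    @property
    def richness(self) -> int:
        return len(self.df)

    def clonotypes(self) -> list[Clonotype]:
        return [
            Clonotype(r.v_gene, r.j_gene, r.cdr3_aa, int(r.count), r.frequency)
            for r in self.df.itertuples()
        ]


# ---------------------------------------------------------------------------
# segment assignment


def _encode(nt: str) -> np.ndarray:
    return np.frombuffer(nt.encode("ascii"), dtype=np.uint8)


class SegmentAligner:
    """Ungapped sliding-identity aligner against a germline set.

    V segments are matched by their 3'-terminal ``v_window`` nucleotides,
    J segments by their 5' ``j_window`` nucleotides. Among equal scores the
    rightmost placement is kept for V and the leftmost for J (innermost
    anchors); ties across genes go to the lexicographically smallest name.
    """

    def __init__(
        self,
        germline: GermlineSet,
        v_window: int = 60,
        j_window: int = 40,
    ):
        self.germline = germline
        self._v = [
            (s.name, _encode(s.nt_sequence[-v_window:]), len(s.nt_sequence), s)
            for s in sorted(germline.v_segments, key=lambda s: s.name)
        ]
        self._j = [
            (s.name, _encode(s.nt_sequence[:j_window]), s)
            for s in sorted(germline.j_segments, key=lambda s: s.name)
        ]

    @staticmethod
    def _scan(read_arr: np.ndarray, seg_arr: np.ndarray, leftmost: bool):
        L = len(seg_arr)
        if L > len(read_arr):
            seg_arr = seg_arr[:len(read_arr)] if leftmost else seg_arr[-len(read_arr):]
            L = len(seg_arr)
        win = sliding_window_view(read_arr, L)
        scores = (win == seg_arr).mean(axis=1)
        if leftmost:
            i = int(np.argmax(scores))
        else:
            i = len(scores) - 1 - int(np.argmax(scores[::-1]))
        return float(scores[i]), i, L

    def assign(
        self, read: SequenceRead, min_identity: float = DEFAULT_MIN_IDENTITY
    ) -> SegmentAssignment:
        if len(read.nt_sequence) < MIN_READ_LENGTH:
            raise ValidationError(
                f"read {read.read_id!r}: shorter than {MIN_READ_LENGTH} nt"
            )
        arr = _encode(read.nt_sequence)

        best_v = None  # (score, name, end, matched_len)
        for name, seg, _, _s in self._v:
            score, off, L = self._scan(arr, seg, leftmost=False)
            if best_v is None or score > best_v[0]:
                best_v = (score, name, off + L, L)
        best_j = None  # (score, name, start)
        for name, seg, _s in self._j:
            score, off, L = self._scan(arr, seg, leftmost=True)
            if best_j is None or score > best_j[0]:
                best_j = (score, name, off)

        if best_v[0] < min_identity or best_j[0] < min_identity:
            return SegmentAssignment(status="unassigned")
        if best_v[2] > best_j[2]:
            return SegmentAssignment(
                status="incoherent",
                v_name=best_v[1],
                j_name=best_j[1],
                v_score=best_v[0],
                j_score=best_j[0],
                v_end_nt=best_v[2],
                j_start_nt=best_j[2],
            )
        return SegmentAssignment(
            status="assigned",
            v_name=best_v[1],
            j_name=best_j[1],
            v_score=best_v[0],
            j_score=best_j[0],
            v_end_nt=best_v[2],
            j_start_nt=best_j[2],
        )


def assign_segments(
    read: SequenceRead,
    germline: GermlineSet,
    min_identity: float = DEFAULT_MIN_IDENTITY,
) -> SegmentAssignment:
    """Assign the best V and J germline segment to one read."""
    return SegmentAligner(germline).assign(read, min_identity=min_identity)


# ---------------------------------------------------------------------------
# junction extraction

_V_SLACK = 2  # residues of slack past the V span when locating Y[YFLI]C


def extract_cdr3(
    read: SequenceRead,
    assignment: SegmentAssignment,
    germline: GermlineSet,
) -> Junction:
    """Extract the CDR3 amino-acid junction given a coherent assignment."""
    if assignment.status != "assigned":
        raise ValidationError(
            f"read {read.read_id!r}: cannot extract from a "
            f"{assignment.status!r} assignment"
        )
    v_seg = germline[assignment.v_name]
    # The matched V suffix ends at v_end_nt; propagate the segment frame.
    frame = (
        assignment.v_end_nt - len(v_seg.nt_sequence) + v_seg.reading_frame_offset
    ) % 3
    aa = translate(read.nt_sequence[frame:])

    # residues whose codons overlap the V span, plus slack
    v_aa_end = -((assignment.v_end_nt - frame) // -3)  # ceil division
    window_end = min(len(aa), v_aa_end + _V_SLACK)
    v_hits = [m.start(1) for m in V_MOTIF.finditer(aa[:window_end])]
    v_hits = [s for s in v_hits if s + 3 <= window_end]
    if not v_hits:
        return Junction("", False, frame, status="no_v_motif")
    v_start = v_hits[-1]  # rightmost
    cdr3_start = v_start + 3  # residue after the conserved C

    m_j = J_MOTIF.search(aa, cdr3_start)
    if m_j is None:
        return Junction("", False, frame, status="no_j_motif")
    cdr3 = aa[cdr3_start : m_j.start()]
    if not cdr3:
        return Junction("", False, frame, status="empty_cdr3")
    productive = "*" not in aa[v_start : m_j.end()]
    return Junction(cdr3, productive, frame, status="ok")


# ---------------------------------------------------------------------------
# per-sample tabulation


def build_clonotype_table(
    reads: Sequence[SequenceRead],
    germline: GermlineSet,
    sample: SampleMeta,
    min_identity: float = DEFAULT_MIN_IDENTITY,
) -> ClonotypeTable:
    """Assign + extract every read and aggregate productive junctions.

    The frequency denominator is the number of productive assigned reads;
    unassigned/incoherent/nonproductive outcomes are tallied in ``table.qc``
    so that ``productive + nonproductive + unassigned + incoherent`` equals
    the number of input reads. Identical reads are processed once.
    """
    if not reads:
        raise ValidationError("no reads supplied")
    aligner = SegmentAligner(germline)
    qc = Counter(
        n_reads=len(reads),
        productive=0,
        nonproductive=0,
        unassigned=0,
        incoherent=0,
    )
    counts: Counter = Counter()
    uniq = Counter(r.nt_sequence for r in reads)
    for nt, mult in uniq.items():
        read = SequenceRead(read_id="u", nt_sequence=nt)
        asn = aligner.assign(read, min_identity=min_identity)
        if asn.status != "assigned":
            qc[asn.status] += mult
            continue
        jct = extract_cdr3(read, asn, germline)
        if jct.status != "ok" or not jct.productive:
            qc["nonproductive"] += mult
            if jct.status != "ok":
                qc[jct.status] += mult
            continue
        qc["productive"] += mult
        counts[(asn.v_name, asn.j_name, jct.cdr3_aa)] += mult
    if not counts:
        raise EmptyRepertoireError("empty_repertoire")
    return ClonotypeTable.from_counts(
        counts, sample_id=sample.sample_id, meta=sample, qc=dict(qc)
    )
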