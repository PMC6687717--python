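"""Cross-sample public-clonotype detection, overlap, clustering, contrasts.

A clonotype is *public* when it is expanded in essentially every case
sample yet undetectable or vanishingly rare in controls. The default
thresholds require presence at >= 1 % of reads in all case samples and a
maximum control frequency below 0.001 % — the regime in which a shared,
drug-specific rearrangement stands out against the private background
repertoire.
"""
from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from ._util import hamming
from .cdr3 import ClonotypeTable
from .io import ValidationError

DEFAULT_MIN_CASE_FRACTION = 1.0
DEFAULT_MIN_CASE_FREQ = 0.01      # 1 % of reads
DEFAULT_MAX_CONTROL_FREQ = 1e-5   # 0.001 %


@dataclass
class PublicClonotypeReport:
    key: tuple
    profile: dict[str, float]  # sample_id -> frequency (cases and controls)
    n_case_present: int
    mean_case_frequency: float
    control_max_frequency: float
    is_public: bool
    specificity_labels: set[tuple[str, str]]  # (drug, phenotype) where seen


@dataclass
class OverlapMatrix:
    """Pairwise shared-clonotype counts; diagonal is per-sample richness."""

    df: pd.DataFrame  # samples x samples, integer cells

    def to_links(self) -> pd.DataFrame:
        rows = []
        ids = list(self.df.index)
        for i, a in enumerate(ids):
            for b in ids[i + 1 :]:
                rows.append(
                    {"source": a, "target": b, "value": int(self.df.loc[a, b])}
                )
        return pd.DataFrame(rows)


@dataclass
class Cdr3Cluster:
    """Clonotypes within one amino-acid substitution of a seed CDR3.

    Membership requires equal length (substitutions only, no indels);
    the seed itself is a member when present, so the cluster frequency is
    never below the seed clonotype's own frequency.
    """

    seed: str
    members: pd.DataFrame  # cdr3_aa, count, frequency, distance
    cluster_frequency: float


@dataclass
class GroupContrast:
    """Per-group summary and pairwise Welch t-tests for one clonotype."""

    key: tuple
    groups: dict[str, tuple[int, float, float | None]]  # label -> (n, mean, se)
    pvalues: dict[tuple[str, str], tuple[float, float] | None]


def _keys(table: ClonotypeTable, level: str) -> set:
    return table.keys(level=level)


def pairwise_overlap(
    tables: Sequence[ClonotypeTable], level: str = "vjcdr3"
) -> OverlapMatrix:
    """Count clonotype keys shared by each sample pair."""
    if len(tables) < 2:
        raise ValidationError("need at least 2 tables")
    ids = [t.sample_id for t in tables]
    keysets = {t.sample_id: _keys(t, level) for t in tables}
    mat = pd.DataFrame(0, index=ids, columns=ids, dtype=int)
    for a, b in itertools.combinations_with_replacement(ids, 2):
        n = len(keysets[a] & keysets[b])
        mat.loc[a, b] = n
        mat.loc[b, a] = n
    return OverlapMatrix(df=mat)


def detect_public(
    case_tables: Sequence[ClonotypeTable],
    control_tables: Sequence[ClonotypeTable],
    min_case_fraction: float = DEFAULT_MIN_CASE_FRACTION,
    min_case_freq: float = DEFAULT_MIN_CASE_FREQ,
    max_control_freq: float = DEFAULT_MAX_CONTROL_FREQ,
    level: str = "vjcdr3",
    include_nonpublic: bool = False,
) -> list[PublicClonotypeReport]:
    """Flag clonotypes expanded across cases and absent/rare in controls.

    A clonotype is public iff it reaches ``min_case_freq`` in at least
    ``min_case_fraction`` of case samples and its maximum control frequency
    is strictly below ``max_control_freq``. Absence is frequency 0 (not
    missing data). Reports are sorted by cases-present then mean case
    frequency, descending; by default only public clonotypes are returned.
    """
    if not case_tables or not control_tables:
        raise ValidationError("case and control collections must be non-empty")
    for name, val in (
        ("min_case_fraction", min_case_fraction),
        ("min_case_freq", min_case_freq),
        ("max_control_freq", max_control_freq),
    ):
        if not 0.0 <= val <= 1.0:
            raise ValidationError(f"{name} must be in [0, 1], got {val}")

    n_cases = len(case_tables)
    needed = math.ceil(min_case_fraction * n_cases - 1e-12)
    candidates: set = set()
    for t in case_tables:
        candidates |= _keys(t, level)

    reports = []
    for key in sorted(candidates):
        case_freqs = {
            t.sample_id: t.frequency_of(key, level=level) for t in case_tables
        }
        ctrl_freqs = {
            t.sample_id: t.frequency_of(key, level=level)
            for t in control_tables
        }
        n_present = sum(1 for f in case_freqs.values() if f >= min_case_freq)
        ctrl_max = max(ctrl_freqs.values())
        is_public = n_present >= needed and ctrl_max < max_control_freq
        if not is_public and not include_nonpublic:
            continue
        labels = {
            (t.meta.drug, t.meta.phenotype)
            for t in case_tables
            if t.meta is not None and case_freqs[t.sample_id] > 0
        }
        reports.append(
            PublicClonotypeReport(
                key=key if level == "cdr3" else tuple(key),
                profile={**case_freqs, **ctrl_freqs},
                n_case_present=n_present,
                mean_case_frequency=float(np.mean(list(case_freqs.values()))),
                control_max_frequency=ctrl_max,
                is_public=is_public,
                specificity_labels=labels,
            )
        )
    reports.sort(key=lambda r: (-r.n_case_present, -r.mean_case_frequency))
    return reports


def cdr3_cluster(seed: str, table: ClonotypeTable) -> Cdr3Cluster:
    """Clonotypes whose CDR3 is within Hamming distance 1 of ``seed``.

    Only equal-length CDR3s qualify (one amino-acid *substitution*); an
    empty cluster is allowed.
    """
    if not seed:
        raise ValidationError("seed must be non-empty")
    rows = []
    for r in table.df.itertuples():
        if len(r.cdr3_aa) != len(seed):
            continue
        d = hamming(r.cdr3_aa, seed)
        if d <= 1:
            rows.append(
                {
                    "cdr3_aa": r.cdr3_aa,
                    "count": int(r.count),
                    "frequency": r.frequency,
                    "distance": d,
                }
            )
    members = pd.DataFrame(
        rows, columns=["cdr3_aa", "count", "frequency", "distance"]
    )
    return Cdr3Cluster(
        seed=seed,
        members=members,
        cluster_frequency=float(members["frequency"].sum()) if rows else 0.0,
    )


def contrast_frequencies(
    freqs_by_group: Mapping[str, Sequence[float]], key: tuple = ()
) -> GroupContrast:
    """Welch two-sided t contrasts between groups of frequencies.

    Groups of size 1 get no standard error and their pairs are skipped.
    Two exactly constant groups compare as t=0, p=1 when equal (and p=0
    when their constants differ), where the Welch statistic is undefined.
    """
    if len(freqs_by_group) < 2:
        raise ValidationError("need at least 2 groups")
    groups: dict[str, tuple[int, float, float | None]] = {}
    arrays: dict[str, np.ndarray] = {}
    for label, freqs in freqs_by_group.items():
        arr = np.asarray(list(freqs), dtype=float)
        if arr.size == 0:
            raise ValidationError(f"group {label!r} is empty")
        se = (
            float(arr.std(ddof=1) / np.sqrt(arr.size)) if arr.size > 1 else None
        )
        groups[label] = (int(arr.size), float(arr.mean()), se)
        arrays[label] = arr

    pvalues: dict[tuple[str, str], tuple[float, float] | None] = {}
    for a, b in itertools.combinations(freqs_by_group, 2):
        xa, xb = arrays[a], arrays[b]
        if xa.size < 2 or xb.size < 2:
            pvalues[(a, b)] = None
            continue
        if (xa == xa[0]).all() and (xb == xb[0]).all():
            same = xa[0] == xb[0]
            pvalues[(a, b)] = (0.0, 1.0) if same else (float("inf"), 0.0)
            continue
        t, p = sps.ttest_ind(xa, xb, equal_var=False)
        pvalues[(a, b)] = (float(t), float(p))
    return GroupContrast(key=key, groups=groups, pvalues=pvalues)


def clonotype_group_contrast(
    key,
    tables_by_group: Mapping[str, Sequence[ClonotypeTable]],
    level: str = "vjcdr3",
) -> GroupContrast:
    """Contrast one clonotype's frequency between sample groups.

    Samples lacking the clonotype contribute frequency 0.
    """
    freqs = {
        label: [t.frequency_of(key, level=level) for t in tables]
        for label, tables in tables_by_group.items()
    }
    return contrast_frequencies(freqs, key=tuple(key) if level != "cdr3" else (key,))
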