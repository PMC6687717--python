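"""Usage, normalisation, pairing, ordination and qPCR-ratio statistics.

These are the per-sample and cohort-level summaries of the clonotype
tables: V/J gene usage vectors, fold changes of a sample's usage against a
control cohort mean, the joint V-J pairing matrix, PCA of usage across
samples, treemap-style ranked clonotype exports, and the TCR-clonotype/CD3
qPCR expression ratio with its detection floor.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from ._util import round_half_up
from .cdr3 import ClonotypeTable
from .io import ValidationError

QPCR_DETECTION_FLOOR = 1e-4


@dataclass
class UsageVector:
    """Per-gene frequency fractions along one axis (V or J); sums to 1."""

    axis: str  # "V" or "J"
    entries: pd.Series  # index: gene, values: frequency
    total_reads: int | None = None

    def __post_init__(self):
        if self.axis not in ("V", "J"):
            raise ValidationError("axis must be V or J")
        if (self.entries < 0).any():
            raise ValidationError("usage entries must be non-negative")
        if abs(float(self.entries.sum()) - 1.0) > 1e-9:
            raise ValidationError("usage entries must sum to 1")


@dataclass
class FoldChangeVector:
    entries: pd.Series  # index: gene, values: fold change
    scale: str = "linear"  # or "log10"


@dataclass
class VJPairingMatrix:
    """Joint V x J rearrangement frequencies; cells sum to 1."""

    df: pd.DataFrame  # rows: V genes, cols: J genes

    def __post_init__(self):
        if abs(float(self.df.to_numpy().sum()) - 1.0) > 1e-9:
            raise ValidationError("pairing cells must sum to 1")

    def row_usage(self) -> pd.Series:
        return self.df.sum(axis=1)

    def col_usage(self) -> pd.Series:
        return self.df.sum(axis=0)

    def to_links(self) -> pd.DataFrame:
        """Long (source, target, value) table, e.g. for Circos-style plots."""
        long = self.df.stack().reset_index()
        long.columns = ["source", "target", "value"]
        return long[long["value"] > 0].reset_index(drop=True)


@dataclass
class PcaResult:
    scores: pd.DataFrame  # samples x components
    explained_variance: np.ndarray  # fraction per component
    loadings: pd.DataFrame  # genes x components


@dataclass
class QpcrMeasurement:
    ct_target: float | None
    ct_reference: float
    ratio: float
    floored: bool


@dataclass
class TreemapEntry:
    label: str
    frequency: float
    area: float


def usage_vector(table: ClonotypeTable, axis: str) -> UsageVector:
    """Gene usage: summed clonotype counts per gene over total reads."""
    if axis not in ("V", "J"):
        raise ValidationError("axis must be V or J")
    col = "v_gene" if axis == "V" else "j_gene"
    freq = (
        table.df.groupby(col)["count"].sum().sort_index() / table.total_reads
    )
    return UsageVector(axis=axis, entries=freq, total_reads=table.total_reads)


def normalize_to_cohort(
    sample_usage: UsageVector,
    control_usages: Sequence[UsageVector],
    pseudocount: float | None = None,
    scale: str = "linear",
) -> FoldChangeVector:
    """Per-gene fold change of a sample against the control cohort mean.

    ``pseudocount`` defaults to ``1 / (2 * max total_reads)`` over the
    sample and controls when read totals are known (below one-read
    resolution, avoids division by zero for genes unseen in controls),
    otherwise to 0.
    """
    if not control_usages:
        raise ValidationError("control collection is empty")
    if any(u.axis != sample_usage.axis for u in control_usages):
        raise ValidationError("axis mismatch between sample and controls")
    if scale not in ("linear", "log10"):
        raise ValidationError(f"unknown scale {scale!r}")
    if pseudocount is None:
        totals = [
            u.total_reads
            for u in [sample_usage, *control_usages]
            if u.total_reads is not None
        ]
        pseudocount = 1.0 / (2.0 * max(totals)) if totals else 0.0

    genes = sample_usage.entries.index
    for u in control_usages:
        genes = genes.union(u.entries.index)
    sample = sample_usage.entries.reindex(genes, fill_value=0.0)
    ctrl = pd.concat(
        [u.entries.reindex(genes, fill_value=0.0) for u in control_usages],
        axis=1,
    ).mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        fc = (sample + pseudocount) / (ctrl + pseudocount)
    if scale == "log10":
        fc = np.log10(fc)
    return FoldChangeVector(entries=fc, scale=scale)


def vj_pairing_matrix(table: ClonotypeTable) -> VJPairingMatrix:
    """Joint V-J frequencies; marginals equal the usage vectors exactly."""
    mat = (
        table.df.pivot_table(
            index="v_gene",
            columns="j_gene",
            values="count",
            aggfunc="sum",
            fill_value=0,
        ).sort_index(axis=0).sort_index(axis=1)
        / table.total_reads
    )
    return VJPairingMatrix(df=mat)


def cohort_mean_pairing(
    matrices: Sequence[VJPairingMatrix],
) -> VJPairingMatrix:
    """Elementwise mean of pairing matrices on union-aligned axes."""
    if not matrices:
        raise ValidationError("no pairing matrices supplied")
    rows = matrices[0].df.index
    cols = matrices[0].df.columns
    for m in matrices[1:]:
        rows = rows.union(m.df.index)
        cols = cols.union(m.df.columns)
    aligned = [
        m.df.reindex(index=rows, columns=cols, fill_value=0.0)
        for m in matrices
    ]
    return VJPairingMatrix(df=sum(aligned) / len(aligned))


def usage_pca(
    cohort_usages: Mapping[str, UsageVector], k: int
) -> PcaResult:
    """PCA (SVD of the column-centered usage matrix) across samples.

    Usage vectors are compositional fractions already, so no unit-variance
    scaling is applied. Explained-variance fractions are singular values
    squared over their total; with zero total variance (identical samples)
    they are reported as zeros.
    """
    if len(cohort_usages) < 2:
        raise ValidationError("PCA needs at least 2 samples")
    sample_ids = list(cohort_usages)
    genes = None
    for u in cohort_usages.values():
        genes = u.entries.index if genes is None else genes.union(u.entries.index)
    X = np.vstack(
        [
            cohort_usages[s].entries.reindex(genes, fill_value=0.0).to_numpy()
            for s in sample_ids
        ]
    )
    max_k = min(len(genes), len(sample_ids) - 1)
    if not 1 <= k <= max_k:
        raise ValidationError(f"k must be in [1, {max_k}], got {k}")
    Xc = X - X.mean(axis=0, keepdims=True)
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    total = float((S**2).sum())
    explained = (S[:k] ** 2 / total) if total > 0 else np.zeros(k)
    comp = [f"PC{i + 1}" for i in range(k)]
    scores = pd.DataFrame(
        (U[:, :k] * S[:k]), index=sample_ids, columns=comp
    )
    loadings = pd.DataFrame(Vt[:k].T, index=genes, columns=comp)
    return PcaResult(
        scores=scores, explained_variance=np.asarray(explained), loadings=loadings
    )


def treemap_export(table: ClonotypeTable, top_n: int) -> list[TreemapEntry]:
    """Top clonotypes ranked by count, with residual mass as ``other``.

    Area weights are frequencies, so entries plus ``other`` sum to 1.
    """
    if top_n < 1:
        raise ValidationError("top_n must be >= 1")
    df = table.df.sort_values(
        ["count", "cdr3_aa", "v_gene", "j_gene"],
        ascending=[False, True, True, True],
    )
    head = df.head(top_n)
    out = [
        TreemapEntry(
            label=f"{r.cdr3_aa}|{r.v_gene}|{r.j_gene}",
            frequency=r.frequency,
            area=r.frequency,
        )
        for r in head.itertuples()
    ]
    residual = float(df["frequency"].iloc[top_n:].sum())
    if residual > 0:
        out.append(TreemapEntry(label="other", frequency=residual, area=residual))
    return out


def qpcr_ratio(
    ct_target: float | None,
    ct_reference: float,
    floor: float = QPCR_DETECTION_FLOOR,
) -> QpcrMeasurement:
    """TCR-clonotype/CD3 expression ratio ``2^(Ct_ref - Ct_target)``.

    Ratios below the assay's detection limit, and "not detected" targets
    (``ct_target`` of None/NaN), are floored at that limit. No PCR
    efficiency correction is applied.
    """
    if ct_reference is None or np.isnan(ct_reference):
        raise ValidationError("reference Ct is required")
    if ct_target is None or np.isnan(ct_target):
        return QpcrMeasurement(None, ct_reference, floor, floored=True)
    ratio = float(2.0 ** (ct_reference - ct_target))
    if ratio < floor:
        return QpcrMeasurement(ct_target, ct_reference, floor, floored=True)
    return QpcrMeasurement(ct_target, ct_reference, ratio, floored=False)
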