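"""Single-cell paired alpha/beta chain summaries and expression matrices.

Each sorted cell carries a beta-chain CDR3 call, usually an alpha-chain
CDR3 call, and expression values over a small functional gene panel
(cytotoxicity, cytokine and differentiation markers). Pairing summaries
report, per beta clonotype, how the alpha clonotypes distribute across its
cells; a rare secondary alpha chain is kept in an auxiliary field and
excluded from pairing percentages.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from ._util import round_half_up
from .io import ValidationError

DEFAULT_PANEL = [
    "GNLY", "GZMB", "PRF1", "IFNG", "TNF", "IL2", "IL4", "IL10", "IL12A",
    "IL17A", "FOXP3", "RORC", "TBX21", "GATA3", "CCR7", "SELL", "PDCD1",
    "CTLA4",
]


@dataclass
class SingleCellClone:
    """One cell's chain calls plus panel-gene expression values."""

    cell_id: str
    beta_cdr3: str | None = None
    alpha_cdr3: str | None = None
    beta_v: str | None = None
    beta_j: str | None = None
    alpha_v: str | None = None
    alpha_j: str | None = None
    secondary_alpha_cdr3: str | None = None
    gene_counts: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if self.beta_cdr3 is None and self.alpha_cdr3 is None:
            raise ValidationError(
                f"cell {self.cell_id!r}: at least one chain call required"
            )


@dataclass
class PairingSummary:
    """Alpha-clonotype distribution per beta clonotype.

    ``pairs`` columns: beta_cdr3, alpha_cdr3, n_cells, percent — the percent
    denominator is the number of cells carrying that beta clonotype, so the
    alpha percentages plus the missing-alpha share sum to 100 per beta.
    Percentages are rounded half-up to two decimals.
    """

    n_total: int
    pairs: pd.DataFrame
    beta_totals: pd.DataFrame  # beta_cdr3, n_cells, percent (of all cells)
    n_missing_alpha: int


def summarize_pairing(cells: Sequence[SingleCellClone]) -> PairingSummary:
    """Group cells by beta then alpha CDR3 and report counts/percentages."""
    if not cells:
        raise ValidationError("no cells supplied")
    n_total = len(cells)
    df = pd.DataFrame(
        {
            "beta_cdr3": [c.beta_cdr3 for c in cells],
            "alpha_cdr3": [c.alpha_cdr3 for c in cells],
        }
    )
    with_beta = df[df["beta_cdr3"].notna()]
    beta_sizes = with_beta.groupby("beta_cdr3").size()

    beta_rows = [
        {
            "beta_cdr3": b,
            "n_cells": int(n),
            "percent": round_half_up(100.0 * n / n_total),
        }
        for b, n in beta_sizes.sort_values(ascending=False).items()
    ]
    paired = with_beta[with_beta["alpha_cdr3"].notna()]
    pair_rows = []
    for (b, a), n in (
        paired.groupby(["beta_cdr3", "alpha_cdr3"])
        .size()
        .sort_values(ascending=False)
        .items()
    ):
        pair_rows.append(
            {
                "beta_cdr3": b,
                "alpha_cdr3": a,
                "n_cells": int(n),
                "percent": round_half_up(100.0 * n / beta_sizes[b]),
            }
        )
    n_missing = int(df["alpha_cdr3"].isna().sum())
    return PairingSummary(
        n_total=n_total,
        pairs=pd.DataFrame(
            pair_rows, columns=["beta_cdr3", "alpha_cdr3", "n_cells", "percent"]
        ),
        beta_totals=pd.DataFrame(
            beta_rows, columns=["beta_cdr3", "n_cells", "percent"]
        ),
        n_missing_alpha=n_missing,
    )


@dataclass
class ExpressionMatrix:
    values: pd.DataFrame  # cells x genes, ordered by (beta, alpha, cell_id)
    annotations: pd.DataFrame  # per-cell beta_cdr3 / alpha_cdr3


def expression_matrix(
    cells: Sequence[SingleCellClone],
    panel: Sequence[str] = DEFAULT_PANEL,
    transform: str = "none",
) -> ExpressionMatrix:
    """Cells-by-genes expression matrix with pairing annotation.

    Rows are ordered by (beta CDR3, alpha CDR3, cell id) so the layout is
    invariant under shuffling of the input; absent genes fill 0. The only
    supported transform beyond raw values is ``log1p``.
    """
    if not panel:
        raise ValidationError("panel must be non-empty")
    if transform not in ("none", "log1p"):
        raise ValidationError(f"unknown transform {transform!r}")
    order = sorted(
        cells, key=lambda c: (c.beta_cdr3 or "", c.alpha_cdr3 or "", c.cell_id)
    )
    values = pd.DataFrame(
        [[float(c.gene_counts.get(g, 0.0)) for g in panel] for c in order],
        index=[c.cell_id for c in order],
        columns=list(panel),
    )
    if transform == "log1p":
        values = np.log1p(values)
    annotations = pd.DataFrame(
        {
            "beta_cdr3": [c.beta_cdr3 for c in order],
            "alpha_cdr3": [c.alpha_cdr3 for c in order],
        },
        index=values.index,
    )
    return ExpressionMatrix(values=values, annotations=annotations)


def read_single_cell_tsv(path: str | Path) -> list[SingleCellClone]:
    """Read a per-cell TSV (cell_id, chain calls, one column per gene)."""
    df = pd.read_csv(path, sep="\t", dtype={"cell_id": str})
    meta_cols = {
        "cell_id", "beta_cdr3", "alpha_cdr3", "beta_v", "beta_j",
        "alpha_v", "alpha_j", "secondary_alpha_cdr3",
    }
    gene_cols = [c for c in df.columns if c not in meta_cols]
    cells = []
    for row in df.itertuples():
        def _get(name):
            val = getattr(row, name, None)
            return None if val is None or pd.isna(val) else str(val)

        cells.append(
            SingleCellClone(
                cell_id=str(row.cell_id),
                beta_cdr3=_get("beta_cdr3"),
                alpha_cdr3=_get("alpha_cdr3"),
                beta_v=_get("beta_v"),
                beta_j=_get("beta_j"),
                alpha_v=_get("alpha_v"),
                alpha_j=_get("alpha_j"),
                secondary_alpha_cdr3=_get("secondary_alpha_cdr3"),
                gene_counts={g: float(getattr(row, g)) for g in gene_cols},
            )
        )
    return cells


def write_single_cell_tsv(
    cells: Sequence[SingleCellClone],
    path: str | Path,
    panel: Sequence[str] = DEFAULT_PANEL,
) -> Path:
    path = Path(path)
    rows = []
    for c in cells:
        row = {
            "cell_id": c.cell_id,
            "beta_cdr3": c.beta_cdr3,
            "alpha_cdr3": c.alpha_cdr3,
            "beta_v": c.beta_v,
            "beta_j": c.beta_j,
            "alpha_v": c.alpha_v,
            "alpha_j": c.alpha_j,
            "secondary_alpha_cdr3": c.secondary_alpha_cdr3,
        }
        for g in panel:
            row[g] = c.gene_counts.get(g, 0.0)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    return path
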