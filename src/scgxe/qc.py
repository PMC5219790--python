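"""TPM normalisation, detected-gene counting and cell exclusion rules.

Counts are normalised to transcripts per million (TPM): per cell, each gene's
count is divided by its (exonic) length, and the resulting rates are scaled to
sum to 1e6.  A gene counts as "detected" in a cell when its TPM is at least 1
(inclusive).  Cells are excluded when flagged as visually confirmed doublets,
when their detected-gene count is more similar to the bulk controls than to
single cells (operationalised as exceeding the midpoint between the
single-cell and bulk median detected-gene counts), or when their starting
cDNA concentration falls below a configured floor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "QCConfig",
    "QCReport",
    "tpm_normalize",
    "detected_genes",
    "filter_cells",
]


@dataclass
class ExpressionMatrix:
    """Gene x cell nonnegative expression values (counts or TPM)."""

    values: np.ndarray
    gene_ids: list
    cell_ids: list
    unit: str = "counts"  # "counts" | "TPM"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = list(self.gene_ids)
        self.cell_ids = list(self.cell_ids)
        if self.values.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise ValueError("values shape does not match gene/cell id lengths")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("gene ids must be unique")
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise ValueError("cell ids must be unique")
        if np.any(self.values < 0):
            raise ValueError("expression values must be nonnegative")
        if self.unit not in ("counts", "TPM"):
            raise ValueError("unit must be 'counts' or 'TPM'")
        if self.unit == "TPM":
            sums = self.values.sum(axis=0)
            nz = sums > 0
            if np.any(np.abs(sums[nz] - 1e6) > 1.0):
                raise ValueError("TPM columns must sum to 1e6")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.cell_ids)

    def subset_cells(self, keep_ids) -> "ExpressionMatrix":
        idx = [self.cell_ids.index(c) for c in keep_ids]
        return ExpressionMatrix(self.values[:, idx], self.gene_ids, list(keep_ids), self.unit)


@dataclass
class QCConfig:
    doublet_col: str = "doublet"
    bead_contact_col: str = "bead_contact"   # consumed as metadata, not a filter
    cdna_col: str = "cdna_ng_ul"
    cdna_floor: float = 0.05                  # ng/ul
    bulk_col: str = "is_bulk"
    bulk_rule: bool = True
    detected_threshold: float = 1.0           # TPM for a gene to count as detected
    detected_cutoff: float | None = None      # explicit bulk-similarity cutoff


@dataclass
class QCReport:
    per_cell: pd.DataFrame       # detected_genes, flags, pass/fail, reason
    detected_cutoff: float | None
    excluded: list = field(default_factory=list)


def tpm_normalize(counts: ExpressionMatrix, gene_lengths) -> ExpressionMatrix:
    """TPM_gc = (count_gc / length_g) / sum_g'(count_g'c / length_g') * 1e6."""
    if counts.unit != "counts":
        raise ValueError("input must be in counts")
    lengths = np.asarray(
        gene_lengths.reindex(counts.gene_ids) if isinstance(gene_lengths, pd.Series)
        else gene_lengths,
        dtype=float,
    )
    if lengths.shape[0] != len(counts.gene_ids) or np.any(~np.isfinite(lengths)):
        raise ValueError("gene lengths must cover all genes")
    if np.any(lengths <= 0):
        raise ValueError("gene lengths must be positive")
    rates = counts.values / lengths[:, None]
    colsum = rates.sum(axis=0)
    zero = colsum == 0
    if zero.any():
        warnings.warn(
            f"{int(zero.sum())} all-zero cell column(s) yield all-zero TPM: "
            f"{[counts.cell_ids[i] for i in np.flatnonzero(zero)[:5]]}"
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        tpm = np.where(zero[None, :], 0.0, rates / np.where(zero, 1.0, colsum)[None, :] * 1e6)
    return ExpressionMatrix(tpm, counts.gene_ids, counts.cell_ids, unit="TPM")


def detected_genes(tpm: ExpressionMatrix, threshold: float = 1.0) -> pd.Series:
    """Per-cell count of genes with TPM >= threshold ("at least", inclusive)."""
    if tpm.unit != "TPM":
        raise ValueError("detected_genes expects TPM input")
    counts = (tpm.values >= threshold).sum(axis=0)
    return pd.Series(counts, index=tpm.cell_ids, name="detected_genes")


def filter_cells(
    expr: ExpressionMatrix,
    meta: pd.DataFrame,
    config: QCConfig | None = None,
) -> tuple[ExpressionMatrix, QCReport]:
    """Apply the exclusion rules; returns the filtered matrix and a QC report.

    ``meta`` is indexed by cell id and may carry more cells than ``expr``
    (notably the bulk control samples, which anchor the bulk-similarity
    cutoff even after they have been removed from the matrix).  Gene order
    and gene set are never touched.
    """
    config = config or QCConfig()
    if expr.unit != "TPM":
        raise ValueError("filter_cells expects a TPM matrix")
    det = detected_genes(expr, config.detected_threshold)
    missing = [c for c in expr.cell_ids if c not in meta.index]
    if missing:
        raise ValueError(f"metadata missing cells: {missing[:5]}")

    cutoff = config.detected_cutoff
    if config.bulk_rule and cutoff is None:
        if config.bulk_col not in meta.columns or not meta[config.bulk_col].any():
            raise ValueError(
                "bulk-similarity rule enabled but no bulk controls in metadata"
            )

        def _detected(cell):
            # in-matrix cells are recomputed; others use the recorded count
            if cell in det.index:
                return float(det[cell])
            if "detected_genes" in meta.columns and pd.notna(meta.loc[cell, "detected_genes"]):
                return float(meta.loc[cell, "detected_genes"])
            return None

        is_bulk = meta[config.bulk_col].astype(bool)
        bulk_vals = [v for c in meta.index[is_bulk] if (v := _detected(c)) is not None]
        sc_vals = [v for c in meta.index[~is_bulk] if (v := _detected(c)) is not None]
        if not bulk_vals:
            raise ValueError(
                "bulk controls absent from the matrix and no 'detected_genes' "
                "column records them in metadata"
            )
        cutoff = (float(np.median(sc_vals)) + float(np.median(bulk_vals))) / 2

    records = []
    for cell in expr.cell_ids:
        row = meta.loc[cell]
        reasons = []
        if config.bulk_col in meta.columns and bool(row.get(config.bulk_col, False)):
            reasons.append("bulk_control")
        if config.doublet_col in meta.columns and bool(row.get(config.doublet_col, False)):
            reasons.append("doublet")
        if config.bulk_rule and cutoff is not None and det[cell] > cutoff:
            if "bulk_control" not in reasons:
                reasons.append("bulk_similar")
        if config.cdna_col in meta.columns:
            cdna = row.get(config.cdna_col, np.nan)
            if pd.notna(cdna) and float(cdna) < config.cdna_floor:
                reasons.append("low_cdna")
        records.append(
            {
                "cell_id": cell,
                "detected_genes": int(det[cell]),
                "doublet": "doublet" in reasons,
                "bulk_similarity": "bulk_similar" in reasons or "bulk_control" in reasons,
                "low_cdna": "low_cdna" in reasons,
                "pass": not reasons,
                "reason": ";".join(reasons),
            }
        )
    report_df = pd.DataFrame(records).set_index("cell_id")
    keep = report_df.index[report_df["pass"]].tolist()
    excluded = report_df.index[~report_df["pass"]].tolist()
    filtered = expr.subset_cells(keep)
    return filtered, QCReport(per_cell=report_df, detected_cutoff=cutoff, excluded=excluded)
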