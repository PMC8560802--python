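"""QC filtering, log-normalization and variable-gene selection.

QC mirrors the usual droplet-data rules: drop observations detecting fewer
than ``min_genes`` genes, with a mitochondrial UMI fraction above
``max_mito_frac``, or (for nucleus data, where barcode collisions inflate
totals) with more than ``max_umi`` total UMIs.

Normalization is global depth normalization followed by log1p:
``value = log(1 + scale_factor * count / total)``.  The bespoke statistics
downstream (spatial coherence, rank-sum markers, set overlaps) are rank- or
overlap-based, so this deliberately simple normalization family suffices;
variance-stabilizing alternatives would not change their inputs' ranks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import CellDataset, NormalizedMatrix

__all__ = ["QCParams", "QCReport", "qc_filter", "lognormalize", "select_variable_genes"]


@dataclass
class QCParams:
    """Quality-control thresholds.

    min_genes : minimum detected genes per observation (default 200)
    max_mito_frac : maximum mitochondrial fraction of UMIs (default 0.20)
    max_umi : maximum total UMIs, or None to disable (use 1_000_000 for
        nucleus data)
    mito_prefix : gene-name prefix identifying mitochondrial genes when the
        dataset carries no explicit flags (default "mt-", matched
        case-insensitively)
    """

    min_genes: int = 200
    max_mito_frac: float = 0.20
    max_umi: int | None = None
    mito_prefix: str = "mt-"

    def __post_init__(self):
        if not (0.0 <= self.max_mito_frac <= 1.0):
            raise ValueError("max_mito_frac must lie in [0, 1]")
        if self.min_genes < 0:
            raise ValueError("min_genes must be >= 0")


@dataclass
class QCReport:
    n_input: int
    n_kept: int
    removed_low_genes: int
    removed_high_mito: int
    removed_high_umi: int

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_kept": self.n_kept,
            "removed_low_genes": self.removed_low_genes,
            "removed_high_mito": self.removed_high_mito,
            "removed_high_umi": self.removed_high_umi,
        }


def qc_filter(data: CellDataset, params: QCParams) -> tuple[CellDataset, QCReport]:
    """Filter observations by detected genes, mito fraction, and UMI total.

    A cell failing several criteria is counted once per criterion in the
    report but removed only once.  Raises if no cell survives.
    """
    counts = np.asarray(data.counts)
    if data.mito_gene_flags is not None:
        mito = data.mito_gene_flags
    else:
        prefix = params.mito_prefix.lower()
        mito = np.array([str(g).lower().startswith(prefix) for g in data.gene_ids])

    detected = (counts > 0).sum(axis=1)
    totals = counts.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(totals > 0, counts[:, mito].sum(axis=1) / np.maximum(totals, 1), 0.0)

    fail_genes = detected < params.min_genes
    fail_mito = mito_frac > params.max_mito_frac
    fail_umi = (
        totals > params.max_umi if params.max_umi is not None else np.zeros(len(totals), bool)
    )
    keep = ~(fail_genes | fail_mito | fail_umi)
    report = QCReport(
        n_input=data.n_cells,
        n_kept=int(keep.sum()),
        removed_low_genes=int(fail_genes.sum()),
        removed_high_mito=int(fail_mito.sum()),
        removed_high_umi=int(fail_umi.sum()),
    )
    if report.n_kept == 0:
        raise ValueError("QC filter removed every observation")
    return data.subset_cells(keep), report


def lognormalize(counts, scale_factor: float = 1e4, gene_ids=None, obs_ids=None) -> NormalizedMatrix:
    """Depth-normalize and log-transform counts.

    ``value(i, g) = log(1 + scale_factor * count(i, g) / total(i))``.
    Rows with zero total map to all-zero rows (with a warning).
    """
    counts = np.asarray(counts, dtype=float)
    if (counts < 0).any():
        raise ValueError("counts must be nonnegative")
    totals = counts.sum(axis=1, keepdims=True)
    zero_rows = totals[:, 0] == 0
    if zero_rows.any():
        warnings.warn(
            f"{int(zero_rows.sum())} observations have zero total counts; "
            "their normalized rows are all zero",
            stacklevel=2,
        )
    values = np.log1p(scale_factor * counts / np.where(totals > 0, totals, 1.0))
    n, g = counts.shape
    if gene_ids is None:
        gene_ids = np.array([f"g{i}" for i in range(g)], dtype=object)
    if obs_ids is None:
        obs_ids = np.array([f"obs{i}" for i in range(n)], dtype=object)
    return NormalizedMatrix(
        values=values,
        gene_ids=gene_ids,
        obs_ids=obs_ids,
        scale_factor=float(scale_factor),
    )


def normalize_dataset(data, scale_factor: float = 1e4) -> NormalizedMatrix:
    """lognormalize a SpotDataset or CellDataset, carrying its ids."""
    obs_ids = getattr(data, "spot_ids", None)
    if obs_ids is None:
        obs_ids = data.cell_ids
    return lognormalize(
        data.counts, scale_factor=scale_factor, gene_ids=data.gene_ids, obs_ids=obs_ids
    )


def select_variable_genes(norm: NormalizedMatrix, n_top: int, n_bins: int = 20) -> list[str]:
    """Top-``n_top`` genes by binned standardized dispersion.

    Dispersion = variance / mean of the normalized values per gene; genes
    are placed in ``n_bins`` equal-count bins by mean expression and the
    dispersion is z-scored within each bin, which removes the trivial
    mean-dispersion trend.  Ties (and the all-constant degenerate case)
    break lexicographically on gene id.
    """
    if n_top > len(norm.gene_ids):
        raise ValueError("n_top exceeds the number of genes")
    values = norm.values
    means = values.mean(axis=0)
    var = values.var(axis=0, ddof=1) if values.shape[0] > 1 else np.zeros_like(means)
    with np.errstate(invalid="ignore", divide="ignore"):
        dispersion = np.where(means > 0, var / means, 0.0)

    if np.allclose(var, 0.0):
        warnings.warn("all genes constant: returning lexicographically first genes", stacklevel=2)
        return sorted(map(str, norm.gene_ids))[:n_top]

    df = pd.DataFrame(
        {"gene": norm.gene_ids.astype(str), "mean": means, "disp": dispersion}
    )
    # equal-count bins by mean; rank first so ties in mean split stably
    order_key = df["mean"].rank(method="first")
    df["bin"] = pd.qcut(order_key, q=min(n_bins, len(df)), labels=False, duplicates="drop")
    def _z(x: pd.Series) -> pd.Series:
        sd = x.std(ddof=1)
        if not np.isfinite(sd) or sd == 0:
            return pd.Series(np.zeros(len(x)), index=x.index)
        return (x - x.mean()) / sd

    df["z"] = df.groupby("bin")["disp"].transform(_z)
    # z ties (e.g. singleton bins) fall back to raw dispersion, then name
    df = df.sort_values(
        ["z", "disp", "gene"], ascending=[False, False, True], kind="mergesort"
    )
    return df["gene"].head(n_top).tolist()
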