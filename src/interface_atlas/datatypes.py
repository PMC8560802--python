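"""Core in-memory containers shared across the pipeline.

Everything downstream operates on three kinds of object: a spot-level
spatial dataset (counts + 2-D coordinates + cluster labels), a cell- or
nucleus-level dataset (counts + cluster labels), and named gene-set
collections.  Containers are plain dataclasses over numpy/pandas so the
statistics modules stay free of any particular I/O framework; a
``to_anndata`` convenience is provided for interoperability.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SpotDataset",
    "CellDataset",
    "GeneSetCollection",
    "NormalizedMatrix",
    "MarkerTable",
    "InterfaceGeneCall",
]


def _check_ids(ids, what: str) -> np.ndarray:
    arr = np.asarray(ids, dtype=object)
    if len(set(arr)) != len(arr):
        raise ValueError(f"duplicate {what} identifiers")
    return arr


@dataclass
class SpotDataset:
    """A spot-by-gene count matrix with spatial coordinates.

    counts : (n_spots, n_genes) nonnegative integer array
    coords : (n_spots, 2) array of spot-center positions (x, y); units are
        whatever the positions file uses (µm for synthetic data, pixels for
        Visium exports) — every distance statistic downstream is rank-based
        and therefore unit-invariant.
    cluster_of_spot : per-spot categorical label (e.g. tumor / interface /
        muscle), supplied by the caller; clustering itself is out of scope.
    """

    counts: np.ndarray
    coords: np.ndarray
    spot_ids: np.ndarray
    gene_ids: np.ndarray
    cluster_of_spot: np.ndarray

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        self.coords = np.asarray(self.coords, dtype=float)
        self.spot_ids = _check_ids(self.spot_ids, "spot")
        self.gene_ids = _check_ids(self.gene_ids, "gene")
        self.cluster_of_spot = np.asarray(self.cluster_of_spot, dtype=object)
        n, g = self.counts.shape
        if self.coords.shape != (n, 2):
            raise ValueError("coords must be (n_spots, 2)")
        if len(self.spot_ids) != n or len(self.gene_ids) != g:
            raise ValueError("id lengths inconsistent with counts shape")
        if len(self.cluster_of_spot) != n:
            raise ValueError("cluster labels inconsistent with counts shape")
        if np.unique(self.coords, axis=0).shape[0] != n:
            raise ValueError("spot coordinates must be unique")
        if (self.counts < 0).any():
            raise ValueError("counts must be nonnegative")

    @property
    def n_spots(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    def subset_spots(self, mask_or_index) -> "SpotDataset":
        idx = np.asarray(mask_or_index)
        return SpotDataset(
            counts=self.counts[idx],
            coords=self.coords[idx],
            spot_ids=self.spot_ids[idx],
            gene_ids=self.gene_ids,
            cluster_of_spot=self.cluster_of_spot[idx],
        )

    def to_anndata(self):
        import anndata as ad

        adata = ad.AnnData(
            X=self.counts,
            obs=pd.DataFrame(
                {"cluster": self.cluster_of_spot}, index=self.spot_ids.astype(str)
            ),
            var=pd.DataFrame(index=self.gene_ids.astype(str)),
        )
        adata.obsm["spatial"] = self.coords.copy()
        return adata


@dataclass
class CellDataset:
    """A cell- or nucleus-by-gene count matrix with cluster labels."""

    counts: np.ndarray
    cell_ids: np.ndarray
    gene_ids: np.ndarray
    cluster_of_cell: np.ndarray
    modality: str = "cell"
    mito_gene_flags: np.ndarray | None = None

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        self.cell_ids = _check_ids(self.cell_ids, "cell")
        self.gene_ids = _check_ids(self.gene_ids, "gene")
        self.cluster_of_cell = np.asarray(self.cluster_of_cell, dtype=object)
        if self.modality not in ("cell", "nucleus"):
            raise ValueError("modality must be 'cell' or 'nucleus'")
        n, g = self.counts.shape
        if len(self.cell_ids) != n or len(self.gene_ids) != g:
            raise ValueError("id lengths inconsistent with counts shape")
        if len(self.cluster_of_cell) != n:
            raise ValueError("cluster labels inconsistent with counts shape")
        if (self.counts < 0).any():
            raise ValueError("counts must be nonnegative")
        if self.mito_gene_flags is not None:
            self.mito_gene_flags = np.asarray(self.mito_gene_flags, dtype=bool)
            if len(self.mito_gene_flags) != g:
                raise ValueError("mito_gene_flags length mismatch")

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    def subset_cells(self, mask_or_index) -> "CellDataset":
        idx = np.asarray(mask_or_index)
        return CellDataset(
            counts=self.counts[idx],
            cell_ids=self.cell_ids[idx],
            gene_ids=self.gene_ids,
            cluster_of_cell=self.cluster_of_cell[idx],
            modality=self.modality,
            mito_gene_flags=self.mito_gene_flags,
        )

    def to_anndata(self):
        import anndata as ad

        adata = ad.AnnData(
            X=self.counts,
            obs=pd.DataFrame(
                {"cluster": self.cluster_of_cell}, index=self.cell_ids.astype(str)
            ),
            var=pd.DataFrame(index=self.gene_ids.astype(str)),
        )
        if self.mito_gene_flags is not None:
            adata.var["mito"] = self.mito_gene_flags
        adata.uns["modality"] = self.modality
        return adata


@dataclass
class GeneSetCollection:
    """Named gene lists over a common universe.

    Every set is harmonized to be a subset of the universe on construction;
    genes falling outside are dropped (the count of dropped genes is
    recorded per set in ``n_dropped``).
    """

    sets: dict[str, list[str]]
    universe: list[str]
    provenance: str = ""
    n_dropped: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        if len(set(self.sets)) != len(self.sets):  # dict keys already unique
            raise ValueError("duplicate set names")
        uni = set(self.universe)
        if len(uni) != len(self.universe):
            raise ValueError("duplicate genes in universe")
        harmonized = {}
        for name, genes in self.sets.items():
            kept = [g for g in genes if g in uni]
            dropped = len(genes) - len(kept)
            if dropped and name not in self.n_dropped:
                self.n_dropped[name] = dropped
            harmonized[name] = kept
        self.sets = harmonized

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def names(self) -> list[str]:
        return list(self.sets)


@dataclass
class NormalizedMatrix:
    """Log-normalized expression: ``log1p(scale_factor * count / total)``.

    ``values`` is observations x genes on the natural-log scale.  Rows with
    zero total counts are all zero.  ``expm1`` of a row recovers relative
    abundances scaled by ``scale_factor``.
    """

    values: np.ndarray
    gene_ids: np.ndarray
    obs_ids: np.ndarray
    scale_factor: float = 1e4
    source: object = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.obs_ids = np.asarray(self.obs_ids, dtype=object)
        n, g = self.values.shape
        if len(self.obs_ids) != n or len(self.gene_ids) != g:
            raise ValueError("id lengths inconsistent with values shape")
        if (self.values < 0).any():
            raise ValueError("normalized values must be nonnegative")

    @property
    def n_obs(self) -> int:
        return self.values.shape[0]

    def gene_index(self, genes) -> np.ndarray:
        """Column indices of ``genes`` that are measured; preserves order."""
        lookup = {g: i for i, g in enumerate(self.gene_ids)}
        return np.array([lookup[g] for g in genes if g in lookup], dtype=int)

    def subset_obs(self, mask_or_index) -> "NormalizedMatrix":
        idx = np.asarray(mask_or_index)
        return NormalizedMatrix(
            values=self.values[idx],
            gene_ids=self.gene_ids,
            obs_ids=self.obs_ids[idx],
            scale_factor=self.scale_factor,
            source=self.source,
        )


@dataclass
class MarkerTable:
    """Per-gene differential-expression results for one contrast.

    ``table`` is indexed by gene with columns log2fc, p, p_adj, pct_in,
    pct_out.  ``group``/``reference`` record the contrast.
    """

    table: pd.DataFrame
    group: str
    reference: str

    REQUIRED = ("log2fc", "p", "p_adj", "pct_in", "pct_out")

    def __post_init__(self):
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValueError(f"marker table missing columns: {missing}")
        bad_p = self.table["p"].dropna()
        if ((bad_p < 0) | (bad_p > 1)).any():
            raise ValueError("p-values outside [0, 1]")
        if (self.table["p_adj"].dropna() + 1e-15 < bad_p.reindex(self.table["p_adj"].dropna().index)).any():
            warnings.warn("adjusted p-values below raw p-values", stacklevel=2)

    @property
    def genes(self) -> pd.Index:
        return self.table.index

    def significant_up(self, alpha: float = 0.05) -> list[str]:
        t = self.table
        return list(t.index[(t["p_adj"] < alpha) & (t["log2fc"] > 0)])


@dataclass
class InterfaceGeneCall:
    """One gene passing the interface-enrichment rule."""

    gene: str
    direction: str  # "up" or "down"
    fc_interface: float
    fc_tumor: float
    fc_muscle: float
    p_adj: float
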