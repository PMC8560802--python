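"""Readers and writers for the on-disk formats the pipeline touches.

Counts travel as 10x-style MatrixMarket triplets (matrix.mtx +
features.tsv + barcodes.tsv), spot positions as the Visium
``tissue_positions`` CSV dialect, gene sets as GMT, and simple gene lists
as one-gene-per-line text.  Writers emit exactly what the readers accept,
so synthetic datasets round-trip losslessly.
"""

from __future__ import annotations

import logging
import os
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .datatypes import CellDataset, GeneSetCollection, SpotDataset

__all__ = [
    "FormatError",
    "read_counts_mtx",
    "write_counts_mtx",
    "read_spot_positions",
    "write_spot_positions",
    "read_gmt",
    "write_gmt",
    "read_gene_list",
    "write_gene_list",
    "write_spot_dataset",
    "read_spot_dataset",
]

logger = logging.getLogger(__name__)

POSITIONS_COLUMNS = ["barcode", "in_tissue", "array_row", "array_col", "pxl_row", "pxl_col"]


class FormatError(ValueError):
    """A file does not conform to its expected on-disk format."""


def _read_id_column(path) -> list[str]:
    """First column of a TSV, whitespace-stripped (10x features/barcodes)."""
    ids = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            ids.append(line.split("\t")[0].strip())
    return ids


def read_counts_mtx(matrix_path, features_path, barcodes_path):
    """Read a 10x-style MatrixMarket triplet as observations x genes.

    The on-disk orientation (genes x barcodes, the 10x convention, or the
    transpose) is detected by matching matrix dimensions against the
    lengths of the features and barcodes files; the returned matrix is
    always barcodes (observations) x genes.

    Returns ``(counts, gene_ids, barcode_ids)`` with ``counts`` a dense
    nonnegative integer array.
    """
    genes = _read_id_column(features_path)
    barcodes = _read_id_column(barcodes_path)
    try:
        mat = scipy.io.mmread(os.fspath(matrix_path))
    except ValueError as exc:
        raise FormatError(f"cannot parse MatrixMarket file: {exc}") from exc
    if scipy.sparse.issparse(mat):
        mat = mat.toarray()
    mat = np.asarray(mat)

    ng, nb = len(genes), len(barcodes)
    if mat.shape == (ng, nb):
        counts = mat.T  # 10x convention: genes x barcodes on disk
    elif mat.shape == (nb, ng):
        counts = mat
    else:
        raise FormatError(
            f"matrix shape {mat.shape} matches neither (features={ng}, "
            f"barcodes={nb}) nor its transpose"
        )
    if (counts < 0).any():
        raise FormatError("negative entries in count matrix")
    if not np.allclose(counts, np.round(counts)):
        raise FormatError("non-integer entries in count matrix")
    return counts.astype(np.int64), np.array(genes, dtype=object), np.array(
        barcodes, dtype=object
    )


def write_counts_mtx(counts, gene_ids, barcode_ids, out_dir):
    """Write counts as a 10x-style triplet (genes x barcodes on disk)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    sparse = scipy.sparse.coo_matrix(np.asarray(counts).T)
    scipy.io.mmwrite(os.fspath(out_dir / "matrix.mtx"), sparse, field="integer")
    with open(out_dir / "features.tsv", "w") as fh:
        for g in gene_ids:
            fh.write(f"{g}\t{g}\tGene Expression\n")
    with open(out_dir / "barcodes.tsv", "w") as fh:
        for b in barcode_ids:
            fh.write(f"{b}\n")


def read_spot_positions(csv_path, id_order):
    """Read a Visium ``tissue_positions`` CSV, reordered to ``id_order``.

    Both dialects (with and without a header line) are accepted.  Returned
    coordinates are ``(x, y) = (pxl_col, pxl_row)``.  Barcodes present in
    the CSV but absent from ``id_order`` are dropped; barcodes requested in
    ``id_order`` but missing from the CSV raise an error naming them.

    Returns ``(coords, in_tissue)`` aligned to ``id_order``.
    """
    with open(csv_path) as fh:
        first = fh.readline().strip().split(",")
    has_header = first and first[0].lower() in ("barcode", "barcodes")
    df = pd.read_csv(
        csv_path,
        header=0 if has_header else None,
        names=POSITIONS_COLUMNS if not has_header else None,
    )
    if has_header:
        rename = {c: c.strip().lower() for c in df.columns}
        df = df.rename(columns=rename)
        alias = {
            "pxl_row_in_fullres": "pxl_row",
            "pxl_col_in_fullres": "pxl_col",
        }
        df = df.rename(columns=alias)
        missing_cols = [c for c in POSITIONS_COLUMNS if c not in df.columns]
        if missing_cols:
            raise FormatError(f"positions file missing columns: {missing_cols}")
    df["barcode"] = df["barcode"].astype(str).str.strip()
    df = df.set_index("barcode")
    id_order = [str(b) for b in id_order]
    missing = [b for b in id_order if b not in df.index]
    if missing:
        raise FormatError(f"barcodes missing from positions file: {missing}")
    df = df.loc[id_order]
    coords = np.column_stack([df["pxl_col"].to_numpy(float), df["pxl_row"].to_numpy(float)])
    in_tissue = df["in_tissue"].to_numpy(int).astype(bool)
    return coords, in_tissue


def write_spot_positions(path, barcodes, coords, in_tissue=None, array_rows=None, array_cols=None):
    """Write a header-less Visium-dialect positions CSV ((x,y)=(col,row) px)."""
    coords = np.asarray(coords, dtype=float)
    n = len(barcodes)
    if in_tissue is None:
        in_tissue = np.ones(n, dtype=int)
    if array_rows is None:
        array_rows = np.zeros(n, dtype=int)
    if array_cols is None:
        array_cols = np.zeros(n, dtype=int)
    with open(path, "w") as fh:
        for i, b in enumerate(barcodes):
            fh.write(
                f"{b},{int(in_tissue[i])},{int(array_rows[i])},{int(array_cols[i])},"
                f"{coords[i, 1]:g},{coords[i, 0]:g}\n"
            )


def read_gmt(path, universe) -> GeneSetCollection:
    """Read a GMT file (``name<TAB>description<TAB>gene...``).

    Genes outside ``universe`` are dropped (count logged per set); empty
    sets are retained with size 0; duplicate set names are an error.
    """
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise FormatError(f"GMT line {lineno}: need name and description fields")
            name = parts[0].strip()
            if name in sets:
                raise FormatError(f"duplicate gene-set name: {name!r}")
            sets[name] = [g.strip() for g in parts[2:] if g.strip()]
    collection = GeneSetCollection(sets=sets, universe=list(universe), provenance=str(path))
    for name, dropped in collection.n_dropped.items():
        logger.info("gene set %s: dropped %d genes outside the universe", name, dropped)
    return collection


def write_gmt(path, collection: GeneSetCollection):
    with open(path, "w") as fh:
        for name, genes in collection.sets.items():
            fh.write("\t".join([name, collection.provenance or "na", *genes]) + "\n")


def read_gene_list(path) -> list[str]:
    """One gene per line, whitespace stripped, blanks skipped."""
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def write_gene_list(path, genes):
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g}\n")


# ---------------------------------------------------------------------------
# dataset-level convenience round-trips


def write_spot_dataset(dataset: SpotDataset, out_dir):
    """Write a spot dataset as mtx triplet + positions CSV + cluster TSV."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    write_counts_mtx(dataset.counts, dataset.gene_ids, dataset.spot_ids, out_dir)
    write_spot_positions(out_dir / "tissue_positions.csv", dataset.spot_ids, dataset.coords)
    pd.DataFrame(
        {"barcode": dataset.spot_ids, "cluster": dataset.cluster_of_spot}
    ).to_csv(out_dir / "clusters.tsv", sep="\t", index=False)


def read_spot_dataset(in_dir) -> SpotDataset:
    in_dir = Path(in_dir)
    counts, genes, barcodes = read_counts_mtx(
        in_dir / "matrix.mtx", in_dir / "features.tsv", in_dir / "barcodes.tsv"
    )
    coords, _ = read_spot_positions(in_dir / "tissue_positions.csv", barcodes)
    clusters = pd.read_csv(in_dir / "clusters.tsv", sep="\t").set_index("barcode")
    labels = clusters.loc[[str(b) for b in barcodes], "cluster"].to_numpy(object)
    return SpotDataset(
        counts=counts,
        coords=coords,
        spot_ids=barcodes,
        gene_ids=genes,
        cluster_of_spot=labels,
    )


def write_cell_dataset(dataset: CellDataset, out_dir):
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    write_counts_mtx(dataset.counts, dataset.gene_ids, dataset.cell_ids, out_dir)
    pd.DataFrame(
        {"barcode": dataset.cell_ids, "cluster": dataset.cluster_of_cell}
    ).to_csv(out_dir / "clusters.tsv", sep="\t", index=False)
    with open(out_dir / "modality.txt", "w") as fh:
        fh.write(dataset.modality + "\n")


def read_cell_dataset(in_dir) -> CellDataset:
    in_dir = Path(in_dir)
    counts, genes, barcodes = read_counts_mtx(
        in_dir / "matrix.mtx", in_dir / "features.tsv", in_dir / "barcodes.tsv"
    )
    clusters = pd.read_csv(in_dir / "clusters.tsv", sep="\t").set_index("barcode")
    labels = clusters.loc[[str(b) for b in barcodes], "cluster"].to_numpy(object)
    modality_path = in_dir / "modality.txt"
    modality = modality_path.read_text().strip() if modality_path.exists() else "cell"
    mito = np.array([str(g).lower().startswith("mt-") for g in genes])
    return CellDataset(
        counts=counts,
        cell_ids=barcodes,
        gene_ids=genes,
        cluster_of_cell=labels,
        modality=modality,
        mito_gene_flags=mito,
    )
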