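"""Readers and writers for the package's on-disk formats.

Count matrices use the 10x-style triplet layout: ``matrix.mtx`` (Matrix
Market coordinate, 1-based indices on disk, 0-based in memory), a
``barcodes.tsv`` with one barcode per line, and a ``genes.tsv`` with
``gene<TAB>species`` per line.  Rows are barcodes, columns are genes.

Read records travel as TSV with columns
cell_barcode, umi, gene, true_barcode, true_umi (gzip accepted
transparently by file extension).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

__all__ = [
    "MatrixBundle",
    "read_matrix",
    "write_matrix",
    "read_reads",
    "write_reads",
    "READ_COLUMNS",
]

READ_COLUMNS = ["cell_barcode", "umi", "gene", "true_barcode", "true_umi"]


@dataclass
class MatrixBundle:
    """A sparse UMI count matrix with its barcode and gene annotations.

    matrix : scipy.sparse.csr_matrix, shape (n_barcodes, n_genes), integer
    barcodes : ordered barcode identifiers
    genes : DataFrame with columns ``gene`` and ``species``
    """

    matrix: sparse.csr_matrix
    barcodes: np.ndarray
    genes: pd.DataFrame

    def __post_init__(self) -> None:
        self.matrix = sparse.csr_matrix(self.matrix)
        self.barcodes = np.asarray(self.barcodes, dtype=object)
        if not {"gene", "species"} <= set(self.genes.columns):
            raise ValueError("genes table must have 'gene' and 'species' columns")
        self.genes = self.genes.reset_index(drop=True)
        n_bc, n_g = self.matrix.shape
        if n_bc != len(self.barcodes):
            raise ValueError(
                f"matrix has {n_bc} rows but {len(self.barcodes)} barcodes"
            )
        if n_g != len(self.genes):
            raise ValueError(f"matrix has {n_g} columns but {len(self.genes)} genes")
        if len(set(self.barcodes)) != len(self.barcodes):
            raise ValueError("barcode identifiers must be unique")
        if self.genes["gene"].duplicated().any():
            dupes = self.genes.loc[self.genes["gene"].duplicated(), "gene"].tolist()
            raise ValueError(f"duplicate gene identifiers: {dupes[:5]}")
        if self.matrix.nnz and self.matrix.data.min() < 0:
            raise ValueError("counts must be non-negative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.matrix.shape

    def totals_per_barcode(self) -> np.ndarray:
        return np.asarray(self.matrix.sum(axis=1)).ravel()

    def to_dense(self) -> np.ndarray:
        return np.asarray(self.matrix.todense())


def write_matrix(bundle: MatrixBundle, outdir: str | Path) -> Path:
    """Write matrix.mtx + barcodes.tsv + genes.tsv into ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    spio.mmwrite(outdir / "matrix.mtx", sparse.coo_matrix(bundle.matrix))
    pd.Series(bundle.barcodes).to_csv(
        outdir / "barcodes.tsv", sep="\t", index=False, header=False
    )
    bundle.genes[["gene", "species"]].to_csv(
        outdir / "genes.tsv", sep="\t", index=False, header=False
    )
    return outdir


def read_matrix(indir: str | Path) -> MatrixBundle:
    """Read a triplet-layout matrix directory back into a MatrixBundle."""
    indir = Path(indir)
    mtx_path = indir / "matrix.mtx"
    if not mtx_path.exists():
        raise FileNotFoundError(f"no matrix.mtx under {indir}")
    matrix = sparse.csr_matrix(spio.mmread(mtx_path))
    barcodes = (
        pd.read_csv(indir / "barcodes.tsv", sep="\t", header=None, dtype=str)[0]
        .to_numpy(dtype=object)
    )
    genes = pd.read_csv(
        indir / "genes.tsv", sep="\t", header=None, names=["gene", "species"], dtype=str
    )
    return MatrixBundle(matrix=matrix, barcodes=barcodes, genes=genes)


def write_reads(reads: pd.DataFrame, path: str | Path) -> Path:
    """Write read records as TSV (gzip if the path ends in .gz)."""
    missing = [c for c in READ_COLUMNS if c not in reads.columns]
    if missing:
        raise ValueError(f"read table is missing columns: {missing}")
    path = Path(path)
    reads[READ_COLUMNS].to_csv(path, sep="\t", index=False)
    return path


def read_reads(path: str | Path, chunksize: int | None = None):
    """Read a read-record TSV (optionally in chunks for constant memory).

    Returns a DataFrame, or an iterator of DataFrames when ``chunksize`` is
    given.  Malformed lines are reported with their line numbers.
    """
    path = Path(path)
    try:
        out = pd.read_csv(path, sep="\t", dtype=str, chunksize=chunksize)
    except pd.errors.ParserError as exc:  # pandas messages carry line numbers
        raise ValueError(f"malformed read table {path}: {exc}") from exc
    if chunksize is None:
        _validate_read_columns(out, path)
        return out
    return _validated_chunks(out, path)


def _validate_read_columns(df: pd.DataFrame, path: Path) -> None:
    missing = [c for c in READ_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path} is missing required columns: {missing}")
    for col in READ_COLUMNS:
        bad = df.index[df[col].isna()]
        if len(bad):
            # +2: header line plus 1-based numbering
            raise ValueError(
                f"{path}: malformed record at line {int(bad[0]) + 2} (empty {col})"
            )


def _validated_chunks(chunks, path: Path):
    for chunk in chunks:
        _validate_read_columns(chunk, path)
        yield chunk
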