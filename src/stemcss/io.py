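"""Readers and writers for the pipeline's on-disk formats.

On disk, expression matrices are genes-by-columns (MatrixMarket ``.mtx``
with gene/cell TSV sidecars for single-cell counts; plain TSV for bulk),
matching how such files circulate in the field.  In memory everything is
units-by-genes; the transpose happens here.  All coordinates in files are
1-based inclusive.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .containers import ExpressionMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "read_expression",
    "write_expression",
    "read_loci",
    "read_clinical",
    "read_mutations",
    "read_cell_annotation",
]


def _sidecar(path: Path, kind: str) -> Path:
    return path.with_suffix(f".{kind}.tsv")


def read_expression(
    path: str | Path,
    format: str = "tsv",
    is_log: bool = False,
    genes_path: str | Path | None = None,
    units_path: str | Path | None = None,
) -> ExpressionMatrix:
    """Read an expression matrix.

    ``format="tsv"``: tab-separated genes x columns with a header row of
    unit ids and gene ids in the first column.  ``format="mtx"``:
    MatrixMarket coordinate format (genes x units) with one-column TSV
    sidecars listing gene and unit ids (default ``<stem>.genes.tsv`` /
    ``<stem>.cells.tsv``).

    Raises ``ValueError`` naming the offending line for malformed headers,
    negative counts, or duplicated identifiers.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"expression file not found: {path}")
    if format == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
        if df.index.name is None and df.empty:
            raise ValueError(f"{path}: malformed header")
        dup = df.index[df.index.duplicated()]
        if len(dup):
            first = int(np.flatnonzero(df.index == dup[0])[0])
            raise ValueError(
                f"{path}: duplicated gene row {dup[0]!r} (first at line {first + 2})"
            )
        data = df.T
    elif format == "mtx":
        genes_path = Path(genes_path) if genes_path else _sidecar(path, "genes")
        units_path = Path(units_path) if units_path else _sidecar(path, "cells")
        for p in (genes_path, units_path):
            if not p.exists():
                raise FileNotFoundError(f"sidecar file not found: {p}")
        mat = scipy.io.mmread(path)
        genes = pd.read_csv(genes_path, sep="\t", header=None)[0].tolist()
        units = pd.read_csv(units_path, sep="\t", header=None)[0].tolist()
        if len(set(genes)) != len(genes):
            seen, dups = set(), []
            for i, g in enumerate(genes):
                if g in seen:
                    dups.append((g, i + 1))
                seen.add(g)
            raise ValueError(f"{genes_path}: duplicated gene ids {dups[:5]}")
        dense = np.asarray(mat.todense() if scipy.sparse.issparse(mat) else mat)
        if dense.shape != (len(genes), len(units)):
            raise ValueError(
                f"{path}: matrix shape {dense.shape} does not match sidecars "
                f"({len(genes)} genes, {len(units)} units)"
            )
        data = pd.DataFrame(dense.T, index=pd.Index(units, name="unit"), columns=genes)
    else:
        raise ValueError(f"unknown format {format!r}; expected 'tsv' or 'mtx'")

    if not is_log:
        arr = data.to_numpy()
        neg = np.argwhere(arr < 0)
        if len(neg):
            r, c = neg[0]
            raise ValueError(
                f"{path}: negative entry at gene {data.columns[c]!r}, "
                f"unit {data.index[r]!r} (value {arr[r, c]})"
            )
    return ExpressionMatrix(data, is_log=is_log)


def write_expression(
    matrix: ExpressionMatrix, path: str | Path, format: str = "tsv"
) -> None:
    """Write genes-by-columns TSV, or MTX plus gene/cell sidecar TSVs."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    on_disk = matrix.data.T  # genes x units
    if format == "tsv":
        on_disk.rename_axis("gene").to_csv(path, sep="\t")
    elif format == "mtx":
        sparse = scipy.sparse.coo_matrix(on_disk.to_numpy())
        scipy.io.mmwrite(str(path), sparse)
        pd.Series(on_disk.index).to_csv(_sidecar(path, "genes"), sep="\t", index=False, header=False)
        pd.Series(on_disk.columns).to_csv(_sidecar(path, "cells"), sep="\t", index=False, header=False)
    else:
        raise ValueError(f"unknown format {format!r}")


def read_loci(path: str | Path) -> pd.DataFrame:
    """Gene locus table: TSV with columns gene, chrom, arm, start (1-based)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"loci file not found: {path}")
    loci = pd.read_csv(path, sep="\t", dtype={"chrom": str, "arm": str})
    required = {"gene", "chrom", "arm", "start"}
    missing = required - set(loci.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    if (loci["start"] < 1).any():
        bad = loci.index[loci["start"] < 1][0]
        raise ValueError(f"{path}: non-positive start at line {bad + 2} (coordinates are 1-based)")
    return loci


def read_cell_annotation(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"cell annotation file not found: {path}")
    ann = pd.read_csv(path, sep="\t", index_col=0)
    if "cluster" not in ann.columns:
        raise ValueError(f"{path}: cell annotation needs a 'cluster' column")
    return ann


def read_clinical(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"clinical file not found: {path}")
    return pd.read_csv(path, sep="\t", index_col=0)


def read_mutations(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"mutation file not found: {path}")
    mut = pd.read_csv(path, sep="\t", index_col=0)
    vals = mut.to_numpy()
    if not np.isin(vals, (0, 1)).all():
        bad = np.argwhere(~np.isin(vals, (0, 1)))[0]
        raise ValueError(
            f"{path}: non-binary entry at sample {mut.index[bad[0]]!r}, "
            f"gene {mut.columns[bad[1]]!r}"
        )
    return mut
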