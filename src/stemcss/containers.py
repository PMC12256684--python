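"""Core in-memory containers shared across the pipeline.

The in-memory orientation is *units x genes* (rows are cells or bulk
samples, columns are genes), matching the scikit-learn samples-by-features
convention.  On-disk formats keep the field-standard genes-by-columns
orientation; :mod:`stemcss.io` converts at the boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = ["ExpressionMatrix", "GeneSignature"]


@dataclass
class ExpressionMatrix:
    """A non-negative expression matrix with an explicit raw/log state.

    Parameters
    ----------
    data:
        DataFrame of shape ``(n_units, n_genes)``; the index holds cell or
        sample identifiers, the columns hold gene symbols.
    is_log:
        ``False`` for raw counts, ``True`` for log-normalized values
        (``log1p`` of counts-per-10k, or any log-scale bulk expression).
    """

    data: pd.DataFrame
    is_log: bool = False

    def __post_init__(self) -> None:
        if not isinstance(self.data, pd.DataFrame):
            self.data = pd.DataFrame(self.data)
        dup_genes = self.data.columns[self.data.columns.duplicated()].unique()
        if len(dup_genes):
            raise ValueError(f"duplicate gene identifiers: {sorted(map(str, dup_genes))}")
        dup_units = self.data.index[self.data.index.duplicated()].unique()
        if len(dup_units):
            raise ValueError(f"duplicate unit identifiers: {sorted(map(str, dup_units))}")
        if not self.is_log and (self.data.to_numpy() < 0).any():
            r, c = np.argwhere(self.data.to_numpy() < 0)[0]
            raise ValueError(
                f"negative count at unit {self.data.index[r]!r}, gene {self.data.columns[c]!r}"
            )

    # -- basic accessors -------------------------------------------------
    @property
    def genes(self) -> pd.Index:
        return self.data.columns

    @property
    def units(self) -> pd.Index:
        return self.data.index

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def subset_units(self, units: Sequence) -> "ExpressionMatrix":
        return replace(self, data=self.data.loc[list(units)])

    # -- normalization ---------------------------------------------------
    def log_normalize(self, scale: float = 1e4) -> "ExpressionMatrix":
        """Counts-per-``scale`` per unit followed by ``log1p``.

        The field-standard library-size normalization: each row is scaled
        to a total of ``scale`` counts before the log transform.  Rows with
        zero total are left at zero.
        """
        if self.is_log:
            return self
        x = self.data.to_numpy(dtype=float)
        totals = x.sum(axis=1, keepdims=True)
        totals[totals == 0] = 1.0
        out = np.log1p(x / totals * scale)
        return ExpressionMatrix(
            pd.DataFrame(out, index=self.data.index, columns=self.data.columns), is_log=True
        )


def as_matrix(x) -> ExpressionMatrix:
    """Coerce a DataFrame (assumed already prepared) or ExpressionMatrix."""
    if isinstance(x, ExpressionMatrix):
        return x
    if isinstance(x, pd.DataFrame):
        return ExpressionMatrix(x, is_log=True)
    raise TypeError(f"expected ExpressionMatrix or DataFrame, got {type(x).__name__}")


@dataclass(frozen=True)
class GeneSignature:
    """A named, ordered gene list with a derivation provenance record."""

    name: str
    genes: tuple[str, ...]
    provenance: Mapping = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "genes", tuple(self.genes))
        if len(self.genes) == 0:
            raise ValueError(f"signature {self.name!r} is empty")
        if len(set(self.genes)) != len(self.genes):
            seen, dups = set(), []
            for g in self.genes:
                if g in seen:
                    dups.append(g)
                seen.add(g)
            raise ValueError(f"signature {self.name!r} has duplicate genes: {dups}")

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes)
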