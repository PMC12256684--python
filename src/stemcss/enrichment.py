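"""Cell-population statistics.

Three tools used throughout the single-cell side of the pipeline:

* :func:`roe` -- ratio of observed to expected cell numbers in a
  cluster-by-group contingency table.  Ro/e > 1 marks enrichment of a
  cluster in a group beyond what the marginals predict, < 1 depletion.
* :func:`diff_expr` -- per-gene two-group differential expression with a
  two-sided Wilcoxon rank-sum test and Benjamini-Hochberg FDR control.
* :func:`gene_set_auc` / :class:`GeneSetAUCScorer` -- AUCell-style
  rank-based per-cell gene-set activity: the area under the recovery
  curve of signature genes within the top-ranked fraction of each cell's
  expression profile, normalized to [0, 1].  Being rank-based, the score
  is invariant to any strictly increasing transform of a cell's
  expression vector.
"""

from __future__ import annotations

import math
import warnings
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted
from statsmodels.stats.multitest import multipletests

from .containers import ExpressionMatrix, GeneSignature, as_matrix

__all__ = ["roe", "diff_expr", "gene_set_auc", "GeneSetAUCScorer", "bh_adjust"]


# ---------------------------------------------------------------------------
# Ro/e
# ---------------------------------------------------------------------------
def roe(table: pd.DataFrame) -> pd.DataFrame:
    """Observed/expected ratios for a cluster-by-group contingency table.

    ``expected[i, j] = row_total[i] * col_total[j] / grand_total``.  Cells
    with zero expected count are undefined and returned as NaN.
    """
    counts = np.asarray(table, dtype=float)
    if counts.size == 0:
        raise ValueError("empty contingency table")
    if (counts < 0).any():
        raise ValueError("contingency table has negative entries")
    grand = counts.sum()
    if grand <= 0:
        raise ValueError("contingency table grand total must be > 0")
    expected = np.outer(counts.sum(axis=1), counts.sum(axis=0)) / grand
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(expected > 0, counts / expected, np.nan)
    if isinstance(table, pd.DataFrame):
        return pd.DataFrame(ratio, index=table.index, columns=table.columns)
    return pd.DataFrame(ratio)


# ---------------------------------------------------------------------------
# BH adjustment
# ---------------------------------------------------------------------------
def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# Differential expression
# ---------------------------------------------------------------------------
def diff_expr(
    matrix: ExpressionMatrix | pd.DataFrame,
    group_a: Iterable,
    group_b: Iterable,
    *,
    pseudocount: float = 1e-9,
    log_base: float = 2.0,
) -> pd.DataFrame:
    """Per-gene two-group differential expression.

    The test is the two-sided Wilcoxon rank-sum (the standard cluster-
    marker test for single-cell data) on log-normalized values; the fold
    change is computed on the de-logged normalized scale,
    ``log2((mean_a + eps) / (mean_b + eps))``.

    Parameters
    ----------
    matrix:
        Log-normalized expression, units x genes.
    group_a, group_b:
        Disjoint unit-id collections, each of size >= 3.

    Returns
    -------
    DataFrame indexed by gene with columns ``log2_fc, p_value, fdr,
    mean_a, mean_b``.
    """
    mat = as_matrix(matrix)
    if not mat.is_log:
        raise ValueError("diff_expr expects a log-normalized matrix")
    a = list(group_a)
    b = list(group_b)
    if len(a) < 3 or len(b) < 3:
        raise ValueError(f"both groups need >= 3 units (got {len(a)} and {len(b)})")
    overlap = set(a) & set(b)
    if overlap:
        raise ValueError(f"groups overlap: {sorted(map(str, overlap))[:5]}")

    xa = mat.data.loc[a].to_numpy(dtype=float)
    xb = mat.data.loc[b].to_numpy(dtype=float)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        res = stats.mannwhitneyu(xa, xb, axis=0, alternative="two-sided")
        pvals = np.asarray(res.pvalue, dtype=float)
    # Genes constant and equal across both groups carry no information.
    degenerate = (xa.std(axis=0) == 0) & (xb.std(axis=0) == 0) & (xa[0] == xb[0])
    pvals = np.where(degenerate | ~np.isfinite(pvals), 1.0, pvals)
    pvals = np.clip(pvals, np.nextafter(0.0, 1.0), 1.0)

    mean_a = np.expm1(xa).mean(axis=0)
    mean_b = np.expm1(xb).mean(axis=0)
    lfc = np.log((mean_a + pseudocount) / (mean_b + pseudocount)) / np.log(log_base)
    lfc = np.where(degenerate, 0.0, lfc)

    return pd.DataFrame(
        {
            "log2_fc": lfc,
            "p_value": pvals,
            "fdr": bh_adjust(pvals),
            "mean_a": mean_a,
            "mean_b": mean_b,
        },
        index=mat.genes,
    )


# ---------------------------------------------------------------------------
# Gene-set AUC (AUCell-style)
# ---------------------------------------------------------------------------
class GeneSetAUCScorer(TransformerMixin, BaseEstimator):
    """Rank-based per-cell gene-set activity score.

    For each cell, genes are ranked by decreasing expression (ties broken
    by a fixed seeded shuffle of the gene order).  With ``k =
    ceil(top_fraction * n_genes)``, the recovery step curve counts the
    cumulative number of signature genes at ranks ``1..k``; the score is
    its area divided by the maximal area achievable if all
    ``min(|S|, k)`` signature genes occupied the top ranks.

    Parameters
    ----------
    gene_set:
        A :class:`GeneSignature` or iterable of gene names.
    top_fraction:
        Fraction of top-ranked genes considered, in (0, 1).  Default 0.05,
        the published AUCell default.
    random_state:
        Seed for the tie-breaking shuffle.
    """

    def __init__(self, gene_set=None, top_fraction: float = 0.05, random_state: int = 0):
        self.gene_set = gene_set
        self.top_fraction = top_fraction
        self.random_state = random_state

    def fit(self, X, y=None):
        if not (0 < self.top_fraction < 1):
            raise ValueError("top_fraction must lie in (0, 1)")
        mat = as_matrix(X)
        genes = list(self.gene_set) if self.gene_set is not None else []
        if not genes:
            raise ValueError("gene_set must be a non-empty gene collection")
        present = [g for g in genes if g in mat.genes]
        missing = [g for g in genes if g not in mat.genes]
        if not present:
            raise ValueError(f"no signature gene found in the matrix; missing: {missing}")
        self.genes_ = list(mat.genes)
        self.signature_genes_ = present
        self.missing_genes_ = missing
        rng = np.random.default_rng(self.random_state)
        self.tiebreak_ = rng.permutation(len(self.genes_))
        return self

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self, "genes_")
        mat = as_matrix(X)
        if list(mat.genes) != self.genes_:
            raise ValueError("gene universe differs from the fitted one")
        x = mat.data.to_numpy(dtype=float)
        n_genes = x.shape[1]
        k = math.ceil(self.top_fraction * n_genes)
        # Rank by decreasing expression; lexsort's secondary key (the fixed
        # shuffle) resolves ties deterministically.
        order = np.lexsort((np.broadcast_to(self.tiebreak_, x.shape), -x), axis=1)
        ranks = np.empty_like(order)
        cell_idx = np.arange(x.shape[0])[:, None]
        ranks[cell_idx, order] = np.arange(1, n_genes + 1)

        sig_idx = [self.genes_.index(g) for g in self.signature_genes_]
        sig_ranks = ranks[:, sig_idx]
        # A hit at rank r contributes (k - r + 1) unit-width columns to the
        # area under the cumulative step curve over ranks 1..k.
        contrib = np.clip(k - sig_ranks + 1, 0, None)
        m = min(len(sig_idx), k)
        max_area = m * k - m * (m - 1) // 2
        return contrib.sum(axis=1) / max_area


def gene_set_auc(
    matrix: ExpressionMatrix | pd.DataFrame,
    gene_set: GeneSignature | Iterable[str],
    top_fraction: float = 0.05,
    random_state: int = 0,
) -> pd.Series:
    """Per-cell AUCell-style score; see :class:`GeneSetAUCScorer`."""
    mat = as_matrix(matrix)
    scorer = GeneSetAUCScorer(gene_set, top_fraction, random_state).fit(mat)
    return pd.Series(scorer.transform(mat), index=mat.units, name="gene_set_auc")
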