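"""Expression-inferred arm-level copy-number scoring and marker discovery.

The arm scorer is a deliberately simplified relative of inferCNV: per-gene
log2 expression is centered by the mean over a set of reference (normal)
cells, clamped, smoothed by a moving average over genes in genomic order
within each chromosome, and averaged per chromosome arm.  No HMM and no
subclustering — the output is used only to flag arm-level gains (here the
chromosome 8q gain carried by the LAPTM4B-type stem-like population) and
to compare clusters.

Marker discovery intersects three gene sets: genes up in the cluster of
interest versus all other clusters, genes up versus its sibling stem-like
cluster, and genes located on a given chromosome arm.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .containers import ExpressionMatrix, as_matrix

logger = logging.getLogger(__name__)

__all__ = ["ArmGainScorer", "infer_arm_scores", "call_cluster_marker", "MarkerCallResult"]

LOG2 = np.log(2.0)


def _chrom_sort_key(chrom: str):
    s = str(chrom).removeprefix("chr")
    return (0, int(s)) if s.isdigit() else (1, s)


def _validate_loci(loci: pd.DataFrame) -> pd.DataFrame:
    required = {"gene", "chrom", "arm", "start"}
    missing = required - set(loci.columns)
    if missing:
        raise ValueError(f"loci table missing columns: {sorted(missing)}")
    if loci["gene"].duplicated().any():
        dups = loci.loc[loci["gene"].duplicated(), "gene"].tolist()
        raise ValueError(f"duplicate genes in loci table: {dups[:5]}")
    return loci


def _moving_average(x: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average along the last axis, truncated at the edges.

    Matches a ``rolling(window, center=True, min_periods=1).mean()``; the
    effective window shrinks near chromosome ends instead of padding.
    """
    if window == 1 or x.shape[-1] == 1:
        return x
    half = window // 2
    n = x.shape[-1]
    csum = np.cumsum(x, axis=-1)
    csum = np.concatenate([np.zeros(x.shape[:-1] + (1,)), csum], axis=-1)
    idx = np.arange(n)
    lo = np.clip(idx - half, 0, n)
    hi = np.clip(idx + half + 1, 0, n)
    return (csum[..., hi] - csum[..., lo]) / (hi - lo)


class ArmGainScorer(TransformerMixin, BaseEstimator):
    """Reference-centered, smoothed arm-level expression score.

    ``fit`` learns per-gene reference means from normal cells; ``transform``
    returns a per-cell arm score matrix (cells x arms).

    Parameters
    ----------
    loci:
        Gene locus table with columns ``gene, chrom, arm, start`` (1-based
        starts; arm assignment is taken from the table, no cytoband
        inference).
    window:
        Odd moving-average width over genes in genomic order (inferCNV's
        default 101).
    clamp:
        Symmetric bound on centered log2 values (inferCNV's default 3).
    gain_threshold:
        Cluster-level arm score above which a gain is called.
    min_genes:
        Arms with fewer located genes yield no gain call.
    min_locus_coverage:
        Minimum fraction of matrix genes that must appear in the loci
        table.
    """

    def __init__(
        self,
        loci: pd.DataFrame = None,
        window: int = 101,
        clamp: float = 3.0,
        gain_threshold: float = 0.1,
        min_genes: int = 30,
        min_locus_coverage: float = 0.8,
    ):
        self.loci = loci
        self.window = window
        self.clamp = clamp
        self.gain_threshold = gain_threshold
        self.min_genes = min_genes
        self.min_locus_coverage = min_locus_coverage

    def _to_log2(self, mat: ExpressionMatrix) -> np.ndarray:
        m = mat if mat.is_log else mat.log_normalize()
        # internal log scale is natural log1p; arm scores are reported in
        # log2 units as is conventional for CNV heatmaps
        return m.data.to_numpy(dtype=float) / LOG2

    def fit(self, X, y=None):
        if self.window < 1 or self.window % 2 == 0:
            raise ValueError("window must be a positive odd integer")
        loci = _validate_loci(self.loci)
        mat = as_matrix(X) if isinstance(X, (ExpressionMatrix, pd.DataFrame)) else X
        genes = mat.genes
        located = loci[loci["gene"].isin(genes)]
        coverage = len(located) / len(genes)
        if coverage < self.min_locus_coverage:
            raise ValueError(
                f"loci cover only {coverage:.0%} of matrix genes "
                f"(need >= {self.min_locus_coverage:.0%})"
            )
        ordered = located.assign(_key=located["chrom"].map(_chrom_sort_key)).sort_values(
            ["_key", "arm", "start"], kind="stable"
        )
        self.gene_order_ = ordered["gene"].tolist()
        self.chroms_ = ordered["chrom"].astype(str).to_numpy()
        self.arms_ = (ordered["chrom"].astype(str) + ordered["arm"].astype(str)).to_numpy()
        self.genes_ = list(genes)
        col_idx = pd.Index(genes).get_indexer(self.gene_order_)
        self._col_idx = col_idx
        ref = self._to_log2(mat)[:, col_idx]
        self.reference_means_ = ref.mean(axis=0)
        return self

    def transform(self, X) -> pd.DataFrame:
        check_is_fitted(self, "reference_means_")
        mat = as_matrix(X)
        if list(mat.genes) != self.genes_:
            raise ValueError("gene universe differs from the fitted one")
        x = self._to_log2(mat)[:, self._col_idx]
        centered = np.clip(x - self.reference_means_, -self.clamp, self.clamp)
        smoothed = np.empty_like(centered)
        for chrom in pd.unique(self.chroms_):
            cols = np.flatnonzero(self.chroms_ == chrom)
            smoothed[:, cols] = _moving_average(centered[:, cols], self.window)
        arm_labels = pd.unique(self.arms_)
        out = {}
        for arm in arm_labels:
            cols = np.flatnonzero(self.arms_ == arm)
            out[arm] = smoothed[:, cols].mean(axis=1)
        return pd.DataFrame(out, index=mat.units)

    def arm_gene_counts(self) -> pd.Series:
        check_is_fitted(self, "arms_")
        return pd.Series(self.arms_).value_counts()


def infer_arm_scores(
    matrix: ExpressionMatrix | pd.DataFrame,
    annotation: pd.DataFrame,
    loci: pd.DataFrame,
    reference_clusters: Iterable[str],
    window: int = 101,
    clamp: float = 3.0,
    gain_threshold: float = 0.1,
    min_genes: int = 30,
) -> pd.DataFrame:
    """Cluster-level arm scores with gain calls.

    Parameters
    ----------
    matrix:
        Expression (raw counts are log-normalized internally), units x genes.
    annotation:
        Per-cell table indexed like the matrix rows with a ``cluster``
        column.
    reference_clusters:
        Cluster labels whose cells define the centering reference
        (typically normal epithelial cell types).

    Returns
    -------
    Long-format DataFrame with columns ``cluster, arm, score, n_genes,
    gain_call``; arms with fewer than ``min_genes`` genes have a null
    gain call.
    """
    reference_clusters = set(reference_clusters)
    if not reference_clusters:
        raise ValueError("reference_clusters must be non-empty")
    mat = as_matrix(matrix)
    clusters = annotation.loc[mat.units, "cluster"]
    unknown = reference_clusters - set(clusters.unique())
    if unknown:
        raise ValueError(f"reference clusters not present in annotation: {sorted(unknown)}")
    ref_units = clusters.index[clusters.isin(reference_clusters)]

    scorer = ArmGainScorer(
        loci=loci,
        window=window,
        clamp=clamp,
        gain_threshold=gain_threshold,
        min_genes=min_genes,
    ).fit(mat.subset_units(ref_units))
    per_cell = scorer.transform(mat)
    counts = scorer.arm_gene_counts()

    rows = []
    for cluster, block in per_cell.groupby(clusters, observed=True):
        means = block.mean(axis=0)
        for arm, score in means.items():
            n = int(counts[arm])
            rows.append(
                {
                    "cluster": cluster,
                    "arm": arm,
                    "score": float(score),
                    "n_genes": n,
                    "gain_call": bool(score > gain_threshold) if n >= min_genes else None,
                }
            )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class MarkerCallResult:
    """Outcome of the three-way marker intersection."""

    up_vs_rest: tuple[str, ...]
    up_vs_sibling: tuple[str, ...]
    arm_genes: tuple[str, ...]
    markers: tuple[str, ...]
    thresholds: dict = field(default_factory=dict)


def call_cluster_marker(
    de_vs_rest: pd.DataFrame,
    de_vs_sibling: pd.DataFrame,
    loci: pd.DataFrame,
    arm: str,
    lfc_min: float = 2.0,
    fdr_max: float = 0.01,
) -> MarkerCallResult:
    """Three-way intersection marker discovery.

    ``markers = {up vs rest} & {up vs sibling} & {genes on arm}`` at
    ``log2_fc > lfc_min`` and ``fdr < fdr_max`` in both contrasts.  The
    call is deterministic; gene order follows the DE table.  An empty
    intersection is a valid (empty) result.
    """
    if len(de_vs_rest) == 0 or len(de_vs_sibling) == 0:
        raise ValueError("empty gene universe in DE input")
    if set(de_vs_rest.index) != set(de_vs_sibling.index):
        raise ValueError("DE tables must cover the same gene universe")
    loci = _validate_loci(loci)

    arm = str(arm)
    chrom_arm = loci["chrom"].astype(str) + loci["arm"].astype(str)
    arm_genes = loci.loc[chrom_arm == arm, "gene"]

    def passing(de: pd.DataFrame) -> pd.Index:
        return de.index[(de["log2_fc"] > lfc_min) & (de["fdr"] < fdr_max)]

    up_rest = passing(de_vs_rest)
    up_sib = passing(de_vs_sibling)
    arm_set = set(arm_genes)
    markers = [g for g in de_vs_rest.index if g in set(up_rest) & set(up_sib) & arm_set]
    if not markers:
        logger.info("marker intersection on arm %s is empty", arm)
    return MarkerCallResult(
        up_vs_rest=tuple(up_rest),
        up_vs_sibling=tuple(up_sib),
        arm_genes=tuple(arm_genes),
        markers=tuple(markers),
        thresholds={"lfc_min": lfc_min, "fdr_max": fdr_max, "arm": arm},
    )
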