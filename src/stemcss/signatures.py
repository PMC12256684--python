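"""Stem-like signature derivation, sample scoring, and CSS subtyping.

Two transcriptional programs anchor the classification: the canonical
LGR5+ intestinal stem-cell program (WNT-associated) and the LAPTM4B+
stem-like program (MYC-associated, chromosome 8q).  Each signature is the
intersection of genes upregulated in tumor epithelium versus other cells
with genes upregulated in the stem-like subpopulation versus the other
tumor-epithelial subpopulations.

Samples are scored by the median log-normalized expression of the
signature genes; the CRC stem-like subtype (CSS) is the quadrant of the
two scores relative to their cohort medians:

====== ============== =================
label  LGR5 score     LAPTM4B score
====== ============== =================
CSS1   low            low
CSS2   low            high  (LAPTM4B-dominant; poorest prognosis)
CSS3   high           high
CSS4   high           low   (LGR5-dominant)
====== ============== =================

A score strictly above the median counts as "high"; ties at the median
are "low", which keeps the all-constant case well defined.
"""

from __future__ import annotations

import logging
from typing import Iterable

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .containers import ExpressionMatrix, GeneSignature, as_matrix

logger = logging.getLogger(__name__)

__all__ = [
    "LGR5_SIGNATURE",
    "LAPTM4B_SIGNATURE",
    "build_signature",
    "score_samples",
    "SignatureScorer",
    "CSSClassifier",
    "assign_css",
    "combined_marker_score",
    "center_cohorts",
    "CSS_LABELS",
]

CSS_LABELS = ("CSS1", "CSS2", "CSS3", "CSS4")

#: Named members of the published 34-gene LGR5+ stem-like signature.  Only
#: the genes spelled out in the text ship here; users supply full lists.
LGR5_SIGNATURE = GeneSignature(
    "LGR5_stem",
    ("LGR5", "OLFM4", "TMEM19", "TMEM238", "CCL20"),
    provenance={"source": "published LGR5+ stem-like signature (named members)"},
)

#: The LAPTM4B+ stem-like signature.
LAPTM4B_SIGNATURE = GeneSignature(
    "LAPTM4B_stem",
    ("LAPTM4B", "TNNC2", "EREG", "C4orf48"),
    provenance={"source": "published LAPTM4B+ stem-like signature"},
)


# ---------------------------------------------------------------------------
# Signature derivation
# ---------------------------------------------------------------------------
def build_signature(
    de_epi_vs_other: pd.DataFrame,
    de_sub_vs_subs: pd.DataFrame,
    lfc_min: float,
    fdr_max: float,
    name: str = "signature",
) -> GeneSignature:
    """Intersect two upregulation contrasts into a signature.

    Contrast 1 is tumor epithelium versus all other cells, contrast 2 the
    stem-like subpopulation versus the remaining tumor-epithelial
    subpopulations.  Genes passing ``log2_fc > lfc_min`` and ``fdr <
    fdr_max`` in both are kept, ordered by descending ``log2_fc`` in
    contrast 2.
    """
    if set(de_epi_vs_other.index) != set(de_sub_vs_subs.index):
        raise ValueError("DE tables must share the same gene universe")

    def passing(de: pd.DataFrame) -> set:
        return set(de.index[(de["log2_fc"] > lfc_min) & (de["fdr"] < fdr_max)])

    genes = passing(de_epi_vs_other) & passing(de_sub_vs_subs)
    if not genes:
        raise ValueError(
            "signature intersection is empty; consider relaxing lfc_min or fdr_max"
        )
    ordered = (
        de_sub_vs_subs.loc[sorted(genes)]
        .sort_values("log2_fc", ascending=False, kind="stable")
        .index.tolist()
    )
    return GeneSignature(
        name,
        tuple(ordered),
        provenance={
            "lfc_min": lfc_min,
            "fdr_max": fdr_max,
            "contrasts": ["epithelial_vs_other", "subpopulation_vs_siblings"],
        },
    )


# ---------------------------------------------------------------------------
# Sample scoring
# ---------------------------------------------------------------------------
class SignatureScorer(TransformerMixin, BaseEstimator):
    """Median-expression signature score per sample.

    ``transform`` returns, for each sample (row), the median log-normalized
    expression over the signature genes present in the matrix.  Missing
    genes are dropped with a logged warning; if fewer than
    ``min_coverage`` of the signature genes are present, fitting fails.
    """

    def __init__(self, signature: GeneSignature = None, min_coverage: float = 0.5):
        self.signature = signature
        self.min_coverage = min_coverage

    def fit(self, X, y=None):
        mat = as_matrix(X)
        genes = list(self.signature)
        present = [g for g in genes if g in mat.genes]
        missing = [g for g in genes if g not in mat.genes]
        coverage = len(present) / len(genes)
        if coverage < self.min_coverage:
            raise ValueError(
                f"only {len(present)}/{len(genes)} signature genes present "
                f"({coverage:.0%} < floor {self.min_coverage:.0%}); missing: {missing}"
            )
        if missing:
            logger.warning(
                "signature %s: dropping %d absent genes: %s",
                getattr(self.signature, "name", "?"),
                len(missing),
                missing,
            )
        self.genes_ = present
        self.missing_genes_ = missing
        return self

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self, "genes_")
        mat = as_matrix(X)
        return mat.data[self.genes_].median(axis=1).to_numpy()


def score_samples(
    bulk: ExpressionMatrix | pd.DataFrame,
    signature: GeneSignature,
    min_coverage: float = 0.5,
) -> pd.Series:
    """Per-sample median signature score; see :class:`SignatureScorer`."""
    mat = as_matrix(bulk)
    scorer = SignatureScorer(signature, min_coverage=min_coverage).fit(mat)
    return pd.Series(scorer.transform(mat), index=mat.units, name=signature.name)


def center_cohorts(bulk: pd.DataFrame, cohort: pd.Series) -> pd.DataFrame:
    """Gene-wise zero-mean, unit-variance scaling within each cohort.

    Applied before pooling bulk cohorts so that cohort-specific location
    and scale do not drive the median thresholds.  Zero-variance genes
    within a cohort are centered only.
    """
    out = bulk.copy().astype(float)
    for _, idx in bulk.groupby(cohort.loc[bulk.index], observed=True).groups.items():
        block = bulk.loc[idx]
        sd = block.std(axis=0, ddof=0).replace(0.0, 1.0)
        out.loc[idx] = (block - block.mean(axis=0)) / sd
    return out


# ---------------------------------------------------------------------------
# CSS assignment
# ---------------------------------------------------------------------------
class CSSClassifier(BaseEstimator):
    """Four-way quadrant classifier on two signature scores.

    ``fit`` learns the cohort medians of the LGR5 and LAPTM4B scores;
    ``predict`` assigns CSS1-4 by the quadrant rule (strictly greater
    than the median counts as "high").  Median thresholding makes the
    assignment invariant under any strictly increasing transform of
    either score vector.
    """

    def __init__(self):
        pass

    @staticmethod
    def _check_X(X) -> np.ndarray:
        arr = np.asarray(X, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 2:
            raise ValueError("X must have two columns: (lgr5_score, laptm4b_score)")
        return arr

    def fit(self, X, y=None):
        arr = self._check_X(X)
        if arr.shape[0] < 4:
            raise ValueError(f"need at least 4 samples to set median thresholds, got {arr.shape[0]}")
        self.median_lgr5_ = float(np.median(arr[:, 0]))
        self.median_laptm4b_ = float(np.median(arr[:, 1]))
        return self

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "median_lgr5_")
        arr = self._check_X(X)
        high_l = arr[:, 0] > self.median_lgr5_
        high_b = arr[:, 1] > self.median_laptm4b_
        # quadrant -> label: (low, low) CSS1, (low, high) CSS2,
        # (high, high) CSS3, (high, low) CSS4
        labels = np.where(
            high_l,
            np.where(high_b, "CSS3", "CSS4"),
            np.where(high_b, "CSS2", "CSS1"),
        )
        return labels

    def fit_predict(self, X, y=None) -> np.ndarray:
        return self.fit(X).predict(X)


def assign_css(scores_lgr5: pd.Series, scores_laptm4b: pd.Series) -> pd.DataFrame:
    """Assign CSS1-4 to every sample at cohort-median thresholds.

    Both score vectors must cover the same samples.  Returns a DataFrame
    with columns ``score_lgr5, score_laptm4b, subtype`` and the thresholds
    in ``DataFrame.attrs["thresholds"]``.
    """
    if set(scores_lgr5.index) != set(scores_laptm4b.index):
        raise ValueError("score vectors must cover the same samples")
    s_l = scores_lgr5
    s_b = scores_laptm4b.loc[s_l.index]
    clf = CSSClassifier().fit(np.column_stack([s_l, s_b]))
    labels = clf.predict(np.column_stack([s_l, s_b]))
    out = pd.DataFrame(
        {"score_lgr5": s_l, "score_laptm4b": s_b, "subtype": labels}, index=s_l.index
    )
    out.attrs["thresholds"] = {
        "median_lgr5": clf.median_lgr5_,
        "median_laptm4b": clf.median_laptm4b_,
    }
    return out


# ---------------------------------------------------------------------------
# Combined two-marker predictor
# ---------------------------------------------------------------------------
def combined_marker_score(
    expr_laptm4b: pd.Series, expr_lgr5: pd.Series
) -> pd.Series:
    """Log-scale LAPTM4B/LGR5 ratio: ``LAPTM4B - LGR5`` on log expression.

    Higher values predict higher recurrence risk.  The difference of logs
    is the monotone equivalent of the expression ratio, so ranking-based
    metrics (ROC/AUC, median dichotomization) are unchanged.
    """
    if set(expr_laptm4b.index) != set(expr_lgr5.index):
        raise ValueError("expression vectors must cover the same samples")
    out = expr_laptm4b - expr_lgr5.loc[expr_laptm4b.index]
    out.name = "laptm4b_minus_lgr5"
    return out


def extract_gene(bulk: ExpressionMatrix | pd.DataFrame, gene: str) -> pd.Series:
    """Per-sample expression of one gene; raises if the gene is absent."""
    mat = as_matrix(bulk)
    if gene not in mat.genes:
        raise KeyError(f"gene {gene!r} not present in the matrix")
    return mat.data[gene]
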