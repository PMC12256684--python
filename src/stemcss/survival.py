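"""Survival and association statistics for subtype outcome analysis.

Thin, validated wrappers around lifelines (Kaplan-Meier, log-rank, Cox
proportional hazards with Breslow tie handling), scikit-learn (ROC/AUC via
the Mann-Whitney identity with tie correction), scipy (Fisher's exact
test, Welch's t-test) and statsmodels (Benjamini-Hochberg).  The wrappers
fix conventions — error on degenerate inputs, two-sided tests, BH across
genes — so every stage of the pipeline reports comparable tables.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import logrank_test
from lifelines.utils import ConvergenceWarning
from scipy import stats
from sklearn.metrics import roc_auc_score, roc_curve

from .enrichment import bh_adjust

logger = logging.getLogger(__name__)

__all__ = [
    "km_estimate",
    "logrank",
    "cox_fit",
    "roc_auc",
    "mutation_enrichment",
    "tmb_compare",
]


def _check_survival(time, event) -> tuple[np.ndarray, np.ndarray]:
    t = np.asarray(time, dtype=float)
    e = np.asarray(event, dtype=int)
    if t.size == 0:
        raise ValueError("no survival records")
    if (t <= 0).any():
        raise ValueError("survival times must be positive")
    if not set(np.unique(e)) <= {0, 1}:
        raise ValueError("event indicators must be 0/1")
    return t, e


def km_estimate(time: Sequence[float], event: Sequence[int]) -> pd.DataFrame:
    """Product-limit (Kaplan-Meier) survival estimate with a risk table.

    Returns a step-function table with columns ``time, survival, at_risk,
    events``; survival starts at 1 and is non-increasing.
    """
    t, e = _check_survival(time, event)
    kmf = KaplanMeierFitter().fit(t, e)
    table = kmf.event_table
    out = pd.DataFrame(
        {
            "time": table.index.to_numpy(dtype=float),
            "survival": kmf.survival_function_["KM_estimate"].to_numpy(),
            "at_risk": table["at_risk"].to_numpy(dtype=int),
            "events": table["observed"].to_numpy(dtype=int),
        }
    ).reset_index(drop=True)
    return out


def logrank(
    time: Sequence[float],
    event: Sequence[int],
    group: Sequence,
    group_a,
    group_b,
) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi-square statistic, p-value)."""
    t, e = _check_survival(time, event)
    g = np.asarray(group)
    mask_a = g == group_a
    mask_b = g == group_b
    if mask_a.sum() == 0 or mask_b.sum() == 0:
        raise ValueError(f"empty group among ({group_a!r}, {group_b!r})")
    if e[mask_a].sum() + e[mask_b].sum() == 0:
        raise ValueError("log-rank test requires at least one event")
    res = logrank_test(t[mask_a], t[mask_b], e[mask_a], e[mask_b])
    return float(res.test_statistic), float(res.p_value)


def cox_fit(
    data: pd.DataFrame,
    duration_col: str,
    event_col: str,
    covariates: Sequence[str] | None = None,
    max_steps: int = 500,
) -> pd.DataFrame:
    """Cox proportional-hazards fit (Breslow tie handling).

    Returns a per-covariate table with columns ``coef, hr, ci_low,
    ci_high, p`` (hazard ratios with Wald 95% intervals).  Raises on
    constant covariates, too few events, separation, or non-convergence.
    """
    if covariates is None:
        covariates = [c for c in data.columns if c not in (duration_col, event_col)]
    covariates = list(covariates)
    if not covariates:
        raise ValueError("no covariates to fit")
    df = data[[duration_col, event_col, *covariates]].astype(float)
    _check_survival(df[duration_col], df[event_col])
    for c in covariates:
        if df[c].nunique() <= 1:
            raise ValueError(f"covariate {c!r} is constant")
    n_events = int(df[event_col].sum())
    if n_events < len(covariates) + 1:
        raise ValueError(
            f"{n_events} events insufficient for {len(covariates)} covariates"
        )
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", ConvergenceWarning)
            cph.fit(
                df,
                duration_col=duration_col,
                event_col=event_col,
                fit_options={"max_steps": max_steps},
            )
    except ConvergenceWarning as w:  # separation / collinearity signals
        raise ValueError(f"Cox model did not fit cleanly: {w}") from w
    except ConvergenceError as err:
        raise ValueError(f"Cox model failed to converge: {err}") from err
    s = cph.summary
    return pd.DataFrame(
        {
            "coef": s["coef"],
            "hr": s["exp(coef)"],
            "ci_low": s["exp(coef) lower 95%"],
            "ci_high": s["exp(coef) upper 95%"],
            "p": s["p"],
        }
    )


def roc_auc(
    scores: Sequence[float], labels: Sequence[int]
) -> tuple[float, pd.DataFrame]:
    """ROC AUC with tie correction plus the empirical ROC points.

    The AUC equals the Mann-Whitney U statistic normalized by the number
    of positive-negative pairs, with tied pairs counting 1/2 — identical
    to the trapezoidal area under the empirical ROC curve.
    """
    y = np.asarray(labels, dtype=int)
    s = np.asarray(scores, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present to compute a ROC curve")
    auc = float(roc_auc_score(y, s))
    fpr, tpr, thr = roc_curve(y, s)
    return auc, pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})


def mutation_enrichment(
    mutations: pd.DataFrame,
    groups: pd.Series,
    group_a,
    group_b,
) -> pd.DataFrame:
    """Per-gene mutation-frequency comparison between two sample groups.

    Two-sided Fisher's exact test on each gene's 2x2 table (mutated /
    wild-type by group), BH-adjusted across genes.  ``mutations`` is a
    binary samples x genes matrix.
    """
    vals = mutations.to_numpy()
    if not np.isin(vals, (0, 1)).all():
        raise ValueError("mutation matrix must be binary 0/1")
    g = groups.loc[mutations.index]
    idx_a = mutations.index[g == group_a]
    idx_b = mutations.index[g == group_b]
    if len(idx_a) == 0 or len(idx_b) == 0:
        raise ValueError(f"empty group among ({group_a!r}, {group_b!r})")
    n_a, n_b = len(idx_a), len(idx_b)
    rows = []
    for gene in mutations.columns:
        ka = int(mutations.loc[idx_a, gene].sum())
        kb = int(mutations.loc[idx_b, gene].sum())
        table = [[ka, n_a - ka], [kb, n_b - kb]]
        odds, p = stats.fisher_exact(table, alternative="two-sided")
        rows.append(
            {
                "gene": gene,
                "mutated_a": ka,
                "mutated_b": kb,
                "freq_a": ka / n_a,
                "freq_b": kb / n_b,
                "odds_ratio": odds,
                "p_value": p,
            }
        )
    out = pd.DataFrame(rows).set_index("gene")
    out["q_value"] = bh_adjust(out["p_value"])
    return out


def tmb_compare(tmb: pd.Series, groups: pd.Series) -> pd.DataFrame:
    """Pairwise Welch two-sided t-tests of mutation burden across groups.

    Zero-variance pairs with equal means yield ``t = 0, p = 1`` by
    convention (logged).  Every compared group needs n >= 3.
    """
    g = groups.loc[tmb.index]
    labels = sorted(map(str, g.unique()))
    rows = []
    for a, b in itertools.combinations(labels, 2):
        xa = tmb[g.astype(str) == a].to_numpy(dtype=float)
        xb = tmb[g.astype(str) == b].to_numpy(dtype=float)
        if len(xa) < 3 or len(xb) < 3:
            raise ValueError(f"group pair ({a}, {b}) needs n >= 3 per group")
        if xa.std() == 0 and xb.std() == 0 and xa.mean() == xb.mean():
            logger.info("tmb_compare: zero-variance equal-mean pair (%s, %s); p = 1", a, b)
            t_stat, p = 0.0, 1.0
        else:
            t_stat, p = stats.ttest_ind(xa, xb, equal_var=False)
        rows.append(
            {
                "group_a": a,
                "group_b": b,
                "mean_a": xa.mean(),
                "mean_b": xb.mean(),
                "t": float(t_stat),
                "p_value": float(p),
            }
        )
    return pd.DataFrame(rows)
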