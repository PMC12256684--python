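"""Ro/e, differential expression, BH, and the rank-based gene-set score."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import stemcss as scs
from stemcss.containers import ExpressionMatrix
from stemcss.enrichment import GeneSetAUCScorer, bh_adjust


# ---------------------------------------------------------------------------
# Ro/e
# ---------------------------------------------------------------------------
class TestRoe:
    @pytest.mark.parametrize(
        "table, expected",
        [
            ([[10, 10], [10, 10]], [[1.0, 1.0], [1.0, 1.0]]),
            ([[30, 10], [10, 30]], [[1.5, 0.5], [0.5, 1.5]]),
            ([[20, 0], [0, 20]], [[2.0, 0.0], [0.0, 2.0]]),
        ],
    )
    def test_known_tables(self, table, expected):
        out = scs.roe(pd.DataFrame(table))
        np.testing.assert_allclose(out.to_numpy(), expected)

    def test_zero_expected_is_nan(self):
        out = scs.roe(pd.DataFrame([[5, 0], [3, 0]]))
        assert out.iloc[:, 1].isna().all()

    def test_empty_table_errors(self):
        with pytest.raises(ValueError):
            scs.roe(pd.DataFrame())

    @given(
        st.lists(st.lists(st.integers(0, 50), min_size=3, max_size=3), min_size=2, max_size=4),
        st.integers(2, 9),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_scale_invariance_and_conservation(self, counts, factor):
        t = pd.DataFrame(counts)
        if t.to_numpy().sum() == 0:
            return
        base = scs.roe(t)
        scaled = scs.roe(t * factor)
        pd.testing.assert_frame_equal(base, scaled)
        # conservation: sum_j roe(i,j) * col_total(j) = grand total for any
        # row with a nonzero total (columns with zero totals contribute 0)
        col_tot = t.sum(axis=0).to_numpy(dtype=float)
        row_tot = t.sum(axis=1).to_numpy(dtype=float)
        recon = np.nansum(base.to_numpy() * col_tot, axis=1)
        np.testing.assert_allclose(
            recon[row_tot > 0], t.to_numpy().sum(), atol=1e-9
        )


# ---------------------------------------------------------------------------
# BH
# ---------------------------------------------------------------------------
def bh_stepup_oracle(p):
    """Direct step-up definition: q_(i) = min_{j >= i} p_(j) * n / j."""
    p = np.asarray(p, dtype=float)
    n = len(p)
    order = np.argsort(p, kind="stable")
    q_sorted = np.minimum.accumulate((p[order] * n / np.arange(1, n + 1))[::-1])[::-1]
    q = np.empty(n)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def test_bh_matches_stepup_definition(rng):
    for n in (1, 2, 7, 100, 1000):
        p = rng.random(n)
        np.testing.assert_allclose(bh_adjust(p), bh_stepup_oracle(p), atol=1e-12)
    # with ties
    p = np.repeat(rng.random(50), 4)
    np.testing.assert_allclose(bh_adjust(p), bh_stepup_oracle(p), atol=1e-12)


# ---------------------------------------------------------------------------
# Differential expression
# ---------------------------------------------------------------------------
def _toy_matrix(rng, n_a=40, n_b=40, n_genes=30, fold_gene=None, fold=4.0):
    mu = np.full(n_genes, 2.0)
    counts_a = rng.poisson(mu, (n_a, n_genes)).astype(float)
    mu_b = mu.copy()
    counts_b = rng.poisson(mu_b, (n_b, n_genes)).astype(float)
    if fold_gene is not None:
        counts_a[:, fold_gene] = rng.poisson(mu[fold_gene] * fold, n_a)
    ids = [f"u{i}" for i in range(n_a + n_b)]
    df = pd.DataFrame(
        np.vstack([counts_a, counts_b]), index=ids, columns=[f"g{j}" for j in range(n_genes)]
    )
    mat = ExpressionMatrix(df).log_normalize()
    return mat, ids[:n_a], ids[n_a:]


class TestDiffExpr:
    def test_label_swap_negates_lfc_and_preserves_p(self, rng):
        mat, a, b = _toy_matrix(rng, fold_gene=3)
        ab = scs.diff_expr(mat, a, b)
        ba = scs.diff_expr(mat, b, a)
        np.testing.assert_allclose(ab["log2_fc"], -ba["log2_fc"], atol=1e-10)
        np.testing.assert_allclose(ab["p_value"], ba["p_value"], atol=1e-12)

    def test_planted_fold_recovered(self, sc_sim, de_tables):
        """Planted 4-fold markers (x2 arm gain) reach log2_fc ~ 2.9 and tiny FDR."""
        de = de_tables["lap_vs_rest"]
        planted = sc_sim.truth["markers"]["stem_laptm4b"]
        assert (de.loc[planted, "log2_fc"] > 2).all()
        assert (de.loc[planted, "fdr"] < 0.01).all()

    def test_null_labels_yield_no_discoveries(self, rng):
        mat, a, b = _toy_matrix(rng, n_a=100, n_b=100, n_genes=200)
        de = scs.diff_expr(mat, a, b)
        assert (de["fdr"] < 0.01).sum() == 0

    def test_all_zero_gene_degenerate(self, rng):
        mat, a, b = _toy_matrix(rng)
        df = mat.data.copy()
        df["gz"] = 0.0
        de = scs.diff_expr(ExpressionMatrix(df, is_log=True), a, b)
        assert de.loc["gz", "p_value"] == 1.0
        assert de.loc["gz", "log2_fc"] == 0.0

    def test_overlap_and_small_group_errors(self, rng):
        mat, a, b = _toy_matrix(rng)
        with pytest.raises(ValueError, match="overlap"):
            scs.diff_expr(mat, a, a[:5] + b[:5])
        with pytest.raises(ValueError, match=">= 3"):
            scs.diff_expr(mat, a[:2], b)

    def test_requires_log_matrix(self, rng):
        raw = ExpressionMatrix(pd.DataFrame(rng.poisson(2, (10, 4)).astype(float)))
        with pytest.raises(ValueError, match="log-normalized"):
            scs.diff_expr(raw, list(range(5)), list(range(5, 10)))


# ---------------------------------------------------------------------------
# Gene-set AUC
# ---------------------------------------------------------------------------
def stepcurve_oracle(ranks_of_hits, n_genes, k):
    """Enumerate the recovery step curve explicitly over ranks 1..k."""
    area = 0
    for i in range(1, k + 1):
        area += sum(1 for r in ranks_of_hits if r <= i)
    m = min(len(ranks_of_hits), k)
    max_area = sum(range(k, k - m, -1))
    return area / max_area


def _matrix_with_ranks(hit_ranks, n_genes=100):
    """One cell whose expression decreases with rank; hits at given ranks."""
    expr = np.arange(n_genes, 0, -1, dtype=float)
    genes = [f"g{j}" for j in range(n_genes)]
    df = pd.DataFrame([expr], index=["cell0"], columns=genes)
    sig = [genes[r - 1] for r in hit_ranks]
    return ExpressionMatrix(df, is_log=True), sig


class TestGeneSetAUC:
    def test_top_ranked_signature_scores_one(self):
        mat, sig = _matrix_with_ranks([1, 2, 3], n_genes=100)
        assert scs.gene_set_auc(mat, sig, top_fraction=0.05).iloc[0] == 1.0

    def test_signature_outside_top_fraction_scores_zero(self):
        mat, sig = _matrix_with_ranks([90, 95], n_genes=100)
        assert scs.gene_set_auc(mat, sig, top_fraction=0.05).iloc[0] == 0.0

    def test_known_stepcurve_example(self):
        # G=100, k=5, hits at ranks 2 and 4: area (4 + 2) over max (5 + 4)
        mat, sig = _matrix_with_ranks([2, 4], n_genes=100)
        got = scs.gene_set_auc(mat, sig, top_fraction=0.05).iloc[0]
        assert got == pytest.approx(stepcurve_oracle([2, 4], 100, 5))
        assert got == pytest.approx(6 / 9)

    def test_matches_oracle_on_random_instances(self, rng):
        n_genes, k = 200, 10
        for _ in range(50):
            hits = sorted(rng.choice(np.arange(1, n_genes + 1), size=4, replace=False))
            mat, sig = _matrix_with_ranks(hits, n_genes=n_genes)
            got = scs.gene_set_auc(mat, sig, top_fraction=k / n_genes).iloc[0]
            assert got == pytest.approx(stepcurve_oracle(hits, n_genes, k))

    def test_monotone_transform_invariance(self, rng):
        x = rng.random((20, 60))
        genes = [f"g{j}" for j in range(60)]
        sig = genes[:4]
        a = ExpressionMatrix(pd.DataFrame(x, columns=genes), is_log=True)
        b = ExpressionMatrix(pd.DataFrame(np.exp(3 * x) + 1, columns=genes), is_log=True)
        pd.testing.assert_series_equal(
            scs.gene_set_auc(a, sig), scs.gene_set_auc(b, sig)
        )

    def test_missing_genes_named_in_error(self, rng):
        mat = ExpressionMatrix(
            pd.DataFrame(rng.random((5, 10)), columns=[f"g{j}" for j in range(10)]),
            is_log=True,
        )
        with pytest.raises(ValueError, match="ABSENT"):
            scs.gene_set_auc(mat, ["ABSENT"])

    def test_transform_requires_same_universe(self, rng):
        genes = [f"g{j}" for j in range(10)]
        mat = ExpressionMatrix(pd.DataFrame(rng.random((5, 10)), columns=genes), is_log=True)
        scorer = GeneSetAUCScorer(genes[:2]).fit(mat)
        other = ExpressionMatrix(pd.DataFrame(rng.random((5, 9)), columns=genes[:9]), is_log=True)
        with pytest.raises(ValueError, match="universe"):
            scorer.transform(other)
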