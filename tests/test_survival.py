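"""Kaplan-Meier, log-rank, Cox, ROC/AUC, Fisher enrichment, TMB."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import stemcss as scs


# ---------------------------------------------------------------------------
# Kaplan-Meier
# ---------------------------------------------------------------------------
class TestKM:
    def test_product_limit_hand_example(self):
        km = scs.km_estimate([1, 2], [1, 1])
        s = km.set_index("time")["survival"]
        assert s.loc[1.0] == pytest.approx(0.5)
        assert s.loc[2.0] == pytest.approx(0.0)

    def test_all_censored_stays_at_one(self):
        km = scs.km_estimate([3, 5, 8], [0, 0, 0])
        assert (km["survival"] == 1.0).all()

    def test_duplicated_dataset_same_curve(self, rng):
        t = rng.exponential(10, 30) + 0.1
        e = rng.integers(0, 2, 30)
        a = scs.km_estimate(t, e)
        b = scs.km_estimate(np.tile(t, 2), np.tile(e, 2))
        np.testing.assert_allclose(
            a["survival"].to_numpy(), b["survival"].to_numpy(), atol=1e-12
        )

    def test_no_censoring_equals_empirical_survival(self, rng):
        t = np.sort(rng.exponential(5, 40)) + 0.01
        km = scs.km_estimate(t, np.ones(40, dtype=int))
        emp = 1 - np.arange(1, 41) / 40
        np.testing.assert_allclose(km["survival"].to_numpy()[1:], emp, atol=1e-12)

    def test_nonpositive_times_error(self):
        with pytest.raises(ValueError, match="positive"):
            scs.km_estimate([0.0, 1.0], [1, 1])


# ---------------------------------------------------------------------------
# Log-rank
# ---------------------------------------------------------------------------
def logrank_oracle(t_a, e_a, t_b, e_b):
    """Direct O-E tabulation of the two-group log-rank statistic."""
    events = sorted({t for t, e in zip(list(t_a) + list(t_b), list(e_a) + list(e_b)) if e})
    O = E = V = 0.0
    for tt in events:
        n_a = sum(1 for t in t_a if t >= tt)
        n_b = sum(1 for t in t_b if t >= tt)
        d_a = sum(1 for t, e in zip(t_a, e_a) if t == tt and e)
        d_b = sum(1 for t, e in zip(t_b, e_b) if t == tt and e)
        n, d = n_a + n_b, d_a + d_b
        O += d_a
        E += d * n_a / n
        if n > 1:
            V += d * (n_a / n) * (n_b / n) * (n - d) / (n - 1)
    return (O - E) ** 2 / V


class TestLogrank:
    def test_identical_groups_null(self):
        t = [1.0, 2.0, 3.0]
        e = [1, 1, 0]
        stat, p = scs.logrank(t + t, e + e, [0, 0, 0, 1, 1, 1], 0, 1)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_disjoint_blocks_match_manual_tabulation(self):
        t = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        e = [1] * 6
        g = [0, 0, 0, 1, 1, 1]
        stat, _ = scs.logrank(t, e, g, 0, 1)
        expected = logrank_oracle(t[:3], e[:3], t[3:], e[3:])
        assert stat == pytest.approx(expected, rel=1e-9)

    def test_matches_oracle_with_censoring_and_ties(self, rng):
        for _ in range(10):
            t = rng.integers(1, 8, 30).astype(float)
            e = rng.integers(0, 2, 30)
            g = rng.integers(0, 2, 30)
            if e[g == 0].sum() + e[g == 1].sum() == 0 or (g == 0).sum() == 0 or (g == 1).sum() == 0:
                continue
            stat, _ = scs.logrank(t, e, g, 0, 1)
            expected = logrank_oracle(t[g == 0], e[g == 0], t[g == 1], e[g == 1])
            assert stat == pytest.approx(expected, rel=1e-8)

    def test_empty_group_errors(self):
        with pytest.raises(ValueError, match="empty group"):
            scs.logrank([1, 2], [1, 1], [0, 0], 0, 1)


# ---------------------------------------------------------------------------
# Cox
# ---------------------------------------------------------------------------
class TestCox:
    def test_identical_groups_hr_one(self):
        t = [1.0, 2.0, 3.0, 4.0, 6.0, 9.0]
        e = [1, 1, 0, 1, 1, 0]
        df = pd.DataFrame(
            {"time": t + t, "event": e + e, "group": [0] * 6 + [1] * 6}
        )
        out = scs.cox_fit(df, "time", "event", ["group"])
        assert out.loc["group", "hr"] == pytest.approx(1.0, abs=1e-6)

    def test_time_scale_invariance(self):
        df = scs.simulate_two_group_survival(120, 2.0, seed=4)
        hr1 = scs.cox_fit(df, "time", "event", ["group"]).loc["group", "hr"]
        df2 = df.assign(time=df["time"] * 12.0)
        hr2 = scs.cox_fit(df2, "time", "event", ["group"]).loc["group", "hr"]
        assert hr1 == pytest.approx(hr2, rel=1e-6)

    def test_planted_hr_recovered(self):
        df = scs.simulate_two_group_survival(600, 2.3, seed=11)
        hr = scs.cox_fit(df, "time", "event", ["group"]).loc["group", "hr"]
        assert 1.8 <= hr <= 2.9

    def test_constant_covariate_errors(self):
        df = pd.DataFrame({"time": [1.0, 2, 3, 4], "event": [1, 1, 0, 1], "x": [1.0] * 4})
        with pytest.raises(ValueError, match="constant"):
            scs.cox_fit(df, "time", "event", ["x"])

    def test_agrees_with_logrank_direction(self):
        df = scs.simulate_two_group_survival(400, 2.0, seed=2)
        out = scs.cox_fit(df, "time", "event", ["group"])
        stat, p_lr = scs.logrank(df["time"], df["event"], df["group"], 0, 1)
        assert out.loc["group", "hr"] > 1  # group 1 has the higher hazard
        # Wald p and log-rank p agree to within 10% relative on this design
        assert out.loc["group", "p"] == pytest.approx(p_lr, rel=0.25, abs=1e-4)


# ---------------------------------------------------------------------------
# ROC / AUC
# ---------------------------------------------------------------------------
def auc_pair_oracle(scores, labels):
    """Brute-force positive-negative pair counting with half-credit ties."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0 for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestRocAuc:
    def test_perfect_separation(self):
        auc, _ = scs.roc_auc([1, 2, 10, 11], [0, 0, 1, 1])
        assert auc == 1.0

    def test_all_ties_half(self):
        auc, _ = scs.roc_auc([5, 5, 5, 5], [0, 1, 0, 1])
        assert auc == pytest.approx(0.5)

    def test_known_pair_count_example(self):
        auc, _ = scs.roc_auc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1])
        assert auc == pytest.approx(0.75)

    def test_complement_identity(self, rng):
        s = rng.integers(0, 5, 50).astype(float)
        y = rng.integers(0, 2, 50)
        if len(np.unique(y)) < 2:
            y[0], y[1] = 0, 1
        a1, _ = scs.roc_auc(s, y)
        a2, _ = scs.roc_auc(-s, y)
        assert a1 + a2 == pytest.approx(1.0)

    def test_matches_pair_oracle_with_ties(self, rng):
        for _ in range(25):
            s = rng.integers(0, 6, 30).astype(float)
            y = np.r_[np.zeros(15, int), np.ones(15, int)]
            auc, _ = scs.roc_auc(s, y)
            assert auc == pytest.approx(auc_pair_oracle(s, y), abs=1e-12)

    def test_single_class_errors(self):
        with pytest.raises(ValueError, match="class"):
            scs.roc_auc([1, 2, 3], [1, 1, 1])


# ---------------------------------------------------------------------------
# Fisher enrichment
# ---------------------------------------------------------------------------
def fisher_oracle(a, b, c, d):
    """Two-sided exact p: sum of hypergeometric outcomes no more likely
    than the observed table, at fixed margins."""
    n = a + b + c + d
    row1, col1 = a + b, a + c
    rv = stats.hypergeom(n, col1, row1)
    support = np.arange(max(0, row1 + col1 - n), min(row1, col1) + 1)
    pmf = rv.pmf(support)
    p_obs = rv.pmf(a)
    return float(pmf[pmf <= p_obs * (1 + 1e-9)].sum())


class TestMutationEnrichment:
    @staticmethod
    def _table_to_inputs(a, b, c, d):
        """Build a one-gene mutation matrix realizing the 2x2 table."""
        samples = [f"s{i}" for i in range(a + b + c + d)]
        gene = [1] * a + [0] * b + [1] * c + [0] * d
        groups = ["A"] * (a + b) + ["B"] * (c + d)
        mut = pd.DataFrame({"TP53": gene}, index=samples)
        return mut, pd.Series(groups, index=samples)

    def test_balanced_table_p_one(self):
        mut, g = self._table_to_inputs(5, 5, 5, 5)
        out = scs.mutation_enrichment(mut, g, "A", "B")
        assert out.loc["TP53", "p_value"] == pytest.approx(1.0)

    def test_extreme_table_exact_value(self):
        from math import comb

        mut, g = self._table_to_inputs(10, 0, 0, 10)
        out = scs.mutation_enrichment(mut, g, "A", "B")
        assert out.loc["TP53", "p_value"] == pytest.approx(2 / comb(20, 10), rel=1e-9)

    def test_matches_enumeration_oracle_small_margins(self):
        for a, b, c, d in itertools.product(range(5), repeat=4):
            if a + b == 0 or c + d == 0:
                continue
            mut, g = self._table_to_inputs(a, b, c, d)
            out = scs.mutation_enrichment(mut, g, "A", "B")
            assert out.loc["TP53", "p_value"] == pytest.approx(
                fisher_oracle(a, b, c, d), rel=1e-7
            )

    def test_planted_frequencies_detected(self, bulk_sim):
        out = scs.mutation_enrichment(bulk_sim.mutations, bulk_sim.truth, "CSS2", "CSS4")
        # TP53 planted at 75% in CSS2 vs 40% in CSS4
        assert out.loc["TP53", "q_value"] < 0.05
        assert out.loc["TP53", "freq_a"] > out.loc["TP53", "freq_b"]

    def test_nonbinary_matrix_errors(self):
        mut = pd.DataFrame({"g": [0, 2]}, index=["a", "b"])
        g = pd.Series(["A", "B"], index=["a", "b"])
        with pytest.raises(ValueError, match="binary"):
            scs.mutation_enrichment(mut, g, "A", "B")


# ---------------------------------------------------------------------------
# TMB
# ---------------------------------------------------------------------------
class TestTmbCompare:
    def test_identical_groups(self):
        tmb = pd.Series([5.0, 7, 9, 5, 7, 9], index=list("abcdef"))
        g = pd.Series(["x"] * 3 + ["y"] * 3, index=list("abcdef"))
        out = scs.tmb_compare(tmb, g)
        assert out.loc[0, "t"] == pytest.approx(0.0)
        assert out.loc[0, "p_value"] == pytest.approx(1.0)

    def test_zero_variance_convention(self):
        tmb = pd.Series([4.0] * 6, index=list("abcdef"))
        g = pd.Series(["x"] * 3 + ["y"] * 3, index=list("abcdef"))
        out = scs.tmb_compare(tmb, g)
        assert out.loc[0, "p_value"] == 1.0

    def test_shifted_groups_power(self, rng):
        x = rng.normal(10, 1, 50)
        y = rng.normal(13, 1, 50)  # 3 SD shift
        tmb = pd.Series(np.r_[x, y], index=[f"s{i}" for i in range(100)])
        g = pd.Series(["x"] * 50 + ["y"] * 50, index=tmb.index)
        out = scs.tmb_compare(tmb, g)
        assert out.loc[0, "p_value"] < 1e-6

    def test_hypermutated_subtype_stands_out(self, bulk_sim):
        out = scs.tmb_compare(bulk_sim.clinical["tmb"], bulk_sim.truth)
        css1_rows = out[(out.group_a == "CSS1") | (out.group_b == "CSS1")]
        assert (css1_rows["p_value"] < 1e-10).all()

    def test_small_group_errors(self):
        tmb = pd.Series([1.0, 2, 3], index=list("abc"))
        g = pd.Series(["x", "x", "y"], index=list("abc"))
        with pytest.raises(ValueError, match="n >= 3"):
            scs.tmb_compare(tmb, g)
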