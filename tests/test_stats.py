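"""ICC QC, Spearman/BH screening, log-rank/cutpoint/Cox, mutation tests."""

import math
from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps
from scipy.special import comb

from fwctex.coxph import cox_gradient_information, cox_score_test
from fwctex.stats import (
    bh_adjust,
    cox_forward_selection,
    icc_two_way,
    km_optimal_cutoff,
    logrank_test,
    mutation_count_test,
    mutation_fisher,
    qc_filter_features,
    spearman,
)


# ------------------------------------------------------------------ ICC


class TestICC:
    def test_identical_columns_give_one(self):
        r = np.column_stack([[1.0, 2, 3, 4], [1.0, 2, 3, 4]])
        assert icc_two_way(r) == pytest.approx(1.0)

    def test_matches_anova_mean_squares_oracle(self):
        ratings = np.array([[9.0, 2.0], [45.0, 40.0], [30.0, 20.0], [15.0, 14.0]])
        n, k = ratings.shape
        grand = ratings.mean()
        msr = k * ((ratings.mean(1) - grand) ** 2).sum() / (n - 1)
        msc = n * ((ratings.mean(0) - grand) ** 2).sum() / (k - 1)
        sst = ((ratings - grand) ** 2).sum()
        mse = (sst - msr * (n - 1) - msc * (k - 1)) / ((n - 1) * (k - 1))
        expected = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
        assert icc_two_way(ratings) == pytest.approx(expected, abs=1e-10)

    def test_agrees_with_pingouin_icc2(self, rng):
        pg = pytest.importorskip("pingouin")
        subj = rng.normal(0, 2, 20)
        ratings = subj[:, None] + rng.normal(0, 1, (20, 2)) + np.array([0.0, 0.5])
        df = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(20), 2),
                "rater": np.tile([0, 1], 20),
                "score": ratings.ravel(),
            }
        )
        table = pg.intraclass_corr(df, targets="subject", raters="rater", ratings="score")
        sel = table["Type"].isin(["ICC2", "ICC(A,1)"])  # two-way random, absolute, single
        expected = float(table.loc[sel, "ICC"].iloc[0])
        assert icc_two_way(ratings) == pytest.approx(expected, abs=1e-8)

    def test_simulation_recovery_of_theoretical_icc(self):
        """Subject var 4, error var 1 => ICC = 0.8; mean estimate within 0.05."""
        r = np.random.default_rng(7)
        estimates = []
        for _ in range(100):
            subj = r.normal(0, 2.0, 200)
            ratings = subj[:, None] + r.normal(0, 1.0, (200, 2))
            estimates.append(icc_two_way(ratings))
        assert np.mean(estimates) == pytest.approx(0.8, abs=0.05)

    def test_zero_variance_errors(self):
        with pytest.raises(ValueError, match="variance"):
            icc_two_way(np.full((5, 2), 3.0))

    def test_too_few_subjects_errors(self):
        with pytest.raises(ValueError):
            icc_two_way(np.array([[1.0, 2.0], [3.0, 4.0]]))


class TestQCFilter:
    def _tables(self, rng, n=20):
        base = pd.DataFrame(
            {"f1": rng.normal(0, 1, n), "f2": rng.normal(5, 2, n)},
            index=[f"P{i}" for i in range(n)],
        )
        return base, base.copy()

    def test_identical_operators_retain_everything(self, rng):
        a, b = self._tables(rng)
        rep = qc_filter_features(a, b)
        assert rep.table["retained"].all()
        assert np.allclose(rep.table["icc"], 1.0)
        assert rep.averaged.equals(a[rep.retained_features])

    def test_corrupted_feature_excluded(self, rng):
        a, b = self._tables(rng)
        b = b.copy()
        a["bad"] = rng.normal(0, 1, len(a))
        b["bad"] = rng.normal(0, 1, len(b))  # independent noise per operator
        rep = qc_filter_features(a, b)
        row = rep.table.set_index("feature")
        assert not row.loc["bad", "retained"]
        assert row.loc["f1", "retained"] and row.loc["f2", "retained"]

    def test_retention_matches_independent_recomputation(self, default_cohort):
        from fwctex.stats import extract_cohort_features

        f1, f2 = extract_cohort_features(default_cohort)
        rep = qc_filter_features(f1, f2)
        for _, row in rep.table.iterrows():
            a = f1[row["feature"]].to_numpy(float)
            b = f2[row["feature"]].to_numpy(float)
            ok = np.isfinite(a) & np.isfinite(b)
            if ok.sum() < 3:
                assert not row["retained"]
                continue
            try:
                icc = icc_two_way(np.column_stack([a[ok], b[ok]]))
            except ValueError:
                assert not row["retained"]
                continue
            assert row["retained"] == (icc > 0.75)

    def test_averaging_is_operator_mean(self, rng):
        a, b = self._tables(rng)
        b = b + 0.01 * rng.normal(size=b.shape)
        rep = qc_filter_features(a, b)
        for feat in rep.retained_features:
            assert np.allclose(rep.averaged[feat], (a[feat] + b[feat]) / 2)


# ------------------------------------------------- Spearman and BH


class TestSpearman:
    def test_perfect_monotone(self):
        r, _ = spearman([1, 2, 3, 4, 5], [10, 20, 40, 80, 100])
        assert r == pytest.approx(1.0)

    def test_rank_difference_formula_oracle(self):
        x, y = [1, 2, 3, 4, 5], [2, 1, 4, 3, 5]
        d2 = sum((xi - yi) ** 2 for xi, yi in zip([1, 2, 3, 4, 5], [2, 1, 4, 3, 5]))
        assert d2 == 4
        r, _ = spearman(x, y)
        assert r == pytest.approx(1 - 6 * d2 / (5 * 24))  # 0.8
        assert r == pytest.approx(0.8)

    def test_zero_rank_variance_errors(self):
        with pytest.raises(ValueError, match="variance"):
            spearman([1, 1, 1, 1], [1, 2, 3, 4])

    def test_too_few_pairs_errors(self):
        with pytest.raises(ValueError):
            spearman([1, 2, 3], [3, 2, 1])


class TestBHAdjust:
    @staticmethod
    def brute_force_bh(p, q):
        """Step-up oracle: scan every threshold p_(k) <= k q / m."""
        p = np.asarray(p, float)
        m = len(p)
        order = np.argsort(p)
        k_star = 0
        for rank, idx in enumerate(order, start=1):
            if p[idx] <= rank * q / m:
                k_star = rank
        reject = np.zeros(m, bool)
        if k_star:
            reject[order[:k_star]] = True
        return reject

    def test_all_ones_no_rejection(self):
        assert not bh_adjust(np.ones(8), 0.1).any()

    def test_matches_brute_force_oracle_on_many_random_vectors(self):
        r = np.random.default_rng(3)
        for _ in range(1000):
            m = int(r.integers(1, 25))
            p = r.uniform(0, 1, m) ** r.uniform(0.3, 3)
            q = float(r.uniform(0.01, 0.5))
            assert np.array_equal(bh_adjust(p, q), self.brute_force_bh(p, q))

    def test_monotone_in_q(self, rng):
        p = rng.uniform(0, 1, 12)
        lo = bh_adjust(p, 0.05)
        hi = bh_adjust(p, 0.2)
        assert np.all(hi[lo])  # raising q never removes a rejection

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])


# -------------------------------------------------------- survival


def _logrank_oracle(times, events, groups):
    """Risk-table enumeration: chi2 = (O1 - E1)^2 / V from first principles."""
    times = np.asarray(times, float)
    events = np.asarray(events, bool)
    groups = np.asarray(groups, bool)
    o_minus_e = 0.0
    var = 0.0
    for t in np.unique(times[events]):
        at_risk = times >= t
        n = at_risk.sum()
        n1 = (at_risk & groups).sum()
        d = (events & (times == t)).sum()
        d1 = (events & (times == t) & groups).sum()
        e1 = d * n1 / n
        o_minus_e += d1 - e1
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    chi2 = o_minus_e**2 / var
    return chi2, float(sps.chi2.sf(chi2, 1))


class TestLogrank:
    def test_label_symmetry(self, rng):
        times = rng.exponential(10, 24) + 0.1
        events = rng.random(24) < 0.7
        groups = rng.random(24) < 0.5
        a = logrank_test(times, events, groups)
        b = logrank_test(times, events, ~groups)
        assert a[0] == pytest.approx(b[0], abs=1e-10)

    def test_six_subject_worked_case_matches_risk_table_oracle(self):
        times = np.array([2.0, 4.0, 5.0, 7.0, 9.0, 12.0])
        events = np.array([1, 1, 0, 1, 1, 1], bool)
        groups = np.array([1, 0, 1, 0, 1, 0], bool)
        chi2, p = logrank_test(times, events, groups)
        chi2_o, p_o = _logrank_oracle(times, events, groups)
        assert chi2 == pytest.approx(chi2_o, abs=1e-8)
        assert p == pytest.approx(p_o, abs=1e-8)

    def test_oracle_agreement_random_instances(self, rng):
        for _ in range(20):
            n = int(rng.integers(8, 30))
            times = np.round(rng.exponential(10, n), 1) + 0.5  # induces ties
            events = rng.random(n) < 0.7
            groups = rng.random(n) < 0.5
            if events.sum() == 0 or len(np.unique(groups)) < 2:
                continue
            chi2, _ = logrank_test(times, events, groups)
            chi2_o, _ = _logrank_oracle(times, events, groups)
            assert chi2 == pytest.approx(chi2_o, abs=1e-8)

    def test_single_group_errors(self):
        with pytest.raises(ValueError, match="2 groups"):
            logrank_test([1, 2, 3], [1, 1, 1], [0, 0, 0])


class TestOptimalCutoff:
    def _cohort(self, rng, n=30):
        values = rng.normal(0, 1, n)
        hazard = 0.03 * np.exp(1.2 * (values > 0))
        t = rng.exponential(1 / hazard)
        times = np.minimum(t, 32.0)
        events = t <= 32.0
        return values, times, events

    def test_single_candidate_equals_fixed_threshold_logrank(self, rng):
        values = np.array([0.0] * 15 + [1.0] * 15)
        _, times, events = self._cohort(rng, 30)
        entry, _ = km_optimal_cutoff(values, times, events)
        assert entry.n_candidates == 1
        chi2, p = logrank_test(times, events, values >= entry.optimal_threshold)
        assert entry.p == pytest.approx(p)
        assert entry.logrank_chi2 == pytest.approx(chi2)

    def test_matches_exhaustive_scan_oracle(self, rng):
        values, times, events = self._cohort(rng, 30)
        entry, _ = km_optimal_cutoff(values, times, events, min_group_frac=0.1)
        sv = np.sort(np.unique(values))
        best_p, best_thr = np.inf, None
        for thr in (sv[:-1] + sv[1:]) / 2:
            high = values >= thr
            if high.sum() < 3 or (~high).sum() < 3:
                continue
            _, p = logrank_test(times, events, high)
            if p < best_p - 1e-15:
                best_p, best_thr = p, thr
        assert entry.optimal_threshold == pytest.approx(best_thr)
        assert entry.p == pytest.approx(best_p)

    def test_reported_p_is_minimal_over_admissible_thresholds(self, rng):
        values, times, events = self._cohort(rng, 30)
        entry, _ = km_optimal_cutoff(values, times, events)
        for thr in np.quantile(values, [0.2, 0.4, 0.5, 0.6, 0.8]):
            high = values >= thr
            if high.sum() < 3 or (~high).sum() < 3:
                continue
            _, p = logrank_test(times, events, high)
            assert entry.p <= p + 1e-12

    def test_group_sizes_sum_to_n(self, rng):
        values, times, events = self._cohort(rng, 30)
        entry, curves = km_optimal_cutoff(values, times, events)
        assert entry.n_high + entry.n_low == 30
        assert set(curves["group"]) == {"high", "low"}

    def test_direction_reflects_worse_survival(self, rng):
        # strongly adverse high group
        values = np.concatenate([np.zeros(15), np.ones(15)])
        times = np.concatenate([np.full(15, 30.0), np.full(15, 3.0) + rng.uniform(0, 1, 15)])
        events = np.concatenate([np.zeros(15, bool), np.ones(15, bool)])
        entry, _ = km_optimal_cutoff(values, times, events)
        assert entry.direction == "high_poor"

    def test_requires_events_and_size(self):
        with pytest.raises(ValueError):
            km_optimal_cutoff(np.arange(5), np.ones(5), np.ones(5, bool))
        with pytest.raises(ValueError):
            km_optimal_cutoff(np.arange(12), np.ones(12), np.zeros(12, bool))


# ------------------------------------------------------------- Cox


class TestCoxScore:
    def test_gradient_zero_at_lifelines_mle(self, rng):
        from lifelines import CoxPHFitter

        n = 120
        x = rng.normal(0, 1, (n, 2))
        t = rng.exponential(np.exp(-(0.8 * x[:, 0] - 0.3 * x[:, 1])))
        e = rng.random(n) < 0.8
        df = pd.DataFrame({"x0": x[:, 0], "x1": x[:, 1], "T": t, "E": e.astype(int)})
        cph = CoxPHFitter().fit(df, "T", "E")
        u, info = cox_gradient_information(t, e, x, cph.params_.to_numpy())
        # zero up to the fitter's own convergence tolerance (score at the
        # null is O(sqrt(n)) ~ 10, so 1e-3 is a 1e-4 relative residual)
        assert np.allclose(u, 0.0, atol=1e-3)
        assert np.all(np.linalg.eigvalsh(info) > 0)

    def test_null_score_test_equals_logrank_without_ties(self, rng):
        n = 40
        groups = rng.random(n) < 0.5
        times = rng.exponential(10 * np.exp(-0.8 * groups))  # continuous: no ties
        events = np.ones(n, bool)
        chi2_score, _ = cox_score_test(times, events, None, None, groups.astype(float))
        chi2_lr, _ = logrank_test(times, events, groups)
        assert chi2_score == pytest.approx(chi2_lr, rel=1e-6)


class TestCoxForward:
    def _survival(self, rng, n, loghr, marker):
        t = rng.exponential(1 / (0.02 * np.exp(loghr * marker)))
        times = np.minimum(t, 32.0)
        events = t <= 32.0
        return times, events

    def test_null_candidates_yield_empty_model_with_scores(self, rng):
        n = 80
        markers = pd.DataFrame(
            {"a": rng.integers(0, 2, n).astype(float), "b": rng.integers(0, 2, n).astype(float)}
        )
        times = rng.exponential(20, n)
        events = np.minimum(times, 32) == times
        times = np.minimum(times, 32)
        rep = cox_forward_selection(times, events, markers, alpha=1e-6)
        assert rep.included.empty
        assert set(rep.excluded["term"]) == {"a", "b", "a*b"}
        assert (rep.excluded["score_p"] <= 1).all()

    def test_true_marker_enters_first_and_recovers_loghr(self):
        r = np.random.default_rng(11)
        firsts, coefs = [], []
        for _ in range(50):
            n = 200
            a = (r.random(n) < 0.5).astype(float)
            b = (r.random(n) < 0.5).astype(float)
            times, events = self._survival(r, n, 1.5, a)
            rep = cox_forward_selection(
                times, events, pd.DataFrame({"a": a, "b": b}), include_interactions=False
            )
            assert not rep.included.empty
            firsts.append(rep.included["term"].iloc[0])
            coefs.append(rep.included.set_index("term").loc["a", "coef"])
        assert firsts.count("a") >= 45
        assert np.mean(coefs) == pytest.approx(1.5, abs=0.3)

    def test_interaction_driven_hazard_scores_highest(self):
        r = np.random.default_rng(5)
        wins = 0
        for _ in range(20):
            n = 300
            a = (r.random(n) < 0.5).astype(float)
            b = (r.random(n) < 0.5).astype(float)
            times, events = self._survival(r, n, 2.0, a * b)
            scores = {}
            for name, z in (("a", a), ("b", b), ("a*b", a * b)):
                chi2, _ = cox_score_test(times, events, None, None, z)
                scores[name] = chi2
            wins += max(scores, key=scores.get) == "a*b"
        assert wins >= 16

    def test_asymptotic_log_hr_bias_small(self):
        r = np.random.default_rng(23)
        coefs = []
        for _ in range(10):
            n = 1000
            a = (r.random(n) < 0.5).astype(float)
            times, events = self._survival(r, n, 1.0, a)
            rep = cox_forward_selection(
                times, events, pd.DataFrame({"a": a}), include_interactions=False
            )
            coefs.append(rep.included["coef"].iloc[0])
        assert abs(np.mean(coefs) - 1.0) < 0.1


# ------------------------------------------------------- mutations


class TestMutationCount:
    def test_identical_groups_p_one(self):
        medians, _, p = mutation_count_test([2, 2, 2], [2, 2, 2])
        assert p == 1.0

    def test_separated_groups_match_enumeration_oracle(self):
        medians, u, p = mutation_count_test([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        # oracle: all 20 label assignments of 6 values into groups of 3
        pooled = np.array([1, 2, 3, 4, 5, 6], float)
        mu = 9 / 2
        devs = []
        for pick in combinations(range(6), 3):
            first = pooled[list(pick)]
            second = pooled[[i for i in range(6) if i not in pick]]
            uu = (first[:, None] > second[None, :]).sum() + 0.5 * (
                first[:, None] == second[None, :]
            ).sum()
            devs.append(abs(uu - mu))
        expected = np.mean(np.array(devs) >= abs(u - mu) - 1e-12)
        assert p == pytest.approx(expected)
        assert p == pytest.approx(2 / 20)

    def test_exact_p_matches_enumeration_with_ties(self, rng):
        for _ in range(10):
            g = rng.integers(0, 5, rng.integers(2, 6))
            q = rng.integers(0, 5, rng.integers(2, 6))
            if np.all(np.concatenate([g, q]) == g[0] if len(set(np.concatenate([g, q]))) == 1 else False):
                continue
            medians, u, p = mutation_count_test(g, q)
            pooled = np.concatenate([g, q]).astype(float)
            n1 = len(g)
            mu = n1 * len(q) / 2
            hits = tot = 0
            for pick in combinations(range(len(pooled)), n1):
                first = pooled[list(pick)]
                second = np.delete(pooled, list(pick))
                uu = (first[:, None] > second[None, :]).sum() + 0.5 * (
                    first[:, None] == second[None, :]
                ).sum()
                tot += 1
                if abs(uu - mu) >= abs(u - mu) - 1e-12:
                    hits += 1
            if np.all(pooled == pooled[0]):
                assert p == 1.0
            else:
                assert p == pytest.approx(hits / tot)

    def test_large_sample_uses_tie_corrected_normal(self, rng):
        g = rng.integers(0, 10, 20)
        q = rng.integers(2, 12, 20)
        _, _, p = mutation_count_test(g, q)
        _, p_ref = sps.mannwhitneyu(g.astype(float), q.astype(float),
                                    alternative="two-sided", method="asymptotic",
                                    use_continuity=False)
        assert p == pytest.approx(float(p_ref))


class TestFisher:
    def test_diagonal_2x2_enumeration(self):
        orr, p = mutation_fisher([[2, 0], [0, 2]])
        assert p == pytest.approx(1 / 3)
        assert orr == np.inf

    def test_identical_rows_p_one(self):
        _, p = mutation_fisher([[3, 2], [3, 2]])
        assert p == pytest.approx(1.0)

    @staticmethod
    def fisher_oracle(table):
        """Hypergeometric enumeration over all tables with fixed margins."""
        a, b = table[0]
        c, d = table[1]
        r1, r2 = a + b, c + d
        c1 = a + c
        n = r1 + r2
        def prob(x):
            return (comb(r1, x, exact=True) * comb(r2, c1 - x, exact=True)
                    / comb(n, c1, exact=True))
        p_obs = prob(a)
        total = 0.0
        for x in range(max(0, c1 - r2), min(r1, c1) + 1):
            px = prob(x)
            if px <= p_obs * (1 + 1e-12):
                total += px
        return min(total, 1.0)

    def test_matches_enumeration_oracle_small_tables(self, rng):
        for _ in range(60):
            t = rng.integers(0, 8, (2, 2))
            if (t.sum(0) == 0).any() or (t.sum(1) == 0).any() or t.sum() > 20:
                continue
            _, p = mutation_fisher(t)
            assert p == pytest.approx(self.fisher_oracle(t), abs=1e-10)

    def test_zero_margin_errors(self):
        with pytest.raises(ValueError, match="margin"):
            mutation_fisher([[0, 0], [1, 2]])

    def test_non_integer_rejected(self):
        with pytest.raises(ValueError):
            mutation_fisher([[1.5, 2], [3, 4]])
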