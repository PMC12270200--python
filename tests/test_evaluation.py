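"""Every statistic against an independent brute-force or closed-form oracle."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pdscreen import evaluation as ev


class TestConfusionMetrics:
    def test_perfect_predictions(self):
        m = ev.confusion_metrics([0, 1, 0, 1], [0, 1, 0, 1])
        assert all(v == 1.0 for v in m.values())

    def test_hand_computed_two_by_two(self):
        # TP=9 FN=1 TN=7 FP=3
        truth = [1] * 10 + [0] * 10
        pred = [1] * 9 + [0] + [1] * 3 + [0] * 7
        m = ev.confusion_metrics(truth, pred)
        assert m["sensitivity"] == pytest.approx(0.9)
        assert m["specificity"] == pytest.approx(0.7)
        assert m["ppv"] == pytest.approx(0.75)
        assert m["npv"] == pytest.approx(0.875)
        assert m["accuracy"] == pytest.approx(0.8)
        assert m["f1"] == pytest.approx(18 / 22)

    def test_degenerate_all_positive(self):
        m = ev.confusion_metrics([1, 0, 1], [1, 1, 1])
        assert m["specificity"] == 0.0
        assert np.isnan(m["npv"])

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            ev.confusion_metrics([], [])


class TestRankMetrics:
    def test_perfect_and_inverted_separation(self):
        y = [0, 0, 1, 1]
        assert ev.roc_auc(y, [0.1, 0.2, 0.8, 0.9]) == 1.0
        assert ev.roc_auc(y, [0.9, 0.8, 0.2, 0.1]) == 0.0

    def test_random_scores_near_half(self):
        g = np.random.default_rng(0)
        y = g.integers(0, 2, 10000)
        s = g.random(10000)
        assert 0.49 < ev.roc_auc(y, s) < 0.51

    def test_matches_pairwise_enumeration_with_ties(self):
        g = np.random.default_rng(3)
        y = g.integers(0, 2, 18)
        s = g.integers(0, 5, 18).astype(float)   # heavy ties
        pos = s[y == 1]
        neg = s[y == 0]
        wins = sum((a > b) + 0.5 * (a == b) for a in pos for b in neg)
        assert ev.roc_auc(y, s) == pytest.approx(wins / (len(pos) * len(neg)))

    def test_pr_auc_matches_step_enumeration(self):
        g = np.random.default_rng(5)
        y = g.integers(0, 2, 15)
        s = g.random(15)
        order = np.argsort(-s)
        ys = np.asarray(y)[order]
        tp = np.cumsum(ys)
        prec = tp / np.arange(1, 16)
        rec = tp / ys.sum()
        ap = np.sum(np.diff(np.concatenate([[0], rec])) * prec)
        assert ev.pr_auc(y, s) == pytest.approx(ap)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            ev.roc_auc([1, 1], [0.2, 0.4])


class TestCalibration:
    def test_confident_correct_is_zero(self):
        y = [1, 0, 1, 0]
        p = [1.0, 0.0, 1.0, 0.0]
        assert ev.brier(p, y) == 0.0
        assert ev.ece(p, y) == 0.0

    def test_constant_half_brier_quarter(self):
        y = [0, 1] * 50
        assert ev.brier([0.5] * 100, y) == pytest.approx(0.25)

    def test_brier_hand_fixture(self):
        pairs = [(0.9, 1), (0.8, 0), (0.3, 0), (0.6, 1), (0.2, 1), (0.5, 0)]
        p, y = zip(*pairs)
        hand = np.mean([(pp - yy) ** 2 for pp, yy in pairs])
        assert ev.brier(p, y) == pytest.approx(hand)

    def test_ece_hand_fixture_two_bins(self):
        # bin [0, .5): probs (.2, .4), labels (0, 1) -> |.3 - .5| = .2, n=2
        # bin [.5, 1]: probs (.6, .9), labels (1, 1) -> |.75 - 1| = .25, n=2
        p = [0.2, 0.4, 0.6, 0.9]
        y = [0, 1, 1, 1]
        assert ev.ece(p, y, bins=2) == pytest.approx(0.5 * 0.2 + 0.5 * 0.25)

    def test_calibration_curve_counts(self):
        curve = ev.calibration_curve([0.05, 0.15, 0.95], [0, 0, 1], bins=10)
        assert [row[2] for row in curve] == [1, 1, 1]
        with pytest.raises(ValueError):
            ev.calibration_curve([0.5], [1], bins=0)


class TestBootstrap:
    def test_degenerate_cases(self):
        res = ev.bootstrap_ci(np.mean, np.array([2.0, 2.0, 2.0]), B=10, seed=0)
        assert res.ci_low == res.ci_high == 2.0
        one = ev.bootstrap_ci(np.mean, np.arange(5.0), B=1, seed=0)
        assert one.ci_low == one.ci_high == one.distribution[0]

    def test_endpoints_inside_resample_range(self):
        g = np.random.default_rng(1)
        res = ev.bootstrap_ci(np.median, g.normal(size=50), B=200, seed=2)
        assert res.distribution.min() <= res.ci_low
        assert res.ci_high <= res.distribution.max()

    def test_undefined_resamples_redrawn(self):
        data = np.array([0.0, 0.0, 0.0, 1.0])

        def stat(x):
            if x.sum() == 0:
                raise ValueError("undefined")
            return x.mean()

        res = ev.bootstrap_ci(stat, data, B=50, seed=3)
        assert len(res.distribution) == 50
        assert res.n_redrawn > 0


class TestMannWhitney:
    def test_identical_distributions_p_near_one(self):
        a = np.arange(10.0)
        u, p = ev.compare_bootstrap_distributions(a, a.copy())
        assert p > 0.9

    def test_complete_separation_extreme(self):
        u, p = ev.compare_bootstrap_distributions(
            np.arange(100, 200.0), np.arange(0, 100.0))
        assert u == 100 * 100
        assert p < 1e-6

    def test_u_matches_pair_enumeration(self):
        a = np.array([3.1, 0.5, 9.2, 4.4, 4.4])
        b = np.array([0.5, 4.4, 2.2, 8.0])
        wins = sum((x > y) + 0.5 * (x == y) for x in a for y in b)
        u, _ = ev.compare_bootstrap_distributions(a, b)
        assert u == pytest.approx(wins)


class TestTwoProportionZ:
    def test_equal_proportions(self):
        z, p = ev.two_proportion_z(30, 100, 30, 100)
        assert z == 0.0
        assert p == pytest.approx(1.0)

    def test_hand_computed_pooled_formula(self):
        x1, n1, x2, n2 = 30, 100, 15, 100
        pool = (x1 + x2) / (n1 + n2)
        se = np.sqrt(pool * (1 - pool) * (1 / n1 + 1 / n2))
        z_hand = (x1 / n1 - x2 / n2) / se
        z, p = ev.two_proportion_z(x1, n1, x2, n2)
        assert z == pytest.approx(z_hand, abs=1e-10)
        assert p == pytest.approx(2 * stats.norm.sf(abs(z_hand)), abs=1e-12)

    def test_assumption_violation_refused(self):
        with pytest.raises(ev.AssumptionError):
            ev.two_proportion_z(3, 100, 50, 100)


class TestMonteCarloChiSquare:
    def test_independent_table_large_p(self):
        table = np.outer([40, 60], [30, 70]) // 100 * 10
        chi2, p = ev.mc_chisquare(table, reps=500, seed=0)
        assert p > 0.5

    def test_p_floor(self):
        table = [[50, 0], [0, 50]]
        chi2, p = ev.mc_chisquare(table, reps=200, seed=1)
        assert p >= 1 / 201

    def test_close_to_asymptotic_on_large_counts(self):
        table = [[120, 90, 60], [80, 110, 140]]
        chi2, p_mc = ev.mc_chisquare(table, reps=10000, seed=2)
        chi2_ref, p_asym, _, _ = stats.chi2_contingency(table, correction=False)
        assert chi2 == pytest.approx(chi2_ref)
        assert abs(p_mc - p_asym) < 0.02

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            ev.mc_chisquare([[0, 0], [3, 4]], reps=10)


class TestBHAdjust:
    def test_single_p_unchanged(self):
        assert ev.bh_adjust([0.03]) == pytest.approx([0.03])

    def test_hand_step_up(self):
        # p_(i) * m / i = (.04, .04, .04, .04) after monotonicity
        out = ev.bh_adjust([0.01, 0.02, 0.03, 0.04])
        np.testing.assert_allclose(out, [0.04, 0.04, 0.04, 0.04])

    def test_matches_brute_force_step_up(self):
        g = np.random.default_rng(7)
        p = g.random(12)
        m = len(p)
        order = np.argsort(p)
        adj = np.empty(m)
        running = 1.0
        for rank in range(m, 0, -1):
            i = order[rank - 1]
            running = min(running, p[i] * m / rank)
            adj[i] = running
        np.testing.assert_allclose(ev.bh_adjust(p), adj)

    def test_all_ones_and_bounds(self):
        np.testing.assert_allclose(ev.bh_adjust([1.0, 1.0]), [1.0, 1.0])
        with pytest.raises(ValueError):
            ev.bh_adjust([0.5, 1.5])
        p = np.random.default_rng(0).random(9)
        assert np.all(ev.bh_adjust(p) >= p - 1e-15)


class TestKappaAndVotes:
    def test_identical_vectors(self):
        assert ev.cohens_kappa([0, 1, 0, 1], [0, 1, 0, 1]) == 1.0
        assert ev.agreement_rate([0, 1], [0, 1]) == 1.0

    def test_independence_table_kappa_zero(self):
        a = [0] * 50 + [1] * 50
        b = ([0] * 25 + [1] * 25) * 2
        assert ev.cohens_kappa(a, b) == pytest.approx(0.0)

    def test_hand_table(self):
        # table [[20, 5], [3, 12]]: po = 0.8, pe from marginals
        a = [0] * 25 + [1] * 15
        b = [0] * 20 + [1] * 5 + [0] * 3 + [1] * 12
        po = 32 / 40
        pe = (25 / 40) * (23 / 40) + (15 / 40) * (17 / 40)
        assert ev.cohens_kappa(a, b) == pytest.approx((po - pe) / (1 - pe))

    def test_symmetry_and_degenerate(self):
        g = np.random.default_rng(2)
        a, b = g.integers(0, 2, 30), g.integers(0, 2, 30)
        assert ev.cohens_kappa(a, b) == pytest.approx(ev.cohens_kappa(b, a))
        assert np.isnan(ev.cohens_kappa([1, 1, 1], [1, 1, 1]))

    def test_majority_vote(self):
        df = pd.DataFrame({"r1": [1, 1, 0], "r2": [1, 0, 0], "r3": [0, 1, 0]})
        np.testing.assert_array_equal(
            ev.majority_vote(df, ["r1", "r2", "r3"]), [1, 1, 0])
        np.testing.assert_array_equal(ev.majority_vote(df, ["r1"]), df["r1"])
        with pytest.raises(ValueError, match="odd"):
            ev.majority_vote(df, ["r1", "r2"])


class TestMisclassificationRegression:
    def test_intercept_only_closed_form(self):
        g = np.random.default_rng(0)
        n = 4000
        err = (g.random(n) < 0.25).astype(int)
        cov = pd.DataFrame(index=range(n))   # no covariates: intercept only
        out = ev.misclassification_regression(err, cov)
        assert out.loc["const", "coefficient"] == pytest.approx(
            np.log(err.mean() / (1 - err.mean())), abs=0.05)

    def test_null_covariate_rarely_significant(self):
        hits = 0
        reps = 10
        for seed in range(reps):
            g = np.random.default_rng(seed)
            n = 2000
            err = (g.random(n) < 0.2).astype(int)
            cov = pd.DataFrame({
                "sex": g.choice(["male", "female"], n),
                "age": g.normal(60, 10, n),
            })
            out = ev.misclassification_regression(err, cov)
            terms = out.drop(index="const")
            if (np.abs(terms["coefficient"]) < 0.3).all() and \
                    (terms["adjusted_p"] > 0.05).all():
                hits += 1
        assert hits >= 0.8 * reps

    def test_separable_fixture_refused(self):
        err = np.array([0] * 20 + [1] * 20)
        cov = pd.DataFrame({"x": np.concatenate([np.zeros(20), np.ones(20)])})
        with pytest.raises(ev.SeparationError):
            ev.misclassification_regression(err, cov)


class TestAccuracyByAgreement:
    def test_region_counts_partition_sessions(self):
        g = np.random.default_rng(1)
        n = 40
        truth = g.integers(0, 2, n)
        tasks = {m: g.integers(0, 2, n) for m in ("a", "b", "c")}
        fused = g.integers(0, 2, n)
        table = ev.accuracy_by_agreement(tasks, fused, truth)
        assert table["n"].sum() == n

    def test_all_correct_single_region(self):
        truth = np.array([0, 1, 1, 0])
        tasks = {m: truth.copy() for m in ("a", "b", "c")}
        fused = np.array([0, 1, 0, 0])
        table = ev.accuracy_by_agreement(tasks, fused, truth)
        full = table[(table["a_correct"]) & (table["b_correct"])
                     & (table["c_correct"])]
        assert int(full["n"].iloc[0]) == 4
        assert full["fused_accuracy"].iloc[0] == pytest.approx(0.75)

    def test_matches_enumeration_on_hand_fixture(self):
        truth = np.array([1, 1, 0, 0, 1, 0, 1, 0, 1, 1])
        tA = np.array([1, 0, 0, 1, 1, 0, 1, 1, 0, 1])
        tB = np.array([1, 1, 1, 0, 0, 0, 1, 0, 1, 0])
        tC = np.array([0, 1, 0, 0, 1, 1, 1, 0, 1, 1])
        fused = np.array([1, 1, 0, 1, 1, 0, 1, 0, 1, 0])
        table = ev.accuracy_by_agreement({"A": tA, "B": tB, "C": tC},
                                         fused, truth)
        # enumerate by hand
        for _, row in table.iterrows():
            mask = ((tA == truth) == row["A_correct"]) \
                & ((tB == truth) == row["B_correct"]) \
                & ((tC == truth) == row["C_correct"])
            assert row["n"] == mask.sum()
            if mask.sum():
                assert row["fused_accuracy"] == pytest.approx(
                    np.mean(fused[mask] == truth[mask]))


def test_evaluate_predictions_report_contract():
    g = np.random.default_rng(0)
    n = 200
    truth = g.integers(0, 2, n)
    probs = np.clip(truth * 0.6 + g.normal(0.2, 0.2, n), 0, 1)
    verdicts = np.where(g.random(n) < 0.1, "withheld",
                        np.where(probs > 0.5, "positive", "negative"))
    rep = ev.evaluate_predictions(truth, probs, verdicts, B=100, seed=1)
    assert 0.85 <= rep.coverage <= 0.95
    for name, (est, lo, hi) in rep.metrics.items():
        assert lo - 1e-12 <= est <= hi + 1e-12, name
        assert 0.0 <= est <= 1.0
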