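"""Welch/Hedges/ROC/kappa battery against independent reference implementations."""

import numpy as np
import pingouin
import pytest
from scipy import stats as sps
from statsmodels.stats.inter_rater import fleiss_kappa as sm_fleiss_kappa

import facesym as fs
from facesym.stats import (
    assumption_checks,
    fleiss_kappa,
    hedges_g,
    majority_label,
    roc_analysis,
    welch_t_test,
)


def brute_force_auc(pos, neg):
    """Concordant-pair probability with half-credit for ties (n <= 20)."""
    wins = sum((p > n_) + 0.5 * (p == n_) for p in pos for n_ in neg)
    return wins / (len(pos) * len(neg))


def panel(ratings):
    ratings = np.asarray(ratings, dtype=object)
    return fs.RaterPanel([f"r{i}" for i in range(ratings.shape[0])], ratings)


class TestWelch:
    def test_identical_groups(self):
        t, df, p = welch_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0 and p == pytest.approx(1.0)

    def test_matches_scipy_on_example(self):
        t, df, p = welch_t_test([1, 2, 3, 4], [3, 4, 5, 6])
        ref = sps.ttest_ind([1, 2, 3, 4], [3, 4, 5, 6], equal_var=False)
        assert t == pytest.approx(ref.statistic, abs=1e-8)
        assert df == pytest.approx(ref.df, abs=1e-8)
        assert p == pytest.approx(ref.pvalue, abs=1e-8)

    def test_antisymmetry(self, rng):
        a, b = rng.normal(0, 1, 8), rng.normal(1, 2, 5)
        t1, df1, p1 = welch_t_test(a, b)
        t2, df2, p2 = welch_t_test(b, a)
        assert t1 == pytest.approx(-t2)
        assert df1 == pytest.approx(df2) and p1 == pytest.approx(p2)

    def test_zero_variance_rejected(self):
        with pytest.raises(fs.DegenerateDataError):
            welch_t_test([2.0, 2.0, 2.0], [2.0, 2.0])

    def test_oracle_equivalence_random_instances(self, rng):
        for _ in range(500):
            na, nb = rng.integers(2, 30, 2)
            a = rng.normal(rng.uniform(-5, 5), rng.uniform(0.5, 3), na)
            b = rng.normal(rng.uniform(-5, 5), rng.uniform(0.5, 3), nb)
            t, df, p = welch_t_test(a, b)
            ref = sps.ttest_ind(a, b, equal_var=False)
            assert t == pytest.approx(ref.statistic, abs=1e-8)
            assert df == pytest.approx(ref.df, abs=1e-8)
            assert p == pytest.approx(ref.pvalue, abs=1e-8)

    def test_null_p_values_uniform(self, rng):
        """Under a true null, Welch p-values are uniform (KS < 0.05 at
        2000 replicates)."""
        ps = []
        for _ in range(2000):
            ps.append(welch_t_test(rng.normal(0, 1, 12), rng.normal(0, 1, 8))[2])
        d = sps.kstest(ps, "uniform").statistic
        assert d < 0.05


class TestHedgesG:
    def test_identical_groups_zero(self):
        assert hedges_g([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == 0.0

    def test_hand_computed_example(self):
        # J = 1 - 3/23; pooled SD of [1..4] vs [3..6]
        g = hedges_g([1, 2, 3, 4], [3, 4, 5, 6])
        j = 1 - 3 / 23
        s_pooled = np.sqrt((3 * 5 / 3 + 3 * 5 / 3) / 6)
        assert g == pytest.approx(j * (-2) / s_pooled, abs=1e-12)
        ref = pingouin.compute_effsize([1, 2, 3, 4], [3, 4, 5, 6],
                                       eftype="hedges")
        assert g == pytest.approx(ref, abs=1e-8)

    def test_scale_invariance(self, rng):
        a, b = rng.normal(0, 1, 10), rng.normal(1, 1, 7)
        assert hedges_g(2 * a, 2 * b) == pytest.approx(hedges_g(a, b), abs=1e-12)

    def test_oracle_equivalence_random_instances(self, rng):
        for _ in range(500):
            na, nb = rng.integers(2, 25, 2)
            a = rng.normal(0, 1, na)
            b = rng.normal(rng.uniform(-2, 2), rng.uniform(0.5, 2), nb)
            ref = pingouin.compute_effsize(a, b, eftype="hedges")
            assert hedges_g(a, b) == pytest.approx(ref, abs=1e-8)


class TestAssumptionChecks:
    def test_degenerate_group_skipped(self):
        sh_a, sh_b, lev = assumption_checks([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        assert sh_a is None and sh_b is not None

    def test_shapiro_type_one_error_calibrated(self, rng):
        """Shapiro-Wilk rejects true normal samples at ~alpha."""
        rejections = sum(
            assumption_checks(rng.normal(0, 1, 30), rng.normal(0, 1, 30))[0] < 0.05
            for _ in range(100)
        )
        # binomial(100, 0.05) 95% interval
        assert 0 <= rejections <= 11

    def test_levene_null_uniform(self, rng):
        ps = [assumption_checks(rng.normal(0, 1, 20), rng.normal(5, 1, 20))[2]
              for _ in range(200)]
        assert sps.kstest(ps, "uniform").statistic < 0.12


class TestROC:
    def test_perfect_separation(self):
        r = roc_analysis([0.9, 0.8, 0.2, 0.1], ["S", "S", "AS", "AS"], "S")
        assert r.auc == 1.0 and r.youden_j == 1.0

    def test_brute_force_derived_auc(self):
        r = roc_analysis([0.9, 0.4, 0.5, 0.1], ["S", "S", "AS", "AS"], "S")
        assert r.auc == pytest.approx(0.75)
        assert r.auc == pytest.approx(brute_force_auc([0.9, 0.4], [0.5, 0.1]))

    def test_label_inversion_maps_auc(self, rng):
        scores = rng.normal(0, 1, 40)
        labels = np.where(rng.random(40) < 0.5, "S", "AS")
        if len(set(labels)) < 2:
            labels[0], labels[1] = "S", "AS"
        a1 = roc_analysis(scores, labels, "S").auc
        a2 = roc_analysis(scores, labels, "AS").auc
        assert a1 == pytest.approx(1.0 - a2, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(fs.DegenerateDataError):
            roc_analysis([0.1, 0.2], ["S", "S"], "S")

    def test_curve_monotone_and_auc_matches_pair_counting(self, rng):
        """Trapezoid AUC equals the tie-corrected concordant-pair
        probability exactly on small random instances."""
        for _ in range(500):
            n_pos, n_neg = rng.integers(2, 11, 2)
            # integer scores force ties
            pos = rng.integers(0, 6, n_pos).astype(float)
            neg = rng.integers(0, 6, n_neg).astype(float)
            scores = np.concatenate([pos, neg])
            labels = ["S"] * n_pos + ["AS"] * n_neg
            r = roc_analysis(scores, labels, "S")
            assert np.all(np.diff(r.tpr) >= 0) and np.all(np.diff(r.fpr) >= 0)
            assert r.auc == pytest.approx(brute_force_auc(pos, neg), abs=1e-12)
            assert -1.0 <= r.youden_j <= 1.0

    def test_youden_tie_broken_toward_lower_threshold(self):
        # J is maximal (=1) anywhere between the classes; several candidate
        # thresholds achieve it only at one point here, so craft a tie:
        r = roc_analysis([3.0, 2.0, 1.0, 0.0], ["S", "S", "AS", "AS"], "S")
        assert r.youden_j == 1.0
        assert r.youden_threshold == pytest.approx(2.0)


class TestFleissKappa:
    def test_unanimous_agreement_two_categories(self):
        r = fleiss_kappa(panel([["S"] * 3, ["AS"] * 3, ["S"] * 3]))
        assert r.kappa == pytest.approx(1.0)

    def test_unanimous_single_category_undefined(self):
        with pytest.raises(fs.DegenerateDataError):
            fleiss_kappa(panel([["S"] * 3, ["S"] * 3]))

    def test_matches_statsmodels_on_crafted_matrix(self, rng):
        ratings = np.where(rng.random((10, 3)) < 0.6, "S", "AS").astype(object)
        ratings[0] = ["S", "AS", "S"]  # ensure both categories occur
        p = panel(ratings)
        counts = np.stack([(p.ratings == c).sum(axis=1) for c in ("AS", "S")], axis=1)
        ref = sm_fleiss_kappa(counts, method="fleiss")
        assert fleiss_kappa(p).kappa == pytest.approx(ref, abs=1e-10)

    def test_oracle_equivalence_random_instances(self, rng):
        checked = 0
        while checked < 500:
            n_items = int(rng.integers(4, 30))
            n_raters = int(rng.integers(2, 6))
            ratings = np.where(rng.random((n_items, n_raters)) < rng.uniform(0.2, 0.8),
                               "S", "AS").astype(object)
            p = panel(ratings)
            counts = np.stack([(p.ratings == c).sum(axis=1) for c in ("AS", "S")],
                              axis=1)
            if (counts.sum(axis=0) == 0).any():
                continue
            ref = sm_fleiss_kappa(counts, method="fleiss")
            assert fleiss_kappa(p).kappa == pytest.approx(ref, abs=1e-8)
            checked += 1

    def test_random_ratings_kappa_near_zero(self, rng):
        """Chance-level raters give kappa ~ 0 (mean over 200 replicates)."""
        kappas = []
        for _ in range(200):
            ratings = np.where(rng.random((30, 3)) < 0.5, "S", "AS").astype(object)
            try:
                kappas.append(fleiss_kappa(panel(ratings)).kappa)
            except fs.DegenerateDataError:
                continue
        assert abs(np.mean(kappas)) < 0.05


class TestMajorityLabel:
    def test_two_of_three_majority(self):
        labels = majority_label(panel([["S", "S", "AS"], ["AS", "AS", "AS"]]))
        assert [l.value for l in labels] == ["S", "AS"]

    def test_even_panel_tie_rejected(self):
        with pytest.raises(fs.DegenerateDataError, match="majority"):
            majority_label(panel([["S", "AS"]]))


class TestCompareGroups:
    def test_single_descriptor_table_shape(self, rng):
        import pandas as pd
        wide = pd.DataFrame({
            "VertDist_dSTD": rng.normal(0, 1, 12),
            "label": ["S"] * 8 + ["AS"] * 4,
        }, index=[f"r{i}" for i in range(12)])
        report, rocs = fs.compare_groups(wide)
        assert len(report.comparisons) == 1 and len(rocs) == 1

    def test_missing_group_fails_loudly(self, rng):
        import pandas as pd
        wide = pd.DataFrame({"x": rng.normal(0, 1, 5), "label": ["S"] * 5})
        with pytest.raises(fs.DegenerateDataError, match="both S and AS"):
            fs.compare_groups(wide)

    def test_label_permutation_kills_significance_rate(self, rng):
        """With labels shuffled independently of the data, the per-descriptor
        rejection rate is ~alpha."""
        import pandas as pd
        n_rej = 0
        n_tests = 0
        for _ in range(200):
            wide = pd.DataFrame({
                "d1": rng.normal(0, 1, 20),
                "label": rng.permutation(["S"] * 13 + ["AS"] * 7),
            }, index=[f"r{i}" for i in range(20)])
            report, _ = fs.compare_groups(wide)
            n_rej += sum(c.significant for c in report.comparisons)
            n_tests += len(report.comparisons)
        assert sps.binom.ppf(0.005, n_tests, 0.05) <= n_rej \
            <= sps.binom.ppf(0.995, n_tests, 0.05)
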