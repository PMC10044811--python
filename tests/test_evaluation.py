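import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from liporadiomics import evaluation as E


def _scored(labels, scores):
    ids = [f"c{i}" for i in range(len(labels))]
    return E.ScoredSet.from_arrays(ids, np.asarray(labels, float), scores)


class TestRocAuc:
    def test_perfect_separation(self):
        s = _scored([1, 1, 0, 0], [0.9, 0.8, 0.7, 0.6])
        assert E.roc_auc(s)["auc"] == 1.0

    def test_one_swapped_pair_gives_075(self):
        s = _scored([1, 0, 1, 0], [0.9, 0.8, 0.7, 0.6])
        # enumerate label pairs: 3 of 4 (pos, neg) pairs correctly ordered
        assert E.roc_auc(s)["auc"] == 0.75

    def test_matches_pairwise_enumeration(self):
        rng = np.random.default_rng(0)
        y = rng.integers(0, 2, size=30).astype(float)
        y[:2] = [0, 1]
        scores = rng.normal(size=30)
        pos = scores[y == 1]
        neg = scores[y == 0]
        brute = np.mean(
            [
                1.0 if p > q else 0.5 if p == q else 0.0
                for p, q in itertools.product(pos, neg)
            ]
        )
        assert E.roc_auc(_scored(y, scores))["auc"] == pytest.approx(brute, rel=1e-12)

    def test_null_scores_near_half(self):
        rng = np.random.default_rng(1)
        y = np.repeat([0.0, 1.0], 500)
        s = _scored(rng.permutation(y), rng.normal(size=1000))
        assert 0.44 < E.roc_auc(s)["auc"] < 0.56

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(2)
        y = rng.integers(0, 2, size=50).astype(float)
        y[:2] = [0, 1]
        scores = rng.normal(size=50)
        a = E.roc_auc(_scored(y, scores))["auc"]
        b = E.roc_auc(_scored(y, np.exp(3 * scores)))["auc"]
        assert a == pytest.approx(b, rel=1e-12)

    def test_single_class_raises(self):
        with pytest.raises(ValueError, match="both classes"):
            E.roc_auc(_scored([1, 1], [0.2, 0.4]))


class TestDeLong:
    def test_identical_scores_p_one(self):
        rng = np.random.default_rng(3)
        y = np.repeat([0.0, 1.0], 20)
        s = rng.normal(size=40)
        out = E.delong_test(_scored(y, s), _scored(y, s.copy()))
        assert out["p"] == 1.0
        assert out["z"] == 0.0

    def test_symmetric_in_arguments(self):
        rng = np.random.default_rng(4)
        y = np.repeat([0.0, 1.0], 30)
        a = _scored(y, rng.normal(size=60) + y)
        b = _scored(y, rng.normal(size=60))
        ab = E.delong_test(a, b)
        ba = E.delong_test(b, a)
        assert ab["p"] == pytest.approx(ba["p"], rel=1e-12)
        assert ab["z"] == pytest.approx(-ba["z"], rel=1e-12)

    def test_strong_vs_random_scorer_significant(self):
        rng = np.random.default_rng(5)
        n = 200
        y = np.repeat([0.0, 1.0], n // 2)
        strong = y * 3 + rng.normal(size=n)
        random_scores = rng.normal(size=n)
        out = E.delong_test(_scored(y, strong), _scored(y, random_scores))
        assert out["p"] < 0.01

    def test_z_matches_bootstrap_oracle(self):
        """The analytic AUC-difference variance agrees with a paired
        bootstrap to ~10% on a moderate fixture."""
        rng = np.random.default_rng(6)
        n = 120
        y = np.repeat([0.0, 1.0], n // 2)
        sa = y * 1.2 + rng.normal(size=n)
        sb = 0.8 * y + rng.normal(size=n)
        out = E.delong_test(_scored(y, sa), _scored(y, sb))
        analytic_sd = abs(out["auc_a"] - out["auc_b"]) / abs(out["z"])

        def auc(yv, sv):
            r = stats.rankdata(sv)
            m = int(yv.sum())
            return (r[yv == 1].sum() - m * (m + 1) / 2) / (m * (len(yv) - m))

        diffs = []
        for _ in range(2000):
            idx = rng.integers(0, n, size=n)
            yb = y[idx]
            if yb.min() == yb.max():
                continue
            diffs.append(auc(yb, sa[idx]) - auc(yb, sb[idx]))
        boot_sd = np.std(diffs, ddof=1)
        assert analytic_sd == pytest.approx(boot_sd, rel=0.10)

    def test_unpaired_inputs_raise(self):
        y = np.repeat([0.0, 1.0], 5)
        a = _scored(y, np.arange(10.0))
        b = E.ScoredSet.from_arrays([f"x{i}" for i in range(10)], y, np.arange(10.0))
        with pytest.raises(ValueError, match="paired"):
            E.delong_test(a, b)


class TestConfusionMetrics:
    def test_all_correct(self):
        s = _scored([1, 1, 0, 0], [0.9, 0.8, 0.1, 0.2])
        out = E.confusion_metrics(s, 0.5)
        assert out["sensitivity"] == out["specificity"] == out["accuracy"] == 1.0

    def test_direct_arithmetic(self):
        y = [1] * 10 + [0] * 10
        scores = [0.9] * 9 + [0.1] + [0.2] * 8 + [0.8] * 2
        out = E.confusion_metrics(_scored(y, scores), 0.5)
        assert out["confusion"] == {"tp": 9, "fn": 1, "tn": 8, "fp": 2}
        assert out["sensitivity"] == pytest.approx(0.9)
        assert out["specificity"] == pytest.approx(0.8)
        assert out["accuracy"] == pytest.approx(0.85)

    def test_clopper_pearson_10_of_10(self):
        lo, hi = E.clopper_pearson(10, 10)
        assert lo == pytest.approx(0.025 ** (1 / 10), rel=1e-9)  # exact beta quantile
        assert lo == pytest.approx(0.692, abs=5e-4)
        assert hi == 1.0

    def test_clopper_pearson_contains_point_estimate(self):
        for k, n in [(0, 7), (3, 7), (7, 7), (25, 50)]:
            lo, hi = E.clopper_pearson(k, n)
            assert lo <= k / n <= hi


class TestCohenKappa:
    def test_identical_calls(self):
        calls = np.array([0, 1, 1, 0, 1])
        assert E.cohen_kappa(calls, calls)["kappa"] == pytest.approx(1.0)

    def test_hand_computed_2x2(self):
        # agreement table: both+ 20, both- 15, a+b- 5, a-b+ 10
        a = np.array([1] * 20 + [0] * 15 + [1] * 5 + [0] * 10)
        b = np.array([1] * 20 + [0] * 15 + [0] * 5 + [1] * 10)
        po = 35 / 50
        pe = (25 / 50) * (30 / 50) + (25 / 50) * (20 / 50)
        expected = (po - pe) / (1 - pe)
        out = E.cohen_kappa(a, b)
        assert out["kappa"] == pytest.approx(expected, rel=1e-9)
        lo, hi = out["kappa_ci"]
        assert lo < expected < hi

    def test_independent_calls_near_zero(self):
        rng = np.random.default_rng(7)
        a = rng.integers(0, 2, size=1000)
        b = rng.integers(0, 2, size=1000)
        assert abs(E.cohen_kappa(a, b)["kappa"]) < 0.1

    def test_rater_swap_invariance(self):
        rng = np.random.default_rng(8)
        a = rng.integers(0, 2, size=100)
        b = (a + (rng.random(100) < 0.2)) % 2
        assert E.cohen_kappa(a, b)["kappa"] == pytest.approx(
            E.cohen_kappa(b, a)["kappa"], rel=1e-12
        )

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError, match="length"):
            E.cohen_kappa([0, 1], [0, 1, 1])


class TestGroupFeatureTests:
    def test_identical_distributions_adjusted_p_one(self):
        vals = np.tile(np.arange(6.0), 2)
        df = pd.DataFrame({"label": ["benign"] * 6 + ["malignant"] * 6, "f": vals})
        out = E.group_feature_tests(df, ["f"])
        assert out.loc["f", "p_bonferroni"] == 1.0

    def test_small_sample_exact_p(self):
        # U = 0 configuration; exact two-sided p = 2/20
        df = pd.DataFrame(
            {"label": ["benign"] * 3 + ["malignant"] * 3, "f": [4, 5, 6, 1, 2, 3]}
        )
        out = E.group_feature_tests(df, ["f"])
        assert out.loc["f", "u_statistic"] == 0.0
        assert out.loc["f", "p_raw"] == pytest.approx(0.1)

    def test_bonferroni_never_below_raw(self):
        rng = np.random.default_rng(9)
        df = pd.DataFrame(rng.normal(size=(40, 5)), columns=[f"f{i}" for i in range(5)])
        df["label"] = ["benign"] * 20 + ["malignant"] * 20
        out = E.group_feature_tests(df)
        assert (out["p_bonferroni"] >= out["p_raw"] - 1e-15).all()
        assert (out["p_bonferroni"] <= 1.0).all()

    def test_planted_shift_detected_among_14_features(self):
        hits, false_hits = 0, 0
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            X = rng.normal(size=(200, 14))
            X[100:, 0] += 1.0  # planted shift in feature 0 for malignant
            df = pd.DataFrame(X, columns=[f"f{i}" for i in range(14)])
            df["label"] = ["benign"] * 100 + ["malignant"] * 100
            out = E.group_feature_tests(df)
            sig = out.index[out["p_bonferroni"] < 0.05]
            hits += "f0" in sig
            false_hits += len(set(sig) - {"f0"})
        assert hits >= 18
        assert false_hits <= 2

    def test_constant_feature_warns_with_p_one(self):
        df = pd.DataFrame(
            {"label": ["benign"] * 4 + ["malignant"] * 4, "f": np.ones(8)}
        )
        with pytest.warns(UserWarning, match="constant"):
            out = E.group_feature_tests(df, ["f"])
        assert out.loc["f", "p_raw"] == 1.0


class TestDemographics:
    def test_gender_2x2_chi_squared(self):
        """10/16 vs 28/14 male/female split rounds to p = 0.02."""
        labels = ["benign"] * 38 + ["malignant"] * 30
        gender = ["male"] * 10 + ["female"] * 28 + ["male"] * 16 + ["female"] * 14
        df = pd.DataFrame({"label": labels, "gender": gender})
        out = E.demographics_tests(df, {"gender": "categorical"})
        assert out.loc["gender", "test"] == "chi2"
        assert round(out.loc["gender", "p"], 2) == 0.02

    def test_nonnormal_branch_uses_mann_whitney(self):
        rng = np.random.default_rng(10)
        df = pd.DataFrame(
            {
                "label": ["benign"] * 15 + ["malignant"] * 15,
                "size": rng.lognormal(size=30),
            }
        )
        out = E.demographics_tests(df, {"size": "continuous_nonnormal"})
        assert out.loc["size", "test"] == "mannwhitney_u"
        g0, g1 = df["size"][:15], df["size"][15:]
        assert out.loc["size", "p"] == pytest.approx(
            stats.mannwhitneyu(g0, g1, alternative="two-sided").pvalue
        )

    def test_identical_continuous_groups_p_one(self):
        vals = np.tile([1.0, 2.0, 3.0, 4.0], 2)
        df = pd.DataFrame({"label": ["benign"] * 4 + ["malignant"] * 4, "age": vals})
        out = E.demographics_tests(df, {"age": "continuous"})
        assert out.loc["age", "p"] == pytest.approx(1.0)

    def test_low_expected_count_uses_fisher_matching_hypergeometric(self):
        labels = ["benign"] * 8 + ["malignant"] * 8
        flag = ["yes"] * 2 + ["no"] * 6 + ["yes"] * 7 + ["no"] * 1
        df = pd.DataFrame({"label": labels, "flag": flag})
        out = E.demographics_tests(df, {"flag": "categorical"})
        assert out.loc["flag", "test"] == "fisher"
        table = pd.crosstab(df["flag"], df["label"]).to_numpy()
        expected = stats.fisher_exact(table)[1]
        assert out.loc["flag", "p"] == pytest.approx(expected, rel=1e-12)
        # fisher's exact p equals the sum of hypergeometric probabilities of
        # tables at least as extreme
        a, total = table[1, 0], table.sum()
        row1, col1 = table[1].sum(), table[:, 0].sum()
        probs = [
            stats.hypergeom.pmf(x, total, row1, col1)
            for x in range(max(0, row1 + col1 - total), min(row1, col1) + 1)
        ]
        p_obs = stats.hypergeom.pmf(a, total, row1, col1)
        brute = sum(p for p in probs if p <= p_obs * (1 + 1e-9))
        assert out.loc["flag", "p"] == pytest.approx(brute, rel=1e-9)
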