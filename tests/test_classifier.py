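import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats
from sklearn.ensemble import RandomForestClassifier

from edvent.classifier import (
    ClassifierConfig,
    _mdgc,
    clopper_pearson,
    compute_metrics,
    confusion_at_threshold,
    design_matrix,
    mcnemar_test,
    mdgc_ranking,
    predict_prob,
    roc_auc,
    roc_auc_ci,
    train_tune,
)
from edvent.cohort import generate_cohort
from edvent.preprocessing import train_test_split
from tests.conftest import make_cohort

FAST = ClassifierConfig(tree_grid=(50, 100), cv_folds=3, seed=0)


class TestTrainTune:
    def test_separable_feature_fits_perfectly(self):
        c = make_cohort(
            [{"DDIMER": 10.0 + i, "outcome": 1} for i in range(30)]
            + [{"DDIMER": -10.0 - i, "outcome": 0} for i in range(30)]
        )
        model = train_tune(c, FAST)
        probs = predict_prob(model, c)
        acc = np.mean((probs >= 0.5).astype(int) == c.df["outcome"].to_numpy(int))
        assert acc == 1.0

    def test_single_class_rejected(self):
        c = make_cohort([{"outcome": 1} for _ in range(20)])
        with pytest.raises(ValueError):
            train_tune(c, FAST)

    def test_null_labels_give_chance_auc(self, spec):
        """Randomly permuted outcomes leave nothing to learn: held-out
        AUC is near 0.5."""
        rng = np.random.default_rng(5)
        c = generate_cohort(spec, 600, seed=5)
        c.df["outcome"] = rng.permutation(c.df["outcome"].to_numpy())
        split = train_test_split(c, 0.7, seed=5)
        model = train_tune(split.train, FAST)
        probs = predict_prob(model, split.test)
        auc = roc_auc(probs, split.test.df["outcome"].to_numpy(int))
        assert abs(auc - 0.5) < 0.12

    def test_tie_break_prefers_smaller_forest(self):
        c = make_cohort(
            [{"DDIMER": 10.0 + i, "outcome": 1} for i in range(20)]
            + [{"DDIMER": -10.0 - i, "outcome": 0} for i in range(20)]
        )
        # fully separable: every tree count reaches CV AUC 1.0
        model = train_tune(c, ClassifierConfig(tree_grid=(50, 100, 150), cv_folds=2, seed=0))
        assert model.n_trees == 50

    def test_deterministic_under_seed(self, spec):
        c = generate_cohort(spec, 300, seed=2)
        m1 = train_tune(c, FAST)
        m2 = train_tune(c, FAST)
        pd.testing.assert_series_equal(m1.importances, m2.importances)


class TestMdgc:
    def test_depth_one_perfect_split_oracle(self):
        """A stump splitting a balanced sample of size n perfectly has
        total Gini decrease n * 0.5 (0.5 at the root, 0 in the leaves)."""
        n = 200
        x = np.zeros((n, 2))
        x[:, 0] = np.repeat([0.0, 1.0], n // 2)
        y = np.repeat([0, 1], n // 2)
        forest = RandomForestClassifier(n_estimators=1, max_depth=1, bootstrap=False,
                                        random_state=0).fit(x, y)
        imp = _mdgc(forest, ("split_feature", "unused"))
        assert imp["split_feature"] == pytest.approx(0.5 * n)
        assert imp["unused"] == 0.0

    def test_noise_feature_ranked_last(self):
        rng = np.random.default_rng(0)
        c = make_cohort([{"outcome": int(i < 100)} for i in range(200)])
        y = c.df["outcome"].to_numpy(int)
        c.df["DDIMER"] = y * 3.0 + rng.normal(size=200)  # strong
        c.df["HB_R1"] = rng.normal(size=200)  # pure noise
        model = train_tune(c, FAST)
        assert model.importances["DDIMER"] > model.importances["HB_R1"]
        ranking = mdgc_ranking(model)
        assert list(ranking.columns) == ["feature", "mdgc"]
        assert ranking["mdgc"].is_monotonic_decreasing

    def test_importances_nonnegative_and_complete(self, spec):
        c = generate_cohort(spec, 300, seed=3)
        model = train_tune(c, FAST)
        assert (model.importances >= 0).all()
        assert len(model.importances) == 13


class TestConfusionAndMetrics:
    def test_basic_counts(self):
        cc = confusion_at_threshold([0.9, 0.1], [1, 0], 0.5)
        assert (cc.tp, cc.tn, cc.fp, cc.fn) == (1, 1, 0, 0)

    def test_threshold_boundary_counts_positive(self):
        cc = confusion_at_threshold([0.5], [0], 0.5)
        assert cc.fp == 1

    def test_all_positive(self):
        cc = confusion_at_threshold([1.0, 1.0], [1, 1], 0.5)
        assert cc.fn == 0 and cc.tn == 0

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            confusion_at_threshold([0.5, 0.6], [1], 0.5)

    def test_sensitivity_point_estimate(self):
        from edvent.classifier import ConfusionCounts

        rep = compute_metrics(ConfusionCounts(tp=148, fp=10, tn=100, fn=11))
        assert rep.sensitivity[0] == pytest.approx(148 / 159)
        assert round(rep.sensitivity[0] * 100, 2) == 93.08

    def test_perfect_classifier(self):
        from edvent.classifier import ConfusionCounts

        rep = compute_metrics(ConfusionCounts(tp=5, fp=0, tn=5, fn=0))
        assert rep.sensitivity[0] == 1.0 and rep.specificity[0] == 1.0

    def test_undefined_metric_is_none(self):
        from edvent.classifier import ConfusionCounts

        rep = compute_metrics(ConfusionCounts(tp=0, fp=0, tn=5, fn=5))
        assert rep.ppv is None
        assert rep.sensitivity is not None

    def test_estimates_inside_cis(self, spec):
        c = generate_cohort(spec, 400, seed=6)
        rng = np.random.default_rng(1)
        probs = np.clip(c.df["outcome"].to_numpy(float) * 0.5 + rng.random(400) * 0.5, 0, 1)
        rep = compute_metrics(confusion_at_threshold(probs, c.df["outcome"].to_numpy(int), 0.5))
        for t in (rep.sensitivity, rep.specificity, rep.ppv, rep.npv):
            assert t is not None and t[1] <= t[0] <= t[2]
            assert 0.0 <= t[1] and t[2] <= 1.0


def cp_bruteforce(k: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Invert the binomial tails by bisection (independent oracle)."""
    from scipy.optimize import brentq

    a = (1 - level) / 2
    lo = 0.0 if k == 0 else brentq(lambda p: stats.binom.sf(k - 1, n, p) - a, 1e-12, 1 - 1e-12)
    hi = 1.0 if k == n else brentq(lambda p: stats.binom.cdf(k, n, p) - a, 1e-12, 1 - 1e-12)
    return lo, hi


class TestClopperPearson:
    def test_reference_interval(self):
        """9 successes of 10 at 95%: CI ~ (0.555, 0.997)."""
        lo, hi = clopper_pearson(9, 10)
        assert lo == pytest.approx(0.555, abs=0.001)
        assert hi == pytest.approx(0.997, abs=0.001)

    def test_agrees_with_binomial_inversion_up_to_n25(self):
        for n in range(1, 26):
            for k in range(n + 1):
                lo, hi = clopper_pearson(k, n)
                blo, bhi = cp_bruteforce(k, n)
                assert lo == pytest.approx(blo, abs=1e-6)
                assert hi == pytest.approx(bhi, abs=1e-6)


class TestAuc:
    def test_reference_values(self):
        assert roc_auc([1.0, 0.0, 1.0, 0.0], [1, 0, 1, 0]) == 1.0
        assert roc_auc([0.4, 0.4, 0.4, 0.4], [1, 0, 1, 0]) == 0.5
        assert roc_auc([0.9, 0.8, 0.4, 0.2], [1, 0, 1, 0]) == pytest.approx(0.75)

    def test_matches_pair_enumeration(self, rng):
        """AUC equals the concordant-pair fraction (ties half)."""
        scores = rng.random(40).round(1)  # rounded: force some ties
        labels = rng.integers(0, 2, 40)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        pos = scores[labels == 1]
        neg = scores[labels == 0]
        conc = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
        assert roc_auc(scores, labels) == pytest.approx(conc / (len(pos) * len(neg)))

    @settings(max_examples=50, derandomize=True)
    @given(st.lists(st.floats(-5, 5), min_size=4, max_size=30),
           st.integers(min_value=0, max_value=2**30))
    def test_monotone_invariance_and_complement(self, scores, label_seed):
        # round to a grid where exp(x/2) stays strictly increasing in floats
        scores = np.round(np.asarray(scores), 3)
        labels = np.random.default_rng(label_seed).integers(0, 2, len(scores))
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        a = roc_auc(scores, labels)
        assert roc_auc(np.exp(scores / 2), labels) == pytest.approx(a)
        assert roc_auc(scores, 1 - labels) == pytest.approx(1.0 - a)

    def test_delong_ci_contains_estimate(self, rng):
        labels = rng.integers(0, 2, 200)
        labels[:2] = [0, 1]
        scores = labels + rng.normal(0, 1, 200)
        auc, lo, hi = roc_auc_ci(scores, labels)
        assert lo <= auc <= hi
        assert 0.0 <= lo and hi <= 1.0

    def test_delong_interval_covers_known_auc(self, rng):
        """Binormal scores with a known population AUC: the DeLong 95%
        interval should cover it in most repetitions."""
        target = stats.norm.cdf(1 / math.sqrt(2))  # AUC for unit shift
        covered = 0
        for i in range(40):
            g = np.random.default_rng(i)
            y = g.integers(0, 2, 150)
            y[:2] = [0, 1]
            s = g.normal(0, 1, 150) + y
            _, lo, hi = roc_auc_ci(s, y)
            covered += lo <= target <= hi
        assert covered >= 33  # ~95% nominal; binomial slack

    def test_single_class_error(self):
        with pytest.raises(ValueError):
            roc_auc([0.5, 0.6], [1, 1])


def mcnemar_bruteforce(b: int, c: int) -> float:
    n = b + c
    if n == 0:
        return 1.0
    pmf = [math.comb(n, i) * 0.5**n for i in range(n + 1)]
    k = min(b, c)
    p = 2.0 * sum(pmf[: k + 1])
    return min(p, 1.0)


class TestMcnemar:
    @pytest.mark.parametrize("b,c,expected", [
        (0, 0, 1.0),
        (3, 9, 2 * (1 + 12 + 66 + 220) / 4096),
        (2, 8, 2 * (1 + 10 + 45) / 1024),
    ])
    def test_reference_values(self, b, c, expected):
        pred = np.array([1] * b + [0] * c + [1, 0])
        obs = np.array([0] * b + [1] * c + [1, 0])
        assert mcnemar_test(pred, obs).p_value == pytest.approx(expected, rel=1e-9)

    def test_agrees_with_enumeration_up_to_n25(self):
        for b in range(0, 13):
            for c in range(0, 13):
                pred = np.array([1] * b + [0] * c + [1])
                obs = np.array([0] * b + [1] * c + [1])
                assert mcnemar_test(pred, obs).p_value == pytest.approx(
                    mcnemar_bruteforce(b, c), rel=1e-9)

    def test_non_binary_rejected(self):
        with pytest.raises(ValueError):
            mcnemar_test(np.array([0, 2]), np.array([0, 1]))


class TestDesignMatrix:
    def test_incomplete_cohort_rejected(self, spec):
        from edvent.cohort import inject_missingness

        c = generate_cohort(spec, 20, seed=1)
        c = inject_missingness(c, {"DDIMER": 1.0}, seed=2)
        with pytest.raises(ValueError, match="complete"):
            design_matrix(c)

    def test_empty_prediction(self, spec):
        c = generate_cohort(spec, 60, seed=1)
        model = train_tune(c, FAST)
        assert len(predict_prob(model, generate_cohort(spec, 0, seed=2))) == 0

    def test_probabilities_in_unit_interval(self, spec):
        c = generate_cohort(spec, 120, seed=1)
        model = train_tune(c, FAST)
        probs = predict_prob(model, c)
        assert np.all((probs >= 0) & (probs <= 1))
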