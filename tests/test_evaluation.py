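import numpy as np
import pandas as pd
import pytest
from scipy import stats
from statsmodels.stats.weightstats import ttest_ind as sm_ttest_ind

from nodtex import (
    ClassifierConfig,
    TestConfig as StatTestConfig,
    compare_auc_distributions,
    confusion_metrics,
    pooled_glcm_features,
    pooled_glcm_tests,
    roc_curve,
    train_eval_ann,
    ttest_features,
)
from nodtex.evaluation import _fit_fold, _welch_test, youden_threshold
from nodtex.glcm import GLCM_FEATURE_NAMES, ORIENTATIONS
from nodtex.pipeline import FEATURE_NAMES


def _random_matrix(rng, n_pos=10, n_neg=10, shift=None):
    """A feature matrix with optional per-class mean shift on every column."""
    n = n_pos + n_neg
    x = rng.standard_normal((n, 94))
    y = np.r_[np.ones(n_pos, int), np.zeros(n_neg, int)]
    if shift is not None:
        x[:n_pos] += shift
    df = pd.DataFrame(x, columns=list(FEATURE_NAMES))
    df["target"] = y
    return df


def test_bonferroni_thresholds():
    cfg = StatTestConfig()
    assert cfg.threshold_all == pytest.approx(0.05 / 94)   # prints as 0.0005
    assert round(cfg.threshold_all, 4) == 0.0005
    assert cfg.threshold_pooled == pytest.approx(0.0025)   # 0.05 / 20 exactly


class TestTTests:
    def test_identical_groups_give_t0_p1(self, rng):
        half = _random_matrix(rng, n_pos=8, n_neg=0)
        dup = half.copy()
        dup["target"] = 0
        res = ttest_features(pd.concat([half, dup], ignore_index=True))
        assert np.allclose(res["t"], 0.0, atol=1e-12)
        assert np.allclose(res["p"], 1.0, atol=1e-12)

    def test_three_sd_shift_is_flagged_significant(self, rng):
        """Power is ~1 for a 3-sd shift at n=40/group; 100 simulation reps."""
        hits = 0
        for _ in range(100):
            a = rng.standard_normal(40) + 3.0
            b = rng.standard_normal(40)
            _, p, _ = _welch_test(a, b)
            hits += p < StatTestConfig().threshold_all
        assert hits >= 99

    def test_matches_statsmodels_oracle(self, rng):
        m = _random_matrix(rng, shift=0.5)
        res = ttest_features(m)
        pos = m[m.target == 1]
        neg = m[m.target == 0]
        for feature in list(FEATURE_NAMES)[::13]:
            t_ref, p_ref, _ = sm_ttest_ind(
                pos[feature], neg[feature], usevar="unequal")
            assert res.loc[feature, "t"] == pytest.approx(t_ref, abs=1e-10)
            assert res.loc[feature, "p"] == pytest.approx(p_ref, abs=1e-10)

    def test_zero_variance_rules(self):
        a = np.full(5, 2.0)
        t, p, sep = _welch_test(a, a.copy())
        assert (t, p, sep) == (0.0, 1.0, False)
        t, p, sep = _welch_test(a, np.full(5, 3.0))
        assert p == 0.0 and sep

    def test_single_class_rejected(self, rng):
        m = _random_matrix(rng, n_pos=10, n_neg=1)
        with pytest.raises(ValueError, match=">= 2 lesions per class"):
            ttest_features(m)


class TestPooledTests:
    def test_pooled_equals_orientation_mean(self, rng):
        m = _random_matrix(rng)
        pooled = pooled_glcm_features(m)
        cols = [f"glcm{a:03d}_contrast" for a in ORIENTATIONS]
        np.testing.assert_allclose(
            pooled["pooled_contrast"], m[cols].mean(axis=1))

    def test_identical_orientation_blocks_match_per_orientation(self, rng):
        m = _random_matrix(rng, shift=1.0)
        for name in GLCM_FEATURE_NAMES[:3]:
            base = m[f"glcm000_{name}"]
            for a in ORIENTATIONS[1:]:
                m[f"glcm{a:03d}_{name}"] = base
        res_pooled = pooled_glcm_tests(m)
        res_all = ttest_features(m)
        for name in GLCM_FEATURE_NAMES[:3]:
            assert res_pooled.loc[f"pooled_{name}", "t"] == pytest.approx(
                res_all.loc[f"glcm000_{name}", "t"], abs=1e-12)

    def test_has_20_rows(self, rng):
        assert len(pooled_glcm_tests(_random_matrix(rng))) == 20


class TestConfusionMetrics:
    def test_radiologist_worked_example(self):
        """Counts 43/6 and 30/12 reproduce 87.76 / 71.43 / 80.2 percent."""
        m = confusion_metrics(tp=43, fn=6, tn=30, fp=12)
        assert m["sensitivity"] == pytest.approx(87.755, abs=1e-2)
        assert m["specificity"] == pytest.approx(71.429, abs=1e-2)
        assert m["accuracy"] == pytest.approx(80.22, abs=1e-2)
        assert round(m["accuracy"], 1) == 80.2

    def test_perfect_and_worthless_classifiers(self):
        perfect = confusion_metrics(5, 0, 5, 0)
        assert all(v == 100.0 for v in perfect.values())
        worthless = confusion_metrics(0, 5, 0, 5)
        assert worthless["sensitivity"] == 0.0
        assert worthless["specificity"] == 0.0

    def test_identities_on_random_confusions(self, rng):
        for _ in range(50):
            tp, fn, tn, fp = rng.integers(0, 30, size=4)
            if tp + fn == 0 or tn + fp == 0:
                continue
            m = confusion_metrics(tp, fn, tn, fp)
            n = tp + fn + tn + fp
            assert m["accuracy"] == pytest.approx(100 * (tp + tn) / n)
            if tp + fp:
                assert m["ppv"] == pytest.approx(100 * tp / (tp + fp))
            if tn + fn:
                assert m["npv"] == pytest.approx(100 * tn / (tn + fn))

    def test_empty_class_rejected(self):
        with pytest.raises(ValueError):
            confusion_metrics(0, 0, 3, 2)


def pairwise_auc(scores, labels):
    """Oracle: fraction of positive-negative pairs correctly ordered."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = ties = 0
    for p in pos:
        for q in neg:
            wins += p > q
            ties += p == q
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


class TestROC:
    def test_scores_equal_labels_auc_one(self):
        roc = roc_curve(np.array([0, 1, 0, 1.0]), np.array([0, 1, 0, 1]))
        assert roc.auc == 1.0

    def test_three_of_four_pairs_ordered(self):
        roc = roc_curve(np.array([0.1, 0.4, 0.35, 0.8]),
                        np.array([0, 0, 1, 1]))
        assert roc.auc == pytest.approx(0.75)

    def test_trapezoid_equals_pair_counting(self, rng):
        for _ in range(30):
            n = int(rng.integers(4, 40))
            labels = rng.integers(0, 2, size=n)
            if labels.min() == labels.max():
                continue
            scores = rng.choice([0.1, 0.2, 0.3, 0.5, 0.9], size=n)  # with ties
            roc = roc_curve(scores, labels)
            assert roc.auc == pytest.approx(
                pairwise_auc(scores, labels), abs=1e-12)
            assert np.all(np.diff(roc.fpr) >= 0)
            assert np.all(np.diff(roc.tpr) >= 0)

    def test_one_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            roc_curve(np.array([0.1, 0.2]), np.array([1, 1]))

    def test_youden_threshold_maximizes_j(self, rng):
        scores = rng.random(30)
        labels = rng.integers(0, 2, size=30)
        labels[:2] = [0, 1]
        roc = roc_curve(scores, labels)
        thr = youden_threshold(roc)
        pred = scores >= thr
        j = (pred[labels == 1].mean()) - (pred[labels == 0].mean())
        for t in np.unique(scores):
            pred_t = scores >= t
            j_t = pred_t[labels == 1].mean() - pred_t[labels == 0].mean()
            assert j >= j_t - 1e-12


class TestTrainEval:
    def test_separable_blobs_reach_high_auc(self, rng):
        m = _random_matrix(rng, n_pos=25, n_neg=25)
        m.loc[m.target == 1, list(FEATURE_NAMES[:8])] += 8.0  # disjoint blobs
        cfg = ClassifierConfig(feature_set="attenuation", folds=5, cycles=3,
                               seed=0)
        _, summary, _ = train_eval_ann(m, cfg)
        assert summary.loc["auc", "mean"] >= 0.99

    def test_rerun_reproduces_every_cycle_metric(self, rng):
        m = _random_matrix(rng, n_pos=12, n_neg=12, shift=1.0)
        cfg = ClassifierConfig(feature_set="lbp", folds=4, cycles=2, seed=7)
        m1, s1, r1 = train_eval_ann(m, cfg)
        m2, s2, r2 = train_eval_ann(m, cfg)
        assert [vars(a) for a in m1] == [vars(b) for b in m2]
        pd.testing.assert_frame_equal(s1, s2)
        np.testing.assert_array_equal(r1.fpr, r2.fpr)

    def test_no_leakage_from_test_rows(self, rng):
        """Scaling and training artifacts depend only on training rows."""
        x_train = rng.standard_normal((30, 6))
        y_train = rng.integers(0, 2, size=30)
        y_train[:2] = [0, 1]
        x_test = rng.standard_normal((5, 6))
        x_test_perturbed = np.vstack([x_test, x_test * 100 + 50])
        cfg = ClassifierConfig(feature_set="lbp", folds=2, cycles=1, seed=0)
        s1, _ = _fit_fold(x_train, y_train, x_test, cfg, seed=3)
        s2, _ = _fit_fold(x_train, y_train, x_test_perturbed, cfg, seed=3)
        np.testing.assert_array_equal(s1, s2[:5])

    def test_too_few_lesions_per_class_rejected(self, rng):
        m = _random_matrix(rng, n_pos=5, n_neg=20)
        with pytest.raises(ValueError, match="10-fold"):
            train_eval_ann(m, ClassifierConfig(feature_set="lbp", folds=10,
                                               cycles=1))


def anova_oracle(groups):
    """Closed-form one-way F from between/within mean squares."""
    k = len(groups)
    n = sum(len(g) for g in groups)
    grand = np.concatenate(groups).mean()
    ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
    f = (ssb / (k - 1)) / (ssw / (n - k))
    p = stats.f.sf(f, k - 1, n - k)
    return f, p


class TestCompareAUC:
    def test_identical_lists_give_f0_p1(self, rng):
        base = rng.random(20)
        res = compare_auc_distributions([base.copy() for _ in range(4)])
        assert res["F"] == pytest.approx(0.0, abs=1e-12)
        assert res["p"] == pytest.approx(1.0)

    def test_shifted_list_flagged_after_bonferroni(self, rng):
        lists = {f"m{i}": rng.normal(0.8, 0.01, 100) for i in range(3)}
        lists["shifted"] = rng.normal(0.9, 0.01, 100)
        res = compare_auc_distributions(lists)
        assert res["p"] < 0.001
        for pair, stats_ in res["pairwise"].items():
            if "shifted" in pair:
                assert stats_["p_bonferroni"] < 0.001

    def test_f_matches_closed_form_oracle(self, rng):
        groups = [rng.normal(loc, 0.05, 30) for loc in (0.8, 0.82, 0.85, 0.8)]
        res = compare_auc_distributions(groups)
        f_ref, p_ref = anova_oracle(groups)
        assert res["F"] == pytest.approx(f_ref, abs=1e-10)
        assert res["p"] == pytest.approx(p_ref, abs=1e-10)

    def test_fewer_than_two_groups_rejected(self, rng):
        with pytest.raises(ValueError):
            compare_auc_distributions([rng.random(5)])
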