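"""Group statistics, repeated cross-validated ANN classification, ROC metrics.

Feature screening uses Welch two-sample t-tests with two Bonferroni
thresholds: 0.05/94 = 0.0005 over the full panel and 0.05/20 = 0.0025 over
the 20 orientation-pooled co-occurrence features.  Classification uses a
feedforward network (50 tanh hidden units, 2-unit softmax output,
cross-entropy loss, early stopping) under stratified 10-fold
cross-validation repeated for a configurable number of cycles, with
fold-wise min-max scaling fitted on training rows only.  The positive
class for all metrics is non-calcified hamartoma (target = 1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.exceptions import ConvergenceWarning
from sklearn.model_selection import StratifiedKFold
from sklearn.neural_network import MLPClassifier

from nodtex.glcm import GLCM_FEATURE_NAMES, ORIENTATIONS
from nodtex.pipeline import FEATURE_BLOCKS, FEATURE_NAMES


@dataclass
class TestConfig:
    """Significance configuration with Bonferroni-corrected thresholds."""

    alpha: float = 0.05
    n_tests_all: int = 94
    n_tests_pooled: int = 20

    @property
    def threshold_all(self) -> float:
        return self.alpha / self.n_tests_all      # 0.0005 at the defaults

    @property
    def threshold_pooled(self) -> float:
        return self.alpha / self.n_tests_pooled   # 0.0025 at the defaults


@dataclass
class ClassifierConfig:
    """Repeated cross-validated ANN configuration."""

    feature_set: str = "all"   # one of attenuation | glcm | lbp | all
    hidden_units: int = 50
    folds: int = 10
    cycles: int = 100
    seed: int = 0
    max_iter: int = 500
    # Loss-plateau stopping (tol-based) is the default: with ~80 training
    # rows per fold a 10% held-out validation split has ~8 samples, and
    # validation-based early stopping halts after ~20 iterations, badly
    # underfitting.  Set True to stop on a 10% validation split instead.
    early_stopping: bool = False

    def __post_init__(self) -> None:
        if self.feature_set not in FEATURE_BLOCKS:
            raise ValueError(f"unknown feature set {self.feature_set!r}")
        if min(self.hidden_units, self.folds, self.cycles) < 1:
            raise ValueError("hidden_units, folds and cycles must be >= 1")


@dataclass
class CycleMetrics:
    """Per-cycle performance at the Youden-optimal threshold (percent)."""

    sensitivity: float
    specificity: float
    accuracy: float
    ppv: float
    npv: float
    auc: float           # unitless, in [0, 1]
    threshold: float
    converged: bool = True


@dataclass
class ROCCurve:
    """Threshold-swept ROC with trapezoidal AUC."""

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float


def _group_split(matrix: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    pos = matrix[matrix["target"] == 1]
    neg = matrix[matrix["target"] == 0]
    if len(pos) < 2 or len(neg) < 2:
        raise ValueError(
            "group statistics require >= 2 lesions per class "
            f"(got {len(pos)} NCH, {len(neg)} ACA)"
        )
    return pos, neg


def _welch_test(a: np.ndarray, b: np.ndarray) -> tuple[float, float, bool]:
    """Welch t and two-sided p; handles zero variance in both groups."""
    exact_sep = False
    if a.var(ddof=1) == 0.0 and b.var(ddof=1) == 0.0:
        if a.mean() == b.mean():
            return 0.0, 1.0, False
        return np.inf, 0.0, True  # 0-variance exact separation
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p), exact_sep


def _ttest_table(matrix: pd.DataFrame, columns: list[str],
                 threshold: float) -> pd.DataFrame:
    pos, neg = _group_split(matrix)
    rows = []
    for col in columns:
        a = pos[col].to_numpy(dtype=float)
        b = neg[col].to_numpy(dtype=float)
        t, p, sep = _welch_test(a, b)
        rows.append({
            "feature": col, "t": t, "p": p,
            "mean_nch": a.mean(), "mean_aca": b.mean(),
            "significant": bool(p < threshold),
            "exact_separation": sep,
        })
    return pd.DataFrame(rows).set_index("feature")


def ttest_features(matrix: pd.DataFrame,
                   cfg: TestConfig | None = None) -> pd.DataFrame:
    """Welch t-test per feature over the 94-column panel, threshold 0.05/94."""
    cfg = cfg or TestConfig()
    return _ttest_table(matrix, list(FEATURE_NAMES), cfg.threshold_all)


def pooled_glcm_features(matrix: pd.DataFrame) -> pd.DataFrame:
    """Average each of the 20 co-occurrence features over the 4 orientations."""
    out = pd.DataFrame(index=matrix.index)
    for name in GLCM_FEATURE_NAMES:
        cols = [f"glcm{angle:03d}_{name}" for angle in ORIENTATIONS]
        out[f"pooled_{name}"] = matrix[cols].mean(axis=1)
    out["target"] = matrix["target"]
    return out


def pooled_glcm_tests(matrix: pd.DataFrame,
                      cfg: TestConfig | None = None) -> pd.DataFrame:
    """Welch t-tests on the 20 pooled co-occurrence features, threshold 0.05/20."""
    cfg = cfg or TestConfig()
    pooled = pooled_glcm_features(matrix)
    cols = [c for c in pooled.columns if c != "target"]
    return _ttest_table(pooled, cols, cfg.threshold_pooled)


def confusion_metrics(tp: int, fn: int, tn: int, fp: int) -> dict[str, float]:
    """Sensitivity, specificity, accuracy, PPV, NPV in percent."""
    if tp + fn == 0 or tn + fp == 0:
        raise ValueError("both classes must be present in the confusion matrix")
    sens = 100.0 * tp / (tp + fn)
    spec = 100.0 * tn / (tn + fp)
    acc = 100.0 * (tp + tn) / (tp + fn + tn + fp)
    ppv = 100.0 * tp / (tp + fp) if tp + fp > 0 else 0.0
    npv = 100.0 * tn / (tn + fn) if tn + fn > 0 else 0.0
    return {"sensitivity": sens, "specificity": spec, "accuracy": acc,
            "ppv": ppv, "npv": npv}


def roc_curve(scores: np.ndarray, labels: np.ndarray) -> ROCCurve:
    """ROC by threshold sweep over the unique scores; AUC by trapezoid rule.

    The trapezoidal AUC equals the pairwise-ordering (Mann-Whitney)
    probability that a positive case outscores a negative one, with ties
    counted 1/2.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC requires both classes present")
    order = np.argsort(-scores, kind="stable")
    s, y = scores[order], labels[order]
    # Cumulative counts at each distinct-score boundary.
    distinct = np.r_[np.nonzero(np.diff(s))[0], len(s) - 1]
    tps = np.cumsum(y == 1)[distinct]
    fps = np.cumsum(y == 0)[distinct]
    tpr = np.r_[0.0, tps / n_pos]
    fpr = np.r_[0.0, fps / n_neg]
    thresholds = np.r_[np.inf, s[distinct]]
    auc = float(np.trapezoid(tpr, fpr))
    return ROCCurve(fpr=fpr, tpr=tpr, thresholds=thresholds, auc=auc)


def youden_threshold(roc: ROCCurve) -> float:
    """Operating threshold maximizing sensitivity + specificity - 1."""
    j = roc.tpr - roc.fpr
    return float(roc.thresholds[int(np.argmax(j))])


def _scores_to_metrics(scores: np.ndarray, labels: np.ndarray,
                       converged: bool) -> CycleMetrics:
    roc = roc_curve(scores, labels)
    thr = youden_threshold(roc)
    pred = scores >= thr
    tp = int(np.sum(pred & (labels == 1)))
    fn = int(np.sum(~pred & (labels == 1)))
    tn = int(np.sum(~pred & (labels == 0)))
    fp = int(np.sum(pred & (labels == 0)))
    m = confusion_metrics(tp, fn, tn, fp)
    return CycleMetrics(
        sensitivity=m["sensitivity"], specificity=m["specificity"],
        accuracy=m["accuracy"], ppv=m["ppv"], npv=m["npv"],
        auc=roc.auc, threshold=thr, converged=converged,
    )


def _fit_fold(x_train, y_train, x_test, cfg: ClassifierConfig, seed):
    """Train one fold's network; returns NCH scores and a convergence flag.

    Scaling parameters derive from training rows only (no leakage); a
    non-convergent fit is retried once with a derived seed.
    """
    lo = x_train.min(axis=0)
    span = x_train.max(axis=0) - lo
    span[span == 0] = 1.0
    xt = (x_train - lo) / span
    xs = (x_test - lo) / span

    for attempt, rs in enumerate((seed, seed + 104729)):
        clf = MLPClassifier(
            hidden_layer_sizes=(cfg.hidden_units,), activation="tanh",
            solver="adam", max_iter=cfg.max_iter,
            early_stopping=cfg.early_stopping,
            validation_fraction=0.1, n_iter_no_change=10,
            random_state=rs,
        )
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always", ConvergenceWarning)
            clf.fit(xt, y_train)
        converged = not any(
            issubclass(w.category, ConvergenceWarning) for w in caught
        )
        if converged or attempt == 1:
            pos = list(clf.classes_).index(1)
            return clf.predict_proba(xs)[:, pos], converged
    raise AssertionError("unreachable")  # pragma: no cover


def train_eval_ann(
    matrix: pd.DataFrame, cfg: ClassifierConfig
) -> tuple[list[CycleMetrics], pd.DataFrame, ROCCurve]:
    """Repeated stratified k-fold evaluation of the ANN on one feature set.

    Per cycle, fold assignment is reseeded from ``cfg.seed``; per fold,
    feature columns are min-max scaled on training rows only; test-fold
    NCH probabilities are pooled within the cycle and summarized at the
    Youden-optimal threshold of the cycle's ROC.

    Returns the per-cycle metrics, a mean +/- sd summary table, and the
    ROC pooled over all cycles' test scores.
    """
    cols = list(FEATURE_NAMES[FEATURE_BLOCKS[cfg.feature_set]])
    x = matrix[cols].to_numpy(dtype=float)
    y = matrix["target"].to_numpy(dtype=int)
    n_pos, n_neg = int((y == 1).sum()), int((y == 0).sum())
    if min(n_pos, n_neg) < cfg.folds:
        raise ValueError(
            f"need >= {cfg.folds} lesions per class for {cfg.folds}-fold CV "
            f"(got {n_pos} NCH, {n_neg} ACA)"
        )

    root = np.random.SeedSequence(cfg.seed)
    cycle_seeds = root.generate_state(2 * cfg.cycles) % (2 ** 31)

    metrics: list[CycleMetrics] = []
    all_scores, all_labels = [], []
    for c in range(cfg.cycles):
        skf = StratifiedKFold(
            n_splits=cfg.folds, shuffle=True,
            random_state=int(cycle_seeds[2 * c]),
        )
        scores = np.empty(len(y))
        converged = True
        for f, (tr, te) in enumerate(skf.split(x, y)):
            fold_seed = int((cycle_seeds[2 * c + 1] + f) % (2 ** 31))
            scores[te], ok = _fit_fold(x[tr], y[tr], x[te], cfg, fold_seed)
            converged &= ok
        metrics.append(_scores_to_metrics(scores, y, converged))
        all_scores.append(scores)
        all_labels.append(y)

    pooled = roc_curve(np.concatenate(all_scores), np.concatenate(all_labels))
    summary = summarize_cycles(metrics, cfg.feature_set)
    return metrics, summary, pooled


def summarize_cycles(metrics: list[CycleMetrics],
                     feature_set: str = "") -> pd.DataFrame:
    """Mean +/- sd over cycles for every metric."""
    df = pd.DataFrame([{
        "sensitivity": m.sensitivity, "specificity": m.specificity,
        "accuracy": m.accuracy, "ppv": m.ppv, "npv": m.npv, "auc": m.auc,
    } for m in metrics])
    out = pd.DataFrame({
        "mean": df.mean(),
        "sd": df.std(ddof=1) if len(df) > 1 else 0.0,
    })
    out.index.name = "metric"
    if feature_set:
        out.insert(0, "feature_set", feature_set)
    return out


def permuted_null_auc(matrix: pd.DataFrame, cfg: ClassifierConfig) -> pd.DataFrame:
    """Label-permutation null for the ANN: fresh permutation every cycle.

    Runs ``cfg.cycles`` single-cycle evaluations, each on an independently
    permuted label vector (seeds derived from ``cfg.seed``), and returns
    the per-permutation cycle metrics.  The mean AUC estimates chance-level
    performance for the feature set.
    """
    root = np.random.SeedSequence((cfg.seed, 0xD1CE))
    perm_seeds = root.generate_state(2 * cfg.cycles) % (2 ** 31)
    rows = []
    for c in range(cfg.cycles):
        rng = np.random.default_rng(int(perm_seeds[2 * c]))
        shuffled = matrix.copy()
        shuffled["target"] = rng.permutation(shuffled["target"].to_numpy())
        one = ClassifierConfig(
            feature_set=cfg.feature_set, hidden_units=cfg.hidden_units,
            folds=cfg.folds, cycles=1, seed=int(perm_seeds[2 * c + 1]),
            max_iter=cfg.max_iter, early_stopping=cfg.early_stopping,
        )
        metrics, _, _ = train_eval_ann(shuffled, one)
        rows.append(metrics[0])
    df = pd.DataFrame([{"auc": m.auc, "accuracy": m.accuracy} for m in rows])
    return df


def compare_auc_distributions(
    auc_lists: dict[str, np.ndarray] | list[np.ndarray],
) -> dict:
    """One-way ANOVA across models' per-cycle AUCs plus Bonferroni pairwise tests.

    Pairwise comparisons are Welch t-tests with p multiplied by the number
    of pairs (capped at 1).
    """
    if isinstance(auc_lists, dict):
        names = list(auc_lists)
        groups = [np.asarray(auc_lists[k], dtype=float) for k in names]
    else:
        groups = [np.asarray(g, dtype=float) for g in auc_lists]
        names = [f"model{i}" for i in range(len(groups))]
    if len(groups) < 2:
        raise ValueError("need at least 2 AUC distributions to compare")
    if len({len(g) for g in groups}) != 1 or len(groups[0]) < 2:
        raise ValueError("AUC lists must have equal length >= 2")

    if all(np.allclose(g, groups[0]) for g in groups[1:]) and all(
        g.var() == 0 for g in groups
    ):
        f_stat, p_omni = 0.0, 1.0
    else:
        f_stat, p_omni = stats.f_oneway(*groups)
    n_pairs = len(groups) * (len(groups) - 1) // 2
    pairwise = {}
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            t, p, _ = _welch_test(groups[i], groups[j])
            pairwise[(names[i], names[j])] = {
                "t": t, "p_raw": p, "p_bonferroni": min(1.0, p * n_pairs),
            }
    return {"F": float(f_stat), "p": float(p_omni), "pairwise": pairwise}
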