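"""Random-forest ventilation-need model and its evaluation battery.

A random forest scores each admitted patient's probability of needing
mechanical ventilation from 13 predictors (sex, age band and 11 numeric
measurements). The tree count is tuned over {100, ..., 500} by mean
cross-validated AUC with 3 variables tried per split; importances are
reported as the Mean Decrease in Gini Coefficient (MDGC) — the total
node-impurity decrease attributed to a feature per tree, in sample
counts, averaged over trees.

Evaluation follows the standard diagnostic-test battery: sensitivity,
specificity, PPV and NPV with exact Clopper-Pearson 95% intervals; ROC
AUC with a DeLong interval; and an exact McNemar test for asymmetry of
misclassification between the classes.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold

from .cohort import AGE_LEVELS, FEATURES, Cohort
from .input_checks import TestResult

__all__ = [
    "ClassifierConfig",
    "TrainedModel",
    "ConfusionCounts",
    "MetricsReport",
    "design_matrix",
    "train_tune",
    "predict_prob",
    "confusion_at_threshold",
    "compute_metrics",
    "clopper_pearson",
    "roc_auc",
    "roc_auc_ci",
    "mcnemar_test",
    "mdgc_ranking",
]

MODEL_FEATURES = ("sex_male", "age_ord") + FEATURES


@dataclass(frozen=True)
class ClassifierConfig:
    tree_grid: tuple[int, ...] = (100, 200, 300, 400, 500)
    mtry: int = 3
    cv_folds: int = 10
    threshold: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if any(t < 1 for t in self.tree_grid):
            raise ValueError("tree counts must be positive")
        if self.mtry < 1:
            raise ValueError("mtry must be >= 1")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if not (0.0 < self.threshold < 1.0):
            raise ValueError("threshold must be in (0, 1)")


def design_matrix(cohort: Cohort) -> tuple[pd.DataFrame, np.ndarray]:
    """Numeric feature matrix (and outcome vector) for the forest.

    Sex becomes an indicator ``sex_male``; the age band becomes an
    ordinal 0/1/2. Requires a complete (post-imputation) cohort.
    """
    df = cohort.df
    missing_cols = [c for c in ("sex", "age_group", *FEATURES, "outcome") if c not in df.columns]
    if missing_cols:
        raise ValueError(f"cohort lacks columns {missing_cols}")
    if df[list(FEATURES)].isna().any().any() or df["sex"].isna().any() or df["age_group"].isna().any():
        raise ValueError("design matrix requires a complete cohort; impute first")
    x = pd.DataFrame(index=df.index)
    x["sex_male"] = (df["sex"] == "male").astype(float)
    x["age_ord"] = df["age_group"].map({lev: i for i, lev in enumerate(AGE_LEVELS)}).astype(float)
    for feat in FEATURES:
        x[feat] = df[feat].astype(float)
    y = df["outcome"].to_numpy(dtype=float)
    if np.isnan(y).any():
        raise ValueError("outcome contains missing values")
    return x, y.astype(int)


@dataclass
class TrainedModel:
    estimator: RandomForestClassifier
    n_trees: int
    importances: pd.Series  # MDGC per feature, descending
    seed: int
    feature_names: tuple[str, ...] = MODEL_FEATURES
    cv_results: pd.DataFrame | None = field(default=None, repr=False)


def _mdgc(forest: RandomForestClassifier, feature_names: tuple[str, ...]) -> pd.Series:
    """Mean decrease in Gini, unnormalised sample-count convention.

    For each tree, every internal node contributes
    ``N * i(node) - N_L * i(left) - N_R * i(right)`` to the feature it
    splits on, with N the (bootstrap-weighted) node sample count; the
    per-feature totals are averaged over trees.
    """
    total = np.zeros(len(feature_names))
    for est in forest.estimators_:
        t = est.tree_
        internal = t.children_left != -1
        w = t.weighted_n_node_samples
        dec = (
            w[internal] * t.impurity[internal]
            - w[t.children_left[internal]] * t.impurity[t.children_left[internal]]
            - w[t.children_right[internal]] * t.impurity[t.children_right[internal]]
        )
        np.add.at(total, t.feature[internal], dec)
    imp = pd.Series(total / len(forest.estimators_), index=list(feature_names))
    # descending by value, ties alphabetical
    return imp.sort_index().sort_values(ascending=False, kind="stable")


def train_tune(train: Cohort, config: ClassifierConfig | None = None) -> TrainedModel:
    """Tune the tree count by mean CV AUC, refit on the full training set."""
    config = config or ClassifierConfig()
    x, y = design_matrix(train)
    if len(np.unique(y)) < 2:
        raise ValueError("training set contains a single outcome class")
    folds = min(config.cv_folds, int(np.bincount(y).min()))
    if folds < 2:
        raise ValueError("too few minority-class cases for cross-validation")

    if len(config.tree_grid) == 1:  # nothing to tune
        best = int(config.tree_grid[0])
        rf = RandomForestClassifier(
            n_estimators=best, max_features=config.mtry, random_state=config.seed, n_jobs=1
        )
        rf.fit(x, y)
        return TrainedModel(estimator=rf, n_trees=best,
                            importances=_mdgc(rf, MODEL_FEATURES), seed=config.seed)

    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=config.seed)
    split_ix = list(cv.split(x, y))

    records = []
    for n_trees in config.tree_grid:
        aucs = []
        for k, (tr, te) in enumerate(split_ix):
            rf = RandomForestClassifier(
                n_estimators=n_trees,
                max_features=config.mtry,
                random_state=config.seed + 1000 * k,
                n_jobs=1,
            )
            rf.fit(x.iloc[tr], y[tr])
            probs = rf.predict_proba(x.iloc[te])[:, 1]
            aucs.append(roc_auc(probs, y[te]))
        records.append({"n_trees": n_trees, "mean_cv_auc": float(np.mean(aucs))})
    cv_results = pd.DataFrame(records)
    # ties broken toward the smallest forest
    best = int(min(t for t, a in zip(cv_results["n_trees"], cv_results["mean_cv_auc"])
                   if a == cv_results["mean_cv_auc"].max()))
    rf = RandomForestClassifier(
        n_estimators=best, max_features=config.mtry, random_state=config.seed, n_jobs=1
    )
    rf.fit(x, y)
    return TrainedModel(
        estimator=rf,
        n_trees=best,
        importances=_mdgc(rf, MODEL_FEATURES),
        seed=config.seed,
        cv_results=cv_results,
    )


def predict_prob(model: TrainedModel, cohort: Cohort) -> np.ndarray:
    """Per-patient ventilation-need probability, one value per record."""
    if len(cohort) == 0:
        return np.empty(0)
    x, _ = design_matrix(cohort)
    return model.estimator.predict_proba(x[list(model.feature_names)])[:, 1]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def confusion_at_threshold(
    probs: np.ndarray, outcomes: np.ndarray, threshold: float = 0.5
) -> ConfusionCounts:
    """Counts with the convention prob >= threshold => predicted positive."""
    probs = np.asarray(probs, dtype=float)
    outcomes = np.asarray(outcomes, dtype=int)
    if probs.shape != outcomes.shape:
        raise ValueError("probs and outcomes must have equal length")
    if not (0.0 < threshold < 1.0):
        raise ValueError("threshold must be in (0, 1)")
    pred = probs >= threshold
    return ConfusionCounts(
        tp=int(np.sum(pred & (outcomes == 1))),
        fp=int(np.sum(pred & (outcomes == 0))),
        tn=int(np.sum(~pred & (outcomes == 0))),
        fn=int(np.sum(~pred & (outcomes == 1))),
    )


def clopper_pearson(k: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Exact binomial confidence interval from beta quantiles."""
    if not (0 <= k <= n) or n == 0:
        raise ValueError(f"invalid counts k={k}, n={n}")
    a = 1.0 - level
    lo = 0.0 if k == 0 else float(stats.beta.ppf(a / 2.0, k, n - k + 1))
    hi = 1.0 if k == n else float(stats.beta.ppf(1.0 - a / 2.0, k + 1, n - k))
    return lo, hi


@dataclass
class MetricsReport:
    """Diagnostic metrics; each entry is (estimate, ci_low, ci_high) or None
    when its denominator is empty."""

    sensitivity: tuple[float, float, float] | None
    specificity: tuple[float, float, float] | None
    ppv: tuple[float, float, float] | None
    npv: tuple[float, float, float] | None
    level: float
    auc: tuple[float, float, float] | None = None
    mcnemar_p: float | None = None

    def to_dict(self) -> dict:
        def unpack(t):
            return None if t is None else {"estimate": t[0], "ci_low": t[1], "ci_high": t[2]}

        return {
            "sensitivity": unpack(self.sensitivity),
            "specificity": unpack(self.specificity),
            "ppv": unpack(self.ppv),
            "npv": unpack(self.npv),
            "auc": unpack(self.auc),
            "mcnemar_p": self.mcnemar_p,
            "level": self.level,
        }


def _metric(k: int, n: int, level: float) -> tuple[float, float, float] | None:
    if n == 0:
        return None
    lo, hi = clopper_pearson(k, n, level)
    return (k / n, lo, hi)


def compute_metrics(counts: ConfusionCounts, level: float = 0.95) -> MetricsReport:
    """Sensitivity/specificity/PPV/NPV with Clopper-Pearson intervals."""
    return MetricsReport(
        sensitivity=_metric(counts.tp, counts.tp + counts.fn, level),
        specificity=_metric(counts.tn, counts.tn + counts.fp, level),
        ppv=_metric(counts.tp, counts.tp + counts.fp, level),
        npv=_metric(counts.tn, counts.tn + counts.fn, level),
        level=level,
    )


def roc_auc(probs: np.ndarray, outcomes: np.ndarray) -> float:
    """AUC = P(random positive outscores random negative), ties count 1/2."""
    probs = np.asarray(probs, dtype=float)
    outcomes = np.asarray(outcomes, dtype=int)
    pos = probs[outcomes == 1]
    neg = probs[outcomes == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("AUC requires both outcome classes")
    ranks = stats.rankdata(np.concatenate([pos, neg]))
    u = ranks[: len(pos)].sum() - len(pos) * (len(pos) + 1) / 2.0
    return float(u / (len(pos) * len(neg)))


def _midrank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def roc_auc_ci(probs: np.ndarray, outcomes: np.ndarray, level: float = 0.95
               ) -> tuple[float, float, float]:
    """AUC with a DeLong confidence interval, clipped to [0, 1].

    The DeLong variance comes from the placement values (structural
    components) of the positives and negatives; when it degenerates
    (perfect separation) the interval collapses onto the estimate.
    """
    probs = np.asarray(probs, dtype=float)
    outcomes = np.asarray(outcomes, dtype=int)
    pos = probs[outcomes == 1]
    neg = probs[outcomes == 0]
    m, n = len(pos), len(neg)
    if m == 0 or n == 0:
        raise ValueError("AUC requires both outcome classes")
    all_r = _midrank(np.concatenate([pos, neg]))
    pos_r = _midrank(pos)
    neg_r = _midrank(neg)
    auc = (all_r[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v01 = (all_r[:m] - pos_r) / n  # placements of positives among negatives
    v10 = 1.0 - (all_r[m:] - neg_r) / m
    var = np.var(v01, ddof=1) / m + np.var(v10, ddof=1) / n if m > 1 and n > 1 else 0.0
    z = stats.norm.ppf(0.5 + level / 2.0)
    half = z * np.sqrt(max(var, 0.0))
    return float(auc), float(max(auc - half, 0.0)), float(min(auc + half, 1.0))


def mcnemar_test(predicted: np.ndarray, observed: np.ndarray, alpha: float = 0.05) -> TestResult:
    """Exact binomial McNemar test on the discordant pairs.

    With b = predicted-positive/observed-negative and c the reverse,
    the two-sided p-value is the exact binomial tail at min(b, c) under
    p0 = 1/2; p = 1 when there is no discordance.
    """
    predicted = np.asarray(predicted)
    observed = np.asarray(observed)
    if predicted.shape != observed.shape:
        raise ValueError("inputs must have equal length")
    for v in (predicted, observed):
        if not np.isin(v, (0, 1)).all():
            raise ValueError("inputs must be binary 0/1")
    b = int(np.sum((predicted == 1) & (observed == 0)))
    c = int(np.sum((predicted == 0) & (observed == 1)))
    nd = b + c
    if nd == 0:
        p = 1.0
    else:
        p = min(1.0, 2.0 * float(stats.binom.cdf(min(b, c), nd, 0.5)))
        if b == c:
            p = 1.0
    return TestResult(name="McNemar exact", statistic=float(min(b, c)), p_value=p,
                      alpha=alpha, extra={"b": b, "c": c})


def mdgc_ranking(model: TrainedModel) -> pd.DataFrame:
    """Importance table sorted by MDGC (descending; ties alphabetical)."""
    return pd.DataFrame({"feature": model.importances.index,
                         "mdgc": model.importances.to_numpy()})
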