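"""Cohort preparation: median imputation, train/test split, feature screen.

The preparation pathway mirrors routine clinical-ML practice: numeric
gaps are filled with training-set medians (medians are computed on the
training cohort only and applied to both splits, so no information
leaks from test to train), the cohort is split 70/30 uniformly at
random, and each candidate predictor is screened for association with
the ventilation outcome — one-way ANOVA for the numeric vitals and
D-dimer, chi-square for sex and age band — at alpha = 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import AGE_LEVELS, FEATURES, SEX_LEVELS, Cohort

__all__ = ["SplitCohort", "FeatureScreenReport", "median_impute", "train_test_split", "screen_features"]

CATEGORICAL = {"sex": SEX_LEVELS, "age_group": AGE_LEVELS}


@dataclass
class SplitCohort:
    train: Cohort
    test: Cohort
    fraction: float
    seed: int

    def sizes(self) -> tuple[int, int]:
        return len(self.train), len(self.test)


def median_impute(train: Cohort, apply_to: Cohort | None = None) -> Cohort:
    """Fill missing numeric features with training-set medians.

    Medians come from ``train``'s observed values; they are substituted
    into ``apply_to`` (default: ``train`` itself). Observed values are
    never altered; categorical columns are left untouched.
    """
    if apply_to is None:
        apply_to = train
    medians = {}
    for feat in FEATURES:
        observed = train.df[feat].dropna()
        if len(observed) == 0:
            raise ValueError(f"feature {feat!r} has no observed values in the training set")
        medians[feat] = float(observed.median())
    out = apply_to.copy()
    for feat, med in medians.items():
        out.df[feat] = out.df[feat].fillna(med)
    return out


def train_test_split(cohort: Cohort, fraction: float = 0.7, seed: int = 0,
                     stratify: bool = False) -> SplitCohort:
    """Random partition with ``|train| = floor(fraction * n)``.

    With ``stratify`` the floor rule is applied within each outcome
    class instead (off by default).
    """
    n = len(cohort)
    if n == 0:
        raise ValueError("cannot split an empty cohort")
    if not (0.0 < fraction <= 1.0):
        raise ValueError(f"fraction {fraction} outside (0, 1]")
    rng = np.random.default_rng(seed)
    if stratify:
        train_idx: list[np.ndarray] = []
        for cls in cohort.df["outcome"].dropna().unique():
            cls_idx = np.flatnonzero((cohort.df["outcome"] == cls).to_numpy())
            k = int(np.floor(fraction * len(cls_idx)))
            train_idx.append(rng.permutation(cls_idx)[:k])
        mask = np.zeros(n, dtype=bool)
        mask[np.concatenate(train_idx)] = True
    else:
        k = int(np.floor(fraction * n))
        perm = rng.permutation(n)
        mask = np.zeros(n, dtype=bool)
        mask[perm[:k]] = True
    train = Cohort(cohort.df.loc[mask].reset_index(drop=True), seed=cohort.seed,
                   provenance=cohort.provenance)
    test = Cohort(cohort.df.loc[~mask].reset_index(drop=True), seed=cohort.seed,
                  provenance=cohort.provenance)
    return SplitCohort(train=train, test=test, fraction=fraction, seed=seed)


@dataclass
class FeatureScreenReport:
    """Per-feature association screen against the outcome."""

    table: pd.DataFrame  # columns: feature, test, statistic, p_value, significant
    alpha: float

    def significant_features(self) -> list[str]:
        return list(self.table.loc[self.table["significant"], "feature"])

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def screen_features(cohort: Cohort, alpha: float = 0.05) -> FeatureScreenReport:
    """Screen every candidate predictor for outcome association.

    Numeric features: one-way ANOVA of observed values across the two
    outcome classes. Categorical features: chi-square on the class x
    level contingency table. Flags are set at ``alpha``.
    """
    df = cohort.df
    classes = df["outcome"].dropna().unique()
    if len(classes) < 2:
        raise ValueError("feature screen requires both outcome classes")
    rows = []
    for col, levels in CATEGORICAL.items():
        table = np.array(
            [[int(((df["outcome"] == cls) & (df[col] == lev)).sum()) for lev in levels]
             for cls in sorted(classes)]
        )
        table = table[:, table.sum(axis=0) > 0]
        chi2, p, _, _ = stats.chi2_contingency(table)
        rows.append({"feature": col, "test": "chi-square", "statistic": float(chi2),
                     "p_value": float(p)})
    for feat in FEATURES:
        groups = [df.loc[df["outcome"] == cls, feat].dropna().to_numpy()
                  for cls in sorted(classes)]
        f, p = stats.f_oneway(*groups)
        rows.append({"feature": feat, "test": "anova", "statistic": float(f),
                     "p_value": float(p)})
    out = pd.DataFrame(rows)
    out["significant"] = out["p_value"] < alpha
    return FeatureScreenReport(table=out, alpha=alpha)
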