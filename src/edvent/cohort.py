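"""Synthetic ED patient cohorts with a ventilation-need outcome.

The generator realises a two-class population (ventilated vs not) whose
class-conditional structure is parameterised by a :class:`CohortSpec`:
categorical sex and a 3-level age band from per-class frequency tables,
and eleven numeric features — paired first/second records of systolic
and diastolic arterial pressure (SAP, DAP, mm Hg), core temperature
(CT, deg C), oxygen saturation (OSL, %), heart rate (HB, beats/min) —
plus a heavy-tailed D-dimer concentration (ng/ml). Each continuous
feature is specified by its class-conditional (median, variance):
vitals are truncated normals with centre = median and pre-truncation
variance as specified; D-dimer is log-normal with exp(mu) = median and
the specified variance, capturing its strongly right-skewed physiology.

Paired records (R1, R2) of the same vital are correlated draws
(Gaussian copula, default rho = 0.8) since repeated measurements on one
patient track each other.

The default spec encodes the case-study cohort of 1,049 respiratory
patients with ventilation prevalence 398/1,049.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ContinuousSpec",
    "CohortSpec",
    "Cohort",
    "ExclusionPolicy",
    "default_cohort_spec",
    "generate_cohort",
    "inject_missingness",
    "exclude_incomplete",
    "summarize_cohort",
    "FEATURES",
    "PAIRED_BASES",
    "AGE_LEVELS",
    "SEX_LEVELS",
]

PAIRED_BASES = ("SAP", "DAP", "CT", "OSL", "HB")
FEATURES = tuple(f"{b}_R{i}" for b in PAIRED_BASES for i in (1, 2)) + ("DDIMER",)
AGE_LEVELS = ("<=30", "30-60", ">60")
SEX_LEVELS = ("male", "female")
CSV_COLUMNS = ("id", "sex", "age_group") + FEATURES + ("outcome",)

VENT, NONVENT = 1, 0


@dataclass(frozen=True)
class ContinuousSpec:
    """Class-conditional parameters of one numeric feature.

    ``family`` is ``"truncnorm"`` (centre = median, pre-truncation
    variance as given, support clipped to ``bounds``) or ``"lognormal"``
    (exp(mu) = median, arithmetic variance as given).
    """

    median: float
    variance: float
    family: str = "truncnorm"
    bounds: tuple[float, float] = (-math.inf, math.inf)

    def __post_init__(self) -> None:
        if self.variance <= 0:
            raise ValueError(f"variance must be > 0, got {self.variance}")
        if self.bounds[0] >= self.bounds[1]:
            raise ValueError(f"bounds out of order: {self.bounds}")
        if self.family not in ("truncnorm", "lognormal"):
            raise ValueError(f"unknown family {self.family!r}")

    def lognormal_params(self) -> tuple[float, float]:
        """(mu, sigma) of the underlying normal for the log-normal family.

        Solves exp(mu) = median and Var = median^2 * e^{s^2}(e^{s^2}-1).
        """
        v = self.variance / self.median**2
        y = 0.5 * (1.0 + math.sqrt(1.0 + 4.0 * v))  # y = e^{sigma^2}
        return math.log(self.median), math.sqrt(math.log(y))

    def ppf(self, u: np.ndarray) -> np.ndarray:
        """Quantile transform used by the copula sampler."""
        if self.family == "lognormal":
            mu, sigma = self.lognormal_params()
            return np.exp(mu + sigma * stats.norm.ppf(u))
        sd = math.sqrt(self.variance)
        loc = _truncnorm_loc(self.median, sd, self.bounds)
        a = (self.bounds[0] - loc) / sd
        b = (self.bounds[1] - loc) / sd
        return stats.truncnorm.ppf(u, a, b, loc=loc, scale=sd)


from functools import lru_cache


@lru_cache(maxsize=256)
def _truncnorm_loc(target_median: float, sd: float, bounds: tuple[float, float]) -> float:
    """Location making the truncated normal's median equal the target.

    Asymmetric truncation shifts the median away from the location
    parameter; this solves for the location so the realised
    (post-truncation) median is exactly the printed one.
    """
    from scipy.optimize import brentq

    lo, hi = bounds
    if not (lo < target_median < hi):
        raise ValueError(f"median {target_median} outside bounds {bounds}")

    def med_err(loc: float) -> float:
        a, b = (lo - loc) / sd, (hi - loc) / sd
        return stats.truncnorm.median(a, b, loc=loc, scale=sd) - target_median

    span = 6.0 * sd
    return float(brentq(med_err, target_median - span, target_median + span, xtol=1e-10))


def _check_prob_table(name: str, table: dict[str, float]) -> None:
    for level, p in table.items():
        if not (0.0 <= p <= 1.0):
            raise ValueError(f"{name}[{level}] = {p} outside [0, 1]")
    if abs(sum(table.values()) - 1.0) > 1e-9:
        raise ValueError(f"{name} probabilities sum to {sum(table.values())}, not 1")


@dataclass(frozen=True)
class CohortSpec:
    """Full parameterisation of the synthetic population.

    ``sex`` and ``age_group`` map outcome class -> {level: probability};
    ``continuous`` maps feature name -> {class: ContinuousSpec};
    ``missing_rates`` maps feature name -> per-value missingness
    probability (applied by :func:`inject_missingness`).
    """

    prevalence: float
    sex: dict[int, dict[str, float]]
    age_group: dict[int, dict[str, float]]
    continuous: dict[str, dict[int, ContinuousSpec]]
    pair_correlation: float = 0.8
    missing_rates: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 < self.prevalence < 1.0):
            raise ValueError(f"prevalence {self.prevalence} outside (0, 1)")
        if not (-1.0 < self.pair_correlation < 1.0):
            raise ValueError("pair correlation must be in (-1, 1)")
        for cls in (VENT, NONVENT):
            _check_prob_table(f"sex[{cls}]", self.sex[cls])
            _check_prob_table(f"age_group[{cls}]", self.age_group[cls])
        for feat in FEATURES:
            if feat not in self.continuous:
                raise ValueError(f"continuous spec missing feature {feat}")
        for rate in self.missing_rates.values():
            if not (0.0 <= rate <= 1.0):
                raise ValueError(f"missing rate {rate} outside [0, 1]")


@dataclass
class Cohort:
    """An ordered collection of synthetic patient records.

    Backed by a DataFrame with columns ``id, sex, age_group,
    SAP_R1 ... DDIMER, outcome``; missing values are NaN (numeric) or
    NA (categorical / outcome).
    """

    df: pd.DataFrame
    seed: int | None = None
    provenance: str = "synthetic"

    def __post_init__(self) -> None:
        if list(self.df.columns) != list(CSV_COLUMNS):
            raise ValueError(f"cohort columns must be {CSV_COLUMNS}")
        if self.df["id"].duplicated().any():
            raise ValueError("duplicate patient ids")

    def __len__(self) -> int:
        return len(self.df)

    def copy(self) -> "Cohort":
        return Cohort(self.df.copy(), seed=self.seed, provenance=self.provenance)

    def to_csv(self, path: str | Path) -> None:
        self.df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, provenance: str = "file") -> "Cohort":
        df = pd.read_csv(path, dtype={"sex": "string", "age_group": "string"})
        df["outcome"] = df["outcome"].astype("Int64")
        return cls(df[list(CSV_COLUMNS)], provenance=provenance)


# Class-conditional frequency tables of the default population
# (counts: ventilated n=398, non-ventilated n=651).
_SEX_COUNTS = {VENT: {"male": 292, "female": 106}, NONVENT: {"male": 373, "female": 278}}
_AGE_COUNTS = {VENT: {"<=30": 14, "30-60": 96, ">60": 288},
               NONVENT: {"<=30": 17, "30-60": 200, ">60": 434}}

# (ventilated median, ventilated variance, non-vent median, non-vent variance)
_VITALS = {
    "SAP_R1": (130.00, 234.85, 133.00, 353.26),
    "SAP_R2": (131.00, 270.57, 133.00, 358.14),
    "DAP_R1": (76.00, 90.252, 76.00, 886.70),
    "DAP_R2": (76.00, 116.087, 77.00, 705.28),
    "CT_R1": (36.7, 0.527, 36.5, 0.466),
    "CT_R2": (36.7, 0.571, 36.5, 4.698),
    "OSL_R1": (92.00, 73.664, 95.00, 29.791),
    "OSL_R2": (92.00, 92.224, 95.00, 29.413),
    "HB_R1": (91.00, 205.155, 88.00, 211.362),
    "HB_R2": (91.00, 235.223, 88.00, 214.949),
}
_DDIMER = (1334.0, 54_071_055.0, 745.0, 13_318_254.0)

# Physiologically plausible truncation bounds per vital base.
_BOUNDS = {"SAP": (60.0, 260.0), "DAP": (30.0, 160.0), "CT": (34.0, 42.0),
           "OSL": (50.0, 100.0), "HB": (30.0, 220.0)}


def default_cohort_spec() -> CohortSpec:
    """Spec encoding the case-study population (prevalence 398/1,049)."""

    def norm(counts: dict[str, int]) -> dict[str, float]:
        tot = sum(counts.values())
        return {k: v / tot for k, v in counts.items()}

    continuous: dict[str, dict[int, ContinuousSpec]] = {}
    for feat, (mv, vv, mn, vn) in _VITALS.items():
        bounds = _BOUNDS[feat.split("_")[0]]
        continuous[feat] = {
            VENT: ContinuousSpec(mv, vv, "truncnorm", bounds),
            NONVENT: ContinuousSpec(mn, vn, "truncnorm", bounds),
        }
    mv, vv, mn, vn = _DDIMER
    continuous["DDIMER"] = {
        VENT: ContinuousSpec(mv, vv, "lognormal", (0.0, math.inf)),
        NONVENT: ContinuousSpec(mn, vn, "lognormal", (0.0, math.inf)),
    }
    return CohortSpec(
        prevalence=398.0 / 1049.0,
        sex={c: norm(t) for c, t in _SEX_COUNTS.items()},
        age_group={c: norm(t) for c, t in _AGE_COUNTS.items()},
        continuous=continuous,
    )


def generate_cohort(spec: CohortSpec, n: int, seed: int) -> Cohort:
    """Draw ``n`` synthetic patients from ``spec``; reproducible in ``seed``."""
    if n < 0:
        raise ValueError("n must be >= 0")
    rng = np.random.default_rng(seed)
    outcome = (rng.random(n) < spec.prevalence).astype(int)

    sex = np.empty(n, dtype=object)
    age = np.empty(n, dtype=object)
    values = {feat: np.empty(n, dtype=float) for feat in FEATURES}
    rho = spec.pair_correlation

    for cls in (VENT, NONVENT):
        idx = np.flatnonzero(outcome == cls)
        m = len(idx)
        sex_tab = spec.sex[cls]
        age_tab = spec.age_group[cls]
        sex[idx] = rng.choice(SEX_LEVELS, size=m, p=[sex_tab[s] for s in SEX_LEVELS])
        age[idx] = rng.choice(AGE_LEVELS, size=m, p=[age_tab[a] for a in AGE_LEVELS])
        for base in PAIRED_BASES:
            z1 = rng.standard_normal(m)
            z2 = rho * z1 + math.sqrt(1.0 - rho**2) * rng.standard_normal(m)
            values[f"{base}_R1"][idx] = spec.continuous[f"{base}_R1"][cls].ppf(stats.norm.cdf(z1))
            values[f"{base}_R2"][idx] = spec.continuous[f"{base}_R2"][cls].ppf(stats.norm.cdf(z2))
        z = rng.standard_normal(m)
        values["DDIMER"][idx] = spec.continuous["DDIMER"][cls].ppf(stats.norm.cdf(z))

    df = pd.DataFrame({"id": np.arange(n)})
    df["sex"] = pd.array(sex, dtype="string") if n else pd.array([], dtype="string")
    df["age_group"] = pd.array(age, dtype="string") if n else pd.array([], dtype="string")
    for feat in FEATURES:
        df[feat] = values[feat]
    df["outcome"] = pd.array(outcome, dtype="Int64")
    return Cohort(df, seed=seed)


def inject_missingness(
    cohort: Cohort,
    rates: dict[str, float],
    seed: int,
    allow_outcome: bool = False,
) -> Cohort:
    """Independently blank each feature value with its per-feature rate.

    The outcome column is only eligible when ``allow_outcome`` is set
    and a rate is given for ``"outcome"``.
    """
    out = cohort.copy()
    rng = np.random.default_rng(seed)
    n = len(out)
    for col, rate in rates.items():
        if not (0.0 <= rate <= 1.0):
            raise ValueError(f"rate for {col} outside [0, 1]: {rate}")
        if col == "outcome" and not allow_outcome:
            raise ValueError("outcome missingness requires allow_outcome=True")
        if col not in out.df.columns or col == "id":
            raise ValueError(f"unknown feature {col!r}")
        mask = rng.random(n) < rate
        if col in ("sex", "age_group"):
            out.df.loc[mask, col] = pd.NA
        elif col == "outcome":
            out.df.loc[mask, col] = pd.NA
        else:
            out.df.loc[mask, col] = np.nan
    return out


@dataclass(frozen=True)
class ExclusionPolicy:
    """Rule deciding which incomplete records are dropped.

    A record is excluded if its outcome is missing (when
    ``require_outcome``) or if more than ``max_missing_predictors`` of
    the 13 predictors (sex, age band and the 11 numerics) are missing.
    """

    require_outcome: bool = True
    max_missing_predictors: int = 10


def exclude_incomplete(
    cohort: Cohort, policy: ExclusionPolicy | None = None
) -> tuple[Cohort, int]:
    """Apply ``policy``; returns (retained cohort, number excluded)."""
    policy = policy or ExclusionPolicy()
    df = cohort.df
    n_missing = df[list(FEATURES)].isna().sum(axis=1)
    n_missing = n_missing + df["sex"].isna().astype(int) + df["age_group"].isna().astype(int)
    drop = n_missing > policy.max_missing_predictors
    if policy.require_outcome:
        drop = drop | df["outcome"].isna()
    retained = Cohort(
        df.loc[~drop].reset_index(drop=True),
        seed=cohort.seed,
        provenance=cohort.provenance,
    )
    return retained, int(drop.sum())


def summarize_cohort(cohort: Cohort) -> pd.DataFrame:
    """Per-class frequency (proportion) and median (variance) table.

    One row per categorical level and per numeric feature, with
    within-class proportions for categorical levels and sample
    median/variance (ddof=1) for numerics, computed on observed values.
    """
    df = cohort.df
    if len(df) == 0:
        raise ValueError("cannot summarise an empty cohort")
    if df["outcome"].isna().all():
        raise ValueError("cohort has no observed outcomes")
    rows = []
    classes = {"ventilated": VENT, "non_ventilated": NONVENT}
    for col, levels in (("sex", SEX_LEVELS), ("age_group", AGE_LEVELS)):
        for level in levels:
            row: dict = {"feature": col, "level": level, "kind": "categorical"}
            for label, cls in classes.items():
                sub = df.loc[df["outcome"] == cls, col].dropna()
                count = int((sub == level).sum())
                row[f"{label}_count"] = count
                row[f"{label}_value"] = count / len(sub) if len(sub) else math.nan
            rows.append(row)
    for feat in FEATURES:
        row = {"feature": feat, "level": "", "kind": "numeric"}
        for label, cls in classes.items():
            sub = df.loc[df["outcome"] == cls, feat].dropna()
            row[f"{label}_count"] = int(len(sub))
            row[f"{label}_value"] = float(sub.median()) if len(sub) else math.nan
            row[f"{label}_var"] = float(sub.var(ddof=1)) if len(sub) > 1 else math.nan
        rows.append(row)
    return pd.DataFrame(rows)
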