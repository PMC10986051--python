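"""Probability expressions for the ED process variables.

The four stochastic inputs of the ED pathway — time between admissions
(TBA, per weekday x 8-hour time slot), triage time (TT), ED length of
stay (ED-LoS, by severity group) and mechanical ventilation duration
(MVD) — are each described by a fitted parametric expression in one of
four families: uniform, exponential, log-normal and Weibull.

Parameter conventions follow commercial simulation-package usage, under
which the fitted expressions were originally reported:

* ``UNIF(a, b)`` — lower and upper bound;
* ``EXPO(m)`` — mean;
* ``LOGN(m, s)`` — arithmetic mean and standard deviation of the
  log-normal variate itself (the underlying normal has
  ``mu = ln(m^2 / sqrt(m^2 + s^2))`` and ``sigma^2 = ln(1 + s^2/m^2)``);
* ``WEIB(beta, alpha)`` — scale, shape.

Units are carried on the spec (``days`` or ``min``); the simulation
clock runs in minutes and conversion happens at this boundary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "DistributionSpec",
    "ArrivalSchedule",
    "FittedVariableSet",
    "make_table2_defaults",
    "sample",
    "dist_mean",
    "dist_var",
    "WEEKDAYS",
    "SLOTS",
    "MINUTES_PER_DAY",
]

WEEKDAYS = ("monday", "tuesday", "wednesday", "thursday", "friday", "saturday", "sunday")
#: Time slots: TS1 00:00-08:00, TS2 08:00-16:00, TS3 16:00-00:00.
SLOTS = ("TS1", "TS2", "TS3")
MINUTES_PER_DAY = 1440.0

_FAMILIES = {"UNIF", "EXPO", "LOGN", "WEIB"}


@dataclass(frozen=True)
class DistributionSpec:
    """A single fitted probability expression.

    Parameters
    ----------
    family : {"UNIF", "EXPO", "LOGN", "WEIB"}
    params : tuple of float
        Family-specific parameters in the conventions above.
    unit : {"days", "min"}
    """

    family: str
    params: tuple[float, ...]
    unit: str = "min"

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ValueError(f"unknown distribution family {self.family!r}")
        if self.unit not in ("days", "min"):
            raise ValueError(f"unknown unit {self.unit!r}")
        object.__setattr__(self, "params", tuple(float(p) for p in self.params))
        p = self.params
        if self.family == "UNIF":
            if len(p) != 2 or p[0] > p[1]:
                raise ValueError(f"UNIF requires a <= b, got {p}")
        elif self.family == "EXPO":
            if len(p) != 1 or p[0] <= 0:
                raise ValueError(f"EXPO requires mean > 0, got {p}")
        elif self.family == "LOGN":
            if len(p) != 2 or p[0] <= 0 or p[1] <= 0:
                raise ValueError(f"LOGN requires mean > 0 and sd > 0, got {p}")
        elif self.family == "WEIB":
            if len(p) != 2 or p[0] <= 0 or p[1] <= 0:
                raise ValueError(f"WEIB requires scale > 0 and shape > 0, got {p}")

    # -- log-normal mean/sd -> underlying normal (mu, sigma) ---------------
    def _logn_musigma(self) -> tuple[float, float]:
        m, s = self.params
        sigma2 = math.log1p((s / m) ** 2)
        mu = math.log(m) - 0.5 * sigma2
        return mu, math.sqrt(sigma2)

    def scipy_dist(self):
        """Frozen :mod:`scipy.stats` distribution in the spec's own unit."""
        p = self.params
        if self.family == "UNIF":
            return stats.uniform(loc=p[0], scale=p[1] - p[0])
        if self.family == "EXPO":
            return stats.expon(scale=p[0])
        if self.family == "LOGN":
            mu, sigma = self._logn_musigma()
            return stats.lognorm(s=sigma, scale=math.exp(mu))
        mu_scale, shape = p  # WEIB
        return stats.weibull_min(c=shape, scale=mu_scale)

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw ``n`` iid values in the spec's own unit (fast numpy path)."""
        p = self.params
        if self.family == "UNIF":
            return rng.uniform(p[0], p[1], size=n)
        if self.family == "EXPO":
            return rng.exponential(p[0], size=n)
        if self.family == "LOGN":
            mu, sigma = self._logn_musigma()
            return rng.lognormal(mu, sigma, size=n)
        scale, shape = p
        return scale * rng.weibull(shape, size=n)

    def sample_minutes(self, rng: np.random.Generator) -> float:
        """One draw converted to simulation-clock minutes."""
        x = float(self.sample(1, rng)[0])
        return x * MINUTES_PER_DAY if self.unit == "days" else x

    def mean(self) -> float:
        """Analytic mean in the spec's own unit."""
        p = self.params
        if self.family == "UNIF":
            return 0.5 * (p[0] + p[1])
        if self.family == "EXPO":
            return p[0]
        if self.family == "LOGN":
            return p[0]
        scale, shape = p
        return scale * math.gamma(1.0 + 1.0 / shape)

    def var(self) -> float:
        """Analytic variance in the spec's own unit."""
        p = self.params
        if self.family == "UNIF":
            return (p[1] - p[0]) ** 2 / 12.0
        if self.family == "EXPO":
            return p[0] ** 2
        if self.family == "LOGN":
            return p[1] ** 2
        scale, shape = p
        g1 = math.gamma(1.0 + 1.0 / shape)
        g2 = math.gamma(1.0 + 2.0 / shape)
        return scale**2 * (g2 - g1**2)

    def mean_minutes(self) -> float:
        m = self.mean()
        return m * MINUTES_PER_DAY if self.unit == "days" else m

    # -- serialization ------------------------------------------------------
    def to_dict(self) -> dict:
        return {"family": self.family, "params": list(self.params), "unit": self.unit}

    @classmethod
    def from_dict(cls, d: dict) -> "DistributionSpec":
        return cls(family=d["family"], params=tuple(d["params"]), unit=d.get("unit", "min"))


def sample(spec: DistributionSpec, n: int, rng: np.random.Generator) -> np.ndarray:
    """Module-level alias for :meth:`DistributionSpec.sample`."""
    return spec.sample(n, rng)


def dist_mean(spec: DistributionSpec) -> float:
    """Analytic mean of ``spec`` in its own unit."""
    return spec.mean()


def dist_var(spec: DistributionSpec) -> float:
    return spec.var()


@dataclass
class ArrivalSchedule:
    """Weekday x time-slot grid of time-between-admission expressions.

    Exactly 21 cells (7 weekdays x 3 slots), each an interarrival-time
    spec in days. ``spec_at(t_minutes)`` resolves the cell containing a
    simulation-clock instant, with the clock starting Monday 00:00.
    """

    cells: dict[tuple[str, str], DistributionSpec] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.cells:
            self.validate()

    def validate(self) -> None:
        expected = {(d, s) for d in WEEKDAYS for s in SLOTS}
        if set(self.cells) != expected:
            missing = expected - set(self.cells)
            extra = set(self.cells) - expected
            raise ValueError(f"arrival schedule must have 21 cells; missing={missing}, extra={extra}")

    def spec_at(self, t_minutes: float) -> DistributionSpec:
        t_days = t_minutes / MINUTES_PER_DAY
        weekday = WEEKDAYS[int(t_days) % 7]
        slot = SLOTS[min(int((t_days % 1.0) * 3.0), 2)]
        return self.cells[(weekday, slot)]

    def mean_arrivals_per_day(self) -> float:
        """Time-averaged arrival rate implied by the grid (1/day).

        Each 8-hour cell contributes ``(1/3)/mean_TBA`` arrivals; the
        weekly total is averaged over 7 days.
        """
        total = sum((1.0 / 3.0) / spec.mean() for spec in self.cells.values())
        return total / 7.0

    def to_records(self) -> list[dict]:
        out = []
        for day in WEEKDAYS:
            for slot in SLOTS:
                spec = self.cells[(day, slot)]
                p = list(spec.params) + [math.nan] * (2 - len(spec.params))
                out.append(
                    {"weekday": day, "slot": slot, "family": spec.family,
                     "p1": p[0], "p2": p[1], "unit": spec.unit}
                )
        return out

    @classmethod
    def from_records(cls, records: list[dict]) -> "ArrivalSchedule":
        cells = {}
        for r in records:
            params = [r["p1"]] if r["family"] == "EXPO" else [r["p1"], r["p2"]]
            cells[(r["weekday"], r["slot"])] = DistributionSpec(
                family=r["family"], params=tuple(params), unit=r["unit"]
            )
        return cls(cells=cells)


@dataclass
class FittedVariableSet:
    """The full set of fitted process-variable expressions."""

    arrivals: ArrivalSchedule
    triage_time: DistributionSpec
    ed_los_severe: DistributionSpec  # triage groups I-II
    ed_los_mild: DistributionSpec  # triage groups III-V
    mv_duration: DistributionSpec

    def to_dict(self) -> dict:
        return {
            "arrivals": self.arrivals.to_records(),
            "triage_time": self.triage_time.to_dict(),
            "ed_los_severe": self.ed_los_severe.to_dict(),
            "ed_los_mild": self.ed_los_mild.to_dict(),
            "mv_duration": self.mv_duration.to_dict(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FittedVariableSet":
        return cls(
            arrivals=ArrivalSchedule.from_records(d["arrivals"]),
            triage_time=DistributionSpec.from_dict(d["triage_time"]),
            ed_los_severe=DistributionSpec.from_dict(d["ed_los_severe"]),
            ed_los_mild=DistributionSpec.from_dict(d["ed_los_mild"]),
            mv_duration=DistributionSpec.from_dict(d["mv_duration"]),
        )


# Fitted TBA expressions, one per weekday x slot, interarrival times in days.
_TBA_TABLE: dict[tuple[str, str], tuple[str, tuple[float, ...]]] = {
    ("monday", "TS1"): ("LOGN", (0.06, 0.15)),
    ("monday", "TS2"): ("LOGN", (0.02, 0.04)),
    ("monday", "TS3"): ("LOGN", (0.01, 0.02)),
    ("tuesday", "TS1"): ("LOGN", (0.09, 0.21)),
    ("tuesday", "TS2"): ("LOGN", (0.02, 0.04)),
    ("tuesday", "TS3"): ("LOGN", (0.01, 0.02)),
    ("wednesday", "TS1"): ("LOGN", (0.14, 0.72)),
    ("wednesday", "TS2"): ("LOGN", (0.02, 0.05)),
    ("wednesday", "TS3"): ("LOGN", (0.01, 0.02)),
    ("thursday", "TS1"): ("EXPO", (0.06,)),
    ("thursday", "TS2"): ("LOGN", (0.03, 0.06)),
    ("thursday", "TS3"): ("LOGN", (0.01, 0.02)),
    ("friday", "TS1"): ("WEIB", (0.05, 0.69)),
    ("friday", "TS2"): ("LOGN", (0.02, 0.05)),
    ("friday", "TS3"): ("LOGN", (0.01, 0.02)),
    ("saturday", "TS1"): ("WEIB", (0.04, 0.89)),
    ("saturday", "TS2"): ("LOGN", (0.03, 0.06)),
    ("saturday", "TS3"): ("LOGN", (0.02, 0.03)),
    ("sunday", "TS1"): ("LOGN", (0.05, 0.18)),
    ("sunday", "TS2"): ("LOGN", (0.03, 0.05)),
    ("sunday", "TS3"): ("LOGN", (0.02, 0.02)),
}


def make_table2_defaults() -> FittedVariableSet:
    """The fitted process-variable expressions of the case-study ED.

    TBA cells are interarrival times in days; triage time and ED-LoS are
    in minutes; mechanical-ventilation duration is in days.
    """
    cells = {
        key: DistributionSpec(family=fam, params=params, unit="days")
        for key, (fam, params) in _TBA_TABLE.items()
    }
    return FittedVariableSet(
        arrivals=ArrivalSchedule(cells=cells),
        triage_time=DistributionSpec("UNIF", (10.0, 15.0), "min"),
        ed_los_severe=DistributionSpec("UNIF", (42.5, 62.5), "min"),
        ed_los_mild=DistributionSpec("UNIF", (32.5, 52.5), "min"),
        mv_duration=DistributionSpec("UNIF", (7.1, 13.2), "days"),
    )
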