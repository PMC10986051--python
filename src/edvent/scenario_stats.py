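"""Model validation and capacity-strategy comparison statistics.

The simulated ED is validated against the observed waiting-time median
with a one-sample sign test; capacity strategies are compared to the
baseline with two-sided Mann-Whitney tests on per-replication median
waiting times, a Hodges-Lehmann shift estimate with confidence
interval, and an improvement percentage on pooled medians (negative =
improvement). The unprinted baseline ventilator fleet is pinned down by
grid-search calibration against the observed median.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .des import EDConfig, ExperimentResult, ScenarioSpec, offered_load, run_experiment
from .input_checks import TestResult

__all__ = [
    "CalibrationResult",
    "sign_test",
    "mann_whitney",
    "hodges_lehmann_ci",
    "calibrate_fleet",
    "replications_needed",
    "compare_scenarios",
    "default_fleet_grid",
]


def sign_test(sample: np.ndarray, eta0: float, alpha: float = 0.05) -> TestResult:
    """Exact two-sided one-sample sign test of median = ``eta0``.

    Values equal to ``eta0`` are dropped; the count above ``eta0`` is
    referred to Binomial(n, 1/2). All values equal to ``eta0`` gives
    p = 1 by convention.
    """
    sample = np.asarray(sample, dtype=float)
    if sample.size == 0:
        raise ValueError("empty sample")
    above = int(np.sum(sample > eta0))
    below = int(np.sum(sample < eta0))
    n = above + below
    if n == 0:
        return TestResult(name="sign test", statistic=0.0, p_value=1.0, alpha=alpha,
                          extra={"above": 0, "below": 0})
    k = min(above, below)
    p = min(1.0, 2.0 * float(stats.binom.cdf(k, n, 0.5)))
    return TestResult(name="sign test", statistic=float(above), p_value=p, alpha=alpha,
                      extra={"above": above, "below": below, "eta0": eta0})


def mann_whitney(x: np.ndarray, y: np.ndarray, alpha: float = 0.05) -> TestResult:
    """Two-sided Mann-Whitney test of stochastic equality.

    Exact null enumeration when min(n) <= 8 with no ties; otherwise the
    normal approximation with tie and continuity corrections. Reports U
    for the first sample and the rank-sum W = U + n1(n1+1)/2.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    has_ties = len(np.unique(np.concatenate([x, y]))) < x.size + y.size
    method = "exact" if (min(x.size, y.size) <= 8 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method,
                             use_continuity=True)
    u = float(res.statistic)
    w = u + x.size * (x.size + 1) / 2.0
    return TestResult(name="Mann-Whitney", statistic=u, p_value=float(res.pvalue),
                      alpha=alpha, extra={"U": u, "W": w, "method": method})


def _u_critical_index(n1: int, n2: int, level: float) -> int:
    """Lower critical value k of U at two-sided ``level`` (normal approx).

    The HL confidence interval is [D_(k+1), D_(n1*n2-k)] over the
    ordered pairwise differences.
    """
    z = stats.norm.ppf(0.5 + level / 2.0)
    mu = n1 * n2 / 2.0
    sd = math.sqrt(n1 * n2 * (n1 + n2 + 1) / 12.0)
    k = int(math.floor(mu - z * sd - 0.5))
    return max(k, 0)


def hodges_lehmann_ci(
    x: np.ndarray, y: np.ndarray, level: float = 0.95
) -> tuple[float, tuple[float, float]]:
    """Hodges-Lehmann shift estimate of x - y with a distribution-free CI.

    The estimate is the median of all pairwise differences x_i - y_j;
    the interval takes the order statistics of those differences at the
    Mann-Whitney critical indices.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    diffs = np.sort((x[:, None] - y[None, :]).ravel())
    est = float(np.median(diffs))
    k = _u_critical_index(x.size, y.size, level)
    lo = float(diffs[min(k, diffs.size - 1)])
    hi = float(diffs[max(diffs.size - 1 - k, 0)])
    return est, (min(lo, est), max(hi, est))


def replications_needed(h0: float, n0: int, h: float) -> int:
    """Sequential half-width rule: ceil(n0 * (h0/h)^2), floored at n0."""
    if h0 <= 0 or h <= 0:
        raise ValueError("half-widths must be positive")
    if h >= h0:
        return n0
    return int(math.ceil(n0 * (h0 / h) ** 2))


@dataclass
class CalibrationResult:
    grid: list[int]
    medians: list[float]
    selected_fleet: int
    achieved_median: float
    target_median: float
    unstable_fleets: list[int]

    def to_records(self) -> list[dict]:
        return [
            {"fleet": f, "pooled_median_mvwt": m, "selected": f == self.selected_fleet}
            for f, m in zip(self.grid, self.medians)
        ]


def default_fleet_grid(config: EDConfig, span: float = 0.10, n_points: int = 20) -> list[int]:
    """Integer fleet grid spanning +/-``span`` around the offered load."""
    load = offered_load(config)
    lo = int(math.floor(load * (1.0 - span)))
    hi = int(math.ceil(load * (1.0 + span)))
    grid = np.unique(np.round(np.linspace(lo, hi, n_points)).astype(int))
    return [int(g) for g in grid if g >= 1]


def calibrate_fleet(
    config: EDConfig,
    target_median: float,
    grid: list[int] | None = None,
    n_reps: int = 29,
    master_seed: int = 0,
    scenario: ScenarioSpec = ScenarioSpec(),
) -> CalibrationResult:
    """Grid-search the integer fleet against the observed waiting median.

    Each candidate runs ``n_reps`` replications with common random
    numbers; the fleet minimising |pooled median MVWT - target| wins,
    ties to the smaller fleet. Candidates whose queues fail to clear
    (infinite waits) are flagged and never selected unless no stable
    candidate exists.
    """
    if grid is None:
        grid = default_fleet_grid(config)
    if not grid or any(g < 1 for g in grid):
        raise ValueError("grid must be non-empty positive integers")
    from dataclasses import replace

    medians: list[float] = []
    unstable: list[int] = []
    for fleet in sorted(grid):
        res = run_experiment(replace(config, n_local_vents=fleet), scenario,
                             n_reps=n_reps, master_seed=master_seed)
        medians.append(res.pooled_median)
        if res.unstable:
            unstable.append(fleet)
    grid_sorted = sorted(grid)
    losses = [
        math.inf if (not math.isfinite(m) or f in unstable) else abs(m - target_median)
        for f, m in zip(grid_sorted, medians)
    ]
    if all(math.isinf(loss) for loss in losses):
        raise RuntimeError("no stable fleet candidate in the calibration grid")
    best_ix = int(np.argmin(losses))  # argmin takes the first (smallest fleet) on ties
    return CalibrationResult(
        grid=grid_sorted,
        medians=medians,
        selected_fleet=grid_sorted[best_ix],
        achieved_median=medians[best_ix],
        target_median=target_median,
        unstable_fleets=unstable,
    )


def compare_scenarios(
    config: EDConfig,
    scenarios: list[ScenarioSpec],
    n_reps: int = 29,
    master_seed: int = 0,
    alpha: float = 0.05,
    level: float = 0.95,
) -> dict:
    """Baseline-vs-strategy comparison report.

    Runs every scenario with common random numbers; for each
    non-baseline scenario reports a Mann-Whitney test on
    per-replication median MVWTs, the Hodges-Lehmann shift
    (scenario - baseline) with CI, and the improvement percentage on
    pooled medians (negative = waiting time reduced).
    """
    kinds = [s.kind for s in scenarios]
    if "baseline" not in kinds:
        raise ValueError("scenario list must include the baseline")
    results: dict[str, ExperimentResult] = {}
    for s in scenarios:
        results[s.kind] = run_experiment(config, s, n_reps=n_reps, master_seed=master_seed)
    base = results["baseline"]
    report: dict = {
        "baseline": base.summary(),
        "n_replications": n_reps,
        "alpha": alpha,
        "comparisons": [],
    }
    for s in scenarios:
        if s.kind == "baseline":
            continue
        res = results[s.kind]
        mw = mann_whitney(res.rep_medians, base.rep_medians, alpha=alpha)
        hl, ci = hodges_lehmann_ci(res.rep_medians, base.rep_medians, level=level)
        improvement = (res.pooled_median - base.pooled_median) / base.pooled_median * 100.0
        report["comparisons"].append(
            {
                "scenario": s.kind,
                **{k: v for k, v in res.summary().items() if k != "scenario"},
                "mann_whitney_U": mw.extra["U"],
                "mann_whitney_W": mw.extra["W"],
                "p_value": mw.p_value,
                "significant": mw.reject,
                "hl_shift": hl,
                "hl_ci_low": ci[0],
                "hl_ci_high": ci[1],
                "improvement_pct": improvement,
            }
        )
    report["experiments"] = results
    return report
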