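"""Input-data analysis: randomness, homogeneity and goodness-of-fit.

Before a fitted probability expression is trusted inside the simulation,
the underlying data stream is checked for randomness (Wald-Wolfowitz
runs test about the median), homogeneity across candidate strata
(Kruskal-Wallis), and distributional fit (Pearson chi-square against
the candidate expression).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .distributions import DistributionSpec

__all__ = ["TestResult", "chisq_gof", "runs_test", "kruskal_test"]


@dataclass(frozen=True)
class TestResult:
    """Outcome of a hypothesis test.

    ``reject`` is evaluated at ``alpha`` (default 0.05); ``ci`` is an
    optional (low, high) interval at ``ci_level``.
    """

    name: str
    statistic: float
    p_value: float
    alpha: float = 0.05
    ci: tuple[float, float] | None = None
    ci_level: float | None = None
    extra: dict | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 + 1e-12):
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")
        if self.ci is not None and self.ci[0] > self.ci[1]:
            raise ValueError(f"CI bounds out of order: {self.ci}")

    @property
    def reject(self) -> bool:
        return self.p_value < self.alpha

    def to_dict(self) -> dict:
        d = {
            "name": self.name,
            "statistic": float(self.statistic),
            "p_value": float(self.p_value),
            "alpha": self.alpha,
            "reject": self.reject,
        }
        if self.ci is not None:
            d["ci"] = [float(self.ci[0]), float(self.ci[1])]
            d["ci_level"] = self.ci_level
        if self.extra:
            d.update({k: (float(v) if np.isscalar(v) else v) for k, v in self.extra.items()})
        return d


def chisq_gof(
    data: np.ndarray,
    spec: DistributionSpec,
    n_bins: int = 10,
    n_fitted_params: int | None = None,
    alpha: float = 0.05,
) -> TestResult:
    """Pearson chi-square goodness of fit of ``data`` against ``spec``.

    Bins are equal-probability under the candidate distribution (edges
    from its quantile function); bins with expected count below 5 are
    merged with their right neighbour (the last bin merges leftward).
    Degrees of freedom are ``bins - 1 - n_fitted_params``, with the
    fitted-parameter count defaulting to the family's parameter count.

    Raises
    ------
    ValueError
        If fewer than 25 observations, or fewer than 3 bins survive
        merging.
    """
    data = np.asarray(data, dtype=float)
    if data.size < 25:
        raise ValueError(f"need at least 25 observations, got {data.size}")
    if n_fitted_params is None:
        n_fitted_params = len(spec.params)

    dist = spec.scipy_dist()
    qs = np.linspace(0.0, 1.0, n_bins + 1)
    edges = dist.ppf(qs)
    edges[0], edges[-1] = -np.inf, np.inf
    # duplicate edges can arise for degenerate specs
    edges = np.unique(edges)
    if len(edges) < 4:
        raise ValueError("candidate distribution too degenerate to bin")

    observed = np.histogram(data, bins=edges)[0].astype(float)
    probs = np.diff(dist.cdf(edges))
    expected = probs * data.size

    obs_m, exp_m = _merge_small_bins(observed, expected, min_expected=5.0)
    if len(obs_m) < 3:
        raise ValueError(f"only {len(obs_m)} bins after merging; need >= 3")

    # renormalize tiny probability leakage so the statistic is exact
    exp_m = exp_m * (data.size / exp_m.sum())
    statistic = float(np.sum((obs_m - exp_m) ** 2 / exp_m))
    df = len(obs_m) - 1 - n_fitted_params
    if df < 1:
        df = 1
    p = float(stats.chi2.sf(statistic, df))
    return TestResult(
        name="chi-square goodness of fit",
        statistic=statistic,
        p_value=p,
        alpha=alpha,
        extra={"df": df, "n_bins": len(obs_m)},
    )


def _merge_small_bins(
    observed: np.ndarray, expected: np.ndarray, min_expected: float
) -> tuple[np.ndarray, np.ndarray]:
    obs: list[float] = []
    exp: list[float] = []
    acc_o = acc_e = 0.0
    for o, e in zip(observed, expected):
        acc_o += o
        acc_e += e
        if acc_e >= min_expected:
            obs.append(acc_o)
            exp.append(acc_e)
            acc_o = acc_e = 0.0
    if acc_e > 0:
        if obs:
            obs[-1] += acc_o
            exp[-1] += acc_e
        else:
            obs.append(acc_o)
            exp.append(acc_e)
    return np.asarray(obs), np.asarray(exp)


def runs_test(data: np.ndarray, alpha: float = 0.05) -> TestResult:
    """Wald-Wolfowitz runs test for randomness about the sample median.

    Values equal to the median are dropped; the remaining sequence is
    coded above/below and the number of runs compared to its null
    moments via a normal approximation with continuity correction.
    """
    data = np.asarray(data, dtype=float)
    if data.size < 10:
        raise ValueError(f"need at least 10 observations, got {data.size}")
    med = np.median(data)
    signs = np.sign(data - med)
    signs = signs[signs != 0]
    n_pos = int(np.sum(signs > 0))
    n_neg = int(np.sum(signs < 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("all retained values on one side of the median")

    runs = 1 + int(np.sum(signs[1:] != signs[:-1]))
    n = n_pos + n_neg
    mu = 2.0 * n_pos * n_neg / n + 1.0
    var = 2.0 * n_pos * n_neg * (2.0 * n_pos * n_neg - n) / (n**2 * (n - 1.0))
    if var <= 0:
        raise ValueError("degenerate runs variance")
    diff = runs - mu
    # continuity correction toward the mean
    z = (abs(diff) - 0.5) / np.sqrt(var)
    z = max(z, 0.0)
    p = float(2.0 * stats.norm.sf(z))
    p = min(p, 1.0)
    return TestResult(
        name="runs test",
        statistic=float(np.sign(diff) * z) if diff != 0 else 0.0,
        p_value=p,
        alpha=alpha,
        extra={"runs": runs, "expected_runs": mu},
    )


def kruskal_test(groups: list[np.ndarray], alpha: float = 0.05) -> TestResult:
    """Kruskal-Wallis homogeneity test across ``groups`` (tie-corrected)."""
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    for i, g in enumerate(groups):
        if len(np.asarray(g)) == 0:
            raise ValueError(f"group {i} is empty")
    h, p = stats.kruskal(*[np.asarray(g, dtype=float) for g in groups])
    return TestResult(
        name="Kruskal-Wallis",
        statistic=float(h),
        p_value=float(p),
        alpha=alpha,
        extra={"df": len(groups) - 1},
    )
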