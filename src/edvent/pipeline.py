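"""End-to-end study pipeline: generate -> preprocess -> train -> evaluate
-> calibrate -> simulate -> compare.

A single :class:`PipelineConfig` (YAML/JSON) drives the whole study;
every stage draws its randomness from a named substream of one master
seed, so a (config, seed) pair reproduces the full report bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .classifier import (
    ClassifierConfig,
    compute_metrics,
    confusion_at_threshold,
    mcnemar_test,
    predict_prob,
    roc_auc_ci,
    train_tune,
)
from .cohort import (
    Cohort,
    default_cohort_spec,
    exclude_incomplete,
    generate_cohort,
    inject_missingness,
    summarize_cohort,
)
from .des import EDConfig, ScenarioSpec, run_experiment
from .distributions import ArrivalSchedule, DistributionSpec, make_table2_defaults
from .preprocessing import median_impute, screen_features, train_test_split
from .scenario_stats import calibrate_fleet, compare_scenarios, sign_test

__all__ = ["PipelineConfig", "StudyReport", "validate_config", "run_pipeline", "substream_seed"]

log = logging.getLogger("edvent")

_STREAMS = ("cohort", "missing", "split", "model", "calibration", "experiment")


def substream_seed(master_seed: int, stream: str) -> int:
    """Named, collision-free integer substream of the master seed."""
    if stream not in _STREAMS:
        raise ValueError(f"unknown stream {stream!r}")
    ss = np.random.SeedSequence(entropy=master_seed, spawn_key=(_STREAMS.index(stream),))
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class PipelineConfig:
    """Study configuration; defaults reproduce the reference setup."""

    n_patients: int = 1049
    split_fraction: float = 0.7
    missing_rates: dict = field(default_factory=dict)
    tree_grid: tuple[int, ...] = (100, 200, 300, 400, 500)
    mtry: int = 3
    cv_folds: int = 10
    threshold: float = 0.5
    alpha: float = 0.05
    target_median_min: float = 116.0
    n_replications: int = 29
    calibration_replications: int = 29
    fleet_grid: list[int] | None = None
    scenarios: list[str] = field(default_factory=lambda: ["baseline", "S1", "S2"])
    partner_capacity: int = 15
    master_seed: int = 0
    # ED overrides
    n_triage_servers: int = 1
    p_severe: float = 0.5
    vent_probability: float = 398.0 / 1049.0
    transfer_delay_min: float = 0.0
    collection_days: float = 15.0
    warmup_hours: float = 2400.0
    arrival_overrides: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (0.0 < self.split_fraction <= 1.0):
            raise ValueError("split.fraction outside (0, 1]")
        if self.n_replications < 1:
            raise ValueError("n_replications must be >= 1")
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")

    def classifier_config(self) -> ClassifierConfig:
        return ClassifierConfig(
            tree_grid=tuple(self.tree_grid),
            mtry=self.mtry,
            cv_folds=self.cv_folds,
            threshold=self.threshold,
            seed=substream_seed(self.master_seed, "model"),
        )

    def ed_config(self, n_local_vents: int = 1) -> EDConfig:
        variables = make_table2_defaults()
        if self.arrival_overrides:
            records = {(r["weekday"], r["slot"]): r for r in self.arrival_overrides}
            cells = dict(variables.arrivals.cells)
            for (day, slot), r in records.items():
                params = [r["p1"]] if r["family"] == "EXPO" else [r["p1"], r["p2"]]
                cells[(day, slot)] = DistributionSpec(r["family"], tuple(params),
                                                      r.get("unit", "days"))
            variables = dataclasses.replace(variables, arrivals=ArrivalSchedule(cells=cells))
        return EDConfig(
            variables=variables,
            n_triage_servers=self.n_triage_servers,
            p_severe=self.p_severe,
            vent_probability=self.vent_probability,
            n_local_vents=n_local_vents,
            transfer_delay_min=self.transfer_delay_min,
            collection_days=self.collection_days,
            warmup_hours=self.warmup_hours,
        )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["tree_grid"] = list(d["tree_grid"])
        return d


_FIELDS = {f.name for f in dataclasses.fields(PipelineConfig)}


def validate_config(raw: str | dict | None) -> PipelineConfig:
    """Parse and validate a YAML/JSON config; unknown keys are rejected."""
    if raw is None or raw == "":
        data: dict = {}
    elif isinstance(raw, dict):
        data = raw
    else:
        data = yaml.safe_load(raw) or {}
    if not isinstance(data, dict):
        raise ValueError("config root must be a mapping")
    unknown = set(data) - _FIELDS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    try:
        cfg = PipelineConfig(**data)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"invalid config: {exc}") from exc
    return cfg


@dataclass
class StudyReport:
    config: PipelineConfig
    cohort_summary: object = None
    n_excluded: int = 0
    split_sizes: tuple[int, int] = (0, 0)
    screen: object = None
    metrics: object = None
    importances: object = None
    n_trees: int = 0
    calibration: object = None
    validation: object = None  # sign test vs target median
    experiments: dict = field(default_factory=dict)
    comparison: object = None
    skipped: list[str] = field(default_factory=list)
    timings: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "version": __version__,
            "config": self.config.to_dict(),
            "n_excluded": self.n_excluded,
            "split_sizes": list(self.split_sizes),
            "n_trees": self.n_trees,
            "metrics": self.metrics.to_dict() if self.metrics else None,
            "calibration": {
                "selected_fleet": self.calibration.selected_fleet,
                "achieved_median": self.calibration.achieved_median,
                "target_median": self.calibration.target_median,
            } if self.calibration else None,
            "validation": self.validation.to_dict() if self.validation else None,
            "experiments": {k: v.summary() for k, v in self.experiments.items()},
            "comparison": [
                {k: v for k, v in c.items()}
                for c in (self.comparison or {}).get("comparisons", [])
            ] if self.comparison else None,
            "skipped": self.skipped,
            "timings": self.timings,
        }


def run_pipeline(config: PipelineConfig, out_dir: str | Path | None = None) -> StudyReport:
    """Execute the full study; optionally write all artifacts to ``out_dir``."""
    report = StudyReport(config=config)
    master = config.master_seed
    t_start = time.time()

    def tick(stage: str) -> None:
        report.timings[stage] = round(time.time() - t_start, 2)
        log.info("stage %-12s done at %.1fs", stage, report.timings[stage])

    # -- cohort --------------------------------------------------------------
    spec = default_cohort_spec()
    cohort = generate_cohort(spec, config.n_patients, seed=substream_seed(master, "cohort"))
    if config.missing_rates:
        cohort = inject_missingness(cohort, config.missing_rates,
                                    seed=substream_seed(master, "missing"))
    cohort, report.n_excluded = exclude_incomplete(cohort)
    report.cohort_summary = summarize_cohort(cohort)
    tick("cohort")

    # -- preprocessing -------------------------------------------------------
    split = train_test_split(cohort, config.split_fraction,
                             seed=substream_seed(master, "split"))
    train = median_impute(split.train)
    test = median_impute(split.train, split.test)
    report.split_sizes = split.sizes()
    report.screen = screen_features(cohort, alpha=config.alpha)
    tick("preprocess")

    # -- classifier ----------------------------------------------------------
    model = train_tune(train, config.classifier_config())
    report.n_trees = model.n_trees
    report.importances = model.importances
    if len(test) > 0:
        probs = predict_prob(model, test)
        outcomes = test.df["outcome"].to_numpy(dtype=int)
        counts = confusion_at_threshold(probs, outcomes, config.threshold)
        metrics = compute_metrics(counts)
        metrics.auc = roc_auc_ci(probs, outcomes)
        metrics.mcnemar_p = mcnemar_test((probs >= config.threshold).astype(int),
                                         outcomes).p_value
        report.metrics = metrics
    else:
        report.skipped.append("evaluation (empty test split)")
    tick("classifier")

    # -- DES calibration and validation --------------------------------------
    # calibration shares the experiment seed stream (common random numbers),
    # so the validated baseline reproduces the calibrated operating point
    ed = config.ed_config()
    exp_seed = substream_seed(master, "experiment")
    calib = calibrate_fleet(
        ed,
        target_median=config.target_median_min,
        grid=config.fleet_grid,
        n_reps=config.calibration_replications,
        master_seed=exp_seed,
    )
    report.calibration = calib
    ed = dataclasses.replace(ed, n_local_vents=calib.selected_fleet)
    tick("calibration")

    baseline = run_experiment(ed, ScenarioSpec("baseline"),
                              n_reps=config.n_replications, master_seed=exp_seed)
    report.experiments["baseline"] = baseline
    report.validation = sign_test(baseline.rep_medians, config.target_median_min,
                                  alpha=config.alpha)
    tick("validate")

    # -- scenario comparison -------------------------------------------------
    extra = [s for s in config.scenarios if s != "baseline"]
    if extra:
        scenarios = [ScenarioSpec("baseline")] + [
            ScenarioSpec(k, partner_capacity=config.partner_capacity) for k in extra
        ]
        report.comparison = compare_scenarios(
            ed, scenarios, n_reps=config.n_replications,
            master_seed=exp_seed, alpha=config.alpha,
        )
        for s in extra:
            report.experiments[s] = report.comparison["experiments"][s]
    else:
        report.skipped.append("comparison (baseline only)")
    tick("compare")

    if out_dir is not None:
        write_report(report, Path(out_dir), cohort=cohort)
    return report


def write_report(report: StudyReport, out_dir: Path, cohort: Cohort | None = None) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    if cohort is not None:
        cohort.to_csv(out_dir / "cohort.csv")
    if report.cohort_summary is not None:
        report.cohort_summary.to_csv(out_dir / "cohort_summary.csv", index=False)
    if report.screen is not None:
        report.screen.to_csv(out_dir / "feature_screen.csv")
    if report.importances is not None:
        report.importances.rename("mdgc").to_csv(out_dir / "importances.csv")
    if report.calibration is not None:
        import pandas as pd

        pd.DataFrame(report.calibration.to_records()).to_csv(
            out_dir / "calibration.csv", index=False)
    with open(out_dir / "report.json", "w") as fh:
        json.dump(report.to_dict(), fh, indent=2, default=_json_default)
    cfg_json = json.dumps(report.config.to_dict(), sort_keys=True, default=_json_default)
    manifest = {
        "edvent_version": __version__,
        "master_seed": report.config.master_seed,
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return None if math.isnan(float(o)) else float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if dataclasses.is_dataclass(o) and not isinstance(o, type):
        return dataclasses.asdict(o)
    return str(o)
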