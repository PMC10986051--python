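import dataclasses
import math

import numpy as np
import pytest

from edvent.des import (
    EDConfig,
    ScenarioSpec,
    apply_scenario,
    erlang_c_wait,
    offered_load,
    run_experiment,
    run_replication,
)
from edvent.distributions import (
    SLOTS,
    WEEKDAYS,
    ArrivalSchedule,
    DistributionSpec,
    FittedVariableSet,
)


def stationary_variables(
    tba_mean_min: float,
    tt=(10.0, 15.0),
    los=(32.5, 62.5),
    mvd_spec: DistributionSpec | None = None,
) -> FittedVariableSet:
    """Constant-rate schedule for controlled engine experiments."""
    cells = {(d, s): DistributionSpec("EXPO", (tba_mean_min,), "min")
             for d in WEEKDAYS for s in SLOTS}
    return FittedVariableSet(
        arrivals=ArrivalSchedule(cells=cells),
        triage_time=DistributionSpec("UNIF", tt, "min"),
        ed_los_severe=DistributionSpec("UNIF", (los[1], los[1]), "min"),
        ed_los_mild=DistributionSpec("UNIF", (los[0], los[0]), "min"),
        mv_duration=mvd_spec or DistributionSpec("UNIF", (7.1, 13.2), "days"),
    )


def mm_c_config(lam: float, mu: float, c: int, warmup_h=200.0, days=40.0) -> EDConfig:
    """Memoryless reduction: Poisson arrivals, zero triage/LoS, all
    patients ventilated, exponential MVD -> pure M/M/c on ventilators."""
    fv = stationary_variables(
        1.0 / lam, tt=(0.0, 0.0), los=(0.0, 0.0),
        mvd_spec=DistributionSpec("EXPO", (1.0 / mu,), "min"),
    )
    return EDConfig(variables=fv, vent_probability=1.0, n_local_vents=c,
                    warmup_hours=warmup_h, collection_days=days)


class TestScenarios:
    def test_baseline_identity(self):
        cfg = dataclasses.replace(EDConfig(), n_local_vents=300)
        assert apply_scenario(cfg, ScenarioSpec("baseline")) is cfg

    def test_s1_doubles_fleet(self):
        cfg = dataclasses.replace(EDConfig(), n_local_vents=300)
        assert apply_scenario(cfg, ScenarioSpec("S1")).n_local_vents == 600

    def test_s2_adds_partner_capacity(self):
        cfg = dataclasses.replace(EDConfig(), n_local_vents=300)
        out = apply_scenario(cfg, ScenarioSpec("S2"))
        assert (out.n_local_vents, out.n_partner_vents) == (300, 15)

    def test_invalid_scenarios(self):
        with pytest.raises(ValueError):
            ScenarioSpec("S3")
        with pytest.raises(ValueError):
            ScenarioSpec("S2", partner_capacity=0)


class TestEngineBasics:
    def test_no_arrivals_no_patients(self):
        fv = stationary_variables(1e12)  # first interarrival far beyond run end
        cfg = EDConfig(variables=fv, warmup_hours=1.0, collection_days=1.0)
        res = run_replication(cfg, seed=1)
        assert res.n_arrivals == 0 and len(res.mvwts) == 0

    def test_uncongested_mvwt_is_pathway_floor(self):
        """With ample servers everywhere, MVWT = TT draw + LoS draw for
        every ventilated patient (no queueing anywhere)."""
        fv = stationary_variables(300.0, tt=(12.0, 12.0), los=(40.0, 40.0))
        cfg = EDConfig(variables=fv, vent_probability=1.0, n_local_vents=10_000,
                       n_triage_servers=100, warmup_hours=0.0, collection_days=10.0)
        res = run_replication(cfg, seed=4)
        assert len(res.mvwts) > 0
        assert np.allclose(res.mvwts, 52.0)

    def test_traces_timestamps_monotone(self):
        cfg = dataclasses.replace(EDConfig(), n_local_vents=190,
                                  warmup_hours=24.0, collection_days=5.0)
        res = run_replication(cfg, seed=2, keep_traces=True)
        for t in res.traces:
            if t.collected and t.vent_needed and math.isfinite(t.vent_start):
                assert (t.arrival <= t.triage_start <= t.triage_end
                        <= t.los_end == t.vent_request <= t.vent_start <= t.vent_end)

    def test_fifo_ventilator_queue_preserves_request_order(self):
        cfg = dataclasses.replace(EDConfig(), n_local_vents=150,
                                  warmup_hours=24.0, collection_days=5.0)
        res = run_replication(cfg, seed=2, keep_traces=True)
        served = sorted(
            (t for t in res.traces if t.vent_needed and t.site == "local"
             and math.isfinite(t.vent_start)),
            key=lambda t: t.vent_request,
        )
        starts = [t.vent_start for t in served]
        assert starts == sorted(starts)

    def test_warmup_patients_excluded_from_statistics(self):
        cfg = dataclasses.replace(EDConfig(), n_local_vents=190,
                                  warmup_hours=48.0, collection_days=2.0)
        res = run_replication(cfg, seed=3, keep_traces=True)
        warmup_min = 48.0 * 60
        assert all(t.arrival >= warmup_min for t in res.traces if t.collected)
        assert any(t.arrival < warmup_min for t in res.traces)

    def test_zero_fleet_flagged_unstable(self):
        cfg = dataclasses.replace(EDConfig(), n_local_vents=0,
                                  warmup_hours=1.0, collection_days=1.0)
        res = run_replication(cfg, seed=5)
        assert res.unstable
        assert np.isinf(res.mvwts).all()

    def test_conservation_of_patients(self):
        cfg = dataclasses.replace(EDConfig(), n_local_vents=190,
                                  warmup_hours=24.0, collection_days=4.0)
        res = run_replication(cfg, seed=9, keep_traces=True)
        collected = [t for t in res.traces if t.collected]
        assert res.n_arrivals == len(collected)
        assert res.n_ventilated == sum(t.vent_needed for t in collected)
        assert len(res.mvwts) == res.n_ventilated

    def test_utilization_in_unit_interval(self):
        cfg = dataclasses.replace(EDConfig(), n_local_vents=200,
                                  warmup_hours=24.0, collection_days=4.0)
        res = run_replication(cfg, seed=9)
        assert 0.0 <= res.utilization <= 1.0


class TestErlangC:
    def test_mm1_closed_form(self):
        # rho/(mu - lam) for M/M/1
        assert erlang_c_wait(0.5, 1.0, 1) == pytest.approx(1.0)

    def test_light_traffic_limit(self):
        assert erlang_c_wait(1e-9, 1.0, 4) == pytest.approx(0.0, abs=1e-6)

    def test_two_server_reference(self):
        """lam=1.8, mu=1, c=2: P_wait/(c*mu - lam) ~ 4.263."""
        lam, mu, c = 1.8, 1.0, 2
        a = lam / mu
        p0 = 1.0 / (1 + a + a**2 / 2 / (1 - a / c))
        p_wait = (a**2 / 2) * p0 / (1 - a / c)
        expected = p_wait / (c * mu - lam)
        assert erlang_c_wait(lam, mu, c) == pytest.approx(expected, rel=1e-9)
        assert expected == pytest.approx(4.263, abs=0.001)

    def test_unstable_rejected(self):
        with pytest.raises(ValueError):
            erlang_c_wait(2.0, 1.0, 2)

    def test_engine_matches_erlang_c(self):
        """The decisive engine oracle: mean ventilator-queue delay of the
        memoryless reduction within 3 MC standard errors of Erlang-C."""
        lam, mu, c = 0.09, 0.05, 2  # rho = 0.9, ~11-min interarrivals
        cfg = mm_c_config(lam, mu, c)
        waits = []
        for rep in range(15):
            r = run_replication(cfg, seed=500 + rep, keep_traces=True)
            w = [t.vent_start - t.vent_request for t in r.traces
                 if t.collected and t.vent_needed]
            waits.append(np.mean(w))
        waits = np.asarray(waits)
        se = waits.std(ddof=1) / math.sqrt(len(waits))
        assert abs(waits.mean() - erlang_c_wait(lam, mu, c)) < 3 * se


class TestExperiments:
    def test_single_replication_aggregate(self):
        cfg = dataclasses.replace(EDConfig(), n_local_vents=190,
                                  warmup_hours=24.0, collection_days=4.0)
        res = run_experiment(cfg, n_reps=1, master_seed=3)
        assert res.pooled_median == res.replications[0].median_mvwt

    def test_reproducible_under_master_seed(self):
        cfg = dataclasses.replace(EDConfig(), n_local_vents=190,
                                  warmup_hours=24.0, collection_days=3.0)
        a = run_experiment(cfg, n_reps=3, master_seed=8)
        b = run_experiment(cfg, n_reps=3, master_seed=8)
        for ra, rb in zip(a.replications, b.replications):
            np.testing.assert_array_equal(ra.mvwts, rb.mvwts)

    def test_overall_median_within_replication_range(self):
        cfg = dataclasses.replace(EDConfig(), n_local_vents=190,
                                  warmup_hours=24.0, collection_days=4.0)
        res = run_experiment(cfg, n_reps=5, master_seed=2)
        lo, hi = res.median_range
        assert lo <= np.median(res.rep_medians) <= hi

    def test_capacity_monotone_with_matched_seeds(self):
        """More ventilators never lengthen the median wait (CRN)."""
        base = dataclasses.replace(EDConfig(), warmup_hours=400.0, collection_days=10.0)
        meds = []
        for fleet in (178, 190, 240):
            cfg = dataclasses.replace(base, n_local_vents=fleet)
            meds.append(run_experiment(cfg, n_reps=4, master_seed=6).pooled_median)
        assert meds[0] >= meds[1] >= meds[2] - 1e-9

    def test_offered_load_formula(self):
        cfg = EDConfig()
        rate = cfg.variables.arrivals.mean_arrivals_per_day()
        expected = rate * cfg.vent_probability * 10.15
        assert offered_load(cfg) == pytest.approx(expected)
        assert 180 < offered_load(cfg) < 190


class TestClassifierDrivenMode:
    def test_model_probabilities_drive_ventilation(self, spec):
        from edvent.classifier import ClassifierConfig, train_tune
        from edvent.cohort import generate_cohort

        train = generate_cohort(spec, 200, seed=1)
        model = train_tune(train, ClassifierConfig(tree_grid=(30,), cv_folds=2, seed=0))
        fv = stationary_variables(60.0)
        cfg = EDConfig(variables=fv, vent_model=model, cohort_spec=spec,
                       n_local_vents=500, warmup_hours=0.0, collection_days=15.0)
        res = run_replication(cfg, seed=7)
        # ventilated fraction should land near the cohort prevalence
        frac = res.n_ventilated / res.n_arrivals
        assert 0.2 < frac < 0.55

    def test_model_without_spec_rejected(self):
        with pytest.raises(ValueError, match="cohort_spec"):
            EDConfig(vent_model=object())
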