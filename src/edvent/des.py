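"""Discrete-event simulation of the ED mechanical-ventilation pathway.

The model follows a patient from ED admission to ventilation start:
nonstationary arrivals (weekday x 8-hour-slot interarrival
expressions), a FIFO triage stage with a small server pool, an ED
processing delay whose length depends on the triage severity group
(I-II vs III-V), a ventilation-need decision at the end of ED
processing (fixed Bernoulli probability or a fitted classifier scoring
a synthetic patient record), and a FIFO queue for a finite ventilator
fleet whose service time is the mechanical-ventilation duration (MVD).

The engine is a hand-rolled event calendar (heapq) with one RNG
substream per stochastic source. All patient attribute draws (triage
time, severity, ED-LoS, ventilation need, MVD) happen at arrival from a
dedicated substream, so runs with different fleet sizes or scenarios
share identical arrival and attribute streams — common random numbers
for scenario comparison.

Statistics cover only patients admitted after the warm-up; the clock
runs warm-up + collection window, then arrivals stop and the calendar
drains so every collected ventilation request is resolved.

Times are minutes on the simulation clock, which starts Monday 00:00.

The key output is the MVWT (mechanical-ventilation waiting time):
admission to ventilation start, for ventilated patients.
"""

from __future__ import annotations

import heapq
import math
from collections import deque
from dataclasses import dataclass, field, replace

import numpy as np

from .distributions import FittedVariableSet, make_table2_defaults

__all__ = [
    "EDConfig",
    "ScenarioSpec",
    "PatientTrace",
    "ReplicationResult",
    "ExperimentResult",
    "apply_scenario",
    "run_replication",
    "run_experiment",
    "erlang_c_wait",
    "offered_load",
]

LOCAL, PARTNER = "local", "partner"


@dataclass(frozen=True)
class EDConfig:
    """Full simulation configuration.

    ``vent_probability`` is the fixed Bernoulli ventilation-need
    probability; when ``vent_model`` (and its ``cohort_spec``) is set,
    the decision instead draws a synthetic patient record, scores it
    with the model, and samples Bernoulli(model probability).
    """

    variables: FittedVariableSet = field(default_factory=make_table2_defaults)
    n_triage_servers: int = 1
    p_severe: float = 0.5  # P(triage group I-II)
    vent_probability: float = 398.0 / 1049.0
    n_local_vents: int = 185
    n_partner_vents: int = 0
    transfer_delay_min: float = 0.0
    collection_days: float = 15.0
    warmup_hours: float = 2400.0
    vent_model: object | None = None  # classifier.TrainedModel
    cohort_spec: object | None = None  # cohort.CohortSpec

    def __post_init__(self) -> None:
        if self.n_local_vents < 0 or self.n_partner_vents < 0:
            raise ValueError("fleet sizes must be >= 0")
        if self.n_triage_servers < 1:
            raise ValueError("need at least one triage server")
        if not (0.0 <= self.vent_probability <= 1.0):
            raise ValueError("vent_probability outside [0, 1]")
        if not (0.0 <= self.p_severe <= 1.0):
            raise ValueError("p_severe outside [0, 1]")
        if self.collection_days <= 0 or self.warmup_hours < 0:
            raise ValueError("invalid run-control parameters")
        if self.vent_model is not None and self.cohort_spec is None:
            raise ValueError("classifier-driven mode requires cohort_spec")


@dataclass(frozen=True)
class ScenarioSpec:
    """Capacity strategy: baseline, S1 (double the local fleet) or
    S2 (transfer overflow to a partner hospital's idle fleet)."""

    kind: str = "baseline"
    partner_capacity: int = 15

    def __post_init__(self) -> None:
        if self.kind not in ("baseline", "S1", "S2"):
            raise ValueError(f"unknown scenario {self.kind!r}")
        if self.kind == "S2" and self.partner_capacity <= 0:
            raise ValueError("S2 requires partner capacity > 0")


def apply_scenario(config: EDConfig, scenario: ScenarioSpec) -> EDConfig:
    """Transform the baseline configuration per the scenario."""
    if scenario.kind == "baseline":
        return config
    if scenario.kind == "S1":
        return replace(config, n_local_vents=2 * config.n_local_vents)
    return replace(config, n_partner_vents=scenario.partner_capacity)


@dataclass
class PatientTrace:
    pid: int
    arrival: float
    triage_start: float = math.nan
    triage_end: float = math.nan
    los_end: float = math.nan
    vent_needed: bool = False
    vent_request: float = math.nan
    vent_start: float = math.nan
    vent_end: float = math.nan
    site: str | None = None
    collected: bool = False

    @property
    def mvwt(self) -> float:
        """Admission -> ventilation start, minutes; inf if never served."""
        if not self.vent_needed:
            return math.nan
        return self.vent_start - self.arrival if not math.isnan(self.vent_start) else math.inf


@dataclass
class ReplicationResult:
    seed: int
    mvwts: np.ndarray  # collected ventilated patients, minutes
    n_arrivals: int
    n_ventilated: int
    utilization: float
    unstable: bool
    traces: list[PatientTrace] | None = None

    @property
    def median_mvwt(self) -> float:
        return float(np.median(self.mvwts)) if len(self.mvwts) else math.nan

    @property
    def mean_mvwt(self) -> float:
        return float(np.mean(self.mvwts)) if len(self.mvwts) else math.nan


@dataclass
class ExperimentResult:
    replications: list[ReplicationResult]
    scenario: ScenarioSpec
    n_local_vents: int

    @property
    def rep_medians(self) -> np.ndarray:
        return np.array([r.median_mvwt for r in self.replications])

    @property
    def pooled_mvwts(self) -> np.ndarray:
        return np.concatenate([r.mvwts for r in self.replications])

    @property
    def pooled_median(self) -> float:
        return float(np.median(self.pooled_mvwts))

    @property
    def median_range(self) -> tuple[float, float]:
        meds = self.rep_medians
        return float(meds.min()), float(meds.max())

    @property
    def unstable(self) -> bool:
        return any(r.unstable for r in self.replications)

    def summary(self) -> dict:
        lo, hi = self.median_range
        return {
            "scenario": self.scenario.kind,
            "n_local_vents": self.n_local_vents,
            "n_replications": len(self.replications),
            "pooled_median_mvwt": self.pooled_median,
            "rep_median_min": lo,
            "rep_median_max": hi,
            "mean_utilization": float(np.mean([r.utilization for r in self.replications])),
            "unstable": self.unstable,
        }


class _ProbProvider:
    """Streams classifier-scored ventilation probabilities for arrivals."""

    def __init__(self, model, spec, seed: int, chunk: int = 1024) -> None:
        from .classifier import predict_prob
        from .cohort import generate_cohort

        self._model = model
        self._spec = spec
        self._chunk = chunk
        self._seeds = iter(range(10**6))
        self._base_seed = seed
        self._buf: list[float] = []
        self._generate = generate_cohort
        self._predict = predict_prob

    def next_prob(self) -> float:
        if not self._buf:
            sub = self._base_seed + next(self._seeds)
            cohort = self._generate(self._spec, self._chunk, seed=sub)
            self._buf = list(self._predict(self._model, cohort))[::-1]
        return self._buf.pop()


class _BusyIntegral:
    """Time integral of a busy-server count over the collection window."""

    def __init__(self, w_start: float, w_end: float) -> None:
        self.w_start, self.w_end = w_start, w_end
        self.area = 0.0
        self._t = 0.0
        self._busy = 0

    def update(self, t: float, busy: int) -> None:
        lo, hi = max(self._t, self.w_start), min(t, self.w_end)
        if hi > lo:
            self.area += self._busy * (hi - lo)
        self._t, self._busy = t, busy


_ARRIVAL, _TRIAGE_END, _LOS_END, _VENT_END = 0, 1, 2, 3


def run_replication(
    config: EDConfig,
    seed: int | np.random.SeedSequence,
    keep_traces: bool = False,
) -> ReplicationResult:
    """Execute one seeded replication of the ED pathway."""
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    seed_repr = int(ss.entropy if np.isscalar(ss.entropy) else ss.entropy[0])
    s_arr, s_pat, s_cls = ss.spawn(3)
    rng_arr = np.random.default_rng(s_arr)
    rng_pat = np.random.default_rng(s_pat)

    v = config.variables
    warmup = config.warmup_hours * 60.0
    t_end = warmup + config.collection_days * 1440.0

    provider = None
    if config.vent_model is not None:
        provider = _ProbProvider(
            config.vent_model, config.cohort_spec,
            seed=int(np.random.default_rng(s_cls).integers(2**31)),
        )

    heap: list[tuple[float, int, int, PatientTrace | None]] = []
    seq = 0

    def push(t: float, kind: int, patient: PatientTrace | None) -> None:
        nonlocal seq
        heapq.heappush(heap, (t, seq, kind, patient))
        seq += 1

    triage_queue: deque[PatientTrace] = deque()
    vent_queue: deque[PatientTrace] = deque()
    triage_busy = 0
    free_local = config.n_local_vents
    free_partner = config.n_partner_vents
    busy_local = _BusyIntegral(warmup, t_end)

    patients: list[PatientTrace] = []
    attrs: dict[int, tuple[float, float, float]] = {}  # pid -> (tt, los, mvd)
    n_arrivals = n_vent = 0

    def draw_patient(t: float) -> PatientTrace:
        nonlocal n_arrivals, n_vent
        pid = n_arrivals
        n_arrivals += 1
        tt = v.triage_time.sample_minutes(rng_pat)
        severe = rng_pat.random() < config.p_severe
        los = (v.ed_los_severe if severe else v.ed_los_mild).sample_minutes(rng_pat)
        p_vent = provider.next_prob() if provider is not None else config.vent_probability
        needed = rng_pat.random() < p_vent
        mvd = v.mv_duration.sample_minutes(rng_pat)  # drawn always: stream sync
        p = PatientTrace(pid=pid, arrival=t, vent_needed=needed,
                         collected=warmup <= t < t_end)
        attrs[pid] = (tt, los, mvd)
        if needed:
            n_vent += 1
        if keep_traces or p.collected:
            patients.append(p)
        return p

    def start_vent(t: float, p: PatientTrace, site: str) -> None:
        delay = config.transfer_delay_min if site == PARTNER else 0.0
        p.site = site
        p.vent_start = t + delay
        p.vent_end = p.vent_start + attrs[p.pid][2]
        push(p.vent_end, _VENT_END, p)
        if site == LOCAL:
            busy_local.update(t, config.n_local_vents - free_local)

    def start_triage(t: float, p: PatientTrace) -> None:
        p.triage_start = t
        push(t + attrs[p.pid][0], _TRIAGE_END, p)

    # first arrival: one interarrival drawn from the slot containing t=0
    t0 = v.arrivals.spec_at(0.0).sample_minutes(rng_arr)
    if t0 < t_end:
        push(t0, _ARRIVAL, None)

    while heap:
        t, _, kind, p = heapq.heappop(heap)
        if kind == _ARRIVAL:
            p = draw_patient(t)
            nxt = t + v.arrivals.spec_at(t).sample_minutes(rng_arr)
            if nxt < t_end:
                push(nxt, _ARRIVAL, None)
            if triage_busy < config.n_triage_servers:
                triage_busy += 1
                start_triage(t, p)
            else:
                triage_queue.append(p)
        elif kind == _TRIAGE_END:
            p.triage_end = t
            push(t + attrs[p.pid][1], _LOS_END, p)
            if triage_queue:
                start_triage(t, triage_queue.popleft())
            else:
                triage_busy -= 1
        elif kind == _LOS_END:
            p.los_end = t
            if p.vent_needed:
                p.vent_request = t
                if free_local > 0:
                    free_local -= 1
                    start_vent(t, p, LOCAL)
                elif free_partner > 0:
                    # transfer policy: only at request time, local all busy
                    free_partner -= 1
                    start_vent(t, p, PARTNER)
                else:
                    vent_queue.append(p)
            else:
                attrs.pop(p.pid, None)  # non-ventilated: attributes no longer needed
        else:  # _VENT_END
            if p.site == LOCAL:
                if vent_queue:
                    start_vent(t, vent_queue.popleft(), LOCAL)
                else:
                    free_local += 1
                    busy_local.update(t, config.n_local_vents - free_local)
            else:
                free_partner += 1

    busy_local.update(t_end, config.n_local_vents - free_local)
    collected = [q for q in patients if q.collected]
    mvwts = np.array([q.mvwt for q in collected if q.vent_needed], dtype=float)
    unstable = bool(np.isinf(mvwts).any())
    window = t_end - warmup
    util = (busy_local.area / (config.n_local_vents * window)
            if config.n_local_vents > 0 else math.nan)
    return ReplicationResult(
        seed=seed_repr,
        mvwts=mvwts,
        n_arrivals=sum(1 for q in collected),
        n_ventilated=int(sum(1 for q in collected if q.vent_needed)),
        utilization=util,
        unstable=unstable,
        traces=patients if keep_traces else None,
    )


def run_experiment(
    config: EDConfig,
    scenario: ScenarioSpec = ScenarioSpec(),
    n_reps: int = 29,
    master_seed: int = 0,
) -> ExperimentResult:
    """Run ``n_reps`` independent replications via seed substreams.

    Replication streams depend only on ``master_seed`` and the
    replication index, so experiments that differ only in capacity
    share arrival and patient-attribute streams (common random
    numbers).
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    cfg = apply_scenario(config, scenario)
    children = np.random.SeedSequence(master_seed).spawn(n_reps)
    reps = [run_replication(cfg, child) for child in children]
    for r, child in zip(reps, children):
        r.seed = int(child.spawn_key[0])
    return ExperimentResult(replications=reps, scenario=scenario,
                            n_local_vents=cfg.n_local_vents)


def offered_load(config: EDConfig) -> float:
    """Deterministic ventilator offered load (mean busy units).

    Arrival rate (from the schedule's analytic means) x ventilation
    probability x mean MVD in days.
    """
    per_day = config.variables.arrivals.mean_arrivals_per_day()
    mvd_days = config.variables.mv_duration.mean_minutes() / 1440.0
    return per_day * config.vent_probability * mvd_days


def erlang_c_wait(lam: float, mu: float, c: int) -> float:
    """Expected M/M/c queueing delay (Erlang-C), analytic oracle.

    ``lam``: arrival rate, ``mu``: per-server service rate, ``c``
    servers; requires lam/(c*mu) < 1.
    """
    if lam <= 0:
        return 0.0
    a = lam / mu  # offered load in Erlangs
    rho = a / c
    if rho >= 1.0:
        raise ValueError(f"unstable system: rho = {rho:.3f} >= 1")
    # P(wait) by the Erlang-C formula, computed stably via recursion
    inv_b = 1.0  # inverse Erlang-B
    for k in range(1, c + 1):
        inv_b = 1.0 + inv_b * k / a
    b = 1.0 / inv_b
    p_wait = b / (1.0 - rho * (1.0 - b))
    return p_wait / (c * mu - lam)
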