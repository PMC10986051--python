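# Methods

`edvent` models the journey of respiratory-season patients through an
emergency department (ED), from admission to the start of mechanical
ventilation, in three coupled pieces: a synthetic electronic-health-record
(EHR) cohort generator, a random-forest ventilation-need classifier, and a
discrete-event simulation (DES) of the ED pathway with a finite ventilator
fleet. This note records the models, their assumptions, the tunable
parameters, and the numerical choices made where the design was open.

## 1. Synthetic cohort model

The source cohort (1,049 analysed patients, 398 ventilated) is available
only as a published characteristics table: per-class frequencies for sex
and a 3-level age band, and per-class *median (variance)* for eleven
numeric features — paired first/second records of systolic and diastolic
arterial pressure (SAP, DAP, mm Hg), core temperature (CT, °C), oxygen
saturation (OSL, %), heart rate (HB, beats/min), plus a single D-dimer
concentration (ng/ml). The generator realises a population whose
class-conditional structure matches those summaries:

* **Outcome**: Bernoulli with prevalence 398/1,049 ≈ 0.379.
* **Sex, age band**: categorical draws from the per-class frequency
  tables (e.g. P(male | ventilated) = 292/398 ≈ 0.73).
* **Vitals**: truncated normal per class. The pre-truncation standard
  deviation is the square root of the printed variance; the location is
  solved numerically (Brent's method) so that the *post-truncation median*
  equals the printed median — with asymmetric truncation the location and
  the median differ by up to ~2 mm Hg, and the printed medians are the
  quantity we reproduce. Default truncation bounds keep values
  physiologically plausible: SAP [60, 260], DAP [30, 160], CT [34, 42],
  OSL [50, 100], HB [30, 220]. The anomalously large printed CT_2 variance
  for non-ventilated patients (4.698 °C²) is kept as printed; truncation
  caps its effect.
* **D-dimer**: log-normal per class, with exp(μ) equal to the printed
  median and (μ, σ) solved so the arithmetic variance equals the printed
  variance (σ² = log[(1+√(1+4v))/2], v = variance/median²). The printed
  variances (5.4·10⁷ against a median of 1,334) imply the strong right
  skew typical of D-dimer.
* **Paired records**: R1 and R2 of the same vital are drawn through a
  Gaussian copula with correlation 0.8 (configurable), since repeated
  measurements on a patient track each other; each record keeps its own
  printed median/variance.

At n = 10⁵ every class-conditional sample median lands within 2% of its
target and every categorical proportion within 3 binomial standard errors
(tested).

**What the generator does not emulate.** Features are conditionally
independent given the class apart from the R1/R2 pairing: real
inter-vital correlations (e.g. SAP with DAP), continuous age, and disease
progression are absent. Consequently classifier results on synthetic data
quantify the pipeline's behaviour, not the clinical signal of the real
EHR. One visible consequence: in the real cohort D-dimer dominated the
Gini importance ranking, whereas on the synthetic stand-in the features
with large between-class *variance* gaps (DAP_1: 90 vs 887; CT_2: 0.57 vs
4.70) are cheaper for trees to exploit than D-dimer's location shift
(≈0.45 log-sd), so D-dimer ranks mid-table. This is a property of the
published moments, not of the forest implementation.

Missingness is injected per feature as independent Bernoulli blanking
(rates are generator knobs, default 0); the exclusion policy drops
records with a missing outcome or more than a configurable number of
missing predictors (default 10 of 13), and remaining gaps are filled with
training-set medians. This reconciles the source's two stated treatments
(exclusion of incomplete records and median imputation): records missing
the outcome cannot be used at all, everything else is imputable.

## 2. Preprocessing and classifier

The split is a uniform random 70/30 partition with |train| =
⌊0.7·n⌋ — 1,049 patients give exactly (734, 315). Imputation medians are
computed on the training split only and applied to both splits (no
test-to-train leakage). The feature screen uses one-way ANOVA for numeric
features and chi-square contingency tests for sex and the age band
(ANOVA is ill-defined for categorical predictors) at α = 0.05, with no
multiplicity correction.

The classifier is a random forest with 3 variables tried per split; the
tree count is tuned over {100, 200, 300, 400, 500} by mean
cross-validated AUC (default 10 folds, stratified; ties go to the
smallest forest) and refitted on the full training split. Evaluation at
the prob ≥ 0.5 threshold reports sensitivity, specificity, PPV and NPV
with exact Clopper–Pearson 95% intervals, ROC AUC (rank statistic, ties
half) with a DeLong interval, and an exact-binomial McNemar test on the
discordant predicted/observed pairs.

Feature importance is the Mean Decrease in Gini Coefficient (MDGC),
computed from the fitted trees in the *unnormalised sample-count*
convention: each internal node contributes N·i(node) − N_L·i(left) −
N_R·i(right) to its split feature, totals are averaged over trees. Under
this convention a stump perfectly splitting a balanced sample of size n
scores 0.5·n, and magnitudes on a ~730-patient training set land in the
single-to-low-hundreds range.

## 3. ED pathway simulation

The DES is a bespoke event-calendar engine (binary-heap calendar,
minute-resolution clock starting Monday 00:00). The pathway is:

1. **Arrivals** — time between admissions (TBA) drawn from a weekday ×
   8-hour-slot grid of 21 fitted expressions (log-normal, exponential or
   Weibull, in days). Each interarrival is drawn from the cell containing
   the previous arrival's time ("slot-switching"), without truncation at
   slot boundaries — simple and with small bias. Parameter conventions
   follow the simulation package in which the expressions were fitted:
   LOGN(m, s) carries the arithmetic mean/sd of the variate, EXPO(m) the
   mean, WEIB(β, α) scale/shape. The grid implies ≈48 arrivals/day.
2. **Triage** — FIFO, 1 server by default, service UNIF(10, 15) min;
   severity group I-II with probability 0.5 (configurable).
3. **ED processing** — pure delay: UNIF(42.5, 62.5) min for groups I-II,
   UNIF(32.5, 52.5) min for III-V.
4. **Ventilation-need decision** at the end of ED processing — Bernoulli
   with p = 398/1,049, or, in classifier mode, Bernoulli at the forest's
   probability for a freshly generated synthetic record.
5. **Ventilator queue** — FIFO over a finite local fleet; service is the
   mechanical-ventilation duration MVD ~ UNIF(7.1, 13.2) days. Queues are
   unbounded (no blocking).

**MVWT** (mechanical-ventilation waiting time) is defined as admission →
ventilation start, i.e. it includes triage wait, triage, ED processing
and the ventilator queue. This is the only reading under which a
~116-minute median is attainable, since the pathway delays alone
contribute ~60–75 min.

**Run control.** 2,400 h (100 days) of warm-up followed by a 15-day
collection window. With a mean MVD of 10.15 days, ventilator occupancy
needs on the order of 100 days to fill, so the warm-up must *precede* the
collection window (total clock 115 days). Statistics cover only patients
admitted inside the window; after arrivals stop the calendar drains so
every collected ventilation request resolves (later arrivals cannot
affect earlier FIFO requests). Experiments run 29 replications.

**Randomness.** One master seed; `numpy` SeedSequence substreams per
replication, and within a replication separate streams for arrivals and
for patient attributes. All per-patient draws (triage time, group,
ED-LoS, ventilation need, MVD) happen at arrival, so configurations that
differ only in capacity share identical sample paths — common random
numbers (CRN) for calibration and scenario comparison, and the basis of
the engine's pathwise capacity-monotonicity property.

**Engine verification.** Reducing the model to memoryless primitives
(Poisson arrivals, zero triage/LoS, ventilation probability 1,
exponential MVD) makes the ventilator stage an exact M/M/c queue; the
simulated mean queue delay is required to match the Erlang-C closed form
within 3 Monte-Carlo standard errors at several (λ, μ, c) settings.

## 4. Fleet calibration and validation

The local fleet size is not an observed quantity; it is identified by
grid search against the observed median MVWT of 116 min. The default
grid is 20 integers spanning ±10% around the deterministic offered load
(arrival rate × ventilation probability × mean MVD ≈ 185 ventilators).
Each candidate runs 29 replications; the fleet minimising
|pooled median MVWT − 116| wins (ties to the smaller fleet), and
candidates whose queues never clear are flagged unstable and excluded.
The final validation run reuses the calibration's seed stream (CRN).
Calibration replications were raised from a smaller pilot count to the
full 29 because the pooled median near the congestion knee is
heavy-tailed across seeds; with 29-replication calibration the selected
fleet lands at 174–182 units and the pooled median within ~6% of the
observed 115.68 min across master seeds. The knee is steep: one
ventilator moves the pooled median by ~5–10 min, which bounds how closely
any integer fleet can sit on the target.

Validation uses the one-sample exact sign test of the 29 per-replication
medians against η₀ = 116 min (α = 0.05). Note the per-replication
medians are far more dispersed than the pooled median: a 15-day window
samples a slow occupancy process whose level at window start varies
across replications.

## 5. Capacity strategies and comparison statistics

* **S1** doubles the local fleet.
* **S2** keeps the local fleet and adds a partner hospital with 15 idle
  ventilators; a patient transfers at ventilator-request time iff all
  local units are busy and a partner unit is free (transfer delay
  configurable, default 0; partner service uses the same MVD). Freed
  partner units do not pull from the local queue.

Comparisons run with CRN and report: a two-sided Mann–Whitney test on
per-replication median MVWTs (exact enumeration when min(n) ≤ 8 without
ties, otherwise normal approximation with tie and continuity
corrections), the Hodges–Lehmann shift (median of pairwise differences)
with a distribution-free CI from the ordered differences at the
Mann–Whitney critical indices, and an improvement percentage on pooled
medians (negative = shorter waits). Both strategies reduce the median
wait significantly at 29 replications; the magnitudes are larger than in
the source study because they depend on the unprinted fleet size and
transfer logic, so only direction and significance are asserted.

The replication-count rule is the standard sequential half-width
formula n = ⌈n₀ (h₀/h)²⌉.

## 6. Input-data analysis battery

For completeness the package carries the input-analysis tests used to
justify fitted expressions: Wald–Wolfowitz runs test about the sample
median (values at the median dropped, continuity-corrected normal
approximation), Kruskal–Wallis homogeneity (tie-corrected, χ² reference),
and Pearson chi-square goodness of fit with equal-probability bins
(default 10, merged to expected ≥ 5, df = bins − 1 − fitted-parameter
count; pass `n_fitted_params=0` when parameters are known rather than
fitted). All three are calibrated: under their nulls the rejection rate
at α = 0.05 stays within 3 binomial standard errors over 1,000
repetitions (tested).

## 7. Known limitations

* The synthetic cohort cannot reproduce real-data classifier metrics
  (the published 93.08% sensitivity etc.); tests assert property gates
  (test AUC ≥ 0.75; importance sanity) instead.
* The printed between-class variance gaps dominate the synthetic Gini
  ranking, displacing D-dimer from the top (see §1).
* Staffing and ancillary resources, ICU downstream flow, and
  animation/visualisation are out of scope.
* The empirical mean TBA quoted for the source data (19.06 min) is a
  data descriptor; the time-averaged mean of the fitted schedule differs
  and no test asserts it.
* Arena-style slot-switching arrivals bias slot boundaries slightly;
  with 8-hour slots and minute-scale interarrivals the effect is
  negligible.
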