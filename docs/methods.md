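# Methods

## What is being modelled

A single-centre, 1:1 randomized comparison of two policies for managing
intraoperative hypotension under general anesthesia with invasive arterial
monitoring:

* **guided arm** — a predictive index (0–100) is computed continuously; when
  it exceeds 85 an alarm sounds and the clinician treats within 2 minutes,
  choosing among six options (fluid, vasopressor, inotrope, the two
  fluid combinations, observation) according to a hemodynamic diagnostic
  table;
* **standard-of-care arm** — the same monitor runs but is muted and covered;
  treatment starts only when MAP < 65 mmHg is observed.

The primary endpoint is the time-weighted average (TWA) of MAP below
65 mmHg; secondary endpoints use 60 and 55 mmHg, and TWA above 130 mmHg
screens for overtreatment. All analyses operate on the monitor's 20-s
summary cadence; no waveform-level synthesis is attempted.

## Burden metrics

Burden uses the rectangle rule on the discrete samples: each sample stands
for its following 20-s interval, the comparison at the threshold is strict,
and no interpolation is performed at crossings. This matches the discrete
update semantics of the monitor and makes results bit-reproducible from the
exported samples; whether the original trial interpolated at crossings is
unknowable from the report, so the choice is isolated in one routine.
The TWA denominator is the **total surgical duration**, including
above-threshold and gap time. Missing samples (NaN) are excluded from
numerators but stay in the denominator; a series with > 10 % gaps is
flagged. Whole-case summaries (median, quartiles) use linear interpolation,
the convention of the standard statistical packages.

## Event analytics

* Hypotensive event: ≥ 3 consecutive sub-65 samples (= 1 min at 20 s);
  the event is anchored at its first sample.
* Alarm: strict upward crossing of index > 85.
* Merging is **anchored**, not chained: the earliest unmerged event opens a
  window `[anchor, anchor + 15 min)`; everything inside merges into it; the
  first event at or past the window end anchors the next window.
  Consequently consecutive anchors are at least 15 min apart. All windows
  are closed on the left, open on the right; times are 0-based seconds.
* Silent alarm (SAT): earliest index exceedance in the 15 min *preceding*
  (and including) a hypotension anchor. The backward reading is forced by
  prediction semantics — the index rises before the pressure falls.
* Latency: first treatment in `[anchor, anchor + 15 min)`; greedy
  earliest-anchor-first matching, each treatment consumed at most once;
  anchors with no in-window treatment are reported untreated.

## Synthetic cohort generator

No patient-level data accompany the study design, so the generator is a
first-class, tested component that creates the statistical structure the
analysis assumes.

**MAP dynamics.** Discrete-time mean-reverting (Ornstein–Uhlenbeck) process
on the 20-s grid with the exact discretisation
`x_{k+1} = T_k + (x_k − T_k)·e^{−θΔ} + σ_Δ ε_k`, reversion rate θ = 0.2/min
(≈ 5-min time constant) and innovation scale σ = 1.5 mmHg/√min (stationary
SD ≈ 2.4 mmHg). The reversion target `T_k` is the patient's baseline MAP
(Normal(85, 6) clipped to [80, 96] mmHg) plus the offsets of active
provocations and treatments. Values are clamped to [20, 200] mmHg.

**Provocations.** Hypotensive insults (vasodilation, bleeding, anesthetic
depth) arrive as a Poisson-like stream at 1.5/h, each a trapezoid: 3-min
linear ramp to a depth drawn U(−38, −22) mmHg, a hold drawn Exp(mean
10 min) clipped to [2, 30] min, and a 3-min release. Each insult carries a
cause (preload 45 %, vasomotor tone 35 %, contractility 20 %) that
perturbs the corresponding auxiliary channel (stroke volume variation +8 %,
systemic vascular resistance −450 dyn·s·cm⁻⁵ with dynamic arterial
elastance −0.3, dP/dtmax −400 mmHg/s) starting **10 min before** the
pressure fall — the causal derangement precedes the hemodynamic
consequence, which is precisely what gives a predictive index something to
predict and lets the protocol diagnose the cause at alarm time.

**Predictive index.** The index is a logistic transform of the projected
minimum of the *noise-free* mean path over the next 15 min,
`index = 100 / (1 + exp((m − 72)/3))`, plus bounded Gaussian noise (SD 2),
clamped to [0, 100]; it crosses 85 when the projected minimum falls below
≈ 66.8 mmHg. Because the generator's projection knows the provocation
schedule, an undiscounted minimum would alarm a full horizon (15 min) ahead
of every event — clairvoyance no real index has, and far enough ahead that
treatment effects decay before the dip arrives. Projected values are
therefore *risk-discounted* by 1 mmHg per minute of remoteness beyond the
first minute, producing graded alarms that lead events by roughly 2–8 min
(deeper dips alarm earlier). The first projected minute is undiscounted and
the projection replicates the deterministic path recurrence exactly on the
20-s grid, so with noise off the alarm strictly precedes every sustained
sub-65 crossing — the property that makes silent-alarm reconstruction
well-posed — as an exact invariant rather than an approximation.

**Treatment policies.** The guided arm treats each merged alarm after a
lognormal delay (median 40 s, clipped to ≤ 110 s, inside the trial's 2-min
action window); both arms additionally treat each merged sustained-
hypotension episode after a U(40, 55) s reaction delay, since the target
MAP ≥ 65 mmHg applies to every patient — in the guided arm this is the
rescue path behind the pre-emptive one. The option comes from the decision
table evaluated on the auxiliary channels at the anchor sample. Each
non-observation treatment injects a pressure effect into the reversion
target from its start time forward: instantaneous onset with exponential
decay (time constant 20 min) for vasoactive options, a 5-min linear ramp
for pure fluid. Doses are titrated: amplitude = U(0.9, 1.3) × the projected
pressure deficit, clipped to [10, 40] mmHg. The treated path is
re-integrated on the *identical* noise innovations as the untreated one, so
paired comparisons (treatments on vs off) isolate the policy effect, and
the index is recomputed causally — a treatment enters projections only once
given.

**Why the arms separate.** Pre-emptive dosing usually keeps the target
above 65 mmHg, so the guided arm's crossings are mostly prevented; the
reactive arm always pays detection (1 min of sustained hypotension) +
response (~45 s) + recovery (relaxation back above threshold) per episode.
This reproduces the qualitative structure of the trial: near-zero guided
burden, substantial reactive burden, equal ~45 s latencies from the audible
anchor, and a several-minute deficit measured from the silent alarm.

**Covariates.** Age Normal(60, 10.5) clipped to the inclusion range
[20, 80]; 80 % male; surgery type pancreas/oral/esophagus at 34/36/30 %;
surgical duration log-normal(μ = 6.194, σ = 0.39) min (median ≈ 490 min,
matching a long major-surgery case mix) clipped below at 240 min. No
dropout is simulated (the design anticipates 10 % but the reference cohort
completed follow-up in full).

**Reproducibility.** One global seed expands into per-patient substreams
keyed by `SeedSequence([seed, crc32(patient_id)])`, so enlarging the cohort
never perturbs existing patients; identical configs yield byte-identical
CSV products, and the pipeline manifest records the config digest and the
SHA-256 of every output.

## Decision table

The six-option protocol is data, not code: an ordered rule list against
configurable cut-offs (defaults: SVV > 13 %, Eadyn < 0.9, SVR < 800
dyn·s·cm⁻⁵, dP/dtmax < 500 mmHg/s). Preload is checked first (high SVV →
fluid component); dynamic arterial elastance below its cut-off within the
preload branch means volume alone will not raise pressure (adds a
vasopressor); low SVR adds a vasopressor; low dP/dtmax adds an inotrope.
Combinations arise when a preload component coexists with a tone or
contractility component; when both tone and contractility fire the earlier
(tone) rule wins; nothing firing yields observation. The published
antecedent protocol prints its cut-offs only graphically, so the defaults
here are standard goal-directed-therapy surrogates and every cut-off is
site-configurable. The traversal is recorded per decision
(`rationale_path`), making recommendations auditable, and raising SVV can
never remove the fluid component (monotone preload response).

## Statistical procedures

* **Mann–Whitney U**: exact enumeration of all C(n+m, n) group assignments
  of the pooled values (a permutation test on the tie-aware U statistic)
  when both groups have ≤ 8 observations; otherwise the normal
  approximation with mid-ranks, tie-corrected variance and **no continuity
  correction** (matching the behaviour of the mainstream clinical
  packages; verified identical to R's `wilcox.test(..., exact = FALSE,
  correct = FALSE)`).
* **Hodges–Lehmann**: median of all n·m pairwise differences (control −
  intervention orientation in the trial tables); Moses CI from the
  k-th smallest/largest pairwise difference with
  k = ⌊nm/2 − z·√(nm(n+m+1)/12)⌋.
* **Means**: pooled two-sample t; the CI uses the t-critical value at
  pooled df — with 30 per arm this reproduces the reference report's
  "large-sample" intervals, which a z-based half-width does not.
* **Proportions**: Pearson chi-square (1 df, no Yates correction — the
  corrected statistic does not reproduce the reference p-values); Fisher's
  exact test (two-sided by summing point probabilities ≤ observed) selected
  when ≥ 50 % of expected cell counts are < 5. Difference-in-proportion
  CIs are continuity-corrected Wald on the percentage scale. One row of the
  reference report (equal proportions 8/30 vs 8/30, ±22.4) is consistent
  only with the *uncorrected* Wald interval; the corrected form is
  implemented and the discrepancy noted here.
* **Sample size**: smallest equal n per group whose noncentral-t power for
  the two-sided pooled t-test reaches the target (0.15 vs 0.40, SD 0.32,
  α = 0.05, power 0.8 → 27/group, 54 total), then inflation for dropout
  rounding up to an even total (10 % → 60).
* **Multiplicity**: Bonferroni (`p_adj = min(1, p·k)`) for the
  complication-family comparisons.

Rounding for display follows the clinical-table conventions (TWA to 2
decimals, p to 2–3); internal values are never rounded.

## Problem sizes in the test suite

Unit tests run on hand-built series and 4-patient bundles; the oracle-
equivalence suite uses 1000 random series for the burden metrics, full
enumeration up to 8 per group for the exact Mann–Whitney, and a 10⁵-sample
permutation oracle for the asymptotic one. The directional-replication
check simulates the full design — 30 patients/arm — across 10 seeds
(~35 s single-core), asking for a lower guided-arm median TWA < 65 with
Mann–Whitney p < 0.05 in at least 9 of 10.

## Known limitations

* The index proxy shares the generator's provocation schedule (discounted
  projection of the known mean path). It has the *predictive-lead* property
  the analysis exploits, and only that; its receiver-operating behaviour is
  not calibrated to any real index, and the proprietary algorithm is not
  reimplemented.
* Simulated reactive-arm episodes are briefer than the reference cohort's
  (median duration below 65 mmHg ≈ 13 min vs ≈ 59 min per case), because
  simulated clinicians re-treat effectively at every merged episode. The
  arm contrast in burden replicates directionally; printed magnitudes, and
  the downstream whole-case median-MAP separation between arms, do not.
* Treatment pharmacodynamics are single-compartment pressure offsets; no
  drug, dose or interaction modelling, no fluid-balance accounting, and no
  postoperative-outcome generation (out of scope by design).
* Gaps, artifacts and sensor failures are not simulated; the gap-handling
  path is exercised only by constructed series.
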