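"""Synthetic two-arm cohort generator.

The generator emulates the monitored-trial setting end to end so every
downstream stage is testable without any recorded data:

* **MAP dynamics** — a discrete-time mean-reverting (Ornstein-Uhlenbeck)
  process at the 20-s monitor cadence.  The reversion target is the
  patient's baseline MAP plus the offsets of any active *provocation*
  (a stochastic hypotensive insult: trapezoidal dip of configurable depth
  and duration) and of any active *treatment* (vasoactive: instantaneous
  onset with exponential decay; volume: linear ramp then decay).
* **Predictive index** — a 0-100 proxy for a hypotension early-warning
  index: a saturating (logistic) transform of the noise-free MAP minimum
  projected over the next 15 min, plus bounded observation noise.  With
  noise off, the index exceeds the alarm threshold strictly before every
  sustained MAP < 65 mmHg crossing, which is what makes the silent-alarm
  reconstruction well-posed.
* **Treatment triggering** — in the guided (intervention) arm a treatment
  follows each *merged* alarm (15-min anchored windows) within the
  configured response delay (<= 2 min); in the standard-of-care (control)
  arm a treatment follows each merged sustained-hypotension episode after
  the configured detection delay.  The option (fluid / vasopressor /
  inotrope / combinations / observation) comes from the hemodynamic
  decision table evaluated on the auxiliary channels at the anchor.
* **Covariates** — age, sex and surgery-type margins calibrated to a
  tertiary-centre major-surgery population (median age ~62 y, ~80 % men,
  median duration ~490 min, pancreas/oral/esophageal cases).

One global seed expands into per-patient substreams keyed by a stable hash
of the patient id, so enlarging the cohort never perturbs existing
patients, and identical configs yield byte-identical CSV products.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Literal, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .config import ProtocolThresholds, SimConfig
from .events import ClinicalEvent, detect_alarm_events, detect_hypotension_events
from .protocol import DecisionInputs, recommend
from .series import VitalSeries

# logistic transform of the projected MAP minimum: index = 85 at a projected
# minimum of ~66.8 mmHg (midpoint - ln(15/85)*scale), saturating toward 100
# as the projected minimum falls well below the hypotension threshold
INDEX_MIDPOINT_MMHG = 72.0
INDEX_SCALE_MMHG = 3.0

#: how long before the MAP starts falling the causal aux derangement is
#: visible (preload loss / vasoplegia precedes the pressure fall; this is
#: what gives a predictive index something to predict from)
AUX_LEAD_MIN = 10.0

MAP_FLOOR, MAP_CEIL = 20.0, 200.0

ARMS = ("intervention", "control")
SURGERY_TYPES = ("pancreas", "oral", "esophagus")


class SimulationError(RuntimeError):
    """Failure inside the stochastic simulation (distinct from I/O errors)."""


class CohortIOError(OSError):
    """Failure writing or reading the cohort bundle."""


@dataclass(frozen=True)
class PatientCovariates:
    patient_id: str
    arm: Literal["intervention", "control"]
    age: float                 # years, trial inclusion range [20, 80]
    sex: Literal["M", "F"]
    surgery_type: str
    surgical_duration: float   # minutes
    baseline_map: float = 85.0 # mmHg

    def __post_init__(self) -> None:
        if self.arm not in ARMS:
            raise ValueError(f"unknown arm {self.arm!r}")
        if not 20.0 <= self.age <= 80.0:
            raise ValueError("age outside the trial inclusion range [20, 80]")
        if self.surgical_duration <= 0:
            raise SimulationError("non-positive surgical duration")


@dataclass(frozen=True)
class Provocation:
    """One hypotensive insult: linear ramp down over `ramp_min` to `depth`
    (negative, mmHg), hold for `duration_min`, linear release."""

    t_start_min: float
    depth: float
    duration_min: float
    cause: Literal["preload", "tone", "contractility"] = "tone"
    ramp_min: float = 3.0

    @property
    def t_end_min(self) -> float:
        return self.t_start_min + self.ramp_min + self.duration_min

    def offset_at(self, t_min: np.ndarray) -> np.ndarray:
        t = np.asarray(t_min, dtype=float)
        up = np.clip((t - self.t_start_min) / self.ramp_min, 0.0, 1.0)
        down = np.clip((t - self.t_end_min) / self.ramp_min, 0.0, 1.0)
        return self.depth * (up - down)


@dataclass(frozen=True)
class TreatmentEffect:
    """Pressure effect of one administered treatment."""

    t_start_min: float
    amplitude: float           # mmHg
    kind: Literal["pressor", "volume"]
    decay_min: float
    ramp_min: float = 5.0      # volume only: linear onset

    def offset_at(self, t_min: np.ndarray) -> np.ndarray:
        t = np.asarray(t_min, dtype=float) - self.t_start_min
        if self.kind == "pressor":
            onset = (t >= 0).astype(float)
            decay = np.exp(-np.maximum(t, 0.0) / self.decay_min)
            return self.amplitude * onset * decay
        onset = np.clip(t / self.ramp_min, 0.0, 1.0)
        decay = np.exp(-np.maximum(t - self.ramp_min, 0.0) / self.decay_min)
        return self.amplitude * onset * decay


# ---------------------------------------------------------------------------
# per-patient random substreams
# ---------------------------------------------------------------------------

def patient_rng(seed: int, patient_id: str) -> np.random.Generator:
    """Generator for one patient, keyed by (global seed, stable id hash)."""
    return np.random.default_rng(np.random.SeedSequence([seed, _stable_hash(patient_id)]))


def _stable_hash(patient_id: str) -> int:
    return zlib.crc32(patient_id.encode())


# ---------------------------------------------------------------------------
# covariates
# ---------------------------------------------------------------------------

def draw_covariates(config: SimConfig, patient_id: str,
                    arm: str, rng: Optional[np.random.Generator] = None) -> PatientCovariates:
    """Draw one patient's covariates from the calibrated margins."""
    rng = rng if rng is not None else patient_rng(config.seed, patient_id)
    age = float(np.clip(rng.normal(60.0, 10.5), 20.0, 80.0))
    sex = "M" if rng.random() < 0.80 else "F"
    surgery = str(rng.choice(SURGERY_TYPES, p=[0.34, 0.36, 0.30]))
    mu, sigma = config.duration_lognorm_params
    duration = float(np.clip(rng.lognormal(mu, sigma), config.duration_min_floor, 1200.0))
    baseline = float(np.clip(rng.normal(config.baseline_map_mean, config.baseline_map_sd),
                             80.0, 96.0))
    return PatientCovariates(patient_id, arm, age, sex, surgery, duration, baseline)


def draw_provocations(config: SimConfig, duration_min: float,
                      rng: np.random.Generator) -> List[Provocation]:
    """Poisson-like provocation schedule at `provocation_rate` events/hour."""
    provs: List[Provocation] = []
    if config.provocation_rate <= 0:
        return provs
    rate_per_min = config.provocation_rate / 60.0
    t = 10.0  # let induction settle
    lo, hi = config.provocation_depth_range
    while True:
        t += float(rng.exponential(1.0 / rate_per_min))
        if t >= duration_min - 5.0:
            break
        depth = float(rng.uniform(lo, hi))
        dur = float(np.clip(rng.exponential(config.provocation_duration_mean), 2.0, 30.0))
        cause = str(rng.choice(["preload", "tone", "contractility"], p=[0.45, 0.35, 0.20]))
        provs.append(Provocation(t, depth, dur, cause, config.provocation_ramp_min))
        t += dur + 2 * config.provocation_ramp_min  # no overlapping insults
    return provs


# ---------------------------------------------------------------------------
# auxiliary hemodynamics
# ---------------------------------------------------------------------------

_AUX_BASE = {"svv_pct": (9.0, 1.5, 4.0, 12.5), "eadyn": (1.05, 0.08, 0.85, 1.4),
             "dpdtmax": (800.0, 100.0, 560.0, 1200.0), "svr": (1150.0, 150.0, 850.0, 1600.0)}


def _draw_aux(provs: Sequence[Provocation], t_min: np.ndarray,
              rng: np.random.Generator) -> pd.DataFrame:
    """Auxiliary channels: per-patient baseline plus cause-linked shifts that
    begin AUX_LEAD_MIN before each provocation's pressure fall."""
    cols = {}
    for name, (mu, sd, lo, hi) in _AUX_BASE.items():
        base = float(np.clip(rng.normal(mu, sd), lo, hi))
        cols[name] = np.full(t_min.size, base) + rng.normal(0.0, 0.03 * mu, t_min.size)
    for p in provs:
        win = (t_min >= p.t_start_min - AUX_LEAD_MIN) & (t_min <= p.t_end_min + p.ramp_min)
        if p.cause == "preload":
            cols["svv_pct"][win] += 8.0
            if rng.random() < 0.5:
                cols["eadyn"][win] -= 0.30
        elif p.cause == "tone":
            cols["svr"][win] -= 450.0
            cols["eadyn"][win] -= 0.30
        else:  # contractility
            cols["dpdtmax"][win] -= 400.0
            if rng.random() < 0.4:
                cols["svv_pct"][win] += 8.0
    cols["svv_pct"] = np.clip(cols["svv_pct"], 0.5, 30.0)
    cols["eadyn"] = np.clip(cols["eadyn"], 0.3, 2.0)
    cols["dpdtmax"] = np.clip(cols["dpdtmax"], 150.0, 2000.0)
    cols["svr"] = np.clip(cols["svr"], 300.0, 2500.0)
    return pd.DataFrame(cols)


# ---------------------------------------------------------------------------
# MAP path integration
# ---------------------------------------------------------------------------

def _ou_coeffs(config: SimConfig) -> Tuple[float, float]:
    """Exact OU discretisation over one cadence step: (decay, noise scale)."""
    dt = config.cadence_s / 60.0
    theta = config.ou_reversion_rate
    if theta <= 0:
        return 1.0, config.ou_noise_sd * np.sqrt(dt)
    a = float(np.exp(-theta * dt))
    s = config.ou_noise_sd * np.sqrt((1.0 - a * a) / (2.0 * theta))
    return a, float(s)


def _integrate(targets: np.ndarray, x0: float, a: float, s: float,
               shocks: Optional[np.ndarray]) -> np.ndarray:
    n = targets.size
    x = np.empty(n)
    x[0] = x0
    z = shocks if shocks is not None else np.zeros(n)
    for k in range(1, n):
        x[k] = targets[k] + (x[k - 1] - targets[k]) * a + s * z[k]
    return np.clip(x, MAP_FLOOR, MAP_CEIL)


def simulate_map_series(config: SimConfig, covariates: PatientCovariates,
                        rng_stream: np.random.Generator,
                        provocations: Optional[Sequence[Provocation]] = None) -> VitalSeries:
    """Untreated MAP path for one patient (mean-reverting toward baseline plus
    any active provocation offset), with auxiliary channels attached."""
    if covariates.surgical_duration <= 0:
        raise SimulationError("non-positive surgical duration")
    n = int(covariates.surgical_duration * 60.0 // config.cadence_s) + 1
    t = np.arange(n) * config.cadence_s
    t_min = t / 60.0
    if provocations is None:
        provocations = draw_provocations(config, covariates.surgical_duration, rng_stream)
    prov_offset = np.zeros(n)
    for p in provocations:
        prov_offset += p.offset_at(t_min)
    a, s = _ou_coeffs(config)
    shocks = rng_stream.standard_normal(n)
    targets = covariates.baseline_map + prov_offset
    x = _integrate(targets, covariates.baseline_map, a, s, shocks)
    aux = _draw_aux(provocations, t_min, rng_stream)
    return VitalSeries(
        patient_id=covariates.patient_id, cadence_s=config.cadence_s, t=t, map=x,
        aux=aux, surgical_duration=covariates.surgical_duration, shocks=shocks,
        meta={"baseline": covariates.baseline_map, "provocations": list(provocations),
              "treatments": [], "arm": covariates.arm})


# ---------------------------------------------------------------------------
# predictive index
# ---------------------------------------------------------------------------

def _index_from_projected_min(projected_min: np.ndarray) -> np.ndarray:
    return 100.0 / (1.0 + np.exp((projected_min - INDEX_MIDPOINT_MMHG) / INDEX_SCALE_MMHG))


class _Projector:
    """Noise-free forward projection of the MAP mean path on the 20-s grid.

    The reversion target (baseline + provocations + treatments given so far)
    is tabulated on the sample grid extended past the horizon; a projection
    from sample k relaxes the current deterministic state across the next
    `horizon` samples with the exact OU decay and takes the minimum of the
    *risk-discounted* values: a dip j minutes away is counted
    `index_risk_discount * max(0, j - 1)` mmHg shallower.  Because the
    projection replicates the deterministic path recurrence sample for
    sample, the first minute ahead carries no discount, which makes the
    alarm strictly precede every sustained sub-65 crossing when noise is
    off, while remote dips raise the index only gradually (alarms lead by
    minutes, not by the full horizon).
    """

    def __init__(self, config: SimConfig, baseline: float,
                 provocations: Sequence[Provocation], n_samples: int):
        cadence_min = config.cadence_s / 60.0
        self.h = int(round(config.index_horizon_min / cadence_min))
        n_ext = n_samples + self.h + 1
        grid = np.arange(n_ext) * cadence_min
        tgt = np.full(n_ext, baseline)
        for p in provocations:
            tgt += p.offset_at(grid)
        self.grid_min = grid
        self.target = tgt
        self.a = float(np.exp(-config.ou_reversion_rate * cadence_min)) \
            if config.ou_reversion_rate > 0 else 1.0
        # discount per projection step: delta * max(0, t_j - 1 min)
        tj = np.arange(1, self.h + 1) * cadence_min
        self.penalty = config.index_risk_discount * np.maximum(0.0, tj - 1.0)

    def add_treatment(self, eff: TreatmentEffect) -> None:
        self.target += eff.offset_at(self.grid_min)

    def projected_min(self, k: int, x_det: float) -> float:
        return self.projected_mins(k, x_det)[0]

    def projected_mins(self, k: int, x_det: float) -> tuple[float, float]:
        """(risk-discounted minimum, raw minimum) over the horizon."""
        y = x_det
        m = x_det
        raw = x_det
        tgt = self.target
        a = self.a
        pen = self.penalty
        for j in range(self.h):
            T = tgt[k + 1 + j]
            y = T + (y - T) * a
            if y < raw:
                raw = y
            v = y + pen[j]
            if v < m:
                m = v
        return m, raw


def simulate_index_series(map_series: VitalSeries, config: SimConfig,
                          rng_stream: np.random.Generator) -> VitalSeries:
    """Fill the predictive-index channel of an (untreated) series.

    The index is the logistic transform of the projected 15-min minimum of
    the noise-free mean path, plus bounded noise, clamped to [0, 100].
    """
    meta = map_series.meta
    if "provocations" not in meta:
        raise SimulationError("series lacks generator metadata; cannot project the mean path")
    baseline = meta["baseline"]
    n = map_series.n
    proj = _Projector(config, baseline, meta["provocations"], n)
    for eff in meta.get("treatments", []):
        proj.add_treatment(eff)
    a, _ = _ou_coeffs(config)
    t_min = map_series.t / 60.0
    # deterministic twin of the MAP path (same dynamics, zero noise)
    tgt20 = np.full(n, baseline)
    for p in meta["provocations"]:
        tgt20 += p.offset_at(t_min)
    for eff in meta.get("treatments", []):
        tgt20 += eff.offset_at(t_min)
    xd = _integrate(tgt20, baseline, a, 0.0, None)
    pmin = np.empty(n)
    for k in range(n):
        pmin[k] = proj.projected_min(k, xd[k])
    noise = meta.get("index_noise")
    if noise is None:
        noise = rng_stream.normal(0.0, config.index_noise_sd, n) \
            if config.index_noise_sd > 0 else np.zeros(n)
    index = np.clip(_index_from_projected_min(pmin) + noise, 0.0, 100.0)
    out = VitalSeries(map_series.patient_id, map_series.cadence_s, map_series.t,
                      map_series.map, index=index, aux=map_series.aux,
                      surgical_duration=map_series.surgical_duration,
                      shocks=map_series.shocks,
                      meta={**meta, "index_noise": noise})
    return out


# ---------------------------------------------------------------------------
# treatments
# ---------------------------------------------------------------------------

def _draw_response_delay(config: SimConfig, arm: str, rng: np.random.Generator) -> float:
    if arm == "intervention":
        d = float(rng.lognormal(np.log(40.0), 0.55))
        return float(np.clip(d, 10.0, config.intervention_response_delay_s))
    # control: clinician reacts to the observed sustained MAP < 65
    return float(rng.uniform(config.control_detection_delay_s - 5.0,
                             config.control_detection_delay_s + 10.0))


def _decide_option(series_aux: Optional[pd.DataFrame], k: int, map_now: float,
                   thresholds: ProtocolThresholds) -> tuple[str, tuple]:
    if series_aux is None:
        # no auxiliary channels to diagnose from: default to a vasopressor
        return "vasopressor", ("no_aux_channels:default_vasopressor",)
    row = series_aux.iloc[k]
    inputs = DecisionInputs(svv=float(row["svv_pct"]), eadyn=float(row["eadyn"]),
                            dpdtmax=float(row["dpdtmax"]), svr=float(row["svr"]),
                            cardiac_index=3.0, map=map_now)
    out = recommend(inputs, thresholds)
    return out.option, out.rationale_path


def simulate_treatments(map_series: VitalSeries, index_series: VitalSeries, arm: str,
                        config: SimConfig, rng_stream: np.random.Generator,
                        thresholds: Optional[ProtocolThresholds] = None,
                        effects_enabled: bool = True
                        ) -> Tuple[List[ClinicalEvent], VitalSeries]:
    """Run the arm-specific treatment policy and re-integrate the MAP path.

    The guided arm treats each merged alarm (upward index crossing opening a
    15-min anchored window) within the configured response delay; the
    standard-of-care arm treats each merged sustained-hypotension episode
    after the detection delay.  Each non-observation treatment injects a
    pressure effect into the path going forward; the path is re-integrated
    on the identical noise innovations as the untreated series, and the
    index is recomputed causally (a treatment affects projections only once
    given).  Returns the full event log (alarms, hypotension onsets,
    treatments) and the treated series.
    """
    if arm not in ARMS:
        raise ValueError(f"unknown arm {arm!r}")
    thresholds = thresholds or ProtocolThresholds()
    meta = map_series.meta
    if "provocations" not in meta:
        raise SimulationError("series lacks generator metadata")
    baseline = meta["baseline"]
    provocations = meta["provocations"]
    n = map_series.n
    t = map_series.t
    t_min = t / 60.0
    cadence_min = config.cadence_s / 60.0
    a, s = _ou_coeffs(config)
    shocks = map_series.shocks if map_series.shocks is not None else np.zeros(n)
    idx_noise = index_series.meta.get("index_noise")
    if idx_noise is None:
        idx_noise = np.zeros(n)

    tgt20 = np.full(n, baseline)
    for p in provocations:
        tgt20 += p.offset_at(t_min)
    proj = _Projector(config, baseline, provocations, n)

    window_s = config.merge_window_min * 60.0
    thr = config.index_alarm_threshold
    min_run = int(np.ceil(60.0 / config.cadence_s - 1e-9))

    x = np.empty(n)
    xd = np.empty(n)
    index = np.empty(n)
    x[0] = xd[0] = baseline
    applied: List[TreatmentEffect] = []
    treatment_events: List[ClinicalEvent] = []
    pending: List[tuple] = []  # (t_treat_s, option, amplitude, kind)
    last_alarm_anchor = -np.inf
    last_ht_anchor = -np.inf
    run_len = 0
    prev_index = 0.0

    amp_lo, amp_hi = config.treatment_effect_amplitude_range
    for k in range(n):
        # activate any treatment due by this sample time
        while pending and pending[0][0] <= t[k]:
            t_treat, option, amp, kind = pending.pop(0)
            treatment_events.append(ClinicalEvent(map_series.patient_id, t_treat,
                                                  "treatment", treatment_option=option))
            if effects_enabled and option != "observation":
                eff = TreatmentEffect(t_treat / 60.0, amp, kind,
                                      config.treatment_effect_decay_min,
                                      config.fluid_ramp_min)
                applied.append(eff)
                live = t >= t_treat - 1e-9
                tgt20[live] += eff.offset_at(t_min[live])
                proj.add_treatment(eff)

        if k > 0:
            x[k] = tgt20[k] + (x[k - 1] - tgt20[k]) * a + s * shocks[k]
            xd[k] = tgt20[k] + (xd[k - 1] - tgt20[k]) * a
        x[k] = min(max(x[k], MAP_FLOOR), MAP_CEIL)
        pmin, raw_min = proj.projected_mins(k, xd[k])
        index[k] = min(max(_index_from_projected_min(np.array([pmin]))[0]
                           + idx_noise[k], 0.0), 100.0)

        # clinicians titrate the dose to the (projected) pressure deficit
        def _amplitude() -> float:
            deficit = max(baseline - raw_min, 5.0)
            return float(np.clip(rng_stream.uniform(0.9, 1.3) * deficit, amp_lo, amp_hi))

        if arm == "intervention":
            crossing = index[k] > thr and (k == 0 or prev_index <= thr)
            if crossing and t[k] - last_alarm_anchor >= window_s:
                last_alarm_anchor = t[k]
                delay = _draw_response_delay(config, "intervention", rng_stream)
                option, _ = _decide_option(map_series.aux, k, x[k], thresholds)
                kind = "volume" if option == "fluid" else "pressor"
                pending.append((t[k] + delay, option, _amplitude(), kind))
                pending.sort()
        # both arms treat observed sustained hypotension (target MAP >= 65
        # everywhere); in the guided arm this is the rescue path on top of
        # the alarm-triggered pre-emptive treatments
        run_len = run_len + 1 if x[k] < 65.0 else 0
        if run_len == min_run:
            onset = t[k - min_run + 1]
            if onset - last_ht_anchor >= window_s:
                last_ht_anchor = onset
                delay = _draw_response_delay(config, "control", rng_stream)
                k_on = k - min_run + 1
                option, _ = _decide_option(map_series.aux, k_on, x[k_on], thresholds)
                kind = "volume" if option == "fluid" else "pressor"
                pending.append((onset + delay, option, _amplitude(), kind))
                pending.sort()
        prev_index = index[k]

    treated = VitalSeries(map_series.patient_id, config.cadence_s, t, x,
                          index=index, aux=map_series.aux,
                          surgical_duration=map_series.surgical_duration,
                          shocks=shocks,
                          meta={**meta, "treatments": applied, "index_noise": idx_noise})
    log = list(treatment_events)
    log += detect_alarm_events(treated, alarm_threshold=thr)
    log += detect_hypotension_events(treated)
    log.sort(key=lambda e: (e.time_s, e.event_type))
    return log, treated


# ---------------------------------------------------------------------------
# cohort bundle
# ---------------------------------------------------------------------------

@dataclass
class CohortBundle:
    cohort: pd.DataFrame                       # one row per patient
    series: dict = field(default_factory=dict) # patient_id -> VitalSeries
    events: dict = field(default_factory=dict) # patient_id -> [ClinicalEvent]
    config: Optional[SimConfig] = None

    def write(self, out_dir: str | Path) -> dict:
        """Write cohort.csv, vitals_*.csv, events_*.csv; returns path map."""
        out = Path(out_dir)
        try:
            out.mkdir(parents=True, exist_ok=True)
            paths = {"cohort": out / "cohort.csv"}
            self.cohort.to_csv(paths["cohort"], index=False, float_format="%.4f")
            for pid, ser in self.series.items():
                p = out / f"vitals_{pid}.csv"
                ser.to_csv(p)
                paths[f"vitals_{pid}"] = p
            for pid, evs in self.events.items():
                p = out / f"events_{pid}.csv"
                pd.DataFrame(
                    [{"time_s": e.time_s, "event_type": e.event_type,
                      "detail": e.treatment_option} for e in evs],
                    columns=["time_s", "event_type", "detail"],
                ).to_csv(p, index=False, float_format="%.4f")
                paths[f"events_{pid}"] = p
        except OSError as exc:
            raise CohortIOError(f"cannot write cohort bundle to {out}: {exc}") from exc
        return paths

    @classmethod
    def read(cls, in_dir: str | Path) -> "CohortBundle":
        src = Path(in_dir)
        try:
            cohort = pd.read_csv(src / "cohort.csv")
        except OSError as exc:
            raise CohortIOError(f"cannot read cohort bundle from {src}: {exc}") from exc
        series, events = {}, {}
        for _, row in cohort.iterrows():
            pid = row["patient_id"]
            series[pid] = VitalSeries.from_csv(src / f"vitals_{pid}.csv", patient_id=pid,
                                               surgical_duration=float(row["duration_min"]))
            ev_path = src / f"events_{pid}.csv"
            evs = []
            if ev_path.exists():
                df = pd.read_csv(ev_path, keep_default_na=False)
                for _, r in df.iterrows():
                    evs.append(ClinicalEvent(pid, float(r["time_s"]), r["event_type"],
                                             treatment_option=str(r["detail"])))
            events[pid] = evs
        return cls(cohort=cohort, series=series, events=events)


def simulate_patient(config: SimConfig, covariates: PatientCovariates,
                     thresholds: Optional[ProtocolThresholds] = None
                     ) -> Tuple[VitalSeries, List[ClinicalEvent]]:
    """Full simulation of one patient from their dedicated substream."""
    rng = patient_rng(config.seed, covariates.patient_id)
    untreated = simulate_map_series(config, covariates, rng)
    indexed = simulate_index_series(untreated, config, rng)
    log, treated = simulate_treatments(indexed, indexed, covariates.arm,
                                       config, rng, thresholds)
    return treated, log


def generate_cohort(config: SimConfig,
                    thresholds: Optional[ProtocolThresholds] = None,
                    out_dir: Optional[str | Path] = None) -> CohortBundle:
    """Generate the full two-arm cohort (1:1 allocation), optionally writing
    the three CSV products.  Deterministic under (config, seed)."""
    rows = []
    series: dict = {}
    events: dict = {}
    for arm, prefix in (("intervention", "I"), ("control", "C")):
        for i in range(1, config.n_per_arm + 1):
            pid = f"{prefix}{i:03d}"
            cov = draw_covariates(config, pid, arm)
            treated, log = simulate_patient(config, cov, thresholds)
            series[pid] = treated
            events[pid] = log
            rows.append({"patient_id": pid, "arm": arm, "age": round(cov.age, 1),
                         "sex": cov.sex, "surgery_type": cov.surgery_type,
                         "duration_min": round(cov.surgical_duration, 1)})
    bundle = CohortBundle(cohort=pd.DataFrame(rows), series=series,
                          events=events, config=config)
    if out_dir is not None:
        bundle.write(out_dir)
    return bundle
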