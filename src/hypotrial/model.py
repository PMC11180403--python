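"""Trial-level analysis: a model object over the cohort bundle whose
``fit()`` reproduces the trial's comparison tables.

The central objects follow the estimator/results split of the statistical
modelling tradition:

* :class:`HypotensionTrial` — built from a cohort table plus per-patient
  vital series and event logs (from the simulator, or from CSVs on disk);
* :class:`HypotensionTrialResults` — per-patient burden metrics and the
  four group-comparison tables (baseline characteristics; hypotension
  burden and clinician behaviour; treatment-option usage; safety), each row
  a :class:`~hypotrial.stats.StatResult` with the estimate, CI, p-value
  and the test that produced it.

Continuous skewed outcomes are compared with the Mann-Whitney U test and
summarised by the Hodges-Lehmann median difference (control minus
intervention); symmetric ones with the pooled t-test; proportions with the
chi-square/Fisher rule.  Latencies are summarised per patient (median
seconds from anchor to first treatment) before group comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import burden as bd
from . import events as ev
from . import stats as st
from .cohort import CohortBundle, generate_cohort
from .config import ProtocolThresholds, SimConfig
from .series import VitalSeries

ARMS = ("intervention", "control")


class HypotensionTrial:
    """Two-arm trial of predictive-alarm-guided vs reactive hypotension
    management, over one cohort bundle."""

    def __init__(self, cohort: pd.DataFrame, series: Dict[str, VitalSeries],
                 events: Dict[str, List[ev.ClinicalEvent]],
                 config: Optional[SimConfig] = None):
        required = {"patient_id", "arm", "age", "sex", "surgery_type", "duration_min"}
        missing = required - set(cohort.columns)
        if missing:
            raise ValueError(f"cohort table missing columns {sorted(missing)}")
        unknown_arms = set(cohort["arm"]) - set(ARMS)
        if unknown_arms:
            raise ValueError(f"unknown arm labels {sorted(unknown_arms)}")
        self.cohort = cohort.reset_index(drop=True)
        self.series = series
        self.events = events
        self.config = config

    # -- constructors -------------------------------------------------------

    @classmethod
    def from_bundle(cls, bundle: CohortBundle) -> "HypotensionTrial":
        return cls(bundle.cohort, bundle.series, bundle.events, bundle.config)

    @classmethod
    def from_csv(cls, in_dir: str | Path) -> "HypotensionTrial":
        return cls.from_bundle(CohortBundle.read(in_dir))

    @classmethod
    def simulate(cls, config: SimConfig,
                 thresholds: Optional[ProtocolThresholds] = None) -> "HypotensionTrial":
        return cls.from_bundle(generate_cohort(config, thresholds))

    # -- per-patient metrics ------------------------------------------------

    def patient_metrics(self, thresholds: Sequence[float] = (65.0, 60.0, 55.0),
                        hypertension_threshold: float = 130.0,
                        merge_window_min: float = 15.0,
                        alarm_threshold: float = 85.0) -> pd.DataFrame:
        """One row per patient: burden at each threshold, MAP summary,
        treatment counts and anchor-to-first-treatment latencies."""
        rows = []
        for _, r in self.cohort.iterrows():
            pid = r["patient_id"]
            ser = self.series[pid]
            log = self.events.get(pid, [])
            treatments = sorted((e for e in log if e.event_type == "treatment"),
                                key=lambda e: e.time_s)
            row = {"patient_id": pid, "arm": r["arm"],
                   "duration_min": float(ser.surgical_duration),
                   "n_treatments": len(treatments)}
            for thr in thresholds:
                b = bd.threshold_burden(ser, thr, "below")
                key = f"{int(thr)}"
                row[f"twa_below_{key}"] = b.twa
                row[f"auc_below_{key}"] = b.auc
                row[f"dur_below_{key}"] = b.duration
            bh = bd.threshold_burden(ser, hypertension_threshold, "above")
            row["twa_above_130"] = bh.twa
            summ = bd.case_map_summary(ser)
            row["map_median"] = summ["median"]
            row["map_mean"] = summ["mean"]

            ht_anchors = ev.anchors_of(ev.merge_events(
                [e for e in log if e.event_type == "hypotension_onset"], merge_window_min))
            row["n_hypotension_events"] = len(ht_anchors)
            if r["arm"] == "intervention":
                at_anchors = ev.anchors_of(ev.merge_events(
                    [e for e in log if e.event_type == "alarm"], merge_window_min))
                lat = ev.compute_latencies(at_anchors, treatments, "AT", merge_window_min)
                treated = [x.latency_s for x in lat if x.treated]
                row["latency_primary_s"] = float(np.median(treated)) if treated else np.nan
                row["latency_silent_s"] = row["latency_primary_s"]
                row["n_anchors"] = len(at_anchors)
            else:
                lat = ev.compute_latencies(ht_anchors, treatments, "HT", merge_window_min)
                treated = [x.latency_s for x in lat if x.treated]
                row["latency_primary_s"] = float(np.median(treated)) if treated else np.nan
                row["n_anchors"] = len(ht_anchors)
                if ser.index is not None:
                    sats = {a.event_id: s for a, s in zip(
                        ht_anchors, _sat_lookup(ser, ht_anchors, alarm_threshold,
                                                merge_window_min))}
                    sat_lat = []
                    for a, x in zip(ht_anchors, lat):
                        s = sats.get(a.event_id)
                        if s is not None and x.treated:
                            sat_lat.append(x.first_treatment_time_s - s.time_s)
                    row["latency_silent_s"] = float(np.median(sat_lat)) if sat_lat else np.nan
                else:
                    row["latency_silent_s"] = np.nan
            rows.append(row)
        return pd.DataFrame(rows)

    # -- fitting ------------------------------------------------------------

    def fit(self, thresholds: Sequence[float] = (65.0, 60.0, 55.0),
            hypertension_threshold: float = 130.0) -> "HypotensionTrialResults":
        metrics = self.patient_metrics(thresholds, hypertension_threshold)
        return HypotensionTrialResults(self, metrics, tuple(thresholds),
                                       hypertension_threshold)


def _sat_lookup(ser: VitalSeries, anchors, alarm_threshold, window_min):
    """Silent alarms aligned with their anchors (None where unreconstructable)."""
    sats = ev.silent_alarm_times(ser, anchors, alarm_threshold, window_min)
    out = []
    i = 0
    for a in anchors:
        if i < len(sats) and sats[i].time_s <= a.time_s and \
                (a.time_s - sats[i].time_s) <= window_min * 60.0:
            out.append(sats[i])
            i += 1
        else:
            out.append(None)
    return out


# ---------------------------------------------------------------------------
# results
# ---------------------------------------------------------------------------

@dataclass
class HypotensionTrialResults:
    model: HypotensionTrial
    metrics: pd.DataFrame
    thresholds: Tuple[float, ...]
    hypertension_threshold: float
    _tables: Dict[str, pd.DataFrame] = field(default_factory=dict, init=False)

    def __post_init__(self) -> None:
        self._build_tables()

    # -- helpers ------------------------------------------------------------

    def _split(self, col: str, df: Optional[pd.DataFrame] = None):
        d = self.metrics if df is None else df
        iv = d.loc[d["arm"] == "intervention", col].dropna().to_numpy(float)
        cv = d.loc[d["arm"] == "control", col].dropna().to_numpy(float)
        return iv, cv

    @staticmethod
    def _median_row(name: str, iv: np.ndarray, cv: np.ndarray) -> dict:
        hl = st.hodges_lehmann(iv, cv)  # control minus intervention
        return {"outcome": name,
                "intervention": _miqr(iv), "control": _miqr(cv),
                "estimate": hl.estimate, "ci_low": hl.ci_low, "ci_high": hl.ci_high,
                "p_value": hl.p_value, "test": "mann_whitney/hodges_lehmann"}

    @staticmethod
    def _mean_row(name: str, iv: np.ndarray, cv: np.ndarray) -> dict:
        r = st.t_test_from_summary(float(np.mean(iv)), float(np.std(iv, ddof=1)), iv.size,
                                   float(np.mean(cv)), float(np.std(cv, ddof=1)), cv.size)
        return {"outcome": name,
                "intervention": _msd(iv), "control": _msd(cv),
                "estimate": r.estimate, "ci_low": r.ci_low, "ci_high": r.ci_high,
                "p_value": r.p_value, "test": "pooled_t"}

    def _prop_row(self, name: str, x_iv: int, n_iv: int, x_cv: int, n_cv: int) -> dict:
        try:
            test = st.compare_proportions(x_iv, n_iv - x_iv, x_cv, n_cv - x_cv)
            p, test_name = test.p_value, test.test_name
        except ValueError:  # degenerate margin: no test, as in 0/0 rows
            p, test_name = float("nan"), "none"
        ci = st.proportion_diff_ci(x_iv, n_iv, x_cv, n_cv, p_value=p)
        return {"outcome": name,
                "intervention": f"{x_iv} ({100 * x_iv / n_iv:.1f}%)",
                "control": f"{x_cv} ({100 * x_cv / n_cv:.1f}%)",
                "estimate": ci.estimate, "ci_low": ci.ci_low, "ci_high": ci.ci_high,
                "p_value": p, "test": test_name}

    # -- table assembly -----------------------------------------------------

    def _build_tables(self) -> None:
        cohort = self.model.cohort
        iv_n = int((cohort["arm"] == "intervention").sum())
        cv_n = int((cohort["arm"] == "control").sum())

        # table 1: baseline characteristics
        rows = []
        iv, cv = self._split("age", cohort)
        rows.append(self._mean_row("Age, years", iv, cv))
        male_iv = int(((cohort["arm"] == "intervention") & (cohort["sex"] == "M")).sum())
        male_cv = int(((cohort["arm"] == "control") & (cohort["sex"] == "M")).sum())
        rows.append(self._prop_row("Men, n (%)", male_iv, iv_n, male_cv, cv_n))
        for surg in sorted(cohort["surgery_type"].unique()):
            a = int(((cohort["arm"] == "intervention") & (cohort["surgery_type"] == surg)).sum())
            b = int(((cohort["arm"] == "control") & (cohort["surgery_type"] == surg)).sum())
            rows.append(self._prop_row(f"Surgery: {surg}, n (%)", a, iv_n, b, cv_n))
        iv, cv = self._split("duration_min", cohort)
        rows.append(self._mean_row("Surgical duration, min", iv, cv))
        self._tables["table1"] = pd.DataFrame(rows)

        # table 2: hypotension burden and clinician behaviour
        rows = []
        for thr in self.thresholds:
            key = f"{int(thr)}"
            for metric, label in (("twa", "TWA-MAP"), ("auc", "AUC"), ("dur", "Duration of MAP")):
                col = f"{metric}_below_{key}"
                iv, cv = self._split(col)
                unit = {"twa": "mmHg", "auc": "mmHg*min", "dur": "min"}[metric]
                rows.append(self._median_row(f"{label} < {key} mmHg, {unit}", iv, cv))
        iv, cv = self._split("map_median")
        rows.append(self._median_row("Median MAP during surgery, mmHg", iv, cv))
        iv, cv = self._split("n_treatments")
        rows.append(self._median_row("Number of treatments per patient", iv, cv))
        iv, cv = self._split("latency_primary_s")
        rows.append(self._median_row("Duration from AT or HT to FTT, s", iv, cv))
        iv, cv = self._split("latency_silent_s")
        rows.append(self._median_row("Duration from AT or SAT to FTT, s", iv, cv))
        self._tables["table2"] = pd.DataFrame(rows)

        # table 3: treatment-option usage (any use per patient)
        rows = []
        for option in ev.TREATMENT_OPTIONS:
            used = {pid: any(e.event_type == "treatment" and e.treatment_option == option
                             for e in self.model.events.get(pid, []))
                    for pid in cohort["patient_id"]}
            arm = cohort.set_index("patient_id")["arm"]
            a = sum(1 for pid, u in used.items() if u and arm[pid] == "intervention")
            b = sum(1 for pid, u in used.items() if u and arm[pid] == "control")
            if a + b == 0:
                continue
            rows.append(self._prop_row(f"{option.replace('_', ' ')}, n (%)",
                                       a, iv_n, b, cv_n))
        self._tables["table3"] = pd.DataFrame(rows)

        # table 4: safety — overtreatment and hypotensive-event counts
        rows = []
        iv, cv = self._split("twa_above_130")
        rows.append(self._median_row(
            f"TWA-MAP > {int(self.hypertension_threshold)} mmHg, mmHg", iv, cv))
        iv, cv = self._split("n_hypotension_events")
        rows.append(self._median_row("Hypotensive events per patient", iv, cv))
        any_iv = int(((self.metrics["arm"] == "intervention")
                      & (self.metrics["n_hypotension_events"] > 0)).sum())
        any_cv = int(((self.metrics["arm"] == "control")
                      & (self.metrics["n_hypotension_events"] > 0)).sum())
        rows.append(self._prop_row("Any hypotensive event, n (%)",
                                   any_iv, iv_n, any_cv, cv_n))
        self._tables["table4"] = pd.DataFrame(rows)

    # -- public surface -----------------------------------------------------

    @property
    def tables(self) -> Dict[str, pd.DataFrame]:
        return dict(self._tables)

    def table(self, name: str) -> pd.DataFrame:
        return self._tables[name].copy()

    @property
    def primary_outcome(self) -> st.StatResult:
        """TWA-MAP below the primary threshold: Hodges-Lehmann difference
        (control minus intervention) with Mann-Whitney p."""
        iv, cv = self._split(f"twa_below_{int(self.thresholds[0])}")
        return st.hodges_lehmann(iv, cv)

    def save(self, out_dir: str | Path) -> Dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {}
        for name, df in self._tables.items():
            p = out / f"{name}.csv"
            df.to_csv(p, index=False, float_format="%.4f")
            paths[name] = p
        p = out / "patient_metrics.csv"
        self.metrics.to_csv(p, index=False, float_format="%.6f")
        paths["patient_metrics"] = p
        return paths

    def summary(self) -> str:
        from .report import render_tables
        head = (f"Two-arm hypotension-management trial analysis\n"
                f"n = {len(self.model.cohort)} patients "
                f"({int((self.model.cohort['arm'] == 'intervention').sum())} guided, "
                f"{int((self.model.cohort['arm'] == 'control').sum())} standard of care)\n")
        return head + render_tables(self._tables)


def _miqr(x: np.ndarray, nd: int = 2) -> str:
    if x.size == 0:
        return "-"
    q1, m, q3 = np.percentile(x, [25, 50, 75])
    return f"{m:.{nd}f} [{q1:.{nd}f}, {q3:.{nd}f}]"


def _msd(x: np.ndarray, nd: int = 1) -> str:
    if x.size == 0:
        return "-"
    return f"{np.mean(x):.{nd}f} ± {np.std(x, ddof=1):.{nd}f}"
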