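"""Synthetic cohort generator: determinism, dynamics, lead-time property."""

import numpy as np
import pytest

from hypotrial.config import SimConfig
from hypotrial.cohort import (PatientCovariates, Provocation, draw_covariates,
                              generate_cohort, patient_rng, simulate_index_series,
                              simulate_map_series, simulate_patient,
                              simulate_treatments)
from hypotrial.events import (anchors_of, detect_hypotension_events, merge_events,
                              silent_alarm_times)
from hypotrial.burden import auc_below, twa


QUIET = dict(provocation_rate=0.0, ou_noise_sd=0.0, index_noise_sd=0.0)


def covariates(pid="T001", arm="control", baseline=85.0, duration=300.0):
    return PatientCovariates(pid, arm, 60.0, "M", "pancreas", duration, baseline)


class TestMapSeries:
    def test_no_disturbance_no_noise_is_constant(self):
        cfg = SimConfig(seed=1, **QUIET)
        ser = simulate_map_series(cfg, covariates(), patient_rng(1, "T001"))
        assert np.allclose(ser.map, 85.0)

    def test_forced_provocation_reaches_depth(self):
        cfg = SimConfig(seed=1, **QUIET)
        prov = [Provocation(t_start_min=60.0, depth=-25.0, duration_min=12.0)]
        ser = simulate_map_series(cfg, covariates(), patient_rng(1, "T001"),
                                  provocations=prov)
        assert ser.map.min() < 85.0 - 15.0

    def test_same_seed_same_series(self):
        cfg = SimConfig(seed=9)
        a = simulate_map_series(cfg, covariates(), patient_rng(9, "T001"))
        b = simulate_map_series(cfg, covariates(), patient_rng(9, "T001"))
        assert np.array_equal(a.map, b.map)

    def test_sample_grid_and_range(self):
        cfg = SimConfig(seed=2)
        ser = simulate_map_series(cfg, covariates(duration=123.0), patient_rng(2, "T001"))
        assert ser.t[0] == 0.0
        assert np.allclose(np.diff(ser.t), cfg.cadence_s)
        assert ser.t[-1] <= 123.0 * 60.0
        assert np.all((ser.map >= 20.0) & (ser.map <= 200.0))

    def test_nonpositive_duration_rejected(self):
        with pytest.raises(Exception):
            covariates(duration=-5.0)


class TestIndexSeries:
    def test_flat_trace_stays_below_alarm_threshold(self):
        cfg = SimConfig(seed=1, **QUIET)
        cov = covariates(baseline=90.0)
        rng = patient_rng(1, "T001")
        ser = simulate_index_series(simulate_map_series(cfg, cov, rng), cfg, rng)
        assert np.all(ser.index < 85.0)

    def test_alarm_precedes_sub65_crossing(self):
        cfg = SimConfig(seed=1, **QUIET)
        prov = [Provocation(t_start_min=60.0, depth=-30.0, duration_min=15.0)]
        cov = covariates(baseline=85.0)
        rng = patient_rng(1, "T001")
        ser = simulate_index_series(
            simulate_map_series(cfg, cov, rng, provocations=prov), cfg, rng)
        crossing = np.flatnonzero(ser.map < 65.0)
        assert crossing.size > 0
        first_alarm = np.flatnonzero(ser.index > 85.0)
        assert first_alarm.size > 0
        assert ser.t[first_alarm[0]] < ser.t[crossing[0]]

    def test_index_bounded_on_noisy_series(self):
        cfg = SimConfig(seed=3)
        cov = covariates()
        rng = patient_rng(3, "T001")
        ser = simulate_index_series(simulate_map_series(cfg, cov, rng), cfg, rng)
        assert np.all((ser.index >= 0.0) & (ser.index <= 100.0))


class TestTreatments:
    def test_no_alarm_no_hypotension_no_treatments(self):
        cfg = SimConfig(seed=1, **QUIET)
        cov = covariates(baseline=90.0, arm="intervention")
        rng = patient_rng(1, "T001")
        idx = simulate_index_series(simulate_map_series(cfg, cov, rng), cfg, rng)
        log, _ = simulate_treatments(idx, idx, "intervention", cfg, rng)
        assert [e for e in log if e.event_type == "treatment"] == []

    def test_alarm_answered_within_response_window(self):
        cfg = SimConfig(seed=1, **QUIET)
        prov = [Provocation(t_start_min=40.0, depth=-30.0, duration_min=10.0)]
        cov = covariates(arm="intervention", duration=120.0)
        rng = patient_rng(1, "T001")
        idx = simulate_index_series(
            simulate_map_series(cfg, cov, rng, provocations=prov), cfg, rng)
        log, treated = simulate_treatments(idx, idx, "intervention", cfg, rng)
        alarms = sorted(e.time_s for e in log if e.event_type == "alarm")
        treats = sorted(e.time_s for e in log if e.event_type == "treatment")
        assert len(treats) >= 1
        assert 0.0 < treats[0] - alarms[0] <= 120.0

    def test_treatment_lowers_burden_on_same_noise(self):
        cfg = SimConfig(seed=12)
        cov = covariates(arm="control", baseline=82.0, duration=400.0)
        rng = patient_rng(12, "T001")
        base = simulate_map_series(cfg, cov, rng)
        idx = simulate_index_series(base, cfg, rng)
        rng_a = patient_rng(12, "T001-a")
        rng_b = patient_rng(12, "T001-a")  # same substream for both runs
        _, with_tx = simulate_treatments(idx, idx, "control", cfg, rng_a)
        _, without_tx = simulate_treatments(idx, idx, "control", cfg, rng_b,
                                            effects_enabled=False)
        assert twa(auc_below(with_tx, 65.0), with_tx.surgical_duration) < \
            twa(auc_below(without_tx, 65.0), without_tx.surgical_duration)

    def test_unknown_arm_rejected(self):
        cfg = SimConfig(seed=1, **QUIET)
        cov = covariates()
        rng = patient_rng(1, "T001")
        idx = simulate_index_series(simulate_map_series(cfg, cov, rng), cfg, rng)
        with pytest.raises(ValueError):
            simulate_treatments(idx, idx, "placebo", cfg, rng)


class TestSilentAlarmWellPosed:
    def test_every_anchor_has_a_silent_alarm_with_noise_off(self):
        cfg = SimConfig(seed=21, n_per_arm=3, ou_noise_sd=0.0, index_noise_sd=0.0)
        total_anchors = 0
        for i in range(1, 4):
            pid = f"C{i:03d}"
            cov = draw_covariates(cfg, pid, "control")
            ser, _ = simulate_patient(cfg, cov)
            anchors = anchors_of(merge_events(detect_hypotension_events(ser)))
            sats = silent_alarm_times(ser, anchors)
            total_anchors += len(anchors)
            assert len(sats) == len(anchors)
            for s, a in zip(sats, anchors):
                assert s.time_s <= a.time_s
        assert total_anchors > 0  # the check must actually exercise anchors


class TestCohortBundle:
    def test_allocation_counts(self, tiny_bundle, tiny_config):
        assert len(tiny_bundle.cohort) == 2 * tiny_config.n_per_arm
        assert (tiny_bundle.cohort["arm"] == "intervention").sum() == tiny_config.n_per_arm

    def test_byte_identical_csv_outputs(self, tiny_config, tmp_path):
        d1, d2 = tmp_path / "a", tmp_path / "b"
        generate_cohort(tiny_config, out_dir=d1)
        generate_cohort(tiny_config, out_dir=d2)
        for p1 in sorted(d1.iterdir()):
            assert p1.read_bytes() == (d2 / p1.name).read_bytes()

    def test_adding_patients_preserves_existing_substreams(self, tiny_config):
        b_small = generate_cohort(tiny_config)
        b_large = generate_cohort(tiny_config.model_copy(update={"n_per_arm": 3}))
        assert np.array_equal(b_small.series["I001"].map, b_large.series["I001"].map)

    def test_covariate_margins_over_seed_sweep(self):
        # cohort median age stays in the calibrated band across 10 seeds
        ages, durs = [], []
        for seed in range(10):
            cfg = SimConfig(seed=seed, n_per_arm=15)
            rows = [draw_covariates(cfg, f"I{i:03d}", "intervention")
                    for i in range(1, 16)]
            ages.append(np.median([c.age for c in rows]))
            durs.append(np.median([c.surgical_duration for c in rows]))
        assert 50.0 <= np.median(ages) <= 70.0
        assert 300.0 <= np.median(durs) <= 700.0

    def test_event_log_types(self, tiny_bundle):
        for log in tiny_bundle.events.values():
            for e in log:
                assert e.event_type in ("alarm", "hypotension_onset", "treatment")
                assert (e.event_type == "treatment") == bool(e.treatment_option)
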