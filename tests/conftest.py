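"""Shared fixtures: small deterministic cohorts and hand-built series."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from hypotrial.config import SimConfig
from hypotrial.cohort import generate_cohort
from hypotrial.series import VitalSeries


def make_series(map_values, cadence_s=20.0, patient_id="P1", index=None,
                total_duration_min=None, aux=None):
    """A VitalSeries from explicit MAP samples (and optional index)."""
    m = np.asarray(map_values, dtype=float)
    t = np.arange(m.size) * cadence_s
    return VitalSeries(
        patient_id=patient_id, cadence_s=cadence_s, t=t, map=m,
        index=None if index is None else np.asarray(index, dtype=float),
        aux=aux,
        surgical_duration=total_duration_min if total_duration_min is not None
        else t[-1] / 60.0 if m.size > 1 else cadence_s / 60.0)


@pytest.fixture(scope="session")
def tiny_config():
    return SimConfig(seed=11, n_per_arm=2)


@pytest.fixture(scope="session")
def tiny_bundle(tiny_config):
    """Four simulated patients, reused across tests (read-only)."""
    return generate_cohort(tiny_config)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
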