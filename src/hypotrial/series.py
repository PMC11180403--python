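"""Fixed-cadence vital-sign series and their CSV representation.

A :class:`VitalSeries` holds one patient's intraoperative trace: mean
arterial pressure (MAP, mmHg) and a 0-100 predictive index sampled on a
regular grid (20 s by default), plus the auxiliary hemodynamics the
treatment protocol consults (stroke volume variation, dynamic arterial
elastance, systolic slope, systemic vascular resistance).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

VITALS_COLUMNS = ["time_s", "map_mmhg", "index", "svv_pct", "eadyn", "dpdtmax", "svr"]


class SeriesError(ValueError):
    """Invalid or empty vital-sign series."""


@dataclass
class VitalSeries:
    patient_id: str
    cadence_s: float
    t: np.ndarray                      # seconds from case start, strictly increasing
    map: np.ndarray                    # mmHg
    index: Optional[np.ndarray] = None # 0-100, optional channel
    aux: Optional[pd.DataFrame] = None # svv_pct, eadyn, dpdtmax, svr
    surgical_duration: float = 0.0     # minutes; >= last sample time
    # standard-normal innovations of the MAP path; kept so a treated path can
    # be re-integrated on the identical noise realisation
    shocks: Optional[np.ndarray] = field(default=None, repr=False)
    # generator-side metadata (baseline, provocation schedule, noise draws);
    # never serialised, absent on series loaded from CSV
    meta: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.map = np.asarray(self.map, dtype=float)
        if self.t.size == 0:
            raise SeriesError(f"empty series for patient {self.patient_id}")
        if self.t.size != self.map.size:
            raise SeriesError("time and MAP arrays differ in length")
        dt = np.diff(self.t)
        if self.t.size > 1 and not np.allclose(dt, self.cadence_s):
            raise SeriesError("sample times must be evenly spaced at cadence_s")
        valid = np.isnan(self.map) | (np.isfinite(self.map) & (self.map > 0))
        if not np.all(valid):  # NaN marks a monitoring gap; anything else must be positive
            raise SeriesError("MAP values must be positive (NaN marks a gap)")
        if self.surgical_duration <= 0:
            self.surgical_duration = float(self.t[-1]) / 60.0
        if self.surgical_duration * 60.0 + 1e-9 < self.t[-1]:
            raise SeriesError("surgical_duration shorter than the sampled trace")

    @property
    def n(self) -> int:
        return int(self.t.size)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"time_s": self.t, "map_mmhg": self.map})
        df["index"] = self.index if self.index is not None else np.nan
        if self.aux is not None:
            for col in ("svv_pct", "eadyn", "dpdtmax", "svr"):
                df[col] = np.asarray(self.aux[col], dtype=float)
        else:
            for col in ("svv_pct", "eadyn", "dpdtmax", "svr"):
                df[col] = np.nan
        return df[VITALS_COLUMNS]

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.4f")

    @classmethod
    def from_csv(cls, path: str | Path, patient_id: str | None = None,
                 surgical_duration: float | None = None) -> "VitalSeries":
        df = pd.read_csv(path)
        missing = [c for c in ("time_s", "map_mmhg") if c not in df.columns]
        if missing:
            raise SeriesError(f"{path}: missing columns {missing}")
        if len(df) == 0:
            raise SeriesError(f"{path}: empty vitals file")
        t = df["time_s"].to_numpy(float)
        cadence = float(t[1] - t[0]) if len(t) > 1 else 20.0
        index = df["index"].to_numpy(float) if "index" in df else None
        if index is not None and np.all(np.isnan(index)):
            index = None
        aux = None
        if all(c in df.columns for c in ("svv_pct", "eadyn", "dpdtmax", "svr")):
            aux = df[["svv_pct", "eadyn", "dpdtmax", "svr"]].copy()
            if aux.isna().to_numpy().all():
                aux = None
        pid = patient_id or Path(path).stem.replace("vitals_", "")
        return cls(patient_id=pid, cadence_s=cadence, t=t,
                   map=df["map_mmhg"].to_numpy(float), index=index, aux=aux,
                   surgical_duration=surgical_duration or float(t[-1]) / 60.0)
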