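"""Hypotensive-episode detection, alarm analytics and treatment latencies.

Definitions, shared with the cohort generator:

* hypotensive event — MAP < 65 mmHg sustained for at least 1 min (three
  consecutive 20-s samples); the event is anchored at its first sample;
* alarm — upward crossing of the predictive index above 85 (strict ">");
* merging — repeats of either event type within 15 min of the first are one
  event.  Merging is *anchored*: the earliest unmerged event opens a window
  [anchor, anchor + 15 min) and everything inside it merges into the anchor;
  the first event at or beyond the window end becomes the next anchor.
  Windows never chain, so consecutive anchors are always > 15 min apart
  (up to the closed-left/open-right boundary convention);
* silent alarm (SAT) — for the standard-of-care arm, the earliest index
  exceedance in the 15 min preceding (and including) a hypotension anchor:
  the alarm the clinician would have heard, reconstructed post hoc;
* latency — time from an anchor (alarm, hypotension onset or silent alarm)
  to the first treatment in the anchor's 15-min window; each treatment can
  satisfy only one anchor (greedy, earliest anchor first).

All times are 0-based seconds from the first sample; windows are closed on
the left and open on the right.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, List, Literal, Optional, Sequence

import numpy as np

from .series import VitalSeries

EventType = Literal["alarm", "hypotension_onset", "treatment"]

#: treatment options of the hemodynamic protocol
TREATMENT_OPTIONS = (
    "fluid", "vasopressor", "inotrope",
    "fluid_plus_vasopressor", "fluid_plus_inotrope", "observation",
)


@dataclass
class ClinicalEvent:
    patient_id: str
    time_s: float
    event_type: EventType
    treatment_option: str = ""
    merged_into: str = ""
    event_id: str = ""

    def __post_init__(self) -> None:
        if self.time_s < 0:
            raise ValueError("event time must be non-negative")
        if (self.event_type == "treatment") != bool(self.treatment_option):
            raise ValueError("treatment_option must be set iff event_type is 'treatment'")
        if not self.event_id:
            self.event_id = f"{self.patient_id}:{self.event_type}:{self.time_s:g}"


@dataclass(frozen=True)
class LatencyRecord:
    patient_id: str
    anchor_type: Literal["AT", "HT", "SAT"]
    anchor_time_s: float
    first_treatment_time_s: Optional[float]
    latency_s: Optional[float]  # None when no treatment fell in the window

    @property
    def treated(self) -> bool:
        return self.latency_s is not None


def detect_hypotension_events(series: VitalSeries, threshold: float = 65.0,
                              min_duration_s: float = 60.0) -> List[ClinicalEvent]:
    """Onset events of maximal sub-threshold runs lasting >= min_duration_s.

    A run of k consecutive sub-threshold samples spans k*cadence seconds
    (each sample stands for its following interval), so at the 20-s cadence
    the 1-min rule requires >= 3 consecutive samples.
    """
    below = np.asarray(series.map) < threshold
    min_run = int(np.ceil(min_duration_s / series.cadence_s - 1e-9))
    events: List[ClinicalEvent] = []
    i, n = 0, below.size
    while i < n:
        if below[i]:
            j = i
            while j < n and below[j]:
                j += 1
            if j - i >= min_run:
                events.append(ClinicalEvent(series.patient_id, float(series.t[i]),
                                            "hypotension_onset"))
            i = j
        else:
            i += 1
    return events


def detect_alarm_events(series: VitalSeries, alarm_threshold: float = 85.0) -> List[ClinicalEvent]:
    """One alarm per upward crossing of the index above the threshold (strict)."""
    if series.index is None:
        raise ValueError(f"patient {series.patient_id}: no index channel")
    idx = np.asarray(series.index, dtype=float)
    high = idx > alarm_threshold
    crossings = high & ~np.concatenate(([False], high[:-1]))
    return [ClinicalEvent(series.patient_id, float(series.t[k]), "alarm")
            for k in np.flatnonzero(crossings)]


def merge_events(events: Sequence[ClinicalEvent], window_min: float = 15.0) -> List[ClinicalEvent]:
    """Anchored merging: repeats within `window_min` of an anchor join it.

    Input events must share a single event_type and be time-sorted.  Every
    input event is preserved; members get `merged_into` set to the anchor's
    event_id.  Re-merging an already merged list is the identity.
    """
    if not events:
        return []
    types = {e.event_type for e in events}
    if len(types) > 1:
        raise ValueError(f"merge_events requires a single event type, got {sorted(types)}")
    times = [e.time_s for e in events]
    if any(b < a for a, b in zip(times, times[1:])):
        raise ValueError("events must be time-sorted")

    out: List[ClinicalEvent] = []
    window_s = window_min * 60.0
    anchor: Optional[ClinicalEvent] = None
    for e in events:
        e = ClinicalEvent(e.patient_id, e.time_s, e.event_type,
                          e.treatment_option, "", e.event_id)
        if anchor is None or e.time_s >= anchor.time_s + window_s:
            anchor = e
        else:
            e.merged_into = anchor.event_id
        out.append(e)
    return out


def anchors_of(merged: Iterable[ClinicalEvent]) -> List[ClinicalEvent]:
    """The unmerged (anchor) events of a merged list."""
    return [e for e in merged if not e.merged_into]


def silent_alarm_times(series: VitalSeries, hypotension_anchors: Sequence[ClinicalEvent],
                       alarm_threshold: float = 85.0,
                       window_min: float = 15.0) -> List[ClinicalEvent]:
    """Reconstruct the silenced alarms of the standard-of-care arm.

    For each merged hypotension anchor at time HT, the silent-alarm time is
    the earliest sample with index > threshold inside [HT - window, HT].
    Anchors whose window holds no exceedance yield no record (they are
    counted by the caller as unreconstructable).
    """
    if series.index is None:
        raise ValueError(f"patient {series.patient_id}: no index channel")
    idx = np.asarray(series.index, dtype=float)
    t = series.t
    out: List[ClinicalEvent] = []
    for anchor in hypotension_anchors:
        ht = anchor.time_s
        in_win = (t >= ht - window_min * 60.0) & (t <= ht) & (idx > alarm_threshold)
        hits = np.flatnonzero(in_win)
        if hits.size:
            out.append(ClinicalEvent(series.patient_id, float(t[hits[0]]), "alarm",
                                     event_id=f"{series.patient_id}:SAT:{t[hits[0]]:g}"))
    return out


def compute_latencies(anchors: Sequence[ClinicalEvent], treatments: Sequence[ClinicalEvent],
                      anchor_type: Literal["AT", "HT", "SAT"],
                      window_min: float = 15.0) -> List[LatencyRecord]:
    """First-treatment latency per anchor; greedy earliest-first matching.

    A treatment qualifies if it falls in [anchor, anchor + window); each
    treatment is consumed by at most one anchor.  Anchors with no qualifying
    treatment are reported untreated (latency None).
    """
    tt = [e.time_s for e in treatments]
    if any(b < a for a, b in zip(tt, tt[1:])):
        raise ValueError("treatments must be time-sorted")
    window_s = window_min * 60.0
    used = [False] * len(treatments)
    out: List[LatencyRecord] = []
    for anchor in anchors:
        match: Optional[float] = None
        for k, e in enumerate(treatments):
            if used[k] or e.time_s < anchor.time_s:
                continue
            if e.time_s >= anchor.time_s + window_s:
                break
            used[k] = True
            match = e.time_s
            break
        out.append(LatencyRecord(anchor.patient_id, anchor_type, anchor.time_s,
                                 match, None if match is None else match - anchor.time_s))
    return out
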