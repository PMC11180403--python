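"""Hemodynamic diagnostic table: snapshot in, one of six treatments out.

The decision logic mirrors the goal-directed differential used at the
bedside: first ask whether the patient is preload-responsive (high stroke
volume variation -> volume), then whether pressure will actually follow
volume (dynamic arterial elastance), then whether the problem is vasomotor
tone (low systemic vascular resistance -> vasopressor) or contractility
(low systolic slope dP/dtmax -> inotrope).  Combination options fire when a
preload rule and a tone/contractility rule fire together; when nothing
fires the recommendation is observation.

The table is data, not code: an ordered list of named rules evaluated
against configurable cut-offs (:class:`~hypotrial.config.ProtocolThresholds`),
because the source protocol publishes its numeric cut-offs only graphically.
Rules are evaluated in fixed order and the traversal is recorded, so every
recommendation is reproducible and auditable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Tuple

from .config import ProtocolThresholds
from .events import TREATMENT_OPTIONS


@dataclass(frozen=True)
class DecisionInputs:
    """One hemodynamic snapshot at a decision point."""

    svv: float            # stroke volume variation, %
    eadyn: float          # dynamic arterial elastance, ratio
    dpdtmax: float        # systolic slope, mmHg/s
    svr: float            # systemic vascular resistance, dyn*s/cm^5
    cardiac_index: float = 3.0  # L/min/m^2
    map: float = 65.0     # mmHg

    def __post_init__(self) -> None:
        vals = (self.svv, self.eadyn, self.dpdtmax, self.svr, self.cardiac_index, self.map)
        if not all(math.isfinite(v) for v in vals):
            raise ValueError("all decision inputs must be finite")
        if self.svv < 0:
            raise ValueError("svv must be non-negative")


@dataclass(frozen=True)
class DecisionOutcome:
    option: str
    rationale_path: Tuple[str, ...]

    def __post_init__(self) -> None:
        if self.option not in TREATMENT_OPTIONS:
            raise ValueError(f"unknown option {self.option!r}")


# ordered rule table: (name, predicate(inputs, thresholds), component)
_RULES = (
    ("preload_responsive:svv_high",
     lambda x, th: x.svv > th.svv_high, "fluid"),
    ("fluid_wont_raise_pressure:eadyn_low",
     lambda x, th: x.svv > th.svv_high and x.eadyn < th.eadyn_high, "vasopressor"),
    ("low_vasomotor_tone:svr_low",
     lambda x, th: x.svr < th.svr_low, "vasopressor"),
    ("low_contractility:dpdtmax_low",
     lambda x, th: x.dpdtmax < th.dpdtmax_low, "inotrope"),
)


def recommend(inputs: DecisionInputs, thresholds: ProtocolThresholds) -> DecisionOutcome:
    """Traverse the decision table; total and deterministic on finite input.

    Component combination: fluid + vasopressor -> fluid_plus_vasopressor,
    fluid + inotrope -> fluid_plus_inotrope; when both vasopressor and
    inotrope components fire, the earlier (tone) rule wins.  No component ->
    observation.
    """
    if thresholds is None:
        raise ValueError("protocol thresholds are not configured")
    path: List[str] = []
    components: List[str] = []
    for name, pred, component in _RULES:
        if pred(inputs, thresholds):
            path.append(name)
            if component not in components:
                components.append(component)

    fluid = "fluid" in components
    vaso = "vasopressor" in components
    ino = "inotrope" in components
    if fluid and vaso:
        option = "fluid_plus_vasopressor"
    elif fluid and ino:
        option = "fluid_plus_inotrope"
    elif fluid:
        option = "fluid"
    elif vaso:
        option = "vasopressor"
    elif ino:
        option = "inotrope"
    else:
        option = "observation"
        path.append("no_rule_fired:observe")
    return DecisionOutcome(option=option, rationale_path=tuple(path))
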