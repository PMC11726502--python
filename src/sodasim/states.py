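"""Health states of the weight / diabetes / cardiovascular state-transition model.

The model tracks ten mutually exclusive states: three BMI-defined weight
categories, diabetes, four cardiovascular/renal complication states (with
acute stroke and acute myocardial infarction modelled as one-year tunnel
states ahead of their chronic sequels), end-stage renal disease, and death.
"""
from __future__ import annotations

import enum


class HealthState(enum.IntEnum):
    """Mutually exclusive health states, ordered as matrix row/column indices."""

    NORMAL = 0
    OVERWEIGHT = 1
    OBESITY = 2
    DIABETES = 3
    STROKE = 4       # acute, first cycle after the event (tunnel state)
    POSTSTROKE = 5
    MI = 6           # acute myocardial infarction (tunnel state)
    POSTMI = 7
    ESRD = 8
    DEATH = 9


N_STATES = len(HealthState)

#: States whose membership is decided each cycle by the individual's BMI.
WEIGHT_GOVERNED = (HealthState.NORMAL, HealthState.OVERWEIGHT, HealthState.OBESITY)

#: Tunnel states: an individual who spends a full cycle in the acute state
#: without transitioning elsewhere moves to the chronic successor.
TUNNEL_SUCCESSOR = {
    HealthState.STROKE: HealthState.POSTSTROKE,
    HealthState.MI: HealthState.POSTMI,
}

STATE_NAMES = {s: s.name.lower() for s in HealthState}
NAME_TO_STATE = {name: s for s, name in STATE_NAMES.items()}


def state_from_name(name: str) -> HealthState:
    try:
        return NAME_TO_STATE[name.strip().lower().replace("-", "").replace("_", "")]
    except KeyError as exc:
        raise KeyError(f"unknown health state name: {name!r}") from exc
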