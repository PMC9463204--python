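"""Deterministic nine-category classification of manipulative actions.

Each combinatory action is categorized on its own, against the workspace
state at the moment it happens (not by judging the whole trial):

* ``PAIRING`` — a single cup inserted into a larger single cup;
* ``POT`` — a single cup inserted into a larger existing unit;
* ``SUBASSEMBLY`` — a multi-cup unit inserted into a larger single cup;
* ``UNIT_UNIT`` — a multi-cup unit inserted into a larger unit (the more
  advanced form of subassembly);
* ``PILE`` / ``PILE_SUB`` — a cup / a unit placed on a *smaller* cup or
  unit, resting on top rather than nesting;
* ``PUT`` — a combination retrieved without releasing the hand (verb H);
* ``DISASSEMBLE`` — a cup/unit detached from a premade unit (verb D);
* ``OTHER`` — mouthing, replacing on the floor, reversing, banging (verb X).

The label is a pure function of (pre-action state, event); pile vs nest
is decided by comparing the object's contact cup with the location's top
cup only.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import TYPE_CHECKING

from . import cupworld
from .errors import ValidationError
from .notation import ActionEvent, canonicalize

if TYPE_CHECKING:  # pragma: no cover
    from .metrics import TrialRecord

__all__ = ["StrategyLabel", "LabeledEvent", "classify_event", "classify_trial"]


class StrategyLabel(Enum):
    PAIRING = "pairing"
    POT = "pot"
    SUBASSEMBLY = "subassembly"
    UNIT_UNIT = "unit_unit"
    PILE = "pile"
    PILE_SUB = "pile_sub"
    PUT = "put"
    DISASSEMBLE = "disassemble"
    OTHER = "other"


#: The two labels forming the subassembly family (unit moved as one piece).
SUBASSEMBLY_FAMILY = (StrategyLabel.SUBASSEMBLY, StrategyLabel.UNIT_UNIT)


@dataclass(frozen=True)
class LabeledEvent:
    """An event with its strategy label and the pre-state it was judged on."""

    event: ActionEvent
    label: StrategyLabel
    pre_state_digest: str


def classify_event(
    pre_state: cupworld.WorkspaceState, event: ActionEvent
) -> StrategyLabel:
    """Assign one of the nine categories to a canonical event.

    First-match rule table: H -> PUT; D -> DISASSEMBLE; X -> OTHER; then
    for N the object size (single cup vs unit), the contact comparison
    (nest vs pile), and the location's unit status decide among the six
    combinatory categories.
    """
    verb = event.verb.code
    if verb == "H":
        return StrategyLabel.PUT
    if verb == "D":
        return StrategyLabel.DISASSEMBLE
    if verb == "X":
        return StrategyLabel.OTHER

    # verb N: check the event is canonical w.r.t. the pre-state
    tgt = pre_state.structure_of(event.loc[0])
    if tgt.unit_token != event.loc:
        raise ValidationError(
            f"event location {event.loc} is not canonical for state "
            f"{pre_state.digest()}; canonicalize first"
        )
    src = pre_state.structure_of(event.obj[0])
    if not src.is_top_segment(event.obj):
        raise ValidationError(
            f"event object {event.obj} is not a movable segment in state "
            f"{pre_state.digest()}; canonicalize first"
        )

    single = len(event.obj) == 1
    loc_single = len(event.loc) == 1
    if event.contact_rank < event.loc_top_rank:  # nests
        if single:
            return StrategyLabel.PAIRING if loc_single else StrategyLabel.POT
        return StrategyLabel.SUBASSEMBLY if loc_single else StrategyLabel.UNIT_UNIT
    # rests on a smaller cup/unit
    return StrategyLabel.PILE if single else StrategyLabel.PILE_SUB


def classify_trial(trial: "TrialRecord") -> list[LabeledEvent]:
    """Replay a trial through the cup world, labeling every event.

    Events are canonicalized against the running state first, so trials
    whose location tokens name only the top cup of the receiving unit
    are accepted. Output length equals the event count.
    """
    events, _flags = canonicalize(trial.events, trial.n_cups)
    state = cupworld.initial_state(trial.n_cups)
    labeled: list[LabeledEvent] = []
    for event in events:
        labeled.append(
            LabeledEvent(event, classify_event(state, event), state.digest())
        )
        state = cupworld.apply_event(state, event).new_state
    return labeled
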