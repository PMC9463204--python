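"""Action-grammar notation for cup-manipulation sequences.

A manipulative action is coded as an ``object, action, location`` triple.
A trial is a "/"-separated list of tokens, each of the form
``<unit><verb><unit|f>``:

* a **unit** is the ordered list of cup size-ranks in a moved or receiving
  structure, written innermost/topmost cup first and base (contact) cup
  last — ``12`` is the two-cup unit made by inserting cup 1 into cup 2;
* the **verb** is one of ``N`` (combine and release), ``H`` (combine
  without releasing the hand), ``D`` (detach from a premade unit) or ``X``
  (other manipulation, optionally subtyped: ``XM`` mouth, ``XR`` replace
  on the floor, ``XV`` reverse orientation, ``XB`` bang);
* the **location** is the receiving unit, the source unit for ``D``, or
  ``f`` for the floor.

``1N2/12N3`` therefore codes inserting the smallest cup into the second
cup and then adding the resulting two-cup unit into the third cup.

Two dialects are supported and auto-detected per sequence: the *compact*
dialect uses one digit per cup (valid while every rank is <= 9); the
*extended* dialect separates ranks with ``.`` (``1.2N3``, required for
ranks >= 10). Parsing is case-insensitive and ignores whitespace around
``/``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Optional, Sequence

from .errors import CanonicalizationError, ParseError, ValidationError

__all__ = [
    "XSubtype",
    "Verb",
    "N",
    "H",
    "D",
    "ActionEvent",
    "FLOOR",
    "parse_sequence",
    "render_sequence",
    "canonicalize",
    "CanonFlag",
    "validate_event",
]


class XSubtype(Enum):
    """Subtype of an 'other' (X) manipulation."""

    MOUTH = "M"
    REPLACE = "R"
    REVERSE = "V"
    BANG = "B"
    UNSPECIFIED = ""


@dataclass(frozen=True)
class Verb:
    """A manipulation verb: N, H, D, or X with a subtype.

    The code set is closed; ``X`` carries exactly one subtype and the
    other verbs carry none.
    """

    code: str
    subtype: Optional[XSubtype] = None

    def __post_init__(self):
        if self.code not in ("N", "H", "D", "X"):
            raise ValidationError(f"unknown verb code {self.code!r}")
        if self.code == "X":
            if self.subtype is None:
                object.__setattr__(self, "subtype", XSubtype.UNSPECIFIED)
        elif self.subtype is not None:
            raise ValidationError(f"verb {self.code} cannot carry a subtype")

    def __str__(self) -> str:
        if self.code == "X":
            return "X" + self.subtype.value
        return self.code


N = Verb("N")
H = Verb("H")
D = Verb("D")

#: Sentinel for the floor location in an :class:`ActionEvent`.
FLOOR = None

Unit = tuple  # ordered cup ranks, innermost/topmost first, base last


@dataclass(frozen=True)
class ActionEvent:
    """One coded manipulative action: object unit, verb, location unit.

    ``obj`` and ``loc`` are tuples of cup ranks listed innermost/topmost
    first with the base (contact) cup last; ``loc`` is :data:`FLOOR`
    (``None``) for floor-directed actions, which only verb ``X`` permits.
    """

    obj: Unit
    verb: Verb
    loc: Optional[Unit] = FLOOR

    @property
    def contact_rank(self) -> int:
        """Rank of the object's contact (base) cup."""
        return self.obj[-1]

    @property
    def loc_top_rank(self) -> Optional[int]:
        """Rank of the location's top cup, or None for the floor."""
        return None if self.loc is None else self.loc[0]


def validate_event(event: ActionEvent, n_cups: Optional[int] = None) -> None:
    """Check the ActionEvent invariants, raising ValidationError on breach."""
    obj, verb, loc = event.obj, event.verb, event.loc
    if not obj:
        raise ValidationError("object unit is empty")
    if len(set(obj)) != len(obj):
        raise ValidationError(f"duplicate cup in object unit {obj}")
    if loc is not None:
        if not loc:
            raise ValidationError("location unit is empty")
        if len(set(loc)) != len(loc):
            raise ValidationError(f"duplicate cup in location unit {loc}")
        overlap = set(obj) & set(loc)
        if overlap:
            raise ValidationError(f"object and location share cup(s) {sorted(overlap)}")
    elif verb.code in ("N", "H", "D"):
        raise ValidationError(f"verb {verb.code} requires a non-floor location")
    if n_cups is not None:
        for rank in obj + (loc or ()):
            if not 1 <= rank <= n_cups:
                raise ValidationError(
                    f"cup rank {rank} outside declared range 1..{n_cups}"
                )


_SUBTYPE_BY_LETTER = {s.value: s for s in XSubtype if s.value}

_COMPACT_RE = re.compile(r"^([1-9]+)([NHDX])([MRVB])?([1-9]+|F)$")
_EXTENDED_RE = re.compile(
    r"^(\d+(?:\.\d+)*)\s*([NHDX])([MRVB])?\s*(\d+(?:\.\d+)*|F)$"
)


def _parse_unit(text: str, extended: bool) -> Unit:
    if extended:
        ranks = tuple(int(p) for p in text.split("."))
    else:
        ranks = tuple(int(ch) for ch in text)
    return ranks


def parse_sequence(
    text: str, n_cups: Optional[int] = None
) -> list[ActionEvent]:
    """Parse a coded sequence into an ordered list of ActionEvents.

    The dialect is auto-detected per sequence: any ``.`` (or a declared
    ``n_cups`` above 9, where the compact one-digit-per-cup form is not
    well defined) selects the extended dialect. An empty or
    whitespace-only string yields ``[]``.

    Raises
    ------
    ParseError
        For a malformed token, with its position and text.
    ValidationError
        For duplicate cups within a token, object/location overlap, or a
        rank outside ``1..n_cups`` when ``n_cups`` is given.
    """
    text = text.strip()
    if not text:
        return []
    # compact is only well defined for ranks <= 9: a dot anywhere, or a
    # declared cup count above 9, selects the extended dialect
    extended = "." in text or (n_cups is not None and n_cups > 9)
    pattern = _EXTENDED_RE if extended else _COMPACT_RE
    events: list[ActionEvent] = []
    for i, raw in enumerate(text.split("/")):
        tok = raw.strip().upper()
        m = pattern.fullmatch(tok)
        if m is None:
            raise ParseError("malformed token", position=i, token=raw.strip())
        unit_txt, verb_letter, sub_letter, loc_txt = m.groups()
        if sub_letter and verb_letter != "X":
            raise ParseError(
                "subtype letter only valid after X", position=i, token=raw.strip()
            )
        if verb_letter == "X":
            verb = Verb(
                "X",
                _SUBTYPE_BY_LETTER[sub_letter]
                if sub_letter
                else XSubtype.UNSPECIFIED,
            )
        else:
            verb = Verb(verb_letter)
        obj = _parse_unit(unit_txt, extended)
        loc = FLOOR if loc_txt == "F" else _parse_unit(loc_txt, extended)
        event = ActionEvent(obj, verb, loc)
        try:
            validate_event(event, n_cups)
        except ValidationError as exc:
            raise ValidationError(f"token {i} ({raw.strip()!r}): {exc}") from exc
        events.append(event)
    return events


def _render_unit(unit: Unit, extended: bool) -> str:
    if extended:
        return ".".join(str(r) for r in unit)
    return "".join(str(r) for r in unit)


def render_sequence(
    events: Iterable[ActionEvent], n_cups: Optional[int] = None
) -> str:
    """Render events to canonical text.

    Uses the compact dialect when all ranks are <= 9, the extended
    ``.``-separated dialect otherwise; declaring ``n_cups`` above 9 also
    forces the extended dialect, keeping the text parseable with the
    same declaration. Inverse of :func:`parse_sequence` on valid input.
    """
    events = list(events)
    if not events:
        return ""
    ranks = [r for e in events for r in e.obj + (e.loc or ())]
    extended = max(ranks) > 9 or (n_cups is not None and n_cups > 9)
    tokens = []
    for i, e in enumerate(events):
        try:
            validate_event(e)
        except ValidationError as exc:
            raise ValidationError(f"event {i}: {exc}") from exc
        loc_txt = "f" if e.loc is None else _render_unit(e.loc, extended)
        tokens.append(f"{_render_unit(e.obj, extended)}{e.verb}{loc_txt}")
    return "/".join(tokens)


@dataclass(frozen=True)
class CanonFlag:
    """Record of a token rewritten during canonicalization."""

    index: int
    field: str  # "obj" or "loc"
    written: Unit
    canonical: Unit


def canonicalize(
    events: Sequence[ActionEvent], n_cups: int
) -> tuple[list[ActionEvent], list[CanonFlag]]:
    """Reconcile hand-coded tokens with the tracked workspace state.

    Replays the sequence from the all-loose initial state. Each event's
    location token is rewritten to the full unit actually targeted (for
    ``D``, to the full remainder of the source structure); a flag records
    every rewrite, so both coder conventions — naming the whole receiving
    unit or only its top cup — are accepted. The object token must name a
    top-contiguous segment of one structure and is left as written (it
    defines the moved set).

    Raises :class:`CanonicalizationError` with the event index when a
    token cannot be reconciled with the state.
    """
    from . import cupworld  # local import to avoid a module cycle

    state = cupworld.initial_state(n_cups)
    out: list[ActionEvent] = []
    flags: list[CanonFlag] = []
    for i, event in enumerate(events):
        try:
            validate_event(event, n_cups)
        except ValidationError as exc:
            raise CanonicalizationError(str(exc), index=i) from exc
        try:
            src = state.structure_of(event.obj[0])
        except KeyError:
            raise CanonicalizationError(
                f"object cup {event.obj[0]} not in workspace", index=i
            )
        if not src.is_top_segment(event.obj):
            raise CanonicalizationError(
                f"object {event.obj} is not a top-contiguous segment of "
                f"{src.unit_token}",
                index=i,
            )
        canon = event
        if event.verb.code == "D":
            remainder = src.stack[: len(src.stack) - len(event.obj)]
            if not remainder:
                raise CanonicalizationError(
                    "cannot detach a whole structure", index=i
                )
            canon_loc = tuple(reversed(remainder))
            if not set(event.loc) <= set(canon_loc):
                raise CanonicalizationError(
                    f"D location {event.loc} not part of source remainder "
                    f"{canon_loc}",
                    index=i,
                )
            if event.loc != canon_loc:
                flags.append(CanonFlag(i, "loc", event.loc, canon_loc))
                canon = ActionEvent(event.obj, event.verb, canon_loc)
        elif event.loc is not None:
            try:
                tgt = state.structure_of(event.loc[0])
            except KeyError:
                raise CanonicalizationError(
                    f"location cup {event.loc[0]} not in workspace", index=i
                )
            if tgt is src and event.verb.code in ("N", "H"):
                raise CanonicalizationError(
                    "object and location are in the same structure", index=i
                )
            canon_loc = tgt.unit_token
            if not set(event.loc) <= set(canon_loc):
                raise CanonicalizationError(
                    f"location {event.loc} spans multiple structures", index=i
                )
            if event.loc != canon_loc:
                flags.append(CanonFlag(i, "loc", event.loc, canon_loc))
                canon = ActionEvent(event.obj, event.verb, canon_loc)
        out.append(canon)
        state = cupworld.apply_event(state, canon).new_state
    return out, flags
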