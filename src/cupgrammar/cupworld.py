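"""Idealized physical state machine for seriated nesting cups.

Cups are identified by distinct size ranks ``1..n`` (1 = smallest). A
*structure* is an ordered stack of cups, base first; each adjacent pair
is either a nesting (``IN``: the upper cup is smaller, so it sits inside)
or a pile (``ON``: the upper cup is larger, so it rests on top). Since
ranks are distinct the relation is fully determined by the ranks, and
only the stack order is stored.

The contact rule is deliberately minimal: when a unit is combined onto a
structure, only the receiving structure's *top* cup decides nest vs pile
— a dropped cup settles on whatever is uppermost, with no re-sorting or
telescoping of intermediate sizes. Moved objects must be top-contiguous
segments (grabbing a buried cup would be coded as a disassembly first);
composite piles move rigidly as units.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Optional

from .errors import DomainError, IllegalMoveError, ValidationError
from .notation import ActionEvent, Unit, XSubtype, validate_event

__all__ = [
    "Relation",
    "Structure",
    "WorkspaceState",
    "OutcomeKind",
    "MoveOutcome",
    "initial_state",
    "apply_event",
    "replay",
    "is_complete_seriation",
    "max_nesting",
    "hierarchical_level",
    "min_moves",
]


class Relation(Enum):
    IN = "IN"  # upper cup smaller: nested inside
    ON = "ON"  # upper cup larger: piled on top


@dataclass(frozen=True)
class Structure:
    """One stack of cups, ordered from base (first placed) to top."""

    stack: tuple  # cup ranks, base first

    def __post_init__(self):
        if not self.stack:
            raise ValidationError("empty structure")
        if len(set(self.stack)) != len(self.stack):
            raise ValidationError(f"duplicate cup in structure {self.stack}")

    @property
    def relations(self) -> tuple:
        """IN/ON relation for each adjacent pair, derived from the ranks."""
        return tuple(
            Relation.IN if b < a else Relation.ON
            for a, b in zip(self.stack, self.stack[1:])
        )

    @property
    def top(self) -> int:
        return self.stack[-1]

    @property
    def base(self) -> int:
        return self.stack[0]

    @property
    def unit_token(self) -> Unit:
        """The structure as a notation unit: topmost first, base last."""
        return tuple(reversed(self.stack))

    def __len__(self) -> int:
        return len(self.stack)

    def is_top_segment(self, unit: Unit) -> bool:
        """True if ``unit`` (topmost-first) is the top of this stack."""
        k = len(unit)
        if k > len(self.stack):
            return False
        return tuple(reversed(self.stack[len(self.stack) - k :])) == tuple(unit)


@dataclass(frozen=True)
class WorkspaceState:
    """The full tabletop: a partition of cups 1..n_cups into structures."""

    structures: tuple  # tuple[Structure, ...], kept in canonical order
    n_cups: int

    def __post_init__(self):
        seen: list[int] = [r for s in self.structures for r in s.stack]
        if sorted(seen) != list(range(1, self.n_cups + 1)):
            raise ValidationError(
                f"cup conservation violated: ranks {sorted(seen)} != 1..{self.n_cups}"
            )

    def structure_of(self, rank: int) -> Structure:
        for s in self.structures:
            if rank in s.stack:
                return s
        raise KeyError(rank)

    def digest(self) -> str:
        """Compact human-readable snapshot, e.g. ``[3,2,1]|[4]``."""
        return "|".join(
            "[" + ",".join(map(str, s.stack)) + "]" for s in self.structures
        )

    def to_json(self) -> str:
        return json.dumps(
            {"n_cups": self.n_cups, "stacks": [list(s.stack) for s in self.structures]}
        )

    @classmethod
    def from_json(cls, text: str) -> "WorkspaceState":
        d = json.loads(text)
        return _make_state(
            (Structure(tuple(st)) for st in d["stacks"]), d["n_cups"]
        )


def _make_state(structures: Iterable[Structure], n_cups: int) -> WorkspaceState:
    ordered = tuple(sorted(structures, key=lambda s: s.stack))
    return WorkspaceState(ordered, n_cups)


class OutcomeKind(Enum):
    NESTED = "NESTED"
    PILED = "PILED"
    HELD = "HELD"
    DETACHED = "DETACHED"
    NOOP = "NOOP"


@dataclass(frozen=True)
class MoveOutcome:
    kind: OutcomeKind
    new_state: WorkspaceState


def initial_state(n_cups: int) -> WorkspaceState:
    """All cups loose on the floor, one singleton structure per cup."""
    if n_cups < 1:
        raise DomainError(f"n_cups must be >= 1, got {n_cups}")
    return _make_state((Structure((r,)) for r in range(1, n_cups + 1)), n_cups)


def _split_object(state: WorkspaceState, obj: Unit) -> tuple[Structure, tuple]:
    """Locate the object's structure; return (structure, remainder stack)."""
    try:
        src = state.structure_of(obj[0])
    except KeyError:
        raise IllegalMoveError(f"cup {obj[0]} not in workspace")
    if not src.is_top_segment(obj):
        raise IllegalMoveError(
            f"object {obj} is not a top-contiguous segment of {tuple(src.stack)}"
        )
    return src, src.stack[: len(src.stack) - len(obj)]


def apply_event(state: WorkspaceState, event: ActionEvent) -> MoveOutcome:
    """Apply one canonical event; deterministic in (state, event).

    ``N`` places the object unit on the location's top cup (nesting if the
    object's contact cup is smaller, piling otherwise); ``H`` leaves the
    state unchanged; ``D`` splits the object off as its own structure;
    ``X`` is a no-op except the replace-on-floor subtype, which detaches
    like ``D`` when the object was part of a unit.
    """
    validate_event(event, state.n_cups)
    verb = event.verb
    src, remainder = _split_object(state, event.obj)
    others = [s for s in state.structures if s is not src]

    if verb.code == "H":
        if event.loc is not None and set(event.loc) & set(src.stack):
            raise IllegalMoveError("object and location overlap")
        return MoveOutcome(OutcomeKind.HELD, state)

    if verb.code == "N":
        try:
            tgt = state.structure_of(event.loc[0])
        except KeyError:
            raise IllegalMoveError(f"location cup {event.loc[0]} not in workspace")
        if tgt is src:
            raise IllegalMoveError("object and location are in the same structure")
        if tgt.unit_token != event.loc:
            raise IllegalMoveError(
                f"non-canonical location {event.loc}; structure is {tgt.unit_token}"
            )
        segment = tuple(reversed(event.obj))  # back to base-first stack order
        kind = (
            OutcomeKind.NESTED
            if event.contact_rank < tgt.top
            else OutcomeKind.PILED
        )
        new = [s for s in others if s is not tgt]
        new.append(Structure(tgt.stack + segment))
        if remainder:
            new.append(Structure(remainder))
        return MoveOutcome(kind, _make_state(new, state.n_cups))

    if verb.code == "D":
        if not remainder:
            raise IllegalMoveError("cannot detach a whole structure")
        if not set(event.loc) <= set(remainder):
            raise IllegalMoveError(
                f"D location {event.loc} does not name the source remainder"
            )
        new = others + [Structure(remainder), Structure(tuple(reversed(event.obj)))]
        return MoveOutcome(OutcomeKind.DETACHED, _make_state(new, state.n_cups))

    # verb X
    if verb.subtype is XSubtype.REPLACE and remainder:
        new = others + [Structure(remainder), Structure(tuple(reversed(event.obj)))]
        return MoveOutcome(OutcomeKind.DETACHED, _make_state(new, state.n_cups))
    return MoveOutcome(OutcomeKind.NOOP, state)


def replay(
    events: Iterable[ActionEvent],
    n_cups: int,
    start: Optional[WorkspaceState] = None,
) -> list[WorkspaceState]:
    """States visited by a sequence: ``[s0, s1, ..., s_final]``."""
    state = start if start is not None else initial_state(n_cups)
    trace = [state]
    for event in events:
        state = apply_event(state, event).new_state
        trace.append(state)
    return trace


def is_complete_seriation(state: WorkspaceState) -> bool:
    """True iff all cups form one fully nested stack (n, n-1, ..., 1)."""
    if len(state.structures) != 1:
        return False
    stack = state.structures[0].stack
    return stack == tuple(range(state.n_cups, 0, -1))


def max_nesting(state: WorkspaceState) -> int:
    """Largest count of cups joined by a contiguous run of IN adjacencies.

    Non-contiguous ranks count (5 holding 3 holding 1 is a 3-cup
    nesting); a workspace with no nesting anywhere scores 1.
    """
    best = 1
    for s in state.structures:
        run = 1
        for a, b in zip(s.stack, s.stack[1:]):
            run = run + 1 if b < a else 1
            best = max(best, run)
    return best


def hierarchical_level(structure: Structure) -> int:
    """Number of combinatory relations: cups in the structure minus one."""
    return len(structure) - 1


def min_moves(n_cups: int) -> int:
    """Minimum number of combine (N) events to seriate n cups: n - 1.

    Every combine event merges exactly two structures, and the initial
    state has n of them; a perfect-size pot policy achieves the bound.
    """
    if n_cups < 1:
        raise DomainError(f"n_cups must be >= 1, got {n_cups}")
    return n_cups - 1
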