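"""Agent-based generator of coded nesting-cup trials with known intents.

Each simulated agent repeatedly samples an *intended* strategy category
from a propensity vector restricted to the categories feasible in the
current workspace state, realizes it as a concrete object/location
choice, and emits the event. Imperfect size judgment corrupts the
nest-vs-pile comparison with a configurable probability, so an intended
pot can be realized (and classified) as a pile — producing the
trial-and-error combine/disassemble loops and piling errors seen in real
coded sequences. Every emitted event carries its ground-truth intent and
the per-step feasibility-adjusted intent probabilities, which are the
targets for parameter-recovery checks.

Feasibility handling: a category impossible in the current state passes
its weight down a fallback chain to its developmental precursor
(POT -> PAIRING, UNIT_UNIT -> SUBASSEMBLY -> PAIRING, PILE_SUB -> PILE),
so e.g. a pure-pot agent starts with the pairing that creates its first
unit. Nest- and pile-intent realizations are size-greedy (largest
fitting object into the tightest receiver), which makes a zero-error
pure-pot agent seriate n cups in exactly the minimum n-1 combine moves;
put, disassemble and other realizations are uniform over legal choices.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np

from . import cupworld
from .classifier import StrategyLabel
from .errors import ConfigError, DomainError
from .notation import FLOOR, ActionEvent, Verb, XSubtype
from .metrics import AGE_CLASSES, TrialRecord

__all__ = [
    "AgentConfig",
    "GroupSpec",
    "CohortSchedule",
    "GroundTruth",
    "simulate_trial",
    "generate_cohort",
    "default_cohort_schedule",
]

_NEST_INTENTS = (
    StrategyLabel.PAIRING,
    StrategyLabel.POT,
    StrategyLabel.SUBASSEMBLY,
    StrategyLabel.UNIT_UNIT,
)
_PILE_INTENTS = (StrategyLabel.PILE, StrategyLabel.PILE_SUB)

_FALLBACK = {
    StrategyLabel.POT: StrategyLabel.PAIRING,
    StrategyLabel.SUBASSEMBLY: StrategyLabel.PAIRING,
    StrategyLabel.UNIT_UNIT: StrategyLabel.SUBASSEMBLY,
    StrategyLabel.PILE_SUB: StrategyLabel.PILE,
}

_OTHER_SUBTYPES = (
    XSubtype.MOUTH,
    XSubtype.REVERSE,
    XSubtype.BANG,
    XSubtype.UNSPECIFIED,
)  # the state-neutral subtypes; replace-on-floor moves cups, so not sampled


@dataclass(frozen=True)
class AgentConfig:
    """Behavioral parameters of one simulated participant.

    ``propensities`` are nonnegative relative weights over the nine
    categories (missing categories get weight 0); ``size_judgment_error``
    is the per-action probability of corrupting the size comparison;
    ``action_budget`` caps the events per trial.
    """

    propensities: dict
    size_judgment_error: float = 0.0
    action_budget: int = 100
    stop_on_success: bool = True
    seed: Optional[int] = None

    def __post_init__(self):
        weights = {}
        for lab, w in self.propensities.items():
            lab = StrategyLabel(lab) if not isinstance(lab, StrategyLabel) else lab
            if w < 0:
                raise ConfigError(f"negative propensity for {lab}")
            weights[lab] = float(w)
        if sum(weights.values()) <= 0:
            raise ConfigError("propensity weights must sum to > 0")
        if not 0.0 <= self.size_judgment_error <= 1.0:
            raise ConfigError("size_judgment_error must be in [0, 1]")
        if self.action_budget < 0:
            raise ConfigError("action_budget must be >= 0")
        object.__setattr__(self, "propensities", weights)


@dataclass(frozen=True)
class GroundTruth:
    """Per-event intended categories and feasibility-adjusted intent probs."""

    intents: tuple  # tuple[StrategyLabel, ...]
    step_probs: tuple  # tuple[dict[StrategyLabel, float], ...]
    propensities: dict

    def feasibility_adjusted_target(self) -> dict:
        """Mean per-step intent probability — the recovery target."""
        target = {lab: 0.0 for lab in StrategyLabel}
        if not self.step_probs:
            return target
        for probs in self.step_probs:
            for lab, p in probs.items():
                target[lab] += p
        return {lab: v / len(self.step_probs) for lab, v in target.items()}


def _feasible(state: cupworld.WorkspaceState) -> dict:
    singles = [s for s in state.structures if len(s) == 1]
    multis = [s for s in state.structures if len(s) > 1]
    feas = {
        StrategyLabel.PAIRING: len(singles) >= 2,
        StrategyLabel.POT: any(
            c.top < m.top for c in singles for m in multis
        ),
        StrategyLabel.SUBASSEMBLY: any(
            m.base < s.top for m in multis for s in singles
        ),
        StrategyLabel.UNIT_UNIT: any(
            m1.base < m2.top for m1 in multis for m2 in multis if m1 is not m2
        ),
        StrategyLabel.PILE: any(
            c.top > t.top for c in singles for t in state.structures if t is not c
        ),
        StrategyLabel.PILE_SUB: any(
            m.base > t.top for m in multis for t in state.structures if t is not m
        ),
        StrategyLabel.PUT: len(state.structures) >= 2,
        StrategyLabel.DISASSEMBLE: bool(multis),
        StrategyLabel.OTHER: True,
    }
    return feas


def _intent_probs(propensities: dict, feas: dict) -> tuple[dict, dict]:
    """Feasibility-adjusted intent distribution for one step.

    Returns ``(probs, sources)`` where ``sources[lab]`` maps each
    original (pre-fallback) intent contributing weight to ``lab`` to its
    share — used to realize e.g. a pot-agent's opening pairing in pot
    style (largest cups first) rather than tight-fit style.
    """
    eff = {lab: 0.0 for lab in StrategyLabel}
    src: dict = {lab: {} for lab in StrategyLabel}
    for lab, w in propensities.items():
        if w <= 0:
            continue
        cur = lab
        while cur is not None and not feas[cur]:
            cur = _FALLBACK.get(cur)
        if cur is not None:
            eff[cur] += w
            src[cur][lab] = src[cur].get(lab, 0.0) + w
    total = sum(eff.values())
    if total <= 0:
        return {StrategyLabel.OTHER: 1.0}, {
            StrategyLabel.OTHER: {StrategyLabel.OTHER: 1.0}
        }
    probs = {lab: w / total for lab, w in eff.items() if w > 0}
    return probs, {lab: src[lab] for lab in probs}


def _choice(rng: np.random.Generator, options: Sequence):
    return options[int(rng.integers(len(options)))]


def _combine_event(obj: cupworld.Structure, tgt: cupworld.Structure) -> ActionEvent:
    return ActionEvent(obj.unit_token, Verb("N"), tgt.unit_token)


def _realize(
    intent: StrategyLabel,
    state: cupworld.WorkspaceState,
    rng: np.random.Generator,
    corrupt: bool,
    origin: Optional[StrategyLabel] = None,
) -> ActionEvent:
    """Turn an intended category into a concrete canonical event."""
    structures = state.structures
    singles = [s for s in structures if len(s) == 1]
    multis = [s for s in structures if len(s) > 1]

    if intent is StrategyLabel.PUT:
        obj = _choice(rng, structures)
        tgt = _choice(rng, [s for s in structures if s is not obj])
        return ActionEvent(obj.unit_token, Verb("H"), tgt.unit_token)

    if intent is StrategyLabel.DISASSEMBLE:
        # corrective bias: when a structure contains a bad junction — a
        # pile (upper cup larger) or a size gap that blocks an exact
        # seriation (upper rank < lower rank - 1) — detach at the topmost
        # such junction; otherwise split a uniform structure uniformly
        def junctions(m):
            return [
                i + 1
                for i, (a, b) in enumerate(zip(m.stack, m.stack[1:]))
                if b > a or b < a - 1
            ]

        bad = [m for m in multis if junctions(m)]
        if bad:
            src = _choice(rng, bad)
            k = len(src) - junctions(src)[-1]
        else:
            src = _choice(rng, multis)
            k = int(rng.integers(1, len(src)))
        obj = tuple(reversed(src.stack[len(src) - k :]))
        loc = tuple(reversed(src.stack[: len(src) - k]))
        return ActionEvent(obj, Verb("D"), loc)

    if intent is StrategyLabel.OTHER:
        subtype = _choice(rng, _OTHER_SUBTYPES)
        s = _choice(rng, structures)
        return ActionEvent((s.top,), Verb("X", subtype), FLOOR)

    # combine intents: nest family (greedy tight fit) or pile family (uniform)
    if intent in _NEST_INTENTS:
        if corrupt:
            # misjudged size: the object lands on a smaller cup and piles
            if intent in (StrategyLabel.PAIRING, StrategyLabel.POT):
                movers = singles
            else:
                movers = multis
            pairs = [
                (o, t)
                for o in movers
                for t in structures
                if t is not o and o.base > t.top
            ]
            if pairs:
                return _combine_event(*_choice(rng, pairs))
            # no misrealization physically possible; act correctly
        if intent is StrategyLabel.PAIRING:
            if origin is StrategyLabel.POT:
                # a pot-strategist's opening move: start the tower with
                # the two largest cups
                tgt = max(singles, key=lambda s: s.top)
            else:
                # similar-size pairing: the tightest available pair
                tgt = min(
                    (s for s in singles if any(c.top < s.top for c in singles)),
                    key=lambda s: s.top,
                )
            obj = max((s for s in singles if s.top < tgt.top), key=lambda s: s.top)
        elif intent is StrategyLabel.POT:
            cands = [m for m in multis if any(c.top < m.top for c in singles)]
            tgt = max(cands, key=lambda m: m.top)
            obj = max((c for c in singles if c.top < tgt.top), key=lambda c: c.top)
        elif intent is StrategyLabel.SUBASSEMBLY:
            cands = [m for m in multis if any(m.base < s.top for s in singles)]
            obj = max(cands, key=lambda m: m.base)
            tgt = min((s for s in singles if s.top > obj.base), key=lambda s: s.top)
        else:  # UNIT_UNIT
            cands = [
                m1
                for m1 in multis
                if any(m1.base < m2.top for m2 in multis if m2 is not m1)
            ]
            obj = max(cands, key=lambda m: m.base)
            tgt = min(
                (m for m in multis if m is not obj and m.top > obj.base),
                key=lambda m: m.top,
            )
        return _combine_event(obj, tgt)

    # pile intents
    movers = singles if intent is StrategyLabel.PILE else multis
    if corrupt:
        pairs = [
            (o, t)
            for o in movers
            for t in structures
            if t is not o and o.base < t.top
        ]
        if pairs:
            return _combine_event(*_choice(rng, pairs))
    pairs = [
        (o, t) for o in movers for t in structures if t is not o and o.base > t.top
    ]
    return _combine_event(*_choice(rng, pairs))


def simulate_trial(
    config: AgentConfig,
    n_cups: int,
    *,
    rng: Optional[np.random.Generator] = None,
    participant_id: str = "sim",
    trial_id: str = "t0",
    species: str = "human",
    age_months: Optional[int] = None,
    date: Optional[str] = None,
) -> tuple[TrialRecord, GroundTruth]:
    """Simulate one trial; all randomness comes from ``rng`` (or the seed).

    Returns the trial record plus the ground truth (one intent per
    emitted event). Runs until complete seriation (if ``stop_on_success``)
    or until the action budget is exhausted.
    """
    if not 1 <= n_cups:
        raise DomainError(f"n_cups must be >= 1, got {n_cups}")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    state = cupworld.initial_state(n_cups)
    events: list[ActionEvent] = []
    intents: list[StrategyLabel] = []
    step_probs: list[dict] = []
    for _ in range(config.action_budget):
        if config.stop_on_success and cupworld.is_complete_seriation(state):
            break
        probs, sources = _intent_probs(config.propensities, _feasible(state))
        labs = sorted(probs, key=lambda lab: lab.value)
        p = np.array([probs[lab] for lab in labs])
        intent = labs[int(rng.choice(len(labs), p=p / p.sum()))]
        origins = sorted(sources[intent], key=lambda lab: lab.value)
        ow = np.array([sources[intent][o] for o in origins])
        origin = origins[int(rng.choice(len(origins), p=ow / ow.sum()))]
        corrupt = bool(
            intent in _NEST_INTENTS + _PILE_INTENTS
            and rng.random() < config.size_judgment_error
        )
        event = _realize(intent, state, rng, corrupt, origin)
        state = cupworld.apply_event(state, event).new_state
        events.append(event)
        intents.append(intent)
        step_probs.append(probs)
    record = TrialRecord(
        participant_id=participant_id,
        species=species,
        trial_id=trial_id,
        n_cups=n_cups,
        events=tuple(events),
        age_months=age_months,
        date=date,
    )
    truth = GroundTruth(
        intents=tuple(intents),
        step_probs=tuple(step_probs),
        propensities=dict(config.propensities),
    )
    return record, truth


@dataclass(frozen=True)
class GroupSpec:
    """One cohort group: an agent profile plus sampling ranges.

    ``budget_range`` samples a per-trial action budget (an attention
    span) uniformly, overriding the agent's fixed budget;
    ``error_spread`` scales the agent's size-judgment error per
    participant by a uniform draw on ``[0, 2]`` (mean 1), emulating
    within-class skill heterogeneity. Both default to off.
    """

    label: str
    species: str
    config: AgentConfig
    n_participants: int
    trials_per_participant: int = 1
    n_cups_range: tuple = (9, 10)
    age_months_range: Optional[tuple] = None  # inclusive; None for adults
    budget_range: Optional[tuple] = None
    error_spread: bool = False


@dataclass(frozen=True)
class CohortSchedule:
    groups: tuple  # tuple[GroupSpec, ...]

    def __post_init__(self):
        if not self.groups:
            raise DomainError("cohort schedule has no groups")


def generate_cohort(
    schedule: CohortSchedule, seed: int
) -> list[tuple[TrialRecord, GroundTruth]]:
    """Simulate every group; reproducible from (schedule, seed).

    Each trial runs on its own stream seeded from
    ``(seed, group, participant, trial)``, so the cohort is order-
    independent and embarrassingly parallel.
    """
    out: list[tuple[TrialRecord, GroundTruth]] = []
    for gi, group in enumerate(schedule.groups):
        for pi in range(group.n_participants):
            p_rng = np.random.default_rng(
                np.random.SeedSequence(entropy=seed, spawn_key=(gi, pi))
            )
            if group.age_months_range is not None:
                lo, hi = group.age_months_range
                age = int(p_rng.integers(lo, hi + 1))
            else:
                age = None
            config = group.config
            if group.error_spread:
                config = replace(
                    config,
                    size_judgment_error=min(
                        1.0, config.size_judgment_error * 2.0 * p_rng.random()
                    ),
                )
            for ti in range(group.trials_per_participant):
                t_rng = np.random.default_rng(
                    np.random.SeedSequence(entropy=seed, spawn_key=(gi, pi, ti))
                )
                lo_c, hi_c = group.n_cups_range
                n_cups = int(t_rng.integers(lo_c, hi_c + 1))
                trial_config = config
                if group.budget_range is not None:
                    lo_b, hi_b = group.budget_range
                    trial_config = replace(
                        config, action_budget=int(t_rng.integers(lo_b, hi_b + 1))
                    )
                out.append(
                    simulate_trial(
                        trial_config,
                        n_cups,
                        rng=t_rng,
                        participant_id=f"{group.label}-p{pi:02d}",
                        trial_id=f"{group.label}-p{pi:02d}-t{ti}",
                        species=group.species,
                        age_months=age,
                    )
                )
    return out


def _w(pairing, pot, sub, uu, pile, pile_sub, put, dis, other) -> dict:
    return {
        StrategyLabel.PAIRING: pairing,
        StrategyLabel.POT: pot,
        StrategyLabel.SUBASSEMBLY: sub,
        StrategyLabel.UNIT_UNIT: uu,
        StrategyLabel.PILE: pile,
        StrategyLabel.PILE_SUB: pile_sub,
        StrategyLabel.PUT: put,
        StrategyLabel.DISASSEMBLE: dis,
        StrategyLabel.OTHER: other,
    }


def default_cohort_schedule() -> CohortSchedule:
    """The default study-like cohort: six child age classes + chimpanzees.

    Participant counts (7/10/12/12/12/14 children per ascending age
    class, 10 chimpanzee trials), cups-provided ranges, and per-trial
    action budgets follow the published envelope of the nesting-cup
    study; the propensity gradient (pairing-dominant toddlers shifting
    toward pot and then subassembly with age, with less random-error and
    off-task behavior) emulates the qualitative developmental trend.
    """
    acs = AGE_CLASSES
    human = [
        # (weights, error, budget range, n_participants, cups range)
        (_w(0.20, 0.04, 0.02, 0.00, 0.06, 0.01, 0.12, 0.15, 0.40), 0.30, (5, 37), 7, (3, 6)),
        (_w(0.22, 0.12, 0.05, 0.01, 0.04, 0.01, 0.10, 0.15, 0.30), 0.15, (4, 44), 10, (4, 9)),
        (_w(0.18, 0.15, 0.08, 0.02, 0.04, 0.01, 0.09, 0.17, 0.26), 0.10, (19, 81), 12, (5, 9)),
        (_w(0.15, 0.18, 0.11, 0.04, 0.03, 0.01, 0.08, 0.19, 0.21), 0.07, (23, 140), 12, (9, 10)),
        (_w(0.13, 0.21, 0.15, 0.05, 0.02, 0.01, 0.06, 0.15, 0.22), 0.04, (16, 67), 12, (7, 10)),
        (_w(0.10, 0.18, 0.26, 0.09, 0.005, 0.005, 0.04, 0.10, 0.12), 0.01, (30, 60), 14, (9, 10)),
    ]
    groups = [
        GroupSpec(
            label=ac.label,
            species="human",
            config=AgentConfig(w, size_judgment_error=err, action_budget=budget[1]),
            n_participants=n,
            trials_per_participant=1,
            n_cups_range=cups,
            age_months_range=(ac.lower_months, ac.upper_months),
            budget_range=budget,
            error_spread=True,
        )
        for ac, (w, err, budget, n, cups) in zip(acs, human)
    ]
    groups.append(
        GroupSpec(
            label="chimpanzee",
            species="chimpanzee",
            config=AgentConfig(
                _w(0.14, 0.14, 0.12, 0.08, 0.03, 0.01, 0.10, 0.20, 0.18),
                size_judgment_error=0.04,
                action_budget=192,
            ),
            n_participants=5,
            trials_per_participant=2,
            n_cups_range=(9, 10),
            age_months_range=None,
            budget_range=(23, 192),
            error_spread=True,
        )
    )
    return CohortSchedule(tuple(groups))
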