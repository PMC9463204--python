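"""Trial- and group-level summaries of nesting-cup performance.

Per trial: category counts and percentages (each category's share of all
manipulative actions in the trial), success (all provided cups combined
into one complete nesting structure), maximum nesting depth reached in
the final state, and the hierarchical level of the final largest
structure. Per group (an age class of children, or a species pool):
success rate, ranges of cups provided and cups nested, the distribution
of manipulations per trial, and mean per-category percentages.

Aggregation over a group defaults to the unweighted mean of member
trials' percentages (the per-participant percentage is the stated unit
of analysis); pooled-count percentages are reported alongside since the
two differ when trials have unequal lengths.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from statistics import mean, stdev
from typing import Iterable, Optional, Sequence

from . import cupworld
from .classifier import StrategyLabel, classify_trial
from .errors import DomainError
from .notation import canonicalize

__all__ = [
    "TrialRecord",
    "TrialSummary",
    "GroupSummary",
    "AgeClass",
    "AGE_CLASSES",
    "age_class_of",
    "select_last_trial",
    "summarize_trial",
    "summarize_group",
    "subassembly_family_pct",
    "round_half_up",
]

SPECIES = ("human", "chimpanzee", "bonobo", "gorilla", "orangutan")


@dataclass(frozen=True)
class TrialRecord:
    """Metadata plus the event sequence for one trial — the unit of analysis."""

    participant_id: str
    species: str
    trial_id: str
    n_cups: int
    events: tuple  # tuple[ActionEvent, ...]
    age_months: Optional[int] = None
    date: Optional[str] = None  # ISO-8601, used for chronological order

    def __post_init__(self):
        if self.species not in SPECIES:
            raise DomainError(f"unknown species {self.species!r}")
        if self.n_cups < 1:
            raise DomainError(f"n_cups must be >= 1, got {self.n_cups}")
        object.__setattr__(self, "events", tuple(self.events))


@dataclass(frozen=True)
class TrialSummary:
    participant_id: str
    trial_id: str
    n_cups: int
    total_manipulations: int
    per_category_counts: dict
    per_category_pct: dict
    success: bool
    max_nesting: int
    hierarchical_level_final: int
    undefined_pcts: bool = False  # True for zero-event trials
    age_months: Optional[int] = None
    species: Optional[str] = None


@dataclass(frozen=True)
class GroupSummary:
    group_label: str
    n_trials: int
    cups_provided_range: tuple  # (min, max)
    max_in_nesting_range: tuple  # (min, max)
    success_rate: float  # percentage
    min_manipulations: int
    max_manipulations: int
    mean_manipulations: float
    sd_manipulations: Optional[float]  # sample SD; None when n == 1
    mean_pct: dict  # unweighted mean of member trials' percentages
    pooled_pct: dict  # pooled-count percentages


@dataclass(frozen=True)
class AgeClass:
    """Inclusive age bin in completed months."""

    lower_months: int
    upper_months: int

    @property
    def label(self) -> str:
        def ym(m: int) -> str:
            return f"{m // 12}y{m % 12}m"

        return f"{ym(self.lower_months)}-{ym(self.upper_months)}"

    def __contains__(self, months: int) -> bool:
        return self.lower_months <= months <= self.upper_months


#: The six half-year age classes spanning 1y0m through 4y0m.
AGE_CLASSES = (
    AgeClass(12, 17),
    AgeClass(18, 23),
    AgeClass(24, 29),
    AgeClass(30, 35),
    AgeClass(36, 41),
    AgeClass(42, 48),
)


def age_class_of(age_months: int) -> Optional[AgeClass]:
    """The age class containing ``age_months``, or None if out of range."""
    for ac in AGE_CLASSES:
        if age_months in ac:
            return ac
    return None


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Presentation rounding: one decimal, ties away from zero."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def select_last_trial(trials: Sequence[TrialRecord]) -> TrialRecord:
    """The chronologically last trial among those with the most cups.

    Chronology follows the ``date`` field when every trial has one,
    otherwise list order. The maximum-cups key dominates recency.
    """
    trials = list(trials)
    if not trials:
        raise DomainError("participant has no trials")
    if all(t.date is not None for t in trials):
        trials.sort(key=lambda t: t.date)
    top = max(t.n_cups for t in trials)
    return [t for t in trials if t.n_cups == top][-1]


def summarize_trial(trial: TrialRecord) -> TrialSummary:
    """Counts, percentages, success and structural metrics for one trial."""
    labeled = classify_trial(trial)
    counts = {lab: 0 for lab in StrategyLabel}
    for le in labeled:
        counts[le.label] += 1
    total = len(labeled)
    if total:
        pct = {lab: 100.0 * c / total for lab, c in counts.items()}
        undefined = False
    else:
        pct = {lab: 0.0 for lab in StrategyLabel}
        undefined = True
    events, _ = canonicalize(trial.events, trial.n_cups)
    final = cupworld.replay(events, trial.n_cups)[-1]
    largest = max(final.structures, key=len)
    return TrialSummary(
        participant_id=trial.participant_id,
        trial_id=trial.trial_id,
        n_cups=trial.n_cups,
        total_manipulations=total,
        per_category_counts=counts,
        per_category_pct=pct,
        success=cupworld.is_complete_seriation(final),
        max_nesting=cupworld.max_nesting(final),
        hierarchical_level_final=cupworld.hierarchical_level(largest),
        undefined_pcts=undefined,
        age_months=trial.age_months,
        species=trial.species,
    )


def summarize_group(
    trials: Iterable[TrialRecord], group_label: str
) -> GroupSummary:
    """Aggregate member trials of one age class or species pool."""
    summaries = [summarize_trial(t) for t in trials]
    if not summaries:
        raise DomainError(f"group {group_label!r} is empty")
    n = len(summaries)
    totals = [s.total_manipulations for s in summaries]
    pooled_counts = {lab: 0 for lab in StrategyLabel}
    for s in summaries:
        for lab, c in s.per_category_counts.items():
            pooled_counts[lab] += c
    pooled_total = sum(pooled_counts.values())
    pooled_pct = {
        lab: (100.0 * c / pooled_total if pooled_total else 0.0)
        for lab, c in pooled_counts.items()
    }
    mean_pct = {
        lab: mean(s.per_category_pct[lab] for s in summaries)
        for lab in StrategyLabel
    }
    return GroupSummary(
        group_label=group_label,
        n_trials=n,
        cups_provided_range=(min(s.n_cups for s in summaries),
                             max(s.n_cups for s in summaries)),
        max_in_nesting_range=(min(s.max_nesting for s in summaries),
                              max(s.max_nesting for s in summaries)),
        success_rate=100.0 * sum(s.success for s in summaries) / n,
        min_manipulations=min(totals),
        max_manipulations=max(totals),
        mean_manipulations=mean(totals),
        sd_manipulations=stdev(totals) if n > 1 else None,
        mean_pct=mean_pct,
        pooled_pct=pooled_pct,
    )


@dataclass(frozen=True)
class SubassemblyFamily:
    """Subassembly-family share: total and its two components, in percent."""

    total: float
    single_recipient: float
    unit_unit: float

    @classmethod
    def from_parts(cls, single_recipient: float, unit_unit: float):
        return cls(single_recipient + unit_unit, single_recipient, unit_unit)


def subassembly_family_pct(summary) -> SubassemblyFamily:
    """Subassembly-family percentage of a trial or group summary.

    The total is identically the sum of the single-recipient
    (subassembly) and unit–unit components; for a group summary the
    unweighted-mean percentages are used.
    """
    pct = summary.mean_pct if isinstance(summary, GroupSummary) else summary.per_category_pct
    single = pct[StrategyLabel.SUBASSEMBLY]
    uu = pct[StrategyLabel.UNIT_UNIT]
    return SubassemblyFamily.from_parts(single, uu)
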