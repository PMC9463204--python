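"""Worked-example trials used in docs, analysis scripts and tests.

These are synthetic fixtures: coded sequences constructed to exercise
the pipeline and to match published per-category counts where those are
known, not transcriptions of any observed trial (no raw coded sequences
are publicly deposited).
"""

from __future__ import annotations

import numpy as np

from . import cupworld
from .metrics import TrialRecord
from .notation import parse_sequence
from .synthetic import AgentConfig, simulate_trial
from .classifier import StrategyLabel

__all__ = [
    "WORKED_CODE",
    "worked_code_trial",
    "SUBASSEMBLY_HEAVY_SEQUENCE",
    "subassembly_heavy_trial",
    "chimpanzee_like_trials",
]

#: The canonical two-action teaching example: insert the smallest cup
#: into the second cup, then add the two-cup unit into the third cup.
WORKED_CODE = "1N2/12N3"


def worked_code_trial() -> TrialRecord:
    """The two-action worked example as a 3-cup trial record."""
    return TrialRecord(
        participant_id="worked",
        species="human",
        trial_id="worked-t0",
        n_cups=3,
        events=tuple(parse_sequence(WORKED_CODE, n_cups=3)),
        age_months=40,
    )


#: Synthetic reconstruction of a high-subassembly chimpanzee-like trial:
#: 23 manipulative actions over nine cups, of which 9 classify as
#: subassembly and 2 as unit-unit (plus 1 pairing, 1 pot, 1 put,
#: 6 disassemble, 1 pile and 2 other), ending in complete seriation.
SUBASSEMBLY_HEAVY_SEQUENCE = (
    "2N3/1N23/123H4/123N4/123D4/123N4/1234N5/1234D5/1234N5/12345N6/"
    "12345D6/12345N6/9XVF/8N7/123456N87/123456D87/123456N87/123456D87/"
    "8D7/123456N7/1234567N8/9XBF/12345678N9"
)


def subassembly_heavy_trial() -> TrialRecord:
    """The 23-action subassembly-heavy synthetic trial (nine cups)."""
    return TrialRecord(
        participant_id="subheavy",
        species="chimpanzee",
        trial_id="subheavy-t0",
        n_cups=9,
        events=tuple(parse_sequence(SUBASSEMBLY_HEAVY_SEQUENCE, n_cups=9)),
    )


def chimpanzee_like_trials(
    n_success: int = 7, n_trials: int = 10, n_cups: int = 9, seed: int = 0
) -> list[TrialRecord]:
    """A pool of adult-chimpanzee-like trials with a fixed success split.

    ``n_success`` trials come from accurate agents that run until
    complete seriation; the rest come from agents whose action budget is
    exhausted before a full structure can exist, so they cannot succeed.
    The split is an input, not a simulation outcome: the pool is built
    for analyses that start from a known number of successful trials.
    """
    if not 0 <= n_success <= n_trials:
        raise ValueError("need 0 <= n_success <= n_trials")
    mixed = {
        StrategyLabel.PAIRING: 0.2,
        StrategyLabel.POT: 0.3,
        StrategyLabel.SUBASSEMBLY: 0.2,
        StrategyLabel.UNIT_UNIT: 0.1,
        StrategyLabel.DISASSEMBLE: 0.1,
        StrategyLabel.OTHER: 0.1,
    }
    good = AgentConfig(mixed, size_judgment_error=0.0, action_budget=300)
    # a pure-pot agent seriates deterministically in n - 1 moves
    pot_only = AgentConfig({StrategyLabel.POT: 1.0}, action_budget=n_cups)
    # budget below the n_cups - 1 minimum combine moves: failure is certain
    poor = AgentConfig(
        mixed, size_judgment_error=0.3, action_budget=n_cups - 2
    )
    trials = []
    for i in range(n_trials):
        rng = np.random.default_rng(seed * 1000 + i)
        if i < n_success:
            rec, _ = simulate_trial(
                good,
                n_cups,
                rng=rng,
                participant_id=f"chimp-{i % 5}",
                trial_id=f"chimp-t{i}",
                species="chimpanzee",
            )
            final = cupworld.replay(rec.events, n_cups)[-1]
            if not cupworld.is_complete_seriation(final):
                # the rare wedged run: substitute the deterministic seriator
                rec, _ = simulate_trial(
                    pot_only,
                    n_cups,
                    rng=np.random.default_rng(seed * 1000 + i),
                    participant_id=f"chimp-{i % 5}",
                    trial_id=f"chimp-t{i}",
                    species="chimpanzee",
                )
        else:
            rec, _ = simulate_trial(
                poor,
                n_cups,
                rng=rng,
                participant_id=f"chimp-{i % 5}",
                trial_id=f"chimp-t{i}",
                species="chimpanzee",
            )
        trials.append(rec)
    return trials
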