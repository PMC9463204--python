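"""Simulator tests: determinism, feasibility, efficiency, noise effects."""

import numpy as np
import pytest

from cupgrammar import cupworld
from cupgrammar.classifier import StrategyLabel, classify_trial
from cupgrammar.errors import ConfigError, DomainError
from cupgrammar.notation import parse_sequence, render_sequence
from cupgrammar.synthetic import (
    AgentConfig,
    CohortSchedule,
    GroupSpec,
    default_cohort_schedule,
    generate_cohort,
    simulate_trial,
)
from conftest import MIXED_WEIGHTS, random_trial


def pot_agent(budget=50):
    return AgentConfig({StrategyLabel.POT: 1.0}, action_budget=budget)


class TestSimulateTrial:
    @pytest.mark.parametrize("n", range(2, 11))
    def test_pure_pot_zero_noise_achieves_min_moves(self, n):
        record, _ = simulate_trial(
            pot_agent(), n, rng=np.random.default_rng(n)
        )
        assert len(record.events) == cupworld.min_moves(n) == n - 1
        final = cupworld.replay(record.events, n)[-1]
        assert cupworld.is_complete_seriation(final)

    def test_zero_budget_gives_empty_failed_trial(self):
        record, truth = simulate_trial(
            pot_agent(budget=0), 5, rng=np.random.default_rng(0)
        )
        assert record.events == () and truth.intents == ()

    def test_fixed_seed_reproduces_identically(self):
        cfg = AgentConfig(MIXED_WEIGHTS, size_judgment_error=0.2, seed=42)
        a, ta = simulate_trial(cfg, 9)
        b, tb = simulate_trial(cfg, 9)
        assert a == b and ta == tb
        assert render_sequence(a.events) == render_sequence(b.events)

    def test_one_intent_per_event(self):
        record, truth = random_trial(5, n_cups=8, error=0.1)
        assert len(truth.intents) == len(record.events)
        assert len(truth.step_probs) == len(record.events)

    @pytest.mark.parametrize("seed", range(20))
    def test_emitted_sequences_parse_and_replay_legally(self, seed):
        record, _ = random_trial(seed, n_cups=9, error=0.3)
        text = render_sequence(record.events)
        events = parse_sequence(text, record.n_cups)
        assert tuple(events) == record.events
        cupworld.replay(events, record.n_cups)  # raises on any illegal move
        assert len(classify_trial(record)) == len(events)

    def test_step_probs_cover_only_feasible_categories(self):
        _, truth = random_trial(1, n_cups=6)
        first = truth.step_probs[0]  # all cups loose: no unit exists yet
        assert StrategyLabel.SUBASSEMBLY not in first
        assert StrategyLabel.DISASSEMBLE not in first
        assert sum(first.values()) == pytest.approx(1.0)

    def test_invalid_configs_rejected(self):
        with pytest.raises(ConfigError):
            AgentConfig({StrategyLabel.POT: -1.0})
        with pytest.raises(ConfigError):
            AgentConfig({StrategyLabel.POT: 0.0})
        with pytest.raises(ConfigError):
            AgentConfig({StrategyLabel.POT: 1.0}, size_judgment_error=1.5)


class TestNoiseEffects:
    def test_success_rate_non_increasing_in_size_error(self):
        """More misjudged size comparisons never help seriation."""
        rates = []
        for error in (0.0, 0.15, 0.30):
            succ = 0
            for seed in range(500):
                record, _ = random_trial(seed, n_cups=6, error=error, budget=40)
                final = cupworld.replay(record.events, 6)[-1]
                succ += cupworld.is_complete_seriation(final)
            rates.append(succ / 500)
        assert rates[0] >= rates[1] >= rates[2]

    def test_parameter_recovery_on_seeded_cohort(self):
        """Classified proportions match feasibility-adjusted intents."""
        cfg = AgentConfig(
            MIXED_WEIGHTS,
            size_judgment_error=0.0,
            action_budget=100,
            stop_on_success=False,
        )
        target = {lab: 0.0 for lab in StrategyLabel}
        observed = {lab: 0 for lab in StrategyLabel}
        n_events = 0
        for seed in range(200):
            record, truth = simulate_trial(
                cfg, 9, rng=np.random.default_rng(seed)
            )
            for probs in truth.step_probs:
                for lab, p in probs.items():
                    target[lab] += p
            for le in classify_trial(record):
                observed[le.label] += 1
            n_events += len(record.events)
        for lab in StrategyLabel:
            t = 100.0 * target[lab] / n_events
            o = 100.0 * observed[lab] / n_events
            assert abs(t - o) <= 3.0, (lab, t, o)


class TestGenerateCohort:
    def test_default_schedule_has_seven_groups(self):
        schedule = default_cohort_schedule()
        assert len(schedule.groups) == 7
        pairs = generate_cohort(schedule, 3)
        species = {rec.species for rec, _ in pairs}
        assert species == {"human", "chimpanzee"}
        chimp = [rec for rec, _ in pairs if rec.species == "chimpanzee"]
        assert len(chimp) == 10

    def test_reproducible_from_schedule_and_seed(self):
        schedule = default_cohort_schedule()
        assert generate_cohort(schedule, 11) == generate_cohort(schedule, 11)

    def test_single_participant_single_trial(self):
        spec = GroupSpec(
            label="solo",
            species="human",
            config=pot_agent(),
            n_participants=1,
            n_cups_range=(5, 5),
            age_months_range=(36, 41),
        )
        pairs = generate_cohort(CohortSchedule((spec,)), 0)
        assert len(pairs) == 1
        assert pairs[0][0].participant_id == "solo-p00"
        assert 36 <= pairs[0][0].age_months <= 41

    def test_empty_schedule_rejected(self):
        with pytest.raises(DomainError):
            CohortSchedule(())

    def test_subassembly_gradient_shows_in_classified_output(self):
        """Raising the subassembly weight raises the classified share."""
        def family_share(sub_weight, seed):
            w = dict(MIXED_WEIGHTS)
            w[StrategyLabel.SUBASSEMBLY] = sub_weight
            spec = GroupSpec(
                label=f"w{sub_weight}",
                species="human",
                config=AgentConfig(w, action_budget=60, stop_on_success=False),
                n_participants=15,
                n_cups_range=(9, 9),
                age_months_range=(36, 41),
            )
            counts = tot = 0
            for rec, _ in generate_cohort(CohortSchedule((spec,)), seed):
                for le in classify_trial(rec):
                    counts += le.label in (
                        StrategyLabel.SUBASSEMBLY,
                        StrategyLabel.UNIT_UNIT,
                    )
                    tot += 1
            return counts / tot

        assert family_share(0.05, 1) < family_share(0.6, 1)
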