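"""Summary-statistics tests: trial/group aggregation, age bins, rounding."""

import pytest

from cupgrammar.classifier import StrategyLabel
from cupgrammar.errors import DomainError
from cupgrammar.examples import chimpanzee_like_trials, subassembly_heavy_trial
from cupgrammar.metrics import (
    AGE_CLASSES,
    SubassemblyFamily,
    TrialRecord,
    age_class_of,
    round_half_up,
    select_last_trial,
    subassembly_family_pct,
    summarize_group,
    summarize_trial,
)
from cupgrammar.notation import parse_sequence
from conftest import random_trial


def trial(sequence: str, n_cups: int, **kw) -> TrialRecord:
    kw.setdefault("participant_id", "p")
    kw.setdefault("species", "human")
    kw.setdefault("trial_id", "t")
    return TrialRecord(
        n_cups=n_cups, events=tuple(parse_sequence(sequence, n_cups)), **kw
    )


class TestSelectLastTrial:
    def test_max_cups_then_last(self):
        trials = [
            trial("", 5, trial_id="a"),
            trial("", 9, trial_id="b"),
            trial("", 9, trial_id="c"),
        ]
        assert select_last_trial(trials).trial_id == "c"

    def test_max_cups_dominates_recency(self):
        trials = [trial("", 9, trial_id="a"), trial("", 5, trial_id="b")]
        assert select_last_trial(trials).trial_id == "a"

    def test_single_trial(self):
        t = trial("", 4)
        assert select_last_trial([t]) is t

    def test_dates_override_list_order(self):
        trials = [
            trial("", 9, trial_id="late", date="2020-05-01"),
            trial("", 9, trial_id="early", date="2020-01-01"),
        ]
        assert select_last_trial(trials).trial_id == "late"

    def test_empty_raises(self):
        with pytest.raises(DomainError):
            select_last_trial([])


class TestSummarizeTrial:
    def test_worked_code(self):
        s = summarize_trial(trial("1N2/12N3", 3))
        assert s.total_manipulations == 2
        assert s.success and s.max_nesting == 3
        assert s.hierarchical_level_final == 2
        assert s.per_category_pct[StrategyLabel.PAIRING] == 50.0
        assert s.per_category_pct[StrategyLabel.SUBASSEMBLY] == 50.0

    def test_counts_sum_to_total_and_pcts_to_100(self):
        for seed in range(20):
            record, _ = random_trial(seed, n_cups=8, error=0.2)
            s = summarize_trial(record)
            assert sum(s.per_category_counts.values()) == s.total_manipulations
            if s.total_manipulations:
                assert sum(s.per_category_pct.values()) == pytest.approx(100.0)

    def test_success_implies_max_nesting_equals_n_cups(self):
        for seed in range(20):
            record, _ = random_trial(seed, n_cups=6, error=0.1)
            s = summarize_trial(record)
            if s.success:
                assert s.max_nesting == record.n_cups

    def test_empty_trial_flagged(self):
        s = summarize_trial(trial("", 3))
        assert s.total_manipulations == 0
        assert not s.success
        assert s.undefined_pcts
        assert all(v == 0.0 for v in s.per_category_pct.values())

    def test_subassembly_heavy_fixture(self):
        s = summarize_trial(subassembly_heavy_trial())
        assert s.total_manipulations == 23
        assert s.per_category_counts[StrategyLabel.SUBASSEMBLY] == 9
        assert s.per_category_counts[StrategyLabel.UNIT_UNIT] == 2
        fam = subassembly_family_pct(s)
        assert round_half_up(fam.total) == 47.8


class TestSummarizeGroup:
    def test_basic_aggregates(self):
        trials = [trial("1N2/12N3", 3), trial("1N2", 3)]
        g = summarize_group(trials, "demo")
        assert g.n_trials == 2
        assert g.success_rate == 50.0
        assert (g.min_manipulations, g.max_manipulations) == (1, 2)
        assert g.mean_manipulations == 1.5
        assert g.cups_provided_range == (3, 3)

    def test_against_hand_rolled_tally(self):
        records = [random_trial(s, n_cups=7, error=0.15)[0] for s in range(8)]
        g = summarize_group(records, "sim")
        summaries = [summarize_trial(r) for r in records]
        # spreadsheet-style recomputation
        assert g.success_rate == pytest.approx(
            100.0 * sum(s.success for s in summaries) / 8
        )
        for lab in StrategyLabel:
            assert g.mean_pct[lab] == pytest.approx(
                sum(s.per_category_pct[lab] for s in summaries) / 8
            )
            pooled_n = sum(s.total_manipulations for s in summaries)
            assert g.pooled_pct[lab] == pytest.approx(
                100.0 * sum(s.per_category_counts[lab] for s in summaries) / pooled_n
            )

    def test_success_rate_invariant_under_reordering(self):
        records = [random_trial(s, n_cups=5)[0] for s in range(6)]
        a = summarize_group(records, "g").success_rate
        b = summarize_group(list(reversed(records)), "g").success_rate
        assert a == b

    def test_mean_and_pooled_agree_for_equal_lengths(self):
        trials = [trial("1N2/12N3", 3), trial("1N2/3N12", 3, trial_id="t2")]
        g = summarize_group(trials, "equal")
        for lab in StrategyLabel:
            assert g.mean_pct[lab] == pytest.approx(g.pooled_pct[lab])

    def test_zero_family_trial_never_raises_pooled_family_share(self):
        base = [random_trial(s, n_cups=6)[0] for s in range(4)]
        g0 = summarize_group(base, "g")
        extra = trial("1N2", 3)  # pairing only
        g1 = summarize_group(base + [extra], "g")
        fam0 = (
            g0.pooled_pct[StrategyLabel.SUBASSEMBLY]
            + g0.pooled_pct[StrategyLabel.UNIT_UNIT]
        )
        fam1 = (
            g1.pooled_pct[StrategyLabel.SUBASSEMBLY]
            + g1.pooled_pct[StrategyLabel.UNIT_UNIT]
        )
        assert fam1 <= fam0

    def test_sd_absent_for_single_trial(self):
        g = summarize_group([trial("1N2", 3)], "solo")
        assert g.sd_manipulations is None

    def test_empty_group_raises(self):
        with pytest.raises(DomainError):
            summarize_group([], "empty")

    def test_constructed_seven_of_ten_success_pool(self):
        g = summarize_group(chimpanzee_like_trials(seed=2), "chimpanzee")
        assert g.success_rate == 70.0


class TestSubassemblyFamily:
    @pytest.mark.parametrize(
        "single,uu,total",
        [(24.1, 7.8, 31.9), (11.6, 8.1, 19.7), (0.0, 0.0, 0.0)],
    )
    def test_total_is_sum_of_parts(self, single, uu, total):
        fam = SubassemblyFamily.from_parts(single, uu)
        assert fam.total == pytest.approx(total)
        assert fam.total == fam.single_recipient + fam.unit_unit


class TestAgeClasses:
    def test_six_bins_cover_12_to_48_months(self):
        assert len(AGE_CLASSES) == 6
        assert AGE_CLASSES[0].lower_months == 12
        assert AGE_CLASSES[-1].upper_months == 48

    @pytest.mark.parametrize(
        "months,label",
        [(12, "1y0m-1y5m"), (17, "1y0m-1y5m"), (18, "1y6m-1y11m"),
         (42, "3y6m-4y0m"), (48, "3y6m-4y0m")],
    )
    def test_binning(self, months, label):
        assert age_class_of(months).label == label

    def test_out_of_range_is_none(self):
        assert age_class_of(11) is None
        assert age_class_of(49) is None


class TestRounding:
    def test_half_up_at_presentation(self):
        assert round_half_up(47.826086, 1) == 47.8
        assert round_half_up(0.25, 1) == 0.3
        assert round_half_up(0.05, 1) == 0.1
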