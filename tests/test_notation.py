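"""Parser/renderer tests: grammar, dialects, round-trips, canonicalization."""

import pytest
from hypothesis import given, settings, strategies as st

from cupgrammar.errors import CanonicalizationError, ParseError, ValidationError
from cupgrammar.notation import (
    FLOOR,
    ActionEvent,
    CanonFlag,
    Verb,
    XSubtype,
    canonicalize,
    parse_sequence,
    render_sequence,
)
from conftest import random_trial


class TestParse:
    def test_worked_code(self):
        events = parse_sequence("1N2/12N3")
        assert events == [
            ActionEvent((1,), Verb("N"), (2,)),
            ActionEvent((1, 2), Verb("N"), (3,)),
        ]

    def test_empty_string_gives_empty_list(self):
        assert parse_sequence("") == []
        assert parse_sequence("   ") == []

    def test_single_token(self):
        assert parse_sequence("4N5") == [ActionEvent((4,), Verb("N"), (5,))]

    @pytest.mark.parametrize(
        "text",
        ["1N2/12N3", "1n2/12n3", " 1N2 / 12N3 ", "1N2/ 12n3"],
    )
    def test_case_and_whitespace_insensitive(self, text):
        assert parse_sequence(text) == parse_sequence("1N2/12N3")

    def test_extended_dialect(self):
        events = parse_sequence("1.2N3/1.2.3N10")
        assert events[0] == ActionEvent((1, 2), Verb("N"), (3,))
        assert events[1] == ActionEvent((1, 2, 3), Verb("N"), (10,))

    def test_dialect_equivalence_for_small_ranks(self):
        compact = parse_sequence("1N2/12N3")
        extended = parse_sequence("1N2/1.2N3")
        assert compact == extended

    def test_verbs_and_floor(self):
        events = parse_sequence("123H4/12D3/9XVF/9XF")
        assert [e.verb.code for e in events] == ["H", "D", "X", "X"]
        assert events[2].verb.subtype is XSubtype.REVERSE
        assert events[3].verb.subtype is XSubtype.UNSPECIFIED
        assert events[2].loc is FLOOR

    @pytest.mark.parametrize("bad", ["1Z2", "NN2", "1N", "/1N2", "1N2//3N4", "1M2"])
    def test_malformed_token_raises_positioned_error(self, bad):
        with pytest.raises(ParseError) as exc:
            parse_sequence(bad)
        assert exc.value.position >= 0

    def test_parse_error_carries_position(self):
        with pytest.raises(ParseError) as exc:
            parse_sequence("1N2/xx/3N4")
        assert exc.value.position == 1
        assert exc.value.token == "xx"

    def test_duplicate_cup_in_token_rejected(self):
        with pytest.raises(ValidationError):
            parse_sequence("11N2")

    def test_object_location_overlap_rejected(self):
        with pytest.raises(ValidationError):
            parse_sequence("1N12")

    def test_rank_outside_declared_n_cups_rejected(self):
        with pytest.raises(ValidationError):
            parse_sequence("1N5", n_cups=3)

    def test_floor_location_rejected_for_combine_verbs(self):
        for text in ("1NF", "1HF", "1DF"):
            with pytest.raises(ValidationError):
                parse_sequence(text)


class TestRender:
    def test_worked_code_round(self):
        events = [
            ActionEvent((1,), Verb("N"), (2,)),
            ActionEvent((1, 2), Verb("N"), (3,)),
        ]
        assert render_sequence(events) == "1N2/12N3"

    def test_empty(self):
        assert render_sequence([]) == ""

    def test_extended_dialect_forced_by_two_digit_rank(self):
        text = render_sequence([ActionEvent((1, 10), Verb("N"), (11,))])
        assert text == "1.10N11"

    def test_invalid_event_rejected(self):
        with pytest.raises(ValidationError):
            render_sequence([ActionEvent((1, 1), Verb("N"), (2,))])


class TestRoundTrip:
    @pytest.mark.parametrize("seed", range(0, 200, 1))
    def test_simulated_sequences_round_trip(self, seed):
        """parse(render(e)) == e on generator output (200 sequences)."""
        n_cups = 3 + seed % 8
        record, _ = random_trial(seed, n_cups=n_cups, error=0.1)
        text = render_sequence(record.events, n_cups)
        assert tuple(parse_sequence(text, n_cups)) == record.events

    @given(
        n_cups=st.integers(2, 14),
        data=st.data(),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_structural_round_trip(self, n_cups, data):
        """Round-trip holds for arbitrary structurally valid events."""
        ranks = list(range(1, n_cups + 1))
        cups = data.draw(
            st.lists(st.sampled_from(ranks), min_size=2, max_size=n_cups, unique=True)
        )
        split = data.draw(st.integers(1, len(cups) - 1))
        obj, loc = tuple(cups[:split]), tuple(cups[split:])
        verb = data.draw(
            st.sampled_from(
                [Verb("N"), Verb("H"), Verb("D")]
                + [Verb("X", s) for s in XSubtype]
            )
        )
        event = ActionEvent(obj, verb, loc)
        assert parse_sequence(render_sequence([event], n_cups), n_cups) == [event]

    def test_render_of_parse_is_canonical_text(self):
        assert render_sequence(parse_sequence(" 1n2 / 12N3 ")) == "1N2/12N3"


class TestCanonicalize:
    def test_partial_location_rewritten_and_flagged(self):
        # coder wrote 1N3 after 2N3: cup 3 already holds cup 2
        events = parse_sequence("2N3/1N3")
        canon, flags = canonicalize(events, n_cups=3)
        assert canon[1].loc == (2, 3)
        assert flags == [CanonFlag(1, "loc", (3,), (2, 3))]

    def test_canonical_sequence_unchanged(self):
        events = parse_sequence("1N2/12N3")
        canon, flags = canonicalize(events, n_cups=3)
        assert canon == events and flags == []

    def test_idempotent(self):
        events = parse_sequence("2N3/1N3/123H4")
        once, _ = canonicalize(events, n_cups=4)
        twice, flags = canonicalize(once, n_cups=4)
        assert twice == once and flags == []

    def test_unresolvable_token_reports_event_index(self):
        # cup 2 is buried under cup 1 inside cup 3: not top-contiguous
        events = parse_sequence("2N3/1N23/2N4")
        with pytest.raises(CanonicalizationError) as exc:
            canonicalize(events, n_cups=4)
        assert exc.value.index == 2

    def test_detach_location_rewritten_to_remainder(self):
        events = parse_sequence("1N2/12N3/1D2")
        canon, flags = canonicalize(events, n_cups=3)
        assert canon[2].loc == (2, 3)
        assert flags and flags[0].index == 2
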