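"""Deck combinatorics, schedules, feedback and the error taxonomy."""

import itertools

import numpy as np
import pytest

from schemabg.task_environment import (
    COLOURS,
    RULES,
    SHAPES,
    Card,
    RuleSchedule,
    TrialRecord,
    applied_rule,
    build_trial_sequence,
    classify_error,
    count_categories,
    generate_deck,
    give_feedback,
    stimulus_match_vector,
)


def brute_force_deck():
    """Independent enumeration: keep cards matching no target on >=2 features."""
    deck = []
    for colour, shape, number in itertools.product(COLOURS, SHAPES, range(1, 5)):
        card = Card(colour, shape, number)
        ambiguous = False
        for t in range(1, 5):
            hits = sum(card.target_index(r) == t for r in RULES)
            if hits >= 2:
                ambiguous = True
        if not ambiguous:
            deck.append(card)
    return deck


class TestDeck:
    def test_matches_brute_force_enumeration(self):
        assert set(generate_deck()) == set(brute_force_deck())

    def test_cardinality_and_match_sums(self):
        deck = generate_deck()
        assert len(deck) == 24
        for card in deck:
            assert sum(stimulus_match_vector(card)) == 3

    def test_triples_bijective_onto_distinct_index_triples(self):
        triples = {c.target_triple() for c in generate_deck()}
        expected = {
            t for t in itertools.permutations(range(1, 5), 3)
        } | {  # permutations of length 3 from 4 values = ordered distinct triples
            t
            for t in itertools.product(range(1, 5), repeat=3)
            if len(set(t)) == 3
        }
        assert triples == expected
        assert len(triples) == 24

    def test_two_red_crosses_matches_targets_1_2_3(self):
        card = Card("red", "cross", 2)
        assert card in generate_deck()
        assert stimulus_match_vector(card) == (1, 1, 1, 0)


class TestSequenceAndRules:
    def test_sequence_is_deterministic_and_from_deck(self):
        deck = set(generate_deck())
        a = build_trial_sequence(64, np.random.default_rng(7))
        b = build_trial_sequence(64, np.random.default_rng(7))
        assert a == b
        assert len(a) == 64
        assert all(c in deck for c in a)

    def test_single_copy_is_a_permutation(self):
        seq = build_trial_sequence(24, np.random.default_rng(1))
        assert set(seq) == set(generate_deck())

    def test_invalid_length_rejected(self):
        with pytest.raises(ValueError):
            build_trial_sequence(0, np.random.default_rng(0))

    def test_applied_rule_unique_for_deck_cards(self):
        for card in generate_deck():
            n_rules = 0
            for resp in range(1, 5):
                rule = applied_rule(card, resp)
                if rule is not None:
                    n_rules += 1
                    assert card.target_index(rule) == resp
            assert n_rules == 3  # one rule per matching target

    def test_applied_rule_examples(self):
        card = Card("red", "cross", 2)
        assert applied_rule(card, 1) == "colour"
        assert applied_rule(card, 4) is None

    def test_feedback_and_criterion_switch(self):
        rng = np.random.default_rng(5)
        sched = RuleSchedule(rng=rng, active_rule="colour")
        card = Card("red", "cross", 2)
        assert give_feedback(card, 3, sched) == -1  # applied shape
        # 10 consecutive correct sorts complete a category and switch rule
        for _ in range(10):
            assert give_feedback(card, 1, sched) == 1
        assert sched.categories == 1
        assert sched.active_rule in ("shape", "number")

    def test_random_run_median_is_3_5(self):
        rng = np.random.default_rng(11)
        sched = RuleSchedule(rng=rng, mode="random_run")
        draws = []
        for _ in range(10_000):
            sched._draw_run_target()
            draws.append(sched._run_target)
        assert np.median(draws) == pytest.approx(3.5, abs=0.5)
        assert set(draws) == {2, 3, 4, 5}


def _rec(t, rule, feedback, response=1):
    """Minimal TrialRecord for taxonomy fixtures."""
    return TrialRecord(
        trial_index=t,
        card=Card("red", "cross", 2),
        response=response,
        applied_rule=rule,
        active_rule="number",
        feedback=feedback,
        rt_cycles=100,
    )


class TestErrorTaxonomy:
    def test_perseverative_error(self):
        # colour rewarded, then punished twice: repeating it is PE
        hist = [_rec(0, "colour", 1), _rec(1, "colour", -1), _rec(2, "colour", -1)]
        assert classify_error(hist, 2) == "PE"

    def test_set_loss_error(self):
        hist = [_rec(0, "colour", 1), _rec(1, "shape", -1)]
        assert classify_error(hist, 1) == "SL"

    def test_integration_error_two_back(self):
        # shape punished at t-2, colour punished at t-1: re-trying shape
        # fails to integrate the earlier feedback
        hist = [_rec(0, "shape", -1), _rec(1, "colour", -1), _rec(2, "shape", -1)]
        assert classify_error(hist, 2) == "IE"

    def test_integration_error_one_back(self):
        # colour rewarded earlier; shape punished at t-1 and re-adopted
        hist = [
            _rec(0, "colour", 1),
            _rec(1, "colour", -1),
            _rec(2, "shape", -1),
            _rec(3, "shape", -1),
        ]
        assert classify_error(hist, 3) == "IE"

    def test_unavoidable_switch_error_is_other(self):
        hist = [_rec(0, "colour", 1), _rec(1, "colour", -1)]
        assert classify_error(hist, 1) == "other_error"

    def test_first_trial_error_is_other(self):
        assert classify_error([_rec(0, "shape", -1)], 0) == "other_error"

    def test_correct_and_omission(self):
        hist = [_rec(0, "number", 1), _rec(1, None, 0, response=None)]
        assert classify_error(hist, 0) == "correct"
        assert classify_error(hist, 1) == "omission"

    def test_out_of_range_rejected(self):
        with pytest.raises(IndexError):
            classify_error([_rec(0, "colour", 1)], 5)

    def test_classification_is_total(self, default_session):
        classes = {"correct", "PE", "SL", "IE", "other_error", "omission"}
        for rec in default_session.records:
            assert rec.error_class in classes


class TestCategories:
    def test_three_completed_runs(self):
        hist = [_rec(t, "number", 1) for t in range(30)]
        assert count_categories(hist) == 3

    def test_all_error_session(self):
        hist = [_rec(t, "shape", -1) for t in range(20)]
        assert count_categories(hist) == 0

    def test_accounting_identity(self, default_session):
        r = default_session
        assert r.counts_identity()
        assert (
            r.cards_correct + r.pe + r.sl + r.ie + r.other + r.omissions
            == r.n_trials
        )
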