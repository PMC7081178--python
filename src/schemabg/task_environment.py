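"""Unambiguous (Madrid) Wisconsin Card Sorting Test environment.

This module implements the task side of the simulation: the 24-card
unambiguous stimulus deck, the four fixed target cards, rule schedules
(criterion-based or random run length), binary feedback, and the
perseverative / set-loss / integration error taxonomy.

In the unambiguous variant every stimulus card shares exactly one feature
(colour, shape or number) with each of three target cards and no feature
with the fourth, so the sorting rule a participant applied can be read off
from the response alone.
"""

from __future__ import annotations

import csv
import itertools
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

__all__ = [
    "COLOURS",
    "SHAPES",
    "RULES",
    "Card",
    "TARGETS",
    "TrialRecord",
    "RuleSchedule",
    "generate_deck",
    "build_trial_sequence",
    "stimulus_match_vector",
    "applied_rule",
    "give_feedback",
    "classify_error",
    "count_categories",
    "write_trial_log",
]

#: Feature values, indexed so that value k belongs to target card k+1.
COLOURS = ("red", "green", "yellow", "blue")
SHAPES = ("triangle", "star", "cross", "circle")
#: The three sorting rules (feature dimensions).
RULES = ("colour", "shape", "number")

_COLOUR_TARGET = {c: i + 1 for i, c in enumerate(COLOURS)}
_SHAPE_TARGET = {s: i + 1 for i, s in enumerate(SHAPES)}


@dataclass(frozen=True)
class Card:
    """A stimulus card: ``number`` identical ``shape`` images in ``colour``."""

    colour: str
    shape: str
    number: int

    def __post_init__(self) -> None:
        if self.colour not in COLOURS:
            raise ValueError(f"unknown colour {self.colour!r}")
        if self.shape not in SHAPES:
            raise ValueError(f"unknown shape {self.shape!r}")
        if not 1 <= self.number <= 4:
            raise ValueError("number must be in 1..4")

    def target_index(self, rule: str) -> int:
        """Index (1-4) of the target card matching this card on ``rule``."""
        if rule == "colour":
            return _COLOUR_TARGET[self.colour]
        if rule == "shape":
            return _SHAPE_TARGET[self.shape]
        if rule == "number":
            return self.number
        raise ValueError(f"unknown rule {rule!r}")

    def target_triple(self) -> tuple[int, int, int]:
        """(colour-target, shape-target, number-target) indices."""
        return (
            _COLOUR_TARGET[self.colour],
            _SHAPE_TARGET[self.shape],
            self.number,
        )


#: The four fixed target cards: 1 red triangle, 2 green stars,
#: 3 yellow crosses, 4 blue circles.
TARGETS = (
    Card("red", "triangle", 1),
    Card("green", "star", 2),
    Card("yellow", "cross", 3),
    Card("blue", "circle", 4),
)


def generate_deck() -> list[Card]:
    """The 24 unambiguous cards.

    A card is unambiguous when its colour-target, shape-target and
    number-target indices are pairwise distinct, i.e. it shares exactly one
    feature with each of three targets and none with the fourth. There are
    4 * 3 * 2 = 24 such cards.
    """
    deck = []
    for colour, shape, number in itertools.product(COLOURS, SHAPES, range(1, 5)):
        card = Card(colour, shape, number)
        triple = card.target_triple()
        if len(set(triple)) == 3:
            deck.append(card)
    return deck


def build_trial_sequence(n_trials: int, rng: np.random.Generator) -> list[Card]:
    """Concatenate independently shuffled copies of the deck, truncated.

    Shuffling whole deck copies (rather than i.i.d. sampling) avoids long
    duplicate runs while keeping the sequence deterministic given ``rng``.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    deck = generate_deck()
    cards: list[Card] = []
    while len(cards) < n_trials:
        order = rng.permutation(len(deck))
        cards.extend(deck[i] for i in order)
    return cards[:n_trials]


def stimulus_match_vector(card: Card) -> tuple[int, int, int, int]:
    """Binary vector over the four targets: 1 iff >=1 shared feature."""
    triple = set(card.target_triple())
    return tuple(1 if (i + 1) in triple else 0 for i in range(4))


def applied_rule(card: Card, response: int) -> Optional[str]:
    """The feature dimension shared by ``card`` and the chosen target.

    For deck cards the shared dimension is unique by construction. Returns
    ``None`` when the card shares no feature with the chosen target.
    """
    if not 1 <= response <= 4:
        raise ValueError("response must be a target index in 1..4")
    shared = [r for r in RULES if card.target_index(r) == response]
    if not shared:
        return None
    return shared[0]


@dataclass
class RuleSchedule:
    """Administers the active sorting rule and the covert rule switches.

    mode='criterion': the rule changes after ``criterion_length`` consecutive
    correct sorts (the classic "after 10 correct trials" administration).
    mode='random_run': the rule changes after a run of consecutive correct
    sorts whose length is drawn uniformly from ``run_length_support``
    (default {2,3,4,5}, median 3.5, emulating frequent-shift administrations).
    """

    rng: np.random.Generator
    mode: str = "criterion"
    criterion_length: int = 10
    run_length_support: tuple[int, ...] = (2, 3, 4, 5)
    active_rule: str = ""
    correct_run: int = 0
    categories: int = 0
    _run_target: int = field(default=0, repr=False)

    def __post_init__(self) -> None:
        if self.mode not in ("criterion", "random_run"):
            raise ValueError(f"unknown schedule mode {self.mode!r}")
        if not self.active_rule:
            self.active_rule = RULES[self.rng.integers(len(RULES))]
        self._draw_run_target()

    def _draw_run_target(self) -> None:
        if self.mode == "criterion":
            self._run_target = self.criterion_length
        else:
            support = self.run_length_support
            self._run_target = int(support[self.rng.integers(len(support))])

    def register(self, feedback: int) -> None:
        """Update the correct-run counter; switch rule when criterion met."""
        if feedback > 0:
            self.correct_run += 1
            if self.correct_run >= self._run_target:
                self.categories += 1
                self.correct_run = 0
                others = [r for r in RULES if r != self.active_rule]
                self.active_rule = others[self.rng.integers(len(others))]
                self._draw_run_target()
        else:
            self.correct_run = 0


def give_feedback(card: Card, response: int, schedule: RuleSchedule) -> int:
    """+1 iff the applied rule equals the schedule's active rule.

    Also advances the schedule (run counter and, at criterion, the covert
    rule switch).
    """
    rule = applied_rule(card, response)
    feedback = 1 if rule == schedule.active_rule else -1
    schedule.register(feedback)
    return feedback


@dataclass
class TrialRecord:
    """One administered trial."""

    trial_index: int
    card: Card
    response: Optional[int]  # target index 1-4, or None (omission)
    applied_rule: Optional[str]
    active_rule: str
    feedback: int  # +1 / -1; 0 for omissions (no feedback delivered)
    rt_cycles: int
    error_class: str = ""
    selected_cog_rule: Optional[str] = None  # model-internal, for shift labels
    response_cycle: int = -1  # global cycle index of the response
    conflict: float = float("nan")  # sensorimotor conflict product at response


def _rule_excluded_by(record: TrialRecord, rule: str) -> bool:
    """Was ``rule`` ruled out by negative feedback on ``record``?

    Only negative feedback excludes (the rule that was applied and
    punished). Positive feedback is not used as exclusion evidence: the
    covert rule switches make stale positive feedback misleading, and the
    positive-feedback case at t-1 is already scored as a set-loss error.
    """
    return (
        record.feedback < 0
        and record.applied_rule is not None
        and rule == record.applied_rule
    )


def classify_error(history: Sequence[TrialRecord], t: int) -> str:
    """Classify the trial at index ``t`` of ``history``.

    Returns one of 'correct', 'omission', 'PE', 'SL', 'IE', 'other_error'.

    PE: the response applies the previously successful rule despite negative
    feedback on the previous trial. SL: the response changes rule despite
    positive feedback on the previous trial. IE: following negative feedback,
    the newly adopted rule was already excluded by feedback on the one or two
    preceding trials (a failure to integrate recent feedback). Everything
    else (including first-trial errors, the unavoidable error after a covert
    rule switch, and responses sharing no feature with the card) is
    'other_error'.
    """
    if not 0 <= t < len(history):
        raise IndexError("trial index out of range")
    rec = history[t]
    if rec.response is None:
        return "omission"
    if rec.feedback > 0:
        return "correct"
    rule = rec.applied_rule
    if t == 0 or history[t - 1].response is None:
        return "other_error"
    prev = history[t - 1]
    if rule is None:
        return "other_error"
    if prev.feedback > 0:
        return "SL" if rule != prev.applied_rule else "other_error"
    # negative feedback on the previous trial
    prev_success = None
    for old in reversed(history[:t]):
        if old.feedback > 0:
            prev_success = old.applied_rule
            break
    if rule == prev_success:
        return "PE"
    if _rule_excluded_by(prev, rule):
        return "IE"
    if t >= 2 and history[t - 2].response is not None and _rule_excluded_by(
        history[t - 2], rule
    ):
        return "IE"
    return "other_error"


def count_categories(history: Iterable[TrialRecord], criterion_length: int = 10) -> int:
    """Completed criterion runs implied by a session history."""
    run = 0
    categories = 0
    for rec in history:
        if rec.feedback > 0:
            run += 1
            if run >= criterion_length:
                categories += 1
                run = 0
        else:
            run = 0
    return categories


def write_trial_log(history: Sequence[TrialRecord], path) -> None:
    """Per-trial CSV log."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            [
                "trial",
                "card_colour",
                "card_shape",
                "card_number",
                "response",
                "applied_rule",
                "active_rule",
                "feedback",
                "rt_cycles",
                "error_class",
            ]
        )
        for rec in history:
            writer.writerow(
                [
                    rec.trial_index,
                    rec.card.colour,
                    rec.card.shape,
                    rec.card.number,
                    rec.response if rec.response is not None else "",
                    rec.applied_rule or "",
                    rec.active_rule,
                    rec.feedback,
                    rec.rt_cycles,
                    rec.error_class,
                ]
            )
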