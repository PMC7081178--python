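"""Cortical schema layers: leaky activation, selection, conflict-driven gain.

Two layers of rate-coded schema nodes sit above the basal ganglia loops:

* three *cognitive* schema nodes, one per sorting rule (colour, shape,
  number), driven by a constant top-down excitation ``o_ext`` plus the
  (inhibitory) thalamic output of their basal-ganglia channel;
* four *sensorimotor* schema nodes, one per target card, driven by the
  stimulus, by the currently selected cognitive schema (scaled by
  ``w_rule`` and routed to the target consistent with that rule for the
  current card), and by their own thalamic channel.

Each node integrates its input with a first-order low-pass filter
``a <- delta * a + (1 - delta) * u`` and squashes it through a logistic
saturation function with gain ``alpha`` and threshold ``beta``, keeping
outputs in (0, 1).

A schema is *selected* when its output exceeds a static threshold
``theta_s`` and the area accumulated under its output since stimulus onset
reaches an integration threshold ``theta_A`` drawn per trial — an
accumulate-to-bound decision rule that produces graded response times.

The gain of the sensorimotor saturation function adapts to response
conflict: after each feedback event it is set to a product over
sensorimotor outputs that grows with the number and strength of competing
action representations.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import exp
from typing import Optional, Sequence

__all__ = [
    "logistic",
    "CorticalLayerState",
    "SelectionThresholds",
    "step_cognitive",
    "step_sensorimotor",
    "topdown_input",
    "check_selection",
    "conflict_product",
    "update_alpha_sma",
]


def logistic(x: float, beta: float, alpha: float) -> float:
    """Saturation function 1 / (1 + exp(-alpha * (x - beta)))."""
    return 1.0 / (1.0 + exp(-alpha * (x - beta)))


@dataclass
class CorticalLayerState:
    """Per-node smoothed activation, output and accumulated area."""

    a: list[float]
    o: list[float]
    area: list[float]
    alpha: float
    beta: float
    selected: Optional[int] = None  # index of the selected node, if any

    @classmethod
    def create(cls, n: int, alpha: float, beta: float) -> "CorticalLayerState":
        return cls(a=[0.0] * n, o=[0.0] * n, area=[0.0] * n, alpha=alpha, beta=beta)

    def reset_area(self) -> None:
        """Called at stimulus onset; the integrators restart each trial."""
        for i in range(len(self.area)):
            self.area[i] = 0.0


@dataclass
class SelectionThresholds:
    """Static output threshold and per-trial integration threshold."""

    theta_s: float = 0.50
    theta_a_mean: float = 4000.0
    theta_a_sd: float = 400.0
    area_scale: float = 1.0

    def draw_theta_a(self, rng) -> float:
        """One truncated-normal integration threshold (> 0)."""
        while True:
            draw = rng.normal(self.theta_a_mean, self.theta_a_sd)
            if draw > 0.0:
                return float(draw)

    def draw_theta_a_per_node(self, rng, n: int) -> list[float]:
        """Independent threshold draws, one per accumulator node."""
        return [self.draw_theta_a(rng) for _ in range(n)]


def step_cognitive(
    state: CorticalLayerState, o_thal_prev: Sequence[float], o_ext: float, delta: float
) -> None:
    """One synchronous update of the cognitive layer.

    u_i = o_ext + o_thal_i(t-1); a smoothed; o = logistic(a; beta, alpha).
    """
    a, o, area = state.a, state.o, state.area
    alpha, beta = state.alpha, state.beta
    for i in range(len(a)):
        u = o_ext + o_thal_prev[i]
        ai = delta * a[i] + (1.0 - delta) * u
        a[i] = ai
        oi = 1.0 / (1.0 + exp(-alpha * (ai - beta)))
        o[i] = oi
        area[i] += oi


def step_sensorimotor(
    state: CorticalLayerState,
    topdown: Sequence[float],
    stim: Sequence[float],
    o_thal_prev: Sequence[float],
    delta: float,
) -> None:
    """One synchronous update of the sensorimotor layer.

    u_i = topdown_i + stim_i + o_thal_i(t-1), where ``topdown`` carries the
    rule-routed drive from the selected cognitive schema and ``stim`` the
    (noisy) stimulus input to matching targets.
    """
    if not (len(topdown) == len(stim) == len(state.a)):
        raise ValueError("input dimension mismatch")
    a, o, area = state.a, state.o, state.area
    alpha, beta = state.alpha, state.beta
    for i in range(len(a)):
        u = topdown[i] + stim[i] + o_thal_prev[i]
        ai = delta * a[i] + (1.0 - delta) * u
        a[i] = ai
        oi = 1.0 / (1.0 + exp(-alpha * (ai - beta)))
        o[i] = oi
        area[i] += oi


def topdown_input(
    target_triple: Sequence[int],
    o_cog: Sequence[float],
    selected: Optional[int],
    w_rule: float,
) -> list[float]:
    """Rule-routed cognitive drive to the four sensorimotor nodes.

    The selected cognitive schema j excites the sensorimotor node whose
    target matches the current card on dimension j; non-selected schemas
    contribute nothing (their effective connection weight is zero).
    """
    drive = [0.0, 0.0, 0.0, 0.0]
    if selected is not None:
        drive[target_triple[selected] - 1] = w_rule * o_cog[selected]
    return drive


def check_selection(
    state: CorticalLayerState,
    thresholds: SelectionThresholds,
    theta_a_draw,
) -> Optional[int]:
    """Node qualifying for selection this cycle, or None.

    A node qualifies when its output exceeds ``theta_s`` and its scaled
    accumulated area reaches its integration threshold; among simultaneous
    qualifiers the most active node wins (ties to the lowest index).
    ``theta_a_draw`` is a scalar shared by all nodes or one draw per node
    (independent accumulator noise).
    """
    if isinstance(theta_a_draw, (int, float)):
        theta = [float(theta_a_draw)] * len(state.o)
    else:
        theta = theta_a_draw
    best = None
    best_o = -1.0
    scale = thresholds.area_scale
    theta_s = thresholds.theta_s
    for i, oi in enumerate(state.o):
        if oi > theta_s and scale * state.area[i] >= theta[i] and oi > best_o:
            best = i
            best_o = oi
    return best


def conflict_product(o_sma: Sequence[float], eps_sma: float) -> float:
    """Conflict measure: product over nodes of (1 + eps_sma + o_i).

    Increases with the number and activation of competing sensorimotor
    representations and peaks when all activations peak.
    """
    prod = 1.0
    for oi in o_sma:
        prod *= 1.0 + eps_sma + oi
    return prod


def update_alpha_sma(o_sma: Sequence[float], eps_sma: float, zeta_sma: float) -> float:
    """New sensorimotor gain after a feedback event.

    alpha_sma <- (1 + zeta_sma) * prod_i (1 + eps_sma + o_i). Applied once
    per feedback; only the sensorimotor layer adapts its gain.
    """
    return (1.0 + zeta_sma) * conflict_product(o_sma, eps_sma)
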