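"""Per-schema basal-ganglia channels and reward-driven striatal plasticity.

Each cortical schema node owns a channel of six rate-coded units —
striatum D1, striatum D2, subthalamic nucleus (STN), globus pallidus
external segment (GPe), globus pallidus internal segment (GPi) and
thalamus — wired as the classic direct (striatum D1 -> GPi), indirect
(striatum D2 -> GPe -> STN/GPi) and hyperdirect (cortex -> STN -> GPi)
pathways. The cognitive layer drives a 3-channel complex, the sensorimotor
layer a 4-channel complex; the two loops are fully segregated.

The STN projection is diffuse: GPe and GPi receive the *sum* of STN
outputs over all channels of the loop, which scales pallidal output with
the global input signal and so turns per-channel disinhibition into a
competition. The thalamic unit is tonically active and its output is the
*negated* logistic of GPi drive, in (-1, 0): high GPi output means strong
cortical suppression, and a channel whose striatal D1 unit fires
disinhibits its own cortical node.

Learning acts on the striatal saturation threshold ``beta_str`` of the
cognitive channels only (identified with striatal dopamine level). After
each feedback event, a reward prediction error — the feedback-signed
difference between the channel's feature-match value and its median
cortical activation over the trial — shifts ``beta_str`` down (easier
disinhibition) for channels consistent with rewarded responses and up for
channels contradicted by them.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import exp
from typing import Sequence

__all__ = [
    "BGWeights",
    "ChannelLayerState",
    "step_striatum",
    "step_stn",
    "step_gpe",
    "step_gpi",
    "step_thalamus",
    "step_channel_layer",
    "feature_match",
    "reward_prediction_error",
    "update_beta_str",
]


@dataclass(frozen=True)
class BGWeights:
    """Pathway weights; excitatory positive, inhibitory negative."""

    ctx_stn: float = 1.20  # hyperdirect: cortex -> STN
    gpe_stn: float = -1.00  # GPe -> STN
    stn_gpe: float = 0.90  # STN (summed) -> GPe
    strd2_gpe: float = -1.00  # striatum D2 -> GPe (indirect)
    stn_gpi: float = 0.90  # STN (summed) -> GPi
    gpe_gpi: float = -0.30  # GPe -> GPi
    strd1_gpi: float = -1.00  # striatum D1 -> GPi (direct)


class ChannelLayerState:
    """State of one N-channel basal-ganglia complex.

    Holds smoothed activations ``a`` and outputs ``o`` for each nucleus,
    plus the previous-cycle outputs the wiring requires (STN reads last
    cycle's GPe, GPe reads last cycle's D2, cortex reads last cycle's
    thalamus).
    """

    __slots__ = (
        "n",
        "a_d1", "o_d1", "a_d2", "o_d2",
        "a_stn", "o_stn", "a_gpe", "o_gpe",
        "a_gpi", "o_gpi", "a_thal", "o_thal",
        "o_gpe_prev", "o_d2_prev", "o_thal_prev",
    )

    def __init__(self, n: int):
        self.n = n
        for name in self.__slots__[1:]:
            setattr(self, name, [0.0] * n)


def _sigmoid_step(
    a: list[float], o: list[float], u: Sequence[float],
    delta: float, beta: float, alpha: float,
) -> None:
    for i in range(len(a)):
        ai = delta * a[i] + (1.0 - delta) * u[i]
        a[i] = ai
        o[i] = 1.0 / (1.0 + exp(-alpha * (ai - beta)))


def step_striatum(
    o_ctx: Sequence[float],
    state: ChannelLayerState,
    delta: float,
    beta_d1: Sequence[float],
    beta_d2: Sequence[float],
    alpha_str: float,
) -> None:
    """D1 and D2 units; input is the corresponding cortical output.

    The two populations share input but may carry different (adapted)
    saturation thresholds.
    """
    a1, o1, a2, o2 = state.a_d1, state.o_d1, state.a_d2, state.o_d2
    for i in range(state.n):
        ai = delta * a1[i] + (1.0 - delta) * o_ctx[i]
        a1[i] = ai
        o1[i] = 1.0 / (1.0 + exp(-alpha_str * (ai - beta_d1[i])))
        ai = delta * a2[i] + (1.0 - delta) * o_ctx[i]
        a2[i] = ai
        o2[i] = 1.0 / (1.0 + exp(-alpha_str * (ai - beta_d2[i])))


def step_stn(
    o_ctx: Sequence[float],
    state: ChannelLayerState,
    weights: BGWeights,
    delta: float,
    beta: float,
    alpha: float,
) -> None:
    """STN: excitation from cortex, inhibition from last cycle's GPe."""
    u = [
        weights.ctx_stn * o_ctx[i] + weights.gpe_stn * state.o_gpe_prev[i]
        for i in range(state.n)
    ]
    _sigmoid_step(state.a_stn, state.o_stn, u, delta, beta, alpha)


def step_gpe(
    state: ChannelLayerState,
    weights: BGWeights,
    delta: float,
    beta: float,
    alpha: float,
) -> None:
    """GPe: diffuse STN excitation, channel-specific D2 inhibition.

    The STN term sums over all channels, so GPe input is identical across
    channels whenever the D2 outputs are.
    """
    stn_sum = sum(state.o_stn)
    u = [
        weights.stn_gpe * stn_sum + weights.strd2_gpe * state.o_d2_prev[i]
        for i in range(state.n)
    ]
    _sigmoid_step(state.a_gpe, state.o_gpe, u, delta, beta, alpha)


def step_gpi(
    state: ChannelLayerState,
    weights: BGWeights,
    delta: float,
    beta: float,
    alpha: float,
) -> None:
    """GPi: diffuse STN excitation, GPe and direct-pathway D1 inhibition."""
    stn_sum = sum(state.o_stn)
    u = [
        weights.stn_gpi * stn_sum
        + weights.gpe_gpi * state.o_gpe[i]
        + weights.strd1_gpi * state.o_d1[i]
        for i in range(state.n)
    ]
    _sigmoid_step(state.a_gpi, state.o_gpi, u, delta, beta, alpha)


def step_thalamus(
    state: ChannelLayerState, delta: float, beta: float, alpha: float
) -> None:
    """Thalamus: tonically active, o = -logistic(a) in (-1, 0).

    More GPi output means stronger suppression of the channel's cortical
    node; a quiet GPi leaves the thalamic brake nearly released.
    """
    a, o = state.a_thal, state.o_thal
    gpi = state.o_gpi
    for i in range(state.n):
        ai = delta * a[i] + (1.0 - delta) * gpi[i]
        a[i] = ai
        o[i] = -1.0 / (1.0 + exp(-alpha * (ai - beta)))


def step_channel_layer(
    o_ctx: Sequence[float],
    state: ChannelLayerState,
    weights: BGWeights,
    delta: float,
    beta_d1: Sequence[float],
    beta_d2: Sequence[float],
    alpha_str: float,
    beta_stn: float,
    alpha_stn: float,
    beta_gpe: float,
    alpha_gpe: float,
    beta_gpi: float,
    alpha_gpi: float,
    beta_thal: float,
    alpha_thal: float,
) -> None:
    """One full cycle of a basal-ganglia complex.

    Within-cycle dataflow: striatum and STN read the current cortical
    output; GPe reads current STN and previous-cycle D2; GPi reads current
    STN, GPe and D1; the thalamus reads current GPi. The previous-cycle
    buffers are rolled at the end.
    """
    step_striatum(o_ctx, state, delta, beta_d1, beta_d2, alpha_str)
    step_stn(o_ctx, state, weights, delta, beta_stn, alpha_stn)
    step_gpe(state, weights, delta, beta_gpe, alpha_gpe)
    step_gpi(state, weights, delta, beta_gpi, alpha_gpi)
    step_thalamus(state, delta, beta_thal, alpha_thal)
    state.o_gpe_prev = state.o_gpe[:]
    state.o_d2_prev = state.o_d2[:]
    state.o_thal_prev = state.o_thal[:]


def feature_match(
    matched: bool, w_neg: float, m_r: float, f_prev: float, r_prev: float
) -> float:
    """Feature-match value f for one cognitive channel.

    +1 when the channel's rule is consistent with the response just made;
    otherwise (2 * w_neg - 1) - m_r * f_prev * r_prev, so that at default
    parameters a mismatch yields -1, higher ``w_neg`` blunts negative
    reward, and higher ``m_r`` lets the previous trial's feedback linger.
    """
    if matched:
        return 1.0
    return (2.0 * w_neg - 1.0) - m_r * f_prev * r_prev


def reward_prediction_error(r: float, f: float, a_median: float) -> float:
    """RPE: feedback sign times (feature match - median trial activation)."""
    return r * (f - a_median)


def update_beta_str(beta: float, eps_str: float, rpe: float, zeta: float) -> float:
    """Striatal threshold update, multiplicative noise, clipped to [0, 1].

    beta <- clip((beta - eps_str * rpe) * (1 + zeta), 0, 1). Applied to
    cognitive channels only, once per feedback event; a positive RPE lowers
    the threshold and so disinhibits the channel.
    """
    value = (beta - eps_str * rpe) * (1.0 + zeta)
    if value < 0.0:
        return 0.0
    if value > 1.0:
        return 1.0
    return value
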