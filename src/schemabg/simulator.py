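"""Session orchestration: parameters, trials, sessions, groups, calibration.

A session presents a sequence of unambiguous WCST cards to the coupled
cortico-basal-ganglia network. Within a trial the network is cycled until a
sensorimotor schema is selected (the response) or a cycle cap is reached
(an omission); response time is the number of cycles from stimulus onset to
selection. Feedback then drives the striatal-threshold and sensorimotor-
gain updates, and the next stimulus appears on the following cycle — the
task is continuous, and cortical and subcortical activations persist across
trials (only the area integrators and the stimulus input reset).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace
from statistics import median
from typing import Optional, Sequence

import numpy as np

from .basal_ganglia import (
    BGWeights,
    ChannelLayerState,
    feature_match,
    reward_prediction_error,
    step_channel_layer,
    update_beta_str,
)
from .cortical_network import (
    CorticalLayerState,
    SelectionThresholds,
    check_selection,
    conflict_product,
    step_cognitive,
    step_sensorimotor,
    topdown_input,
)
from .task_environment import (
    RULES,
    RuleSchedule,
    TrialRecord,
    applied_rule,
    build_trial_sequence,
    classify_error,
    stimulus_match_vector,
)

__all__ = [
    "ParameterSet",
    "GroupSpec",
    "RunResult",
    "PD_GROUPS",
    "HC_SPACE",
    "PD_SPACE",
    "run_session",
    "run_group",
    "summarize_runs",
    "calibrate_area_scale",
]


@dataclass(frozen=True)
class ParameterSet:
    """Every model parameter with its default value.

    Activation dynamics: ``delta`` is the low-pass smoothing constant used
    in every integration; ``o_ext`` the constant top-down drive to
    cognitive schemas; ``o_stim`` the stimulus drive to matching
    sensorimotor schemas; ``w_rule`` the selected-rule-to-action weight.
    ``alpha_*`` / ``beta_*`` are the gain and threshold of each layer's or
    nucleus's saturation function. Learning: ``eps_str`` scales striatal
    threshold adaptation (identified with striatal dopamine sensitivity,
    the parameter reduced to model Parkinson's disease), ``eps_sma`` the
    conflict-driven sensorimotor gain, ``w_neg`` negative-reward
    sensitivity and ``m_r`` the memory for previous feedback. Selection:
    ``theta_s`` is the static output threshold and ``theta_a_mean/sd``
    parameterise the per-trial Normal draw of the integration threshold.
    Noise half-widths ``zeta_*`` give the uniform noise on the stimulus,
    the striatal update and the gain update.

    ``area_scale`` converts accumulated output area (output units x cycles)
    to the scale of the integration threshold; its default was produced by
    :func:`calibrate_area_scale` so that the default model's mean response
    time on trials following positive feedback is ~129 cycles.
    ``cycle_cap`` bounds the cycles spent on one trial; hitting it scores
    an omission.
    """

    delta: float = 0.60
    o_ext: float = 0.75
    o_stim: float = 0.50
    w_rule: float = 0.40
    w_neg: float = 0.00
    m_r: float = 0.00
    weights: BGWeights = field(default_factory=BGWeights)
    eps_str: float = 0.40
    eps_sma: float = 0.50
    theta_a_mean: float = 4000.0
    theta_a_sd: float = 400.0
    theta_s: float = 0.50
    alpha_pfc: float = 8.0
    alpha_sma: float = 8.0  # initial value; adapts with conflict
    alpha_stn: float = 8.0
    alpha_gpe: float = 8.0
    alpha_gpi: float = 8.0
    alpha_thal: float = 8.0
    alpha_str: float = 8.5
    beta_pfc: float = 0.50
    beta_sma: float = 0.40
    beta_str: float = 0.50  # initial (cognitive) and fixed (sensorimotor)
    beta_stn: float = 0.30
    beta_gpe: float = 0.25
    beta_gpi: float = 0.25
    beta_thal: float = 0.45
    zeta_stim: float = 0.20
    zeta_str: float = 0.10
    zeta_sma: float = 0.10
    area_scale: float = 33.39
    area_scale_cog: float = 300.0
    iti_cycles: int = 10
    cycle_cap: int = 1000
    # How the cognitive D2 threshold relates to the adapted (D1) beta_str:
    # 'mirror'  - dopamine moves D1 and D2 excitability oppositely, so
    #             beta_d2 = 1 - beta_d1 (default);
    # 'shared'  - D2 uses the same adapted threshold as D1;
    # 'fixed'   - D2 keeps the Table-default threshold, only D1 adapts.
    d2_coupling: str = "mirror"
    adapt_alpha_sma: bool = True  # conflict-driven sensorimotor gain on/off
    criterion_length: int = 10

    def override(self, **kwargs) -> "ParameterSet":
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


#: Virtual Parkinson's-disease groups: reduced striatal learning rate,
#: optionally with blunted negative-reward sensitivity (w_neg) and/or
#: feedback memory (m_r).
PD_GROUPS: dict[str, dict[str, float]] = {
    "PD_1": {"eps_str": 0.10, "w_neg": 0.00, "m_r": 0.00},
    "PD_2": {"eps_str": 0.10, "w_neg": 0.65, "m_r": 0.00},
    "PD_3": {"eps_str": 0.10, "w_neg": 0.00, "m_r": 0.60},
    "PD_4": {"eps_str": 0.10, "w_neg": 0.65, "m_r": 0.60},
}

#: Four-dimensional parameter spaces for virtual healthy controls and
#: Parkinson's patients (ranges over eps_str, eps_sma, w_neg, m_r).
HC_SPACE: dict[str, tuple[float, float]] = {
    "eps_str": (0.40, 0.70),
    "eps_sma": (0.50, 0.70),
    "w_neg": (0.00, 0.20),
    "m_r": (0.00, 0.20),
}
PD_SPACE: dict[str, tuple[float, float]] = {
    "eps_str": (0.05, 0.20),
    "eps_sma": (0.30, 0.50),
    "w_neg": (0.50, 0.80),
    "m_r": (0.50, 0.70),
}


@dataclass
class GroupSpec:
    """A virtual participant group over the four learning parameters.

    mode='fixed': simulate at the given values (ranges collapse to their
    midpoint is an error — pass scalars). mode='midpoint': simulate at the
    midpoint of each range. mode='grid': simulate at the midpoints of
    ``subintervals`` equal subintervals of each range (k^4 points).
    """

    name: str
    params: dict[str, object]  # scalar or (lo, hi) range per parameter
    mode: str = "fixed"
    subintervals: int = 4

    def points(self) -> list[dict[str, float]]:
        if not self.params:
            raise ValueError("empty parameter specification")
        axes: list[list[float]] = []
        names = list(self.params)
        for name in names:
            v = self.params[name]
            if isinstance(v, (tuple, list)):
                lo, hi = float(v[0]), float(v[1])
                if hi < lo:
                    raise ValueError(f"empty range for {name}")
                if self.mode == "midpoint":
                    axes.append([(lo + hi) / 2.0])
                elif self.mode == "grid":
                    k = self.subintervals
                    if k < 1:
                        raise ValueError("subintervals must be >= 1")
                    axes.append(
                        [lo + (hi - lo) * (2 * j + 1) / (2 * k) for j in range(k)]
                    )
                else:  # fixed mode with a range: use the midpoint
                    axes.append([(lo + hi) / 2.0])
            else:
                axes.append([float(v)])
        points = [{}]
        for name, axis in zip(names, axes):
            points = [dict(p, **{name: val}) for p in points for val in axis]
        return points


@dataclass
class RunResult:
    """Summary of one simulated session."""

    n_trials: int
    cards_correct: int
    categories: int
    pe: int
    sl: int
    ie: int
    other: int
    omissions: int
    rt_post_positive_mean: float
    rt_post_negative_mean: float
    records: list[TrialRecord]
    seed: object
    traces: Optional[dict] = None

    def counts_identity(self) -> bool:
        return (
            self.cards_correct + self.pe + self.sl + self.ie + self.other
            + self.omissions
            == self.n_trials
        )


_ZERO4 = (0.0, 0.0, 0.0, 0.0)


def _streams(seed) -> dict[str, np.random.Generator]:
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    names = ("deck", "stim", "str_noise", "sma_noise", "theta_a", "rule")
    children = ss.spawn(len(names))
    return {n: np.random.default_rng(c) for n, c in zip(names, children)}


def run_session(
    params: ParameterSet,
    n_trials: int = 64,
    schedule_mode: str = "criterion",
    seed=0,
    record_traces: bool = False,
) -> RunResult:
    """Simulate one full session; deterministic given ``seed``.

    ``seed`` may be an int or a ``numpy.random.SeedSequence``. With
    ``record_traces`` the per-cycle cortical outputs (both layers) and the
    sensorimotor GPi outputs are kept for ERP-proxy and trace analyses.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    rng = _streams(seed)
    cards = build_trial_sequence(n_trials, rng["deck"])
    schedule = RuleSchedule(
        rng=rng["rule"], mode=schedule_mode, criterion_length=params.criterion_length
    )

    p = params
    delta = p.delta
    # the two layers share the integration-threshold distribution but not
    # the area calibration: the sensorimotor scale sets the response time,
    # while the (larger) cognitive scale makes re-adoption of a task set
    # cost a fraction of a response time rather than a whole trial
    thresholds = SelectionThresholds(
        theta_s=p.theta_s,
        theta_a_mean=p.theta_a_mean,
        theta_a_sd=p.theta_a_sd,
        area_scale=p.area_scale,
    )
    thresholds_cog = SelectionThresholds(
        theta_s=p.theta_s,
        theta_a_mean=p.theta_a_mean,
        theta_a_sd=p.theta_a_sd,
        area_scale=p.area_scale_cog,
    )

    cog = CorticalLayerState.create(3, p.alpha_pfc, p.beta_pfc)
    sma = CorticalLayerState.create(4, p.alpha_sma, p.beta_sma)
    cog_bg = ChannelLayerState(3)
    sma_bg = ChannelLayerState(4)

    beta_d1_cog = [p.beta_str] * 3
    beta_d2_cog = [p.beta_str] * 3
    beta_sma_fixed = [p.beta_str] * 4
    f_prev = [0.0] * 3
    r_prev = [0.0] * 3

    records: list[TrialRecord] = []
    trace_sma: list[list[float]] = []
    trace_pfc: list[list[float]] = []
    trace_gpi: list[list[float]] = []

    theta_rng = rng["theta_a"]
    stim_rng = rng["stim"]
    strn_rng = rng["str_noise"]
    sman_rng = rng["sma_noise"]

    global_cycle = -1
    # the cognitive integrator is not tied to trials: its area accumulates
    # from the last (de)selection event, so a task set adopted mid-trial
    # persists and re-adoption does not restart at each stimulus onset
    theta_cog = thresholds_cog.draw_theta_a_per_node(theta_rng, 3)
    for t, card in enumerate(cards):
        triple = card.target_triple()
        match = stimulus_match_vector(card)
        # one stimulus-noise draw per trial shared by all matching nodes
        # (the striatal noise term carries a per-channel index; the
        # stimulus noise does not): differential tie-breaking comes from
        # the per-node integration thresholds, not from the stimulus
        stim_level = p.o_stim + stim_rng.uniform(-p.zeta_stim, p.zeta_stim)
        stim = [stim_level if m else 0.0 for m in match]
        theta_sma = thresholds.draw_theta_a_per_node(theta_rng, 4)
        sma.reset_area()
        cog_hist: list[list[float]] = [[], [], []]

        response = None
        rt = p.cycle_cap
        for cycle in range(p.cycle_cap):
            global_cycle += 1
            step_cognitive(cog, cog_bg.o_thal_prev, p.o_ext, delta)
            # a selected cognitive schema persists while its output holds
            # above the static threshold; re-selection is gated by the
            # area criterion with a fresh threshold draw
            if cog.selected is not None and cog.o[cog.selected] <= p.theta_s:
                cog.selected = None
                cog.reset_area()
                theta_cog = thresholds_cog.draw_theta_a_per_node(theta_rng, 3)
            if cog.selected is None:
                sel = check_selection(cog, thresholds_cog, theta_cog)
                if sel is not None:
                    cog.selected = sel
            topdown = topdown_input(triple, cog.o, cog.selected, p.w_rule)
            step_sensorimotor(sma, topdown, stim, sma_bg.o_thal_prev, delta)
            step_channel_layer(
                cog.o, cog_bg, p.weights, delta,
                beta_d1_cog, beta_d2_cog, p.alpha_str,
                p.beta_stn, p.alpha_stn, p.beta_gpe, p.alpha_gpe,
                p.beta_gpi, p.alpha_gpi, p.beta_thal, p.alpha_thal,
            )
            step_channel_layer(
                sma.o, sma_bg, p.weights, delta,
                beta_sma_fixed, beta_sma_fixed, p.alpha_str,
                p.beta_stn, p.alpha_stn, p.beta_gpe, p.alpha_gpe,
                p.beta_gpi, p.alpha_gpi, p.beta_thal, p.alpha_thal,
            )
            for i in range(3):
                cog_hist[i].append(cog.o[i])
            if record_traces:
                trace_sma.append(sma.o[:])
                trace_pfc.append(cog.o[:])
                trace_gpi.append(sma_bg.o_gpi[:])
            resp = check_selection(sma, thresholds, theta_sma)
            if resp is not None:
                response = resp + 1
                rt = cycle + 1
                break

        if response is None:
            # omission: no action, no feedback, no learning
            records.append(
                TrialRecord(
                    trial_index=t, card=card, response=None, applied_rule=None,
                    active_rule=schedule.active_rule, feedback=0,
                    rt_cycles=p.cycle_cap, response_cycle=global_cycle,
                )
            )
            continue

        applied = applied_rule(card, response)
        active_before = schedule.active_rule
        selected_at_response = (
            RULES[cog.selected] if cog.selected is not None else None
        )
        feedback = 1 if applied == active_before else -1
        schedule.register(feedback)

        # striatal threshold adaptation (cognitive channels only)
        for i in range(3):
            matched = applied == RULES[i]
            f = feature_match(matched, p.w_neg, p.m_r, f_prev[i], r_prev[i])
            a_med = median(cog_hist[i])
            rpe = reward_prediction_error(float(feedback), f, a_med)
            zeta = strn_rng.uniform(-p.zeta_str, p.zeta_str)
            new_beta = update_beta_str(beta_d1_cog[i], p.eps_str, rpe, zeta)
            beta_d1_cog[i] = new_beta
            if p.d2_coupling == "mirror":
                beta_d2_cog[i] = 1.0 - new_beta
            elif p.d2_coupling == "shared":
                beta_d2_cog[i] = new_beta
            # 'fixed': beta_d2 keeps its default
            f_prev[i] = f
            r_prev[i] = float(feedback)

        # conflict-driven sensorimotor gain, once per feedback event
        conflict = conflict_product(sma.o, p.eps_sma)
        zeta_s = sman_rng.uniform(-p.zeta_sma, p.zeta_sma)
        if p.adapt_alpha_sma:
            sma.alpha = (1.0 + zeta_s) * conflict

        # reactive control: negative feedback interrupts the ongoing task
        # set, quenching the cognitive competition so that the next
        # selection is decided by the updated striatal thresholds rather
        # than by the incumbent schema's activation advantage (the
        # post-error exploration period)
        if feedback < 0:
            cog.selected = None
            cog.reset_area()
            theta_cog = thresholds_cog.draw_theta_a_per_node(theta_rng, 3)
            for i in range(3):
                cog.a[i] = 0.0
                cog.o[i] = 0.0
            for name in (
                "a_d1", "o_d1", "a_d2", "o_d2", "a_stn", "o_stn", "a_gpe",
                "o_gpe", "a_gpi", "o_gpi", "a_thal", "o_thal",
                "o_gpe_prev", "o_d2_prev", "o_thal_prev",
            ):
                arr = getattr(cog_bg, name)
                for i in range(3):
                    arr[i] = 0.0

        # executing the motor act quenches the sensorimotor competition:
        # the selected schema self-deactivates on completion and the
        # loop's winner-take-all state (thalamic disinhibition of the
        # winner, STN-mediated suppression of the losers) is released, so
        # the next card is contested by a fresh race. The cognitive loop
        # persists untouched across trials.
        for i in range(4):
            sma.a[i] = 0.0
            sma.o[i] = 0.0
        for name in (
            "a_d1", "o_d1", "a_d2", "o_d2", "a_stn", "o_stn", "a_gpe",
            "o_gpe", "a_gpi", "o_gpi", "a_thal", "o_thal",
            "o_gpe_prev", "o_d2_prev", "o_thal_prev",
        ):
            arr = getattr(sma_bg, name)
            for i in range(4):
                arr[i] = 0.0

        records.append(
            TrialRecord(
                trial_index=t, card=card, response=response, applied_rule=applied,
                active_rule=active_before, feedback=feedback, rt_cycles=rt,
                selected_cog_rule=selected_at_response,
                response_cycle=global_cycle, conflict=conflict,
            )
        )

        # feedback-processing interval: motor execution and feedback
        # evaluation occupy a few cycles before the next card is attended.
        # No stimulus is present; the cognitive loop keeps running, so
        # after an error the interrupted task-set competition is re-sorted
        # under the updated striatal thresholds before the next race
        for _ in range(p.iti_cycles):
            global_cycle += 1
            step_cognitive(cog, cog_bg.o_thal_prev, p.o_ext, delta)
            if cog.selected is not None and cog.o[cog.selected] <= p.theta_s:
                cog.selected = None
                cog.reset_area()
                theta_cog = thresholds_cog.draw_theta_a_per_node(theta_rng, 3)
            if cog.selected is None:
                sel = check_selection(cog, thresholds_cog, theta_cog)
                if sel is not None:
                    cog.selected = sel
            step_sensorimotor(sma, _ZERO4, _ZERO4, sma_bg.o_thal_prev, delta)
            step_channel_layer(
                cog.o, cog_bg, p.weights, delta,
                beta_d1_cog, beta_d2_cog, p.alpha_str,
                p.beta_stn, p.alpha_stn, p.beta_gpe, p.alpha_gpe,
                p.beta_gpi, p.alpha_gpi, p.beta_thal, p.alpha_thal,
            )
            step_channel_layer(
                sma.o, sma_bg, p.weights, delta,
                beta_sma_fixed, beta_sma_fixed, p.alpha_str,
                p.beta_stn, p.alpha_stn, p.beta_gpe, p.alpha_gpe,
                p.beta_gpi, p.alpha_gpi, p.beta_thal, p.alpha_thal,
            )
            if record_traces:
                trace_sma.append(sma.o[:])
                trace_pfc.append(cog.o[:])
                trace_gpi.append(sma_bg.o_gpi[:])

    for t in range(len(records)):
        records[t].error_class = classify_error(records, t)

    counts = {"correct": 0, "PE": 0, "SL": 0, "IE": 0, "other_error": 0, "omission": 0}
    for rec in records:
        counts[rec.error_class] += 1
    rt_pos = [
        rec.rt_cycles
        for t, rec in enumerate(records)
        if t > 0 and rec.response is not None and records[t - 1].feedback > 0
    ]
    rt_neg = [
        rec.rt_cycles
        for t, rec in enumerate(records)
        if t > 0 and rec.response is not None and records[t - 1].feedback < 0
    ]
    traces = None
    if record_traces:
        traces = {
            "o_sma": np.array(trace_sma),
            "o_pfc": np.array(trace_pfc),
            "o_gpi_sma": np.array(trace_gpi),
        }
    return RunResult(
        n_trials=n_trials,
        cards_correct=counts["correct"],
        categories=schedule.categories,
        pe=counts["PE"],
        sl=counts["SL"],
        ie=counts["IE"],
        other=counts["other_error"],
        omissions=counts["omission"],
        rt_post_positive_mean=float(np.mean(rt_pos)) if rt_pos else float("nan"),
        rt_post_negative_mean=float(np.mean(rt_neg)) if rt_neg else float("nan"),
        records=records,
        seed=seed,
        traces=traces,
    )


def run_group(
    group: GroupSpec,
    n_runs_per_point: int,
    base: ParameterSet,
    seed=0,
    n_trials: int = 64,
    schedule_mode: str = "criterion",
    record_traces: bool = False,
) -> list[tuple[dict[str, float], RunResult]]:
    """Simulate a virtual participant group.

    Returns one ``(parameter_point, RunResult)`` pair per session, with
    ``n_runs_per_point`` sessions at each parameter point of the group.
    """
    points = group.points()
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = ss.spawn(len(points) * n_runs_per_point)
    out: list[tuple[dict[str, float], RunResult]] = []
    k = 0
    for point in points:
        params = base.override(**point)
        for _ in range(n_runs_per_point):
            res = run_session(
                params,
                n_trials=n_trials,
                schedule_mode=schedule_mode,
                seed=children[k],
                record_traces=record_traces,
            )
            out.append((point, res))
            k += 1
    return out


_MEASURES = (
    ("cards_correct", "Cards correctly sorted"),
    ("categories", "Categories achieved"),
    ("pe", "Perseverative errors"),
    ("sl", "Set loss errors"),
    ("ie", "Integration errors"),
    ("rt_post_positive_mean", "RT (post positive feedback, cycles)"),
    ("rt_post_negative_mean", "RT (post negative feedback, cycles)"),
)


def summarize_runs(results: Sequence[RunResult]):
    """Mean and sample s.d. of the dependent measures over sessions."""
    import pandas as pd

    if len(results) == 0:
        raise ValueError("no results to summarize")
    rows = []
    for attr, label in _MEASURES:
        values = np.array([getattr(r, attr) for r in results], dtype=float)
        values = values[~np.isnan(values)]
        mean = float(np.mean(values)) if values.size else float("nan")
        sd = float(np.std(values, ddof=1)) if values.size > 1 else 0.0
        rows.append({"measure": label, "mean": mean, "sd": sd, "n": int(values.size)})
    return pd.DataFrame(rows)


def calibrate_area_scale(
    base: ParameterSet,
    target_rt: float = 129.10,
    n_runs: int = 20,
    seed: int = 0,
    tol: float = 2.0,
    bracket: tuple[float, float] = (4.0, 400.0),
    max_iter: int = 20,
) -> float:
    """Find ``area_scale`` whose mean post-positive RT matches ``target_rt``.

    The integration threshold is stated on a scale (mean 4000) that is
    large relative to the per-trial output area the network accumulates, so
    a single positive calibration constant maps accumulated area onto the
    threshold scale. Mean RT decreases monotonically in ``area_scale``
    (a larger scale reaches the bound sooner), so a bisection search
    suffices. Only the post-positive-feedback RT is used; all other
    statistics are out-of-sample with respect to this calibration.
    """
    if target_rt <= 0:
        raise ValueError("target_rt must be positive")

    def mean_rt(scale: float) -> float:
        params = base.override(area_scale=scale)
        ss = np.random.SeedSequence(seed)
        rts = []
        for child in ss.spawn(n_runs):
            res = run_session(params, seed=child)
            if not np.isnan(res.rt_post_positive_mean):
                rts.append(res.rt_post_positive_mean)
        return float(np.mean(rts))

    lo, hi = bracket
    rt_lo, rt_hi = mean_rt(lo), mean_rt(hi)
    if not (rt_hi <= target_rt <= rt_lo):
        raise ValueError(
            f"target RT {target_rt} not bracketed by scales {bracket} "
            f"(RTs {rt_lo:.1f}..{rt_hi:.1f})"
        )
    mid = 0.5 * (lo + hi)
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        rt_mid = mean_rt(mid)
        if abs(rt_mid - target_rt) <= tol:
            return mid
        if rt_mid > target_rt:
            lo = mid
        else:
            hi = mid
    return mid
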