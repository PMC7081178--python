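"""ERP-component proxies computed from per-cycle schema outputs.

Two event-related-potential components are proxied by functions of the
model's internal variables:

* the error-related negativity (ERN), proxied by the negated extreme
  one-step change across sensorimotor schema outputs,
  ``-absmax(o_sma(t) - o_sma(t-1))``, response-locked and contrasted
  between correct and incorrect trials;
* the sustained parietal / posterior switch positivity (SPP / PSP),
  proxied by the extreme one-step change across cognitive schema outputs,
  contrasted between set-shift trials and the trials immediately after.

These are proxies for the components' coarse properties — sign, relative
timing around the response, attenuation between groups — not for
millisecond-scale waveforms.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np

__all__ = [
    "absmax",
    "signal_trace",
    "ern_trace",
    "ern_attenuation",
    "spp_trace",
    "psp_attenuation",
    "smooth_signal",
    "session_erp_summary",
]

#: Response-locked window (cycles before, cycles after the response).
ERN_WINDOW = (20, 40)
#: Baseline length: cycles immediately preceding the window.
ERN_BASELINE = 10


def absmax(v) -> float:
    """Element of ``v`` with the greatest absolute value, sign preserved.

    Ties go to the lowest index.
    """
    v = np.asarray(v, dtype=float)
    if v.size == 0:
        raise ValueError("absmax of an empty vector")
    return float(v[int(np.argmax(np.abs(v)))])


def signal_trace(
    outputs: np.ndarray,
    sign: float = 1.0,
    mask_cycles: Optional[Sequence[int]] = None,
) -> np.ndarray:
    """Per-cycle absmax of one-step output differences.

    ``outputs`` is a (cycles, nodes) array; the first cycle has no
    predecessor and yields 0. ``sign=-1`` gives the ERN convention.
    ``mask_cycles`` lists cycles whose one-step difference is an
    administrative state reset (schema self-deactivation at response, the
    post-error interrupt) rather than loop dynamics; the signal is zeroed
    there so the proxies reflect network dynamics only.
    """
    outputs = np.asarray(outputs, dtype=float)
    if outputs.ndim != 2:
        raise ValueError("outputs must be a (cycles, nodes) array")
    diff = np.diff(outputs, axis=0)
    idx = np.argmax(np.abs(diff), axis=1)
    vals = diff[np.arange(diff.shape[0]), idx]
    out = np.zeros(outputs.shape[0])
    out[1:] = sign * vals
    if mask_cycles is not None:
        for c in mask_cycles:
            if 0 <= c < len(out):
                out[c] = 0.0
    return out


def _locked_mean(
    signal: np.ndarray, events: Sequence[int], window: tuple[int, int], baseline: int
) -> Optional[np.ndarray]:
    """Mean signal over events, aligned to each event cycle.

    Returns an array of length ``baseline + pre + post + 1`` covering
    cycles ``[-(pre+baseline), +post]`` around the event, or None when no
    event has full coverage.
    """
    pre, post = window
    lo, hi = pre + baseline, post
    segments = [
        signal[e - lo : e + hi + 1]
        for e in events
        if e - lo >= 0 and e + hi < len(signal)
    ]
    if not segments:
        return None
    return np.mean(segments, axis=0)


def ern_trace(
    sma_outputs: np.ndarray,
    response_cycles: Sequence[int],
    outcomes: Sequence[int],
    window: tuple[int, int] = ERN_WINDOW,
    baseline: int = ERN_BASELINE,
) -> dict:
    """ERN proxy: response-locked signal averaged by outcome.

    ``outcomes`` holds +1/-1 per response event. Returns the per-cycle
    signal plus the mean response-locked traces for correct and incorrect
    trials (None when a class is empty); the ERN component is the
    difference of the two class means. The cycle following each response
    carries the executed schema's self-deactivation and is masked.
    """
    signal = signal_trace(
        sma_outputs, sign=-1.0, mask_cycles=[e + 1 for e in response_cycles]
    )
    events_c = [e for e, oc in zip(response_cycles, outcomes) if oc > 0]
    events_i = [e for e, oc in zip(response_cycles, outcomes) if oc < 0]
    mean_c = _locked_mean(signal, events_c, window, baseline)
    mean_i = _locked_mean(signal, events_i, window, baseline)
    component = None
    if mean_c is not None and mean_i is not None:
        component = mean_c - mean_i
    return {
        "signal": signal,
        "correct_mean": mean_c,
        "incorrect_mean": mean_i,
        "component": component,
        "window": window,
        "baseline": baseline,
    }


def _signed_extreme(trace: np.ndarray, baseline: int) -> float:
    """Signed extreme deviation from the baseline mean, post-baseline."""
    base = float(np.mean(trace[:baseline]))
    dev = trace[baseline:] - base
    return float(dev[int(np.argmax(np.abs(dev)))])


def ern_attenuation(trace: dict) -> Optional[float]:
    """Scalar ERN summary: correct-class extreme minus incorrect-class.

    Each class's response-locked mean is summarised by its signed extreme
    deviation from baseline. The error class sits above the correct class
    (its value after an error is greater), so healthy behaviour gives a
    clearly negative difference; attenuation of the error response moves
    the value toward zero. None when either trial class is absent.
    """
    if trace["correct_mean"] is None or trace["incorrect_mean"] is None:
        return None
    b = trace["baseline"]
    return _signed_extreme(trace["correct_mean"], b) - _signed_extreme(
        trace["incorrect_mean"], b
    )


def spp_trace(pfc_outputs: np.ndarray) -> np.ndarray:
    """SPP proxy: per-cycle absmax of one-step cognitive-output changes."""
    return signal_trace(pfc_outputs, sign=1.0)


def _trial_peak(signal: np.ndarray, start: int, end: int) -> float:
    seg = signal[start : end + 1]
    return float(np.max(np.abs(seg))) if seg.size else 0.0


def psp_attenuation(
    spp: np.ndarray,
    trial_windows: Sequence[tuple[int, int]],
    shift_flags: Sequence[bool],
) -> Optional[float]:
    """Mean peak SPP on shift trials minus on first-post-shift trials.

    A shift trial is the first trial after negative feedback on which the
    model's selected cognitive schema has changed. Returns None (flagged
    undefined) when the session contains no shift trial with a successor —
    e.g. when perseveration is so strong that the model never switches.
    """
    shift_peaks, post_peaks = [], []
    n = len(trial_windows)
    for t, is_shift in enumerate(shift_flags):
        if is_shift and t + 1 < n:
            s, e = trial_windows[t]
            shift_peaks.append(_trial_peak(spp, s, e))
            s, e = trial_windows[t + 1]
            post_peaks.append(_trial_peak(spp, s, e))
    if not shift_peaks:
        return None
    return float(np.mean(shift_peaks) - np.mean(post_peaks))


def smooth_signal(x: Sequence[float], window: int) -> np.ndarray:
    """Centred moving average; endpoints use shrunken windows.

    ``window`` must be odd; window=1 is the identity.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be a positive odd integer")
    x = np.asarray(x, dtype=float)
    if window == 1:
        return x.copy()
    half = window // 2
    out = np.empty_like(x)
    for i in range(len(x)):
        lo = max(0, i - half)
        hi = min(len(x), i + half + 1)
        out[i] = x[lo:hi].mean()
    return out


def shift_labels(records) -> list[bool]:
    """Shift-trial flags from a session's trial records.

    Trial t is a shift trial when the previous trial drew negative
    feedback and the model's selected cognitive schema at response differs
    from the previous trial's (both defined).
    """
    flags = [False] * len(records)
    for t in range(1, len(records)):
        prev, cur = records[t - 1], records[t]
        flags[t] = (
            prev.feedback < 0
            and cur.selected_cog_rule is not None
            and prev.selected_cog_rule is not None
            and cur.selected_cog_rule != prev.selected_cog_rule
        )
    return flags


def session_erp_summary(result, window=ERN_WINDOW, baseline=ERN_BASELINE) -> dict:
    """ERN and PSP attenuation summaries for one traced session.

    ``result`` is a RunResult simulated with ``record_traces=True``.
    """
    if result.traces is None:
        raise ValueError("session was run without traces")
    recs = [r for r in result.records if r.response is not None]
    response_cycles = [r.response_cycle for r in recs]
    outcomes = [r.feedback for r in recs]
    trace = ern_trace(
        result.traces["o_sma"], response_cycles, outcomes, window, baseline
    )
    # the post-error interrupt resets the cognitive layer on the cycle
    # after negative feedback; mask it as for the sensorimotor resets
    quench_cycles = [
        r.response_cycle + 1 for r in recs if r.feedback < 0
    ]
    spp = signal_trace(result.traces["o_pfc"], sign=1.0, mask_cycles=quench_cycles)
    # trial epochs for the set-shift contrast run stimulus-to-next-stimulus,
    # so each trial's window includes the processing of its own feedback
    # (the interval in which the task-set competition is re-sorted)
    starts = [r.response_cycle - r.rt_cycles + 1 for r in result.records]
    ends = [s - 1 for s in starts[1:]] + [result.records[-1].response_cycle]
    windows = list(zip(starts, ends))
    flags = shift_labels(result.records)
    return {
        "ern_att": ern_attenuation(trace),
        "psp_att": psp_attenuation(spp, windows, flags),
        "ern_trace": trace,
        "spp": spp,
        "n_shift": int(sum(flags)),
    }
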