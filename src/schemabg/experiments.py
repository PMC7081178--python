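"""Study drivers: group tables, ERP contrasts, correlation analyses, sweeps.

Each ``study*`` function reproduces one simulation study design:

1. default-parameter performance statistics over repeated sessions;
2. four virtual Parkinson's-disease groups (reduced striatal learning
   rate, optionally blunted negative-reward sensitivity and feedback
   memory) against the defaults;
3. midpoint healthy-control vs PD parameter settings with ERN / PSP proxy
   traces and attenuations;
4. full four-parameter grids for both spaces with Spearman correlations
   between per-session ERP attenuations and error frequencies;
5. one-dimensional parameter sweeps of the attenuations.

All drivers accept scaled-down run counts; the defaults are the full
study sizes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .erp_proxies import session_erp_summary, smooth_signal
from .simulator import (
    HC_SPACE,
    PD_GROUPS,
    PD_SPACE,
    GroupSpec,
    ParameterSet,
    RunResult,
    run_group,
    run_session,
    summarize_runs,
)

__all__ = [
    "StudyReport",
    "spearman_rho",
    "minmax_normalise",
    "study1",
    "study2",
    "study3",
    "study4",
    "study5",
    "gpi_sma_lagged_correlation",
]


@dataclass
class StudyReport:
    """Container for one study's tables and metadata."""

    study: str
    summary: Optional[pd.DataFrame] = None
    correlations: Optional[pd.DataFrame] = None
    curves: Optional[pd.DataFrame] = None
    extras: dict = field(default_factory=dict)
    params: dict = field(default_factory=dict)
    seed: Optional[int] = None


def spearman_rho(x, y) -> tuple[float, float]:
    """Spearman rank correlation with average ranks for ties.

    Returns (rho, two-sided p). Requires equal lengths >= 3.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("length mismatch")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def minmax_normalise(v) -> np.ndarray:
    """(v - min) / (max - min); undefined for constant vectors."""
    v = np.asarray(v, dtype=float)
    lo, hi = np.min(v), np.max(v)
    if hi == lo:
        raise ValueError("minmax normalisation undefined for a constant vector")
    return (v - lo) / (hi - lo)


def study1(seed: int = 0, n_runs: int = 100, n_trials: int = 64) -> StudyReport:
    """Default-parameter performance statistics."""
    base = ParameterSet()
    ss = np.random.SeedSequence(seed)
    results = [
        run_session(base, n_trials=n_trials, seed=c) for c in ss.spawn(n_runs)
    ]
    report = StudyReport(
        study="1", summary=summarize_runs(results), params=base.to_dict(), seed=seed
    )
    report.extras["results"] = results
    return report


def study2(seed: int = 0, n_runs: int = 100, n_trials: int = 64) -> StudyReport:
    """Virtual PD groups PD_1..PD_4 (per-group summary tables)."""
    base = ParameterSet()
    frames = {}
    results = {}
    for k, (name, overrides) in enumerate(PD_GROUPS.items()):
        group = GroupSpec(name=name, params=dict(overrides), mode="fixed")
        out = run_group(
            group, n_runs, base, seed=np.random.SeedSequence((seed, k)),
            n_trials=n_trials,
        )
        rs = [r for _, r in out]
        frames[name] = summarize_runs(rs).set_index("measure")
        results[name] = rs
    summary = pd.concat(frames, axis=1)
    report = StudyReport(study="2", summary=summary, params=base.to_dict(), seed=seed)
    report.extras["results"] = results
    return report


def _midpoint_params(space: dict[str, tuple[float, float]]) -> dict[str, float]:
    return {k: (lo + hi) / 2.0 for k, (lo, hi) in space.items()}


def study3(
    seed: int = 0, n_per_group: int = 20, n_trials: int = 64, smooth_window: int = 9
) -> StudyReport:
    """Midpoint HC vs PD groups: mean ERN traces and attenuations."""
    base = ParameterSet()
    out = {}
    for k, (name, space) in enumerate((("HC", HC_SPACE), ("PD", PD_SPACE))):
        params = base.override(**_midpoint_params(space))
        ss = np.random.SeedSequence((seed, k))
        summaries = []
        for c in ss.spawn(n_per_group):
            res = run_session(params, n_trials=n_trials, seed=c, record_traces=True)
            summaries.append(session_erp_summary(res))
        comps = [
            s["ern_trace"]["component"]
            for s in summaries
            if s["ern_trace"]["component"] is not None
        ]
        mean_component = (
            smooth_signal(np.mean(comps, axis=0), smooth_window) if comps else None
        )
        ern = [s["ern_att"] for s in summaries if s["ern_att"] is not None]
        psp = [s["psp_att"] for s in summaries if s["psp_att"] is not None]
        out[name] = {
            "mean_ern_component": mean_component,
            "ern_att_mean": float(np.mean(ern)) if ern else float("nan"),
            "psp_att_mean": float(np.mean(psp)) if psp else float("nan"),
            "n_psp_defined": len(psp),
            "midpoint": _midpoint_params(HC_SPACE if name == "HC" else PD_SPACE),
        }
    summary = pd.DataFrame(
        {
            g: {
                "ern_att_mean": v["ern_att_mean"],
                "psp_att_mean": v["psp_att_mean"],
                "n_psp_defined": v["n_psp_defined"],
            }
            for g, v in out.items()
        }
    )
    report = StudyReport(study="3", summary=summary, params=base.to_dict(), seed=seed)
    report.extras.update(out)
    return report


def _grid_sessions(
    space: dict[str, tuple[float, float]],
    seed,
    subintervals: int,
    runs_per_point: int,
    n_trials: int,
) -> pd.DataFrame:
    """One row per traced session: parameter point, errors, attenuations."""
    base = ParameterSet()
    group = GroupSpec("grid", dict(space), mode="grid", subintervals=subintervals)
    out = run_group(
        group, runs_per_point, base, seed=seed, n_trials=n_trials, record_traces=True
    )
    rows = []
    for point, res in out:
        s = session_erp_summary(res)
        rows.append(
            dict(
                point,
                pe=res.pe,
                sl=res.sl,
                ie=res.ie,
                ern_att=s["ern_att"],
                psp_att=s["psp_att"],
            )
        )
    return pd.DataFrame(rows)


def _correlation_table(df: pd.DataFrame) -> pd.DataFrame:
    """Spearman rho (and p) of each attenuation against each error count."""
    rows = {}
    for att in ("ern_att", "psp_att"):
        cells = {}
        for err in ("pe", "sl", "ie"):
            sub = df[[att, err]].dropna()
            if len(sub) >= 3:
                rho, p = spearman_rho(sub[att], sub[err])
            else:
                rho, p = float("nan"), float("nan")
            cells[err.upper()] = rho
            cells[err.upper() + "_p"] = p
        rows[att] = cells
    return pd.DataFrame(rows).T


def study4(
    seed: int = 0,
    subintervals: int = 4,
    runs_per_point: int = 10,
    n_trials: int = 64,
) -> StudyReport:
    """Grid simulations over both parameter spaces with Spearman tables.

    The full design is 4 subintervals x 10 runs per point = 2560 sessions
    per space; pass smaller arguments for a scaled-down run.
    """
    if subintervals < 1:
        raise ValueError("subintervals must be >= 1")
    tables = {}
    data = {}
    for k, (name, space) in enumerate((("HC", HC_SPACE), ("PD", PD_SPACE))):
        df = _grid_sessions(
            space, np.random.SeedSequence((seed, k)), subintervals,
            runs_per_point, n_trials,
        )
        tables[name] = _correlation_table(df)
        data[name] = df
    correlations = pd.concat(tables, axis=0)
    report = StudyReport(study="4", correlations=correlations, seed=seed)
    report.extras["sessions"] = data
    report.extras["monotonicity"] = {
        name: _binned_monotonicity(df) for name, df in data.items()
    }
    return report


def _binned_monotonicity(df: pd.DataFrame, n_bins: int = 4) -> dict:
    """Sign-consistency of binned means: a scatter-inspection surrogate.

    For each attenuation-error pair, bin sessions by the attenuation into
    quantile bins and check whether the bin means of the error count are
    monotone. Returns the fraction of consistent (monotone) pairs.
    """
    out = {}
    for att in ("ern_att", "psp_att"):
        for err in ("pe", "sl", "ie"):
            sub = df[[att, err]].dropna()
            if len(sub) < 4 * n_bins:
                out[f"{att}-{err}"] = None
                continue
            try:
                bins = pd.qcut(sub[att], n_bins, duplicates="drop")
            except ValueError:
                out[f"{att}-{err}"] = None
                continue
            means = sub.groupby(bins, observed=True)[err].mean().to_numpy()
            diffs = np.diff(means)
            out[f"{att}-{err}"] = bool(np.all(diffs >= 0) or np.all(diffs <= 0))
    return out


def study5(
    seed: int = 0,
    runs_per_point: int = 20,
    values: Optional[np.ndarray] = None,
    companions: tuple[float, ...] = (0.2, 0.5, 0.8),
    n_trials: int = 64,
) -> StudyReport:
    """One-dimensional sweeps of ERN / PSP attenuation.

    Sweeps eps_str, eps_sma and w_neg in turn over ``values`` (default 0
    to 1 in steps of 0.05), each crossed with three fixed values of the
    companion parameter (eps_sma for the eps_str sweep, eps_str for the
    other two); everything else stays at defaults. Curves are reported
    raw; min-max normalisation is applied per curve where defined.
    """
    if values is None:
        values = np.round(np.arange(0.0, 1.0001, 0.05), 3)
    base = ParameterSet()
    sweeps = (
        ("eps_str", "eps_sma"),
        ("eps_sma", "eps_str"),
        ("w_neg", "eps_str"),
    )
    rows = []
    for si, (swept, companion) in enumerate(sweeps):
        for ci, comp_val in enumerate(companions):
            for vi, v in enumerate(values):
                params = base.override(**{swept: float(v), companion: comp_val})
                ss = np.random.SeedSequence((seed, si, ci, vi))
                ern, psp, undef = [], [], 0
                for c in ss.spawn(runs_per_point):
                    res = run_session(
                        params, n_trials=n_trials, seed=c, record_traces=True
                    )
                    s = session_erp_summary(res)
                    if s["ern_att"] is not None:
                        ern.append(s["ern_att"])
                    if s["psp_att"] is None:
                        undef += 1
                    else:
                        psp.append(s["psp_att"])
                rows.append(
                    {
                        "sweep": swept,
                        "companion": companion,
                        "companion_value": comp_val,
                        "value": float(v),
                        "ern_att": float(np.mean(ern)) if ern else float("nan"),
                        "ern_se": float(np.std(ern, ddof=1) / np.sqrt(len(ern)))
                        if len(ern) > 1
                        else float("nan"),
                        "psp_att": float(np.mean(psp)) if psp else float("nan"),
                        "psp_se": float(np.std(psp, ddof=1) / np.sqrt(len(psp)))
                        if len(psp) > 1
                        else float("nan"),
                        "psp_undefined": undef,
                    }
                )
    report = StudyReport(study="5", curves=pd.DataFrame(rows), seed=seed)
    return report


def gpi_sma_lagged_correlation(
    seed: int = 0,
    eps_sma_values: Optional[np.ndarray] = None,
    n_runs: int = 20,
    max_lag: int = 10,
    n_trials: int = 64,
) -> pd.DataFrame:
    """Extreme lagged rank correlation between GPi and sensorimotor output.

    For each eps_sma value (defaults otherwise), runs traced sessions and
    computes, per session, the largest-magnitude (sign-preserved) Spearman
    correlation over the four sensorimotor schemas and lags 1..max_lag
    between GPi output at cycle t and cortical sensorimotor output at
    t+lag. Returns one row per eps_sma value with the across-session mean.
    A near-constant, clearly negative coefficient across the whole range
    indicates that basal-ganglia selection operates independently of the
    conflict-driven cortical gain.
    """
    if eps_sma_values is None:
        eps_sma_values = np.round(np.arange(0.0, 1.0001, 0.05), 3)
    base = ParameterSet()
    rows = []
    for vi, v in enumerate(eps_sma_values):
        params = base.override(eps_sma=float(v))
        ss = np.random.SeedSequence((seed, vi))
        extremes = []
        for c in ss.spawn(n_runs):
            res = run_session(params, n_trials=n_trials, seed=c, record_traces=True)
            gpi = res.traces["o_gpi_sma"]
            sma = res.traces["o_sma"]
            if len(gpi) <= max_lag + 2:
                raise ValueError("trace shorter than the maximum lag")
            best = 0.0
            for lag in range(1, max_lag + 1):
                a = gpi[:-lag]
                b = sma[lag:]
                for j in range(a.shape[1]):
                    rho, _ = stats.spearmanr(a[:, j], b[:, j])
                    if np.isnan(rho):
                        continue
                    if abs(rho) > abs(best):
                        best = float(rho)
            extremes.append(best)
        rows.append(
            {
                "eps_sma": float(v),
                "rho_extreme_mean": float(np.mean(extremes)),
                "rho_extreme_sd": float(np.std(extremes, ddof=1))
                if len(extremes) > 1
                else 0.0,
            }
        )
    return pd.DataFrame(rows)
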