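"""Trial-to-trial reliability of latent factor trajectories.

Two complementary metrics:

- ``stereotypy_position`` — per trial, the Pearson correlation of the
  (time-warped) single-trial factor trace against the mean trace of all
  *other* matched trials, over the reach-onset -> retract span; the
  session value is the median over trials.  Higher = more stereotyped
  trajectories.
- ``consistency_velocity`` — per trial, the absolute deviation of the
  factor's instantaneous velocity (first difference) from the across-trial
  mean velocity at a behavioral timepoint (reach onset, touch, retract);
  the reported timepoint per factor is the one with the lowest median
  absolute deviation.  Lower = more consistent.  No duration matching is
  needed since the metric is instantaneous.

Both are computed on the cross-area factors' area-A view by default (the
area-B view is exposed via ``view``).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .behavior import select_matched_trials, warp_trials
from .containers import EmptySelectionError, TrialTable
from .dlag import DLAGModel, LatentTrajectories

__all__ = ["ReliabilityResult", "TimescaleSummary", "stereotypy_position",
           "consistency_velocity", "summarize_timescales",
           "delay_distribution"]

TIMEPOINTS = ("reach", "touch", "retract")


@dataclass
class ReliabilityResult:
    per_trial: np.ndarray           # trials_used x factors (NaN-padded)
    session_median: np.ndarray      # per factor
    n_trials_used: int
    best_timepoint: Optional[List[str]] = None   # consistency only
    trial_indices: Optional[np.ndarray] = None


@dataclass
class TimescaleSummary:
    taus: Dict[str, np.ndarray]          # group -> pooled tau values (ms)
    medians: Dict[str, float]
    ranksum: Dict[Tuple[str, str], Tuple[float, float]]  # (stat, p)


def _factor_traces(latents, view: str) -> np.ndarray:
    if isinstance(latents, np.ndarray):
        return latents
    return latents.cf_A if view == "A" else latents.cf_B


def stereotypy_position(latents, table: TrialTable,
                        tolerance: float = 0.1, view: str = "A",
                        min_trials: int = 3) -> Optional[ReliabilityResult]:
    """Leave-one-out template correlation of warped factor trajectories.

    Trials are restricted to first-attempt successes within ``tolerance``
    (s) of the session's median epoch durations, then time-warped onto the
    median timing; the correlation runs over the reach-onset -> retract
    span.  Returns None (metric undefined) when fewer than ``min_trials``
    trials match.
    """
    traces = _factor_traces(latents, view)       # trials x bins x factors
    try:
        idx = select_matched_trials(table, tolerance=tolerance,
                                    require_first_attempt=True)
    except EmptySelectionError:
        return None
    if idx.size < min_trials:
        return None

    ok = table.success
    m_rt = float(np.median(table.reach_to_touch()[ok]))
    m_tr = float(np.median(table.touch_to_retract()[ok]))
    time_ms = (latents.time_axis if isinstance(latents, LatentTrajectories)
               else np.arange(traces.shape[1], dtype=float))
    warped = warp_trials(traces, time_ms, table, idx, medians=(m_rt, m_tr))

    span = (time_ms / 1000.0 >= -m_rt) & (time_ms / 1000.0 <= m_tr)
    W = warped[:, span, :]                        # n x bins_span x F
    n, _, F = W.shape
    r = np.full((n, F), np.nan)
    for i in range(n):
        template = (W.sum(axis=0) - W[i]) / (n - 1)
        for f in range(F):
            r[i, f] = _pearson(W[i, :, f], template[:, f])
    return ReliabilityResult(per_trial=r,
                             session_median=np.nanmedian(r, axis=0),
                             n_trials_used=n, trial_indices=idx)


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        return np.nan
    return float(np.mean((a - a.mean()) * (b - b.mean())) / (sa * sb))


def consistency_velocity(latents, table: TrialTable,
                         timepoints: Sequence[str] = TIMEPOINTS,
                         view: str = "A",
                         reduce: str = "best") -> Optional[ReliabilityResult]:
    """Absolute deviation of instantaneous factor velocity at key events.

    Velocity is the first difference of the factor trace (trace units per
    bin).  For each factor and timepoint, the per-trial value is
    |v_i - mean_j v_j| at the event's nearest bin (ties toward the earlier
    bin); the factor's reported timepoint is the one with the lowest
    median absolute deviation (``reduce='best'``), or the mean over the
    grasp pair touch/retract (``reduce='grasp_mean'``).  All successful
    trials are included.
    """
    traces = _factor_traces(latents, view)
    ok = np.where(table.success)[0]
    if ok.size < 2:
        return None
    time_ms = (latents.time_axis if isinstance(latents, LatentTrajectories)
               else np.arange(traces.shape[1], dtype=float))
    vel = np.diff(traces[ok], axis=1)             # n x (bins-1) x F
    vel_t = 0.5 * (time_ms[:-1] + time_ms[1:])
    n, _, F = vel.shape

    event_ms = {
        "reach": (table.reach_onset[ok] - table.touch[ok]) * 1000.0,
        "touch": np.zeros(ok.size),
        "retract": (table.retract[ok] - table.touch[ok]) * 1000.0,
    }
    dev = {}
    for tp in timepoints:
        if tp not in event_ms:
            raise ValueError(f"unknown timepoint {tp!r}")
        bins = _nearest_bin(event_ms[tp], vel_t)
        valid = bins >= 0
        if not valid.any():
            continue   # timepoint outside the trial window for every trial
        v = np.full((n, F), np.nan)
        v[valid] = vel[np.arange(n)[valid], bins[valid], :]
        dev[tp] = np.abs(v - np.nanmean(v, axis=0))
    if not dev:
        return None

    if reduce == "grasp_mean" and {"touch", "retract"} <= set(dev):
        combined = 0.5 * (dev["touch"] + dev["retract"])
        per_trial = combined
        best = ["grasp"] * F
        session = np.nanmedian(combined, axis=0)
    else:
        per_trial = np.full((n, F), np.nan)
        best = []
        session = np.empty(F)
        for f in range(F):
            meds = {tp: np.nanmedian(d[:, f]) for tp, d in dev.items()}
            tp_best = min(meds, key=lambda k: (meds[k], TIMEPOINTS.index(k)))
            best.append(tp_best)
            per_trial[:, f] = dev[tp_best][:, f]
            session[f] = meds[tp_best]
    return ReliabilityResult(per_trial=per_trial, session_median=session,
                             n_trials_used=n, best_timepoint=best,
                             trial_indices=ok)


def _nearest_bin(event_ms: np.ndarray, grid_ms: np.ndarray) -> np.ndarray:
    """Nearest grid bin per event, ties toward the earlier bin; -1 if the
    event falls outside the grid span."""
    out = np.full(event_ms.size, -1, dtype=int)
    inside = (event_ms >= grid_ms[0]) & (event_ms <= grid_ms[-1])
    if inside.any():
        d = np.abs(grid_ms[None, :] - event_ms[inside, None])
        # argmin returns the first (earlier) index on ties
        out[inside] = np.argmin(d, axis=1)
    return out


def summarize_timescales(models: Sequence[DLAGModel]) -> TimescaleSummary:
    """Pool fitted GP timescales by factor group with rank-sum contrasts."""
    if not models:
        raise ValueError("need at least one fitted model")
    taus = {"CF": [], "WF_A": [], "WF_B": []}
    for m in models:
        for g, vals in m.taus_by_group().items():
            taus[g].extend(vals)
    taus = {g: np.asarray(v, dtype=float) for g, v in taus.items()}
    medians = {g: (float(np.median(v)) if v.size else np.nan)
               for g, v in taus.items()}
    ranksum = {}
    for a, b in (("CF", "WF_A"), ("CF", "WF_B"), ("WF_A", "WF_B")):
        if taus[a].size and taus[b].size:
            res = stats.ranksums(taus[a], taus[b])
            ranksum[(a, b)] = (float(res.statistic), float(res.pvalue))
    return TimescaleSummary(taus=taus, medians=medians, ranksum=ranksum)


def delay_distribution(models: Sequence[DLAGModel]) -> Dict[str, object]:
    """Pool fitted CF delays; positive = area B follows area A."""
    if not models:
        raise ValueError("need at least one fitted model")
    delays = np.concatenate([m.delays for m in models]) if models else np.array([])
    frac_pos = float(np.mean(delays > 0)) if delays.size else np.nan
    return {"delays_ms": delays, "fraction_positive": frac_pos,
            "support_ms": (float(delays.min()), float(delays.max()))
            if delays.size else (np.nan, np.nan)}
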