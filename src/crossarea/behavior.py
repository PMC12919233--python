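"""Kinematics, behavioral events, trial matching, time warping, modulation.

Kinematic traces stay in pixel units (no camera calibration); the wrist is
tracked at three redundant points and each digit at two, so that momentary
tracking loss degrades gracefully: speed/aperture use whatever points are
available, and a frame with no valid points is missing (NaN), not an
error.  Gaps of at most three frames are linearly interpolated; longer
gaps stay missing and are excluded downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .containers import (EmptySelectionError, KinematicTrace, SessionRecord,
                         TrialTable)

__all__ = [
    "wrist_speed", "hand_aperture", "interpolate_short_gaps",
    "select_matched_trials", "time_warp", "epoch_modulation",
    "EpochModulation", "classify_sessions", "EPOCH_WINDOWS_MS",
]

#: 200-ms epoch windows, ms relative to their anchoring event.
EPOCH_WINDOWS_MS: Dict[str, Tuple[str, float, float]] = {
    "pre_reach": ("reach_onset", -500.0, -300.0),
    "reach": ("reach_onset", -100.0, 100.0),
    "grasp": ("touch", -50.0, 150.0),
    "retract": ("retract", 0.0, 200.0),
}

_SPEED_KERNEL = None


def _speed_kernel() -> np.ndarray:
    # 5-sample Gaussian kernel, unit sum
    global _SPEED_KERNEL
    if _SPEED_KERNEL is None:
        from scipy.signal.windows import gaussian
        k = gaussian(5, std=1.0)
        _SPEED_KERNEL = k / k.sum()
    return _SPEED_KERNEL


def interpolate_short_gaps(series: np.ndarray, max_gap: int = 3) -> np.ndarray:
    """Linearly fill NaN runs of length <= max_gap; longer runs stay NaN."""
    x = np.asarray(series, dtype=float).copy()
    isnan = np.isnan(x)
    if not isnan.any() or isnan.all():
        return x
    idx = np.arange(x.size)
    # find NaN runs
    edges = np.diff(isnan.astype(int))
    starts = list(np.where(edges == 1)[0] + 1)
    ends = list(np.where(edges == -1)[0] + 1)
    if isnan[0]:
        starts = [0] + starts
    if isnan[-1]:
        ends = ends + [x.size]
    good = ~isnan
    for s, e in zip(starts, ends):
        if e - s <= max_gap and s > 0 and e < x.size:
            x[s:e] = np.interp(idx[s:e], idx[good], x[good])
    return x


def wrist_speed(trace: KinematicTrace, smooth: bool = True) -> np.ndarray:
    """Wrist speed (px/frame): per-point frame-to-frame Euclidean
    displacement, averaged over the three redundant wrist points, smoothed
    with a 5-sample Gaussian kernel.  The first frame is NaN (no previous
    frame); frames where all three points are missing are NaN.
    """
    pts = trace.wrist_points                       # F x 3 x 2
    if pts.shape[0] < 2:
        raise ValueError("need at least 2 frames")
    disp = np.diff(pts, axis=0)                    # (F-1) x 3 x 2
    speed = np.hypot(disp[:, :, 0], disp[:, :, 1])  # (F-1) x 3
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        mean_speed = np.nanmean(speed, axis=1)
    out = np.full(pts.shape[0], np.nan)
    out[1:] = mean_speed
    if smooth:
        out = _nan_convolve(out, _speed_kernel())
    trace.wrist_speed = out
    return out


def _nan_convolve(x: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Convolution that renormalizes over non-missing samples."""
    mask = np.isfinite(x)
    filled = np.where(mask, x, 0.0)
    num = np.convolve(filled, kernel, mode="same")
    den = np.convolve(mask.astype(float), kernel, mode="same")
    out = np.full_like(x, np.nan)
    ok = den > 1e-12
    out[ok] = num[ok] / den[ok]
    out[~mask] = np.nan
    return out


def hand_aperture(trace: KinematicTrace, table: Optional[TrialTable] = None
                  ) -> Tuple[np.ndarray, Optional[np.ndarray]]:
    """Thumb-index distance (px) per frame, and per-trial max-aperture times.

    Thumb and index positions are each the mean of their two redundant
    palmar points.  When a trial table is given, the per-trial maximum
    aperture time is the argmax between reach onset and touch; trials with
    no valid frame in that span get NaN (flagged, not an error).
    """
    pts = trace.digit_points                       # F x 4 x 2
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        thumb = np.nanmean(pts[:, :2, :], axis=1)
        index = np.nanmean(pts[:, 2:, :], axis=1)
    aperture = np.hypot(*(thumb - index).T)
    trace.aperture = aperture
    if table is None:
        return aperture, None
    t = trace.frame_times
    max_t = np.full(len(table), np.nan)
    for i in range(len(table)):
        sel = (t >= table.reach_onset[i]) & (t <= table.touch[i])
        vals = aperture[sel]
        if sel.any() and np.any(np.isfinite(vals)):
            max_t[i] = t[sel][np.nanargmax(vals)]
        else:
            warnings.warn(f"trial {i}: no valid aperture frame in reach epoch")
    return aperture, max_t


def select_matched_trials(table: TrialTable, tolerance: float = 0.1,
                          require_first_attempt: bool = True,
                          medians: Optional[Tuple[float, float]] = None
                          ) -> np.ndarray:
    """Indices of successful trials with near-median epoch durations.

    Keeps successful trials whose reach-to-touch AND touch-to-retract
    durations are both within ``tolerance`` (s) of the session medians
    (computed over successful trials unless given).  Defaults: 0.1 s for
    stereotypy, 0.2 s for trial averaging.  ``require_first_attempt``
    drops trials with more than one grasp attempt.
    """
    ok = table.success.copy()
    if require_first_attempt:
        ok &= table.grasp_attempts <= 1
    if not ok.any():
        raise EmptySelectionError("no successful trials to match")
    rt = table.reach_to_touch()
    tr = table.touch_to_retract()
    if medians is None:
        medians = (float(np.median(rt[ok])), float(np.median(tr[ok])))
    m_rt, m_tr = medians
    sel = ok & (np.abs(rt - m_rt) <= tolerance) & (np.abs(tr - m_tr) <= tolerance)
    idx = np.where(sel)[0]
    if idx.size == 0:
        raise EmptySelectionError("no trial matches the duration tolerance")
    return idx


def time_warp(series: np.ndarray, time_axis: np.ndarray,
              reach_to_touch: float, touch_to_retract: float,
              medians: Tuple[float, float]) -> np.ndarray:
    """Piecewise-linear warp of one trial's trace onto the median timing.

    ``time_axis`` is seconds relative to touch.  The pre-touch segment is
    linearly rescaled so the reach-to-touch duration equals the median,
    likewise post-touch for touch-to-retract; samples outside
    [reach_onset, retract] are carried rigidly.  Touch (t = 0) is a fixed
    point of the warp, and a trial already at both medians passes through
    unchanged bit for bit.
    """
    if not (reach_to_touch > 0 and touch_to_retract > 0):
        raise ValueError("trial events out of order")
    m_rt, m_tr = medians
    t = np.asarray(time_axis, dtype=float)
    x = np.asarray(series, dtype=float)
    pre_gain = m_rt / reach_to_touch
    post_gain = m_tr / touch_to_retract
    w = np.empty_like(t)
    pre = t < -reach_to_touch
    mid_pre = (~pre) & (t < 0)
    mid_post = (t >= 0) & (t <= touch_to_retract)
    post = t > touch_to_retract
    # rigid shifts are exact identities when the trial is at the medians
    w[pre] = t[pre] + (reach_to_touch - m_rt)
    w[mid_pre] = t[mid_pre] * pre_gain
    w[mid_post] = t[mid_post] * post_gain
    w[post] = t[post] - (touch_to_retract - m_tr)
    return np.interp(t, w, x)


def warp_trials(traces: np.ndarray, time_axis_ms: np.ndarray,
                table: TrialTable, idx: Sequence[int],
                medians: Optional[Tuple[float, float]] = None) -> np.ndarray:
    """Time-warp trials ``idx`` of a trials x bins (x factors) array onto
    the (median) timing; returns len(idx) x bins (x factors)."""
    rt = table.reach_to_touch()
    tr = table.touch_to_retract()
    if medians is None:
        ok = table.success
        medians = (float(np.median(rt[ok])), float(np.median(tr[ok])))
    t_s = np.asarray(time_axis_ms, dtype=float) / 1000.0
    idx = np.asarray(idx)
    single = traces.ndim == 2
    tr3 = traces[:, :, None] if single else traces
    out = np.empty((idx.size,) + tr3.shape[1:])
    for k, i in enumerate(idx):
        for f in range(tr3.shape[2]):
            out[k, :, f] = time_warp(tr3[i, :, f], t_s, rt[i], tr[i], medians)
    return out[:, :, 0] if single else out


@dataclass
class EpochModulation:
    """Per-channel task/epoch modulation flags and magnitudes."""

    task_modulated: np.ndarray            # bool per channel
    epoch_modulated: Dict[str, np.ndarray]
    magnitude: Dict[str, np.ndarray]      # max |trace| within each epoch


def epoch_modulation(trial_avg: np.ndarray, time_axis_ms: np.ndarray,
                     event_times_ms: Dict[str, float],
                     threshold: float = 1.0,
                     epochs: Dict[str, Tuple[str, float, float]] = EPOCH_WINDOWS_MS
                     ) -> EpochModulation:
    """Flag channels whose trial-averaged z-scored trace leaves +/-1 SD.

    ``trial_avg`` is bins x channels (trial-averaged from time-warped,
    similarly timed trials); ``event_times_ms`` maps 'reach_onset',
    'touch', 'retract' to times on ``time_axis_ms``.  A channel is task
    modulated if |trace| exceeds the threshold anywhere, and epoch
    modulated if it does so within that epoch's window; the magnitude is
    the max |trace| in the epoch.
    """
    trace = np.asarray(trial_avg, dtype=float)
    if trace.ndim == 1:
        trace = trace[:, None]
    absx = np.abs(trace)
    task = absx.max(axis=0) > threshold
    epoch_mod, magnitude = {}, {}
    for name, (anchor, lo, hi) in epochs.items():
        if anchor not in event_times_ms:
            warnings.warn(f"epoch {name!r}: no event time for {anchor!r}; skipped")
            continue
        t0 = event_times_ms[anchor]
        sel = (time_axis_ms >= t0 + lo) & (time_axis_ms <= t0 + hi)
        if not sel.any():
            warnings.warn(f"epoch {name!r} outside trace support; skipped")
            continue
        mag = absx[sel].max(axis=0)
        magnitude[name] = mag
        epoch_mod[name] = mag > threshold
    return EpochModulation(task_modulated=task, epoch_modulated=epoch_mod,
                           magnitude=magnitude)


def classify_sessions(records: List[SessionRecord],
                      session_durations: List[np.ndarray],
                      baseline_durations: np.ndarray,
                      early_min_rewarded: int = 5,
                      alpha: float = 0.05) -> List[SessionRecord]:
    """Assign recovery phases and normalized task durations.

    ``session_durations`` holds each session's trial durations
    (reach onset -> retract, s); ``baseline_durations`` the pre-lesion
    distribution.  The normalized duration is the session median divided
    by the baseline median.  "Early" = the first two post-lesion sessions
    with more than ``early_min_rewarded`` rewarded trials; "Late" =
    sessions whose duration distribution is not significantly different
    from baseline (two-sided rank-sum at ``alpha``).
    """
    baseline = np.asarray(baseline_durations, dtype=float)
    if baseline.size == 0:
        raise ValueError("baseline duration distribution is required")
    base_med = float(np.median(baseline))
    n_early = 0
    out = []
    for rec, durs in zip(records, session_durations):
        durs = np.asarray(durs, dtype=float)
        norm = float(np.median(durs)) / base_med
        phase = "Other"
        if n_early < 2 and rec.n_rewarded > early_min_rewarded:
            phase = "Early"
            n_early += 1
        else:
            p = stats.ranksums(durs, baseline).pvalue
            if p >= alpha:
                phase = "Late"
        out.append(SessionRecord(
            animal_id=rec.animal_id, day_post_lesion=rec.day_post_lesion,
            normalized_r2g_duration=norm, phase=phase,
            n_rewarded=rec.n_rewarded))
    return out
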