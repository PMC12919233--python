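"""Lagged kinematic decoding and comparative / recovery-trend statistics.

Wrist speed and hand aperture are reconstructed from latent predictors by
ordinary least squares on time-lagged duplicates of each factor (default
lags 0, -60, -120, -180 ms — the current sample plus three copies stepped
into the past), validated by repeated hold-out: 30 random 80/20 bin-level
splits, reporting the test-set coefficient of determination per split.

Predictor families are compared with a Kruskal-Wallis omnibus across
session-level median R^2, followed by pairwise two-sided rank-sum
post-hocs only when the omnibus rejects at alpha = 0.05.  Recovery trends
are Spearman correlations against normalized task duration (all animals)
or linear mixed-effects slopes with an animal-specific random intercept
(recovery animals only).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LinearRegression
from sklearn.metrics import r2_score

__all__ = [
    "DecodingResult", "TrendResult", "build_lagged_predictors",
    "interpolate_to_bins", "decode_kinematics", "grid_search_lags",
    "compare_predictors", "recovery_trends", "DEFAULT_LAGS_MS",
]

DEFAULT_LAGS_MS = (0.0, -60.0, -120.0, -180.0)


@dataclass
class DecodingResult:
    predictor_type: str             # 'CF' | 'WF' | 'PC_top5' | ...
    area: str
    target: str                     # 'wrist_speed' | 'aperture'
    r2_per_iteration: np.ndarray    # one value per hold-out split
    median: float


@dataclass
class TrendResult:
    metric: str
    mode: str                       # 'spearman' | 'mixed_effects'
    statistic: float                # rho, or slope t value
    pvalue: float
    slope: Optional[float] = None
    n_sessions: int = 0
    direction: str = "none"


def build_lagged_predictors(latents: np.ndarray, lags_ms: Sequence[float]
                            = DEFAULT_LAGS_MS, bin_width: float = 20.0
                            ) -> np.ndarray:
    """Time-lagged duplicate columns of each factor.

    ``latents`` is trials x bins x factors.  A lag of -60 ms means the
    predictor at time t is the latent at t - 60 ms.  Bins whose lagged
    sample falls outside the trial are NaN (excluded downstream).  Output
    is trials x bins x (factors * len(lags)), lag-major per factor.
    """
    n, T, F = latents.shape
    cols = []
    for f in range(F):
        for lag in lags_ms:
            shift = lag / bin_width
            if abs(shift - round(shift)) > 1e-9:
                raise ValueError(f"lag {lag} ms is not a bin multiple")
            shift = int(round(shift))
            col = np.full((n, T), np.nan)
            if shift == 0:
                col[:] = latents[:, :, f]
            elif shift < 0:
                col[:, -shift:] = latents[:, :T + shift, f]
            else:
                col[:, :T - shift] = latents[:, shift:, f]
            cols.append(col)
    return np.stack(cols, axis=2)


def interpolate_to_bins(frame_times: np.ndarray, series: np.ndarray,
                        bin_times: np.ndarray) -> np.ndarray:
    """Linear interpolation of a video-rate trace onto neural bin times (s).

    Extrapolation beyond the sampled range is forbidden: such bins are
    NaN, as are bins bracketed by missing samples.
    """
    good = np.isfinite(series)
    out = np.full(bin_times.size, np.nan)
    if good.sum() < 2:
        return out
    t, x = frame_times[good], series[good]
    inside = (bin_times >= t[0]) & (bin_times <= t[-1])
    out[inside] = np.interp(bin_times[inside], t, x)
    # a bin interpolated across a gap in the raw trace is unreliable only
    # if the gap was long; short gaps were already filled upstream
    return out


def decode_kinematics(design: np.ndarray, target: np.ndarray,
                      split: float = 0.8, iterations: int = 30,
                      seed: int = 0, predictor_type: str = "CF",
                      area: str = "A", target_name: str = "wrist_speed",
                      split_unit: str = "bin",
                      min_rows_per_col: int = 10) -> DecodingResult:
    """Repeated hold-out OLS decoding of a kinematic series.

    ``design`` is trials x bins x columns (or rows x columns), ``target``
    the kinematic series on the same bin grid.  Rows with any missing
    value are dropped.  Each iteration draws a random 80/20 train/test
    split, fits OLS on train, and scores R^2 on test.  ``split_unit``
    selects what is held out: individual bins (default) or whole trials
    (for leakage-sensitive analyses; requires the 3-d design).
    """
    X = design.reshape(-1, design.shape[-1])
    y = np.asarray(target, dtype=float).ravel()
    if X.shape[0] != y.size:
        raise ValueError("design and target lengths differ")
    if split_unit == "trial":
        if design.ndim != 3:
            raise ValueError("trial-level splitting needs trials x bins x "
                             "columns input")
        trial_of_row = np.repeat(np.arange(design.shape[0]), design.shape[1])
    elif split_unit != "bin":
        raise ValueError(f"unknown split_unit {split_unit!r}")
    ok = np.isfinite(y) & np.all(np.isfinite(X), axis=1)
    X, y = X[ok], y[ok]
    if X.shape[0] < min_rows_per_col * X.shape[1]:
        raise ValueError(
            f"too few valid bins ({X.shape[0]}) for {X.shape[1]} columns")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        warnings.warn("rank-deficient design; OLS uses the pseudo-inverse")

    rng = np.random.default_rng(seed)
    n = X.shape[0]
    r2 = np.empty(iterations)
    for it in range(iterations):
        if split_unit == "trial":
            trials = trial_of_row[ok]
            uniq = np.unique(trials)
            perm = rng.permutation(uniq.size)
            n_tr = int(round(split * uniq.size))
            train_mask = np.isin(trials, uniq[perm[:n_tr]])
            tr, te = np.where(train_mask)[0], np.where(~train_mask)[0]
        else:
            perm = rng.permutation(n)
            n_tr = int(round(split * n))
            tr, te = perm[:n_tr], perm[n_tr:]
        model = LinearRegression().fit(X[tr], y[tr])
        r2[it] = r2_score(y[te], model.predict(X[te]))
    return DecodingResult(predictor_type=predictor_type, area=area,
                          target=target_name, r2_per_iteration=r2,
                          median=float(np.median(r2)))


def grid_search_lags(latents: np.ndarray, target: np.ndarray,
                     lag_sets: Sequence[Sequence[float]],
                     bin_width: float = 20.0, seed: int = 0,
                     **decode_kw) -> Dict[tuple, float]:
    """Median hold-out R^2 for each candidate lag set.

    A thin search over the temporal-offset hyperparameter: each lag set is
    expanded into a lagged design and scored by ``decode_kinematics``.
    Smoothing-width searches are composed upstream by regenerating the
    latents (or re-normalizing activity) at each candidate width.
    """
    out = {}
    for lags in lag_sets:
        X = build_lagged_predictors(latents, lags_ms=lags,
                                    bin_width=bin_width)
        res = decode_kinematics(X, target, seed=seed, **decode_kw)
        out[tuple(lags)] = res.median
    return out


def compare_predictors(results: Sequence[DecodingResult],
                       alpha: float = 0.05) -> Dict[str, object]:
    """Kruskal-Wallis omnibus over predictor types, gated rank-sum post-hocs.

    ``results`` are session-level decoding results of the same area and
    target; the omnibus runs on their median R^2 grouped by predictor
    type, and pairwise two-sided rank-sum tests run only if the omnibus
    rejects at ``alpha``.
    """
    groups: Dict[str, List[float]] = {}
    for r in results:
        groups.setdefault(r.predictor_type, []).append(r.median)
    if len(groups) < 2:
        raise ValueError("need at least two predictor types")
    names = sorted(groups)
    samples = [np.asarray(groups[g]) for g in names]
    if np.ptp(np.concatenate(samples)) == 0:
        # identical distributions: nothing to test, gate stays closed
        omnibus_stat, omnibus_p = 0.0, 1.0
    else:
        res = stats.kruskal(*samples)
        omnibus_stat, omnibus_p = float(res.statistic), float(res.pvalue)
    posthoc = {}
    if omnibus_p < alpha:
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                rs = stats.ranksums(samples[i], samples[j])
                posthoc[(names[i], names[j])] = (float(rs.statistic),
                                                 float(rs.pvalue))
    return {"omnibus_statistic": omnibus_stat, "omnibus_p": omnibus_p,
            "posthoc": posthoc, "groups": {g: np.asarray(v)
                                           for g, v in groups.items()}}


def recovery_trends(values: Sequence[float], predictor: Sequence[float],
                    metric: str = "metric", mode: str = "spearman",
                    animals: Optional[Sequence[str]] = None,
                    min_sessions: int = 5) -> TrendResult:
    """Trend of a per-session metric against recovery.

    ``predictor`` is normalized task duration (or a day index).  Spearman
    mode reports the rank correlation; mixed-effects mode fits
    metric ~ predictor with an animal-specific random intercept and
    reports the slope's t statistic and p value (requires >= 2 animals).
    A constant metric leaves the trend undefined (NaN), not zero.
    """
    y = np.asarray(values, dtype=float)
    x = np.asarray(predictor, dtype=float)
    ok = np.isfinite(y) & np.isfinite(x)
    y, x = y[ok], x[ok]
    if y.size < min_sessions:
        raise ValueError(f"need at least {min_sessions} sessions, got {y.size}")
    if np.ptp(y) == 0 or np.ptp(x) == 0:
        return TrendResult(metric=metric, mode=mode, statistic=np.nan,
                           pvalue=np.nan, n_sessions=y.size,
                           direction="undefined")

    if mode == "spearman":
        rho, p = stats.spearmanr(x, y)
        return TrendResult(metric=metric, mode=mode, statistic=float(rho),
                           pvalue=float(p), n_sessions=y.size,
                           direction="positive" if rho > 0 else "negative")
    if mode == "mixed_effects":
        if animals is None:
            raise ValueError("mixed_effects mode requires animal labels")
        an = np.asarray(animals)[ok]
        if np.unique(an).size < 2:
            raise ValueError("mixed_effects mode requires >= 2 animals")
        import statsmodels.formula.api as smf
        df = pd.DataFrame({"y": y, "x": x, "animal": an})
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = smf.mixedlm("y ~ x", df, groups=df["animal"]).fit(reml=True)
        slope = float(fit.params["x"])
        t = float(fit.tvalues["x"])
        p = float(fit.pvalues["x"])
        return TrendResult(metric=metric, mode=mode, statistic=t, pvalue=p,
                           slope=slope, n_sessions=y.size,
                           direction="positive" if slope > 0 else "negative")
    raise ValueError(f"unknown mode {mode!r}")
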