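"""Core in-memory containers shared across the pipeline.

Times are seconds in session clock unless a field says otherwise; bin and
window parameters are milliseconds; neural activity arrays are always
``trials x bins x channels``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

WELL_DIAMETERS_MM = (13, 19, 25, 31, 37)

#: Allowed normalization states, in pipeline order.
NORMALIZATION_STATES = (
    "raw_counts", "raw_sbp", "rate_normalized", "sqrt", "smoothed",
    "demeaned", "zscored",
)


class EmptySelectionError(RuntimeError):
    """Raised when a filtering step removes every trial or channel."""


@dataclass
class TrialTable:
    """Per-trial behavioral events and outcome flags.

    ``df`` columns (times in seconds, session clock):

    - ``reach_onset``, ``touch``, ``retract`` — the three annotated events;
      ``touch`` is the first pellet contact and anchors all alignment.
    - ``extra_touches`` (object, optional) — later touch onsets on fumbled
      grasps.
    - ``max_aperture_time`` (optional, NaN when undefined).
    - ``well_diameter`` — mm, one of 13/19/25/31/37.
    - ``success``, ``attempted`` — bool flags.
    - ``grasp_attempts`` — int, >= 1.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"reach_onset", "touch", "retract", "success",
                    "attempted", "grasp_attempts"}
        missing = required - set(self.df.columns)
        if missing:
            raise ValueError(f"TrialTable missing columns: {sorted(missing)}")
        if "well_diameter" in self.df.columns:
            bad = set(self.df["well_diameter"].dropna().unique()) - set(WELL_DIAMETERS_MM)
            if bad:
                raise ValueError(f"well diameters outside allowed set: {bad}")
        valid = self.df["attempted"].to_numpy(dtype=bool)
        order_ok = (
            (self.df["reach_onset"] < self.df["touch"])
            & (self.df["touch"] < self.df["retract"])
        ).to_numpy()
        if np.any(valid & ~order_ok & np.isfinite(self.df["touch"])):
            raise ValueError("event order violated: need reach_onset < touch < retract")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def touch(self) -> np.ndarray:
        return self.df["touch"].to_numpy(dtype=float)

    @property
    def reach_onset(self) -> np.ndarray:
        return self.df["reach_onset"].to_numpy(dtype=float)

    @property
    def retract(self) -> np.ndarray:
        return self.df["retract"].to_numpy(dtype=float)

    @property
    def success(self) -> np.ndarray:
        return self.df["success"].to_numpy(dtype=bool)

    @property
    def grasp_attempts(self) -> np.ndarray:
        return self.df["grasp_attempts"].to_numpy(dtype=int)

    def reach_to_touch(self) -> np.ndarray:
        """Reach-onset -> touch durations (s)."""
        return self.touch - self.reach_onset

    def touch_to_retract(self) -> np.ndarray:
        """Touch -> retract durations (s)."""
        return self.retract - self.touch

    def subset(self, idx) -> "TrialTable":
        return TrialTable(self.df.iloc[np.asarray(idx)].reset_index(drop=True))


@dataclass
class BinnedActivity:
    """Trial-aligned neural activity for one area: trials x bins x channels."""

    values: np.ndarray
    bin_width: float                 # ms
    time_axis: np.ndarray            # ms, bin centers relative to touch
    area_label: str
    channel_ids: np.ndarray
    normalization_state: str = "raw_counts"
    session_rate_hz: Optional[np.ndarray] = None   # per-channel session-wide rate
    rate_source: str = "trial_epochs"              # or "session_wide"
    smoothed_sd: Optional[float] = None            # ms, set once smoothing applied

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.time_axis = np.asarray(self.time_axis, dtype=float)
        self.channel_ids = np.asarray(self.channel_ids)
        if self.values.ndim != 3:
            raise ValueError("values must be trials x bins x channels")
        if self.values.shape[1] != self.time_axis.size:
            raise ValueError("time_axis length must equal number of bins")
        if self.values.shape[2] != self.channel_ids.size:
            raise ValueError("channel_ids length must equal number of channels")
        if self.normalization_state not in NORMALIZATION_STATES:
            raise ValueError(f"unknown normalization state {self.normalization_state!r}")

    @property
    def n_trials(self) -> int:
        return self.values.shape[0]

    @property
    def n_bins(self) -> int:
        return self.values.shape[1]

    @property
    def n_channels(self) -> int:
        return self.values.shape[2]

    def with_values(self, values: np.ndarray, state: str, **kw) -> "BinnedActivity":
        out = replace(self, values=values, normalization_state=state)
        for k, v in kw.items():
            setattr(out, k, v)
        return out


@dataclass
class SBPTrace:
    """Spiking-band power per trial bin: trials x bins x channels."""

    values: np.ndarray
    band: tuple = (300.0, 500.0)     # Hz
    bin_width: float = 20.0          # ms
    window_width: float = 20.0       # ms
    time_axis: Optional[np.ndarray] = None
    channel_ids: Optional[np.ndarray] = None
    freqs_averaged: Optional[np.ndarray] = None  # spectrogram freqs inside band

    def __post_init__(self) -> None:
        if not self.band[0] < self.band[1]:
            raise ValueError("band_low must be < band_high")

    def as_binned(self, area_label: str = "A") -> BinnedActivity:
        """View the SBP bins as a BinnedActivity in the raw_sbp state."""
        return BinnedActivity(
            values=self.values, bin_width=self.bin_width,
            time_axis=self.time_axis, area_label=area_label,
            channel_ids=self.channel_ids, normalization_state="raw_sbp",
        )


@dataclass
class KinematicTrace:
    """Pose-tracking coordinates and derived kinematics at the video rate.

    Wrist position is tracked at three redundant points, thumb and index at
    two redundant palmar points each; all coordinates are pixels and missing
    samples are NaN.
    """

    frame_times: np.ndarray                  # s, strictly increasing, ~50 fps
    wrist_points: np.ndarray                 # frames x 3 x 2 (x, y)
    digit_points: np.ndarray                 # frames x 4 x 2 (thumb0, thumb1, index0, index1)
    wrist_speed: Optional[np.ndarray] = None  # px/frame, filled by behavior.wrist_speed
    aperture: Optional[np.ndarray] = None     # px, filled by behavior.hand_aperture

    def __post_init__(self) -> None:
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        if np.any(np.diff(self.frame_times) <= 0):
            raise ValueError("frame timestamps must be strictly increasing")
        if self.wrist_points.shape != (self.frame_times.size, 3, 2):
            raise ValueError("wrist_points must be frames x 3 x 2")
        if self.digit_points.shape != (self.frame_times.size, 4, 2):
            raise ValueError("digit_points must be frames x 4 x 2")


@dataclass
class SessionRecord:
    """Session metadata for recovery-series analyses."""

    animal_id: str
    day_post_lesion: int
    normalized_r2g_duration: float = np.nan
    phase: str = "Other"                    # Baseline | Early | Late | Other
    n_rewarded: int = 0

    def __post_init__(self) -> None:
        if self.phase not in ("Baseline", "Early", "Late", "Other"):
            raise ValueError(f"unknown phase {self.phase!r}")
        if np.isfinite(self.normalized_r2g_duration) and self.normalized_r2g_duration <= 0:
            raise ValueError("normalized duration must be positive")
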