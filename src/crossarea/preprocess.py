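"""Spike binning, channel screening, normalization, and spiking-band power.

The normalization chain mirrors standard practice for GP factor models on
trial-aligned data: per-channel firing-rate normalization (spiking only),
square-root variance stabilization, optional Gaussian smoothing, then
per-channel demeaning and z-scoring over all trial bins.  The order is
fixed and recorded in ``normalization_state``; running a stage out of
order raises.

Spiking-band power (SBP) is the band-limited high-frequency power of the
broadband voltage, a spiking proxy: high-pass at 240 Hz (5th-order
Butterworth, zero-phase), bank-of-16 median subtraction, per-channel
z-scoring, then a multitaper spectrogram (20-ms bins and windows, NW=2,
3 DPSS tapers) averaged over the 300-500 Hz band.
"""

from __future__ import annotations

import warnings
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy import signal
from scipy.ndimage import gaussian_filter1d

from .containers import BinnedActivity, EmptySelectionError, SBPTrace, TrialTable

__all__ = ["bin_spikes", "filter_channels", "normalize_activity",
           "compute_low_sbp"]

SBP_SAMPLING_HZ = 1017.25
BANK_SIZE = 16


def bin_spikes(spike_times: Sequence[np.ndarray], trial_table: TrialTable,
               bin_width: float = 20.0,
               window: Tuple[float, float] = (-1000.0, 1000.0),
               area_label: str = "A",
               channel_ids: Optional[Sequence] = None,
               session_duration: Optional[float] = None) -> BinnedActivity:
    """Count spikes in half-open bins [t, t + bin_width) aligned to touch.

    ``spike_times`` is one array of spike times (s) per channel.  Trials
    without a finite touch time are excluded with a warning.  If
    ``session_duration`` is given (s), a session-wide per-channel rate is
    recorded for channel screening; otherwise the trial-epoch mean rate is
    used downstream (flagged via ``rate_source``).
    """
    for st in spike_times:
        if not np.all(np.isfinite(st)):
            raise ValueError("spike times must be finite")
    w0, w1 = window
    n_bins = (w1 - w0) / bin_width
    if abs(n_bins - round(n_bins)) > 1e-9:
        raise ValueError("bin_width must divide the window length")
    n_bins = int(round(n_bins))

    touch = trial_table.touch
    keep = np.isfinite(touch)
    if not keep.all():
        warnings.warn(f"excluding {np.sum(~keep)} trial(s) without touch time")
    touch = touch[keep]

    q = len(spike_times)
    counts = np.zeros((touch.size, n_bins, q))
    edges = w0 / 1000.0 + np.arange(n_bins + 1) * bin_width / 1000.0
    for c, st in enumerate(spike_times):
        st = np.asarray(st, dtype=float)
        for i, t0 in enumerate(touch):
            rel = st - t0
            # half-open bins: spike exactly at the window end excluded
            counts[i, :, c] = np.histogram(rel[rel < edges[-1]], bins=edges)[0]

    session_rate = None
    source = "trial_epochs"
    if session_duration is not None:
        session_rate = np.array([len(st) / session_duration
                                 for st in spike_times])
        source = "session_wide"
    time_axis = w0 + (np.arange(n_bins) + 0.5) * bin_width
    if channel_ids is None:
        channel_ids = np.arange(q)
    return BinnedActivity(values=counts, bin_width=bin_width,
                          time_axis=time_axis, area_label=area_label,
                          channel_ids=np.asarray(channel_ids),
                          normalization_state="raw_counts",
                          session_rate_hz=session_rate, rate_source=source)


def filter_channels(binned: BinnedActivity, min_rate: float = 1.0
                    ) -> BinnedActivity:
    """Drop channels below a session-wide mean firing rate (Hz).

    The default 1 Hz threshold suits healthy arrays; 0.5 Hz is the relaxed
    setting for degraded arrays.  Uses the recorded session-wide rate when
    available, else the trial-epoch mean rate.
    """
    if binned.normalization_state != "raw_counts":
        raise ValueError("filter_channels expects raw spike counts")
    if binned.session_rate_hz is not None:
        rates = binned.session_rate_hz
    else:
        rates = binned.values.mean(axis=(0, 1)) / (binned.bin_width / 1000.0)
    keep = rates >= min_rate
    if not np.any(keep):
        raise EmptySelectionError(
            f"no channel reaches the {min_rate} Hz rate threshold")
    out = BinnedActivity(
        values=binned.values[:, :, keep], bin_width=binned.bin_width,
        time_axis=binned.time_axis, area_label=binned.area_label,
        channel_ids=binned.channel_ids[keep],
        normalization_state="raw_counts",
        session_rate_hz=(binned.session_rate_hz[keep]
                         if binned.session_rate_hz is not None else None),
        rate_source=binned.rate_source)
    return out


def normalize_activity(binned: BinnedActivity,
                       smooth_sd: Optional[float] = None) -> BinnedActivity:
    """Rate-normalize (spiking), sqrt, optionally smooth, demean, z-score.

    ``smooth_sd`` is the Gaussian kernel SD in ms and is applied between
    the square-root transform and demeaning (40 ms for the PCA/decoding
    path; None for the latent-model path).  Demeaning subtracts the
    per-channel scalar mean over all trial bins — not the per-bin PSTH, so
    trial-averaged structure survives.  Channels with zero variance are
    dropped with a warning.
    """
    state = binned.normalization_state
    if state not in ("raw_counts", "raw_sbp"):
        raise ValueError(f"normalize_activity expects raw input, got {state!r}")
    vals = binned.values
    if np.any(vals < 0):
        raise ValueError("counts/power must be nonnegative")

    if state == "raw_counts":
        if binned.session_rate_hz is not None:
            mean_per_bin = binned.session_rate_hz * binned.bin_width / 1000.0
        else:
            mean_per_bin = vals.mean(axis=(0, 1))
        mean_per_bin = np.where(mean_per_bin > 0, mean_per_bin, 1.0)
        vals = vals / mean_per_bin

    vals = np.sqrt(vals)

    if smooth_sd is not None:
        sigma_bins = smooth_sd / binned.bin_width
        vals = gaussian_filter1d(vals, sigma_bins, axis=1, mode="nearest")

    mean = vals.mean(axis=(0, 1))
    sd = vals.std(axis=(0, 1))
    keep = sd > 0
    if not np.all(keep):
        warnings.warn(f"dropping {np.sum(~keep)} zero-variance channel(s)")
    if not np.any(keep):
        raise EmptySelectionError("all channels have zero variance")
    vals = (vals[:, :, keep] - mean[keep]) / sd[keep]

    return BinnedActivity(
        values=vals, bin_width=binned.bin_width, time_axis=binned.time_axis,
        area_label=binned.area_label, channel_ids=binned.channel_ids[keep],
        normalization_state="zscored",
        session_rate_hz=(binned.session_rate_hz[keep]
                         if binned.session_rate_hz is not None else None),
        rate_source=binned.rate_source, smoothed_sd=smooth_sd)


# --------------------------------------------------------------------------
# spiking-band power

def compute_low_sbp(voltage: np.ndarray, trial_table: TrialTable,
                    fs: float = SBP_SAMPLING_HZ, t0: float = 0.0,
                    band: Tuple[float, float] = (300.0, 500.0),
                    bin_width: float = 20.0, window_width: float = 20.0,
                    window: Tuple[float, float] = (-1000.0, 1000.0),
                    highpass_hz: float = 240.0,
                    nw: float = 2.0, n_tapers: int = 3,
                    area_label: str = "A") -> SBPTrace:
    """Trial-aligned spiking-band power from broadband voltage.

    ``voltage`` is samples x channels starting at session time ``t0``.
    Channels are grouped into banks of 16 for median subtraction; a
    trailing remainder bank is allowed (logged).  A sampling-rate mismatch
    beyond 1% of the nominal 1017.25 Hz is an input error.
    """
    if abs(fs - SBP_SAMPLING_HZ) / SBP_SAMPLING_HZ > 0.01:
        raise ValueError(f"sampling rate {fs} Hz deviates >1% from nominal "
                         f"{SBP_SAMPLING_HZ} Hz")
    if band[0] >= band[1]:
        raise ValueError("band_low must be < band_high")
    voltage = np.asarray(voltage, dtype=float)
    nsamp, q = voltage.shape
    if q % BANK_SIZE:
        warnings.warn(f"channel count {q} not a multiple of {BANK_SIZE}; "
                      "last bank is the remainder")

    sos = signal.butter(5, highpass_hz, btype="highpass", fs=fs, output="sos")
    filt = signal.sosfiltfilt(sos, voltage, axis=0)
    for start in range(0, q, BANK_SIZE):
        bank = slice(start, min(start + BANK_SIZE, q))
        filt[:, bank] -= np.median(filt[:, bank], axis=1, keepdims=True)
    sd = filt.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    filt = (filt - filt.mean(axis=0)) / sd

    nperseg = int(round(window_width / 1000.0 * fs))
    tapers = signal.windows.dpss(nperseg, nw, Kmax=n_tapers)
    freqs = np.fft.rfftfreq(nperseg, d=1.0 / fs)
    in_band = (freqs >= band[0]) & (freqs <= band[1])
    if not np.any(in_band):
        raise ValueError("no spectrogram frequency falls inside the band")

    w0, w1 = window
    n_bins = int(round((w1 - w0) / bin_width))
    hop = bin_width / 1000.0

    touch = trial_table.touch
    keep = np.isfinite(touch)
    touch = touch[keep]
    values = np.full((touch.size, n_bins, q), np.nan)
    for i, tt in enumerate(touch):
        for b in range(n_bins):
            t_start = tt + w0 / 1000.0 + b * hop
            s0 = int(round((t_start - t0) * fs))
            s1 = s0 + nperseg
            if s0 < 0 or s1 > nsamp:
                continue
            seg = filt[s0:s1, :]                       # nperseg x q
            spec = np.fft.rfft(tapers[:, :, None] * seg[None, :, :], axis=1)
            power = np.mean(np.abs(spec) ** 2, axis=0) / fs
            values[i, b, :] = power[in_band].mean(axis=0)

    time_axis = w0 + (np.arange(n_bins) + 0.5) * bin_width
    return SBPTrace(values=values, band=tuple(band), bin_width=bin_width,
                    window_width=window_width, time_axis=time_axis,
                    channel_ids=np.arange(q),
                    freqs_averaged=freqs[in_band])
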