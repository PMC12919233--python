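"""Synthetic two-area reach-to-grasp sessions with known latent ground truth.

Emulates simultaneous recordings from a premotor-like area ("A") and a
somatosensory-like area ("B") during a pellet-retrieval task: shared
cross-area latent factors (CFs) with per-factor GP timescales and an
inter-area delay, within-area factors (WFs) local to each area, Poisson
spiking observations (and optionally a broadband voltage trace for the
spiking-band-power path), trial event tables, and video-rate kinematics
(wrist speed, hand aperture) read out linearly from the CF latents.

Every stochastic step is driven by a single seed; fixed seed implies
bit-identical sessions.  A multi-session "recovery" series lengthens CF
timescales, shrinks CF trial-to-trial jitter, and shortens trial durations
across sessions, emulating the re-emergence of slow, stereotyped cross-area
dynamics as task performance recovers.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import signal

from .containers import (
    KinematicTrace, SessionRecord, TrialTable, WELL_DIAMETERS_MM,
)
from .kernels import se_gram

__all__ = [
    "GroundTruthLatentSpec", "EventSchedule", "KinematicReadout",
    "SyntheticSessionConfig", "GroundTruthLatents", "SyntheticSession",
    "default_latent_specs", "draw_latents", "generate_session",
    "generate_recovery_series",
]

VIDEO_FPS = 50.0
VOLTAGE_FS = 1017.25  # Hz, broadband acquisition rate for the SBP path


# --------------------------------------------------------------------------
# configuration types

@dataclass(frozen=True)
class GroundTruthLatentSpec:
    """Kernel parameters of one ground-truth latent.

    kind: 'CF' (shared, delayed between areas), 'WF_A' or 'WF_B' (local).
    delay is ms and present iff kind == 'CF'; positive delay means area B
    follows area A.
    """

    kind: str
    timescale_tau: float                  # ms
    delay: Optional[float] = None         # ms, CF only
    kernel_noise_floor: float = 1e-3
    amplitude: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in ("CF", "WF_A", "WF_B"):
            raise ValueError(f"unknown latent kind {self.kind!r}")
        if not self.timescale_tau > 0:
            raise ValueError("timescale_tau must be positive")
        if not 0.0 < self.kernel_noise_floor < 1.0:
            raise ValueError("kernel_noise_floor must be in (0, 1)")
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if (self.kind == "CF") != (self.delay is not None):
            raise ValueError("delay must be present iff kind == 'CF'")


def default_latent_specs() -> List[GroundTruthLatentSpec]:
    """5 CFs + 5 WFs per area with the study's timescale/delay structure.

    CF timescales span 60-200 ms with a +30 ms area-B lag; within-area
    timescales are slower in the premotor-like area (120 ms) than in the
    somatosensory-like area (40 ms).
    """
    cfs = [GroundTruthLatentSpec("CF", tau, delay=30.0)
           for tau in (60.0, 100.0, 140.0, 180.0, 200.0)]
    wfa = [GroundTruthLatentSpec("WF_A", 120.0) for _ in range(5)]
    wfb = [GroundTruthLatentSpec("WF_B", 40.0) for _ in range(5)]
    return cfs + wfa + wfb


@dataclass(frozen=True)
class EventSchedule:
    """Nominal trial event offsets (ms relative to pellet touch).

    ``duration_scale`` multiplies both nominal epoch durations — the handle
    the recovery series uses to emulate slow (impaired) vs fast (recovered)
    trials.  Per-trial noise is uniform on +/- ``event_jitter_ms``.
    """

    reach_offset_ms: float = -450.0
    retract_offset_ms: float = 300.0
    duration_scale: float = 1.0
    event_jitter_ms: float = 40.0
    trial_spacing_s: float = 5.0

    def __post_init__(self) -> None:
        if not self.reach_offset_ms < 0 < self.retract_offset_ms:
            raise ValueError("need reach before touch (0) before retract")
        if self.duration_scale <= 0:
            raise ValueError("duration_scale must be positive")


@dataclass(frozen=True)
class KinematicReadout:
    """Linear mapping from CF latents to wrist speed and hand aperture.

    Weights index CF latents only (length = number of CFs); referencing
    within-area latents is a config error by construction.  ``snr`` is the
    amplitude (SD) ratio of the latent-driven component to additive noise.
    """

    speed_weights: Tuple[float, ...] = (1.0, 0.6, 0.3, 0.0, 0.0)
    aperture_weights: Tuple[float, ...] = (0.0, 0.0, 0.3, 0.6, 1.0)
    snr: float = 3.0
    speed_base: float = 6.0       # px/frame
    speed_sd: float = 2.0         # px/frame, SD of the latent-driven part
    aperture_base: float = 40.0   # px
    aperture_sd: float = 8.0      # px


@dataclass(frozen=True)
class SyntheticSessionConfig:
    n_trials: int = 80
    n_channels_A: int = 40
    n_channels_B: int = 40
    bin_width: float = 20.0                      # ms
    trial_window: Tuple[float, float] = (-1000.0, 1000.0)  # ms around touch
    latent_specs: Tuple[GroundTruthLatentSpec, ...] = field(
        default_factory=lambda: tuple(default_latent_specs()))
    loading_scale: float = 0.5
    observation_noise_sd: float = 0.2
    spike_rate_base: float = 20.0                # Hz
    trial_jitter_sd: float = 0.5                 # in (0, 1]: latent share not locked to the session template
    cf_trial_jitter_sd: Optional[float] = None   # override for CF latents only
    event_schedule: EventSchedule = field(default_factory=EventSchedule)
    kinematic_readout: KinematicReadout = field(default_factory=KinematicReadout)
    include_voltage: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        w0, w1 = self.trial_window
        span = w1 - w0
        nbins = span / self.bin_width
        if abs(nbins - round(nbins)) > 1e-9:
            raise ValueError("bin_width must divide the trial window length")
        sched = self.event_schedule
        if (sched.duration_scale * sched.reach_offset_ms - sched.event_jitter_ms < w0
                or sched.duration_scale * sched.retract_offset_ms + sched.event_jitter_ms > w1):
            raise ValueError("trial window must contain all scheduled events")
        ncf = sum(s.kind == "CF" for s in self.latent_specs)
        ro = self.kinematic_readout
        if len(ro.speed_weights) != ncf or len(ro.aperture_weights) != ncf:
            raise ValueError(
                "kinematic readout weights must index the CF latents "
                f"(expected length {ncf})")
        for s in self.latent_specs:
            if s.kind == "CF" and abs(s.delay) >= span / 2:
                raise ValueError("CF delay magnitude must be < half the trial window")

    @property
    def n_bins(self) -> int:
        return int(round((self.trial_window[1] - self.trial_window[0]) / self.bin_width))

    @property
    def bin_centers(self) -> np.ndarray:
        """Bin-center times, ms relative to touch."""
        w0 = self.trial_window[0]
        return w0 + (np.arange(self.n_bins) + 0.5) * self.bin_width


# --------------------------------------------------------------------------
# ground-truth latents

@dataclass
class GroundTruthLatents:
    """Per-trial latent trajectories, split by factor kind and area view."""

    cf_A: np.ndarray      # trials x bins x nCF (area-A view)
    cf_B: np.ndarray      # trials x bins x nCF (area-B view, delayed)
    wf_A: np.ndarray      # trials x bins x nWF_A
    wf_B: np.ndarray      # trials x bins x nWF_B
    bin_grid: np.ndarray  # ms relative to touch
    specs: Tuple[GroundTruthLatentSpec, ...] = ()

    @property
    def area_A(self) -> np.ndarray:
        """Latents observed by area A: [CF_A view, WF_A]."""
        return np.concatenate([self.cf_A, self.wf_A], axis=2)

    @property
    def area_B(self) -> np.ndarray:
        return np.concatenate([self.cf_B, self.wf_B], axis=2)


def draw_latents(specs: Sequence[GroundTruthLatentSpec], n_trials: int,
                 bin_grid: np.ndarray, seed: int,
                 trial_jitter_sd: float = 0.0,
                 cf_trial_jitter_sd: Optional[float] = None) -> GroundTruthLatents:
    """Draw per-trial latent trajectories for both areas.

    Each latent is a unit-variance GP with the squared-exponential +
    noise-floor kernel.  A per-latent session "template" trace ``m`` is
    drawn once and each trial mixes it with an independent draw:

        x_i = sqrt(1 - j^2) * m + j * eps_i

    so the marginal variance stays 1 while ``j`` (the trial jitter) sets
    how much of the trajectory varies trial to trial.  CF latents are a
    single GP evaluated at ``t`` for the area-A view and ``t - delay`` for
    the area-B view (both views drawn jointly from one Gram on the union
    grid, so on-grid delays make area B an exact shifted copy of area A).
    """
    bin_grid = np.asarray(bin_grid, dtype=float)
    if bin_grid.size > 1:
        steps = np.diff(bin_grid)
        if not np.allclose(steps, steps[0], rtol=0, atol=1e-9):
            raise ValueError("bin_grid must be uniform")
    rng = np.random.default_rng(seed)
    T = bin_grid.size
    out = {"CF": ([], []), "WF_A": ([], None), "WF_B": ([], None)}
    for spec in specs:
        j = cf_trial_jitter_sd if (spec.kind == "CF" and cf_trial_jitter_sd
                                   is not None) else trial_jitter_sd
        j = float(np.clip(j, 0.0, 1.0))
        if spec.kind == "CF":
            shifted = np.round(bin_grid - spec.delay, 9)
            union = np.unique(np.concatenate([np.round(bin_grid, 9), shifted]))
            gram = se_gram(union, spec.timescale_tau, spec.kernel_noise_floor,
                           max(spec.amplitude, 1e-12))
            L = np.linalg.cholesky(gram + 1e-10 * np.eye(union.size))
            idx_a = np.searchsorted(union, np.round(bin_grid, 9))
            idx_b = np.searchsorted(union, shifted)
            draws = _template_trial_draws(L, n_trials, j, rng)
            if spec.amplitude == 0.0:
                draws = np.zeros_like(draws)
            out["CF"][0].append(draws[:, idx_a])
            out["CF"][1].append(draws[:, idx_b])
        else:
            gram = se_gram(bin_grid, spec.timescale_tau,
                           spec.kernel_noise_floor, max(spec.amplitude, 1e-12))
            L = np.linalg.cholesky(gram + 1e-10 * np.eye(T))
            draws = _template_trial_draws(L, n_trials, j, rng)
            if spec.amplitude == 0.0:
                draws = np.zeros_like(draws)
            out[spec.kind][0].append(draws)

    def stack(lst):
        if not lst:
            return np.zeros((n_trials, T, 0))
        return np.stack(lst, axis=2)

    return GroundTruthLatents(
        cf_A=stack(out["CF"][0]), cf_B=stack(out["CF"][1]),
        wf_A=stack(out["WF_A"][0]), wf_B=stack(out["WF_B"][0]),
        bin_grid=bin_grid, specs=tuple(specs),
    )


def _template_trial_draws(L: np.ndarray, n_trials: int, jitter: float,
                          rng: np.random.Generator) -> np.ndarray:
    """Session template + per-trial deviations; returns trials x grid."""
    m = L @ rng.standard_normal(L.shape[0])
    eps = rng.standard_normal((n_trials, L.shape[0])) @ L.T
    return np.sqrt(max(0.0, 1.0 - jitter**2)) * m[None, :] + jitter * eps


# --------------------------------------------------------------------------
# full session

@dataclass
class SyntheticSession:
    config: SyntheticSessionConfig
    trial_table: TrialTable
    spike_times: Dict[str, List[np.ndarray]]      # area -> per-channel arrays (s)
    kinematics: KinematicTrace
    ground_truth: "GroundTruth"
    voltage: Optional[Dict[str, np.ndarray]] = None  # area -> samples x channels
    voltage_t0: float = 0.0
    voltage_fs: float = VOLTAGE_FS


@dataclass
class GroundTruth:
    latents: GroundTruthLatents
    loadings_A: np.ndarray     # channels_A x (nCF + nWF_A)
    loadings_B: np.ndarray
    specs: Tuple[GroundTruthLatentSpec, ...]
    clean_speed: np.ndarray    # px/frame on the video frame grid
    clean_aperture: np.ndarray


def generate_session(config: SyntheticSessionConfig) -> SyntheticSession:
    """Generate one synthetic two-area session from a known latent model."""
    ss = np.random.SeedSequence(config.seed)
    (s_lat, s_load, s_events, s_spk_a, s_spk_b, s_kin, s_volt) = ss.spawn(7)

    table = _make_trial_table(config, np.random.default_rng(s_events))
    latents = draw_latents(
        config.latent_specs, config.n_trials, config.bin_centers,
        seed=s_lat, trial_jitter_sd=config.trial_jitter_sd,
        cf_trial_jitter_sd=config.cf_trial_jitter_sd)

    rng_load = np.random.default_rng(s_load)
    x_A, x_B = latents.area_A, latents.area_B
    C_A = _draw_loadings(rng_load, config.n_channels_A, x_A.shape[2],
                         config.loading_scale)
    C_B = _draw_loadings(rng_load, config.n_channels_B, x_B.shape[2],
                         config.loading_scale)

    act_A = x_A @ C_A.T
    act_B = x_B @ C_B.T
    if config.observation_noise_sd > 0:
        act_A = act_A + np.random.default_rng(s_spk_a).normal(
            0.0, config.observation_noise_sd, act_A.shape)
        act_B = act_B + np.random.default_rng(s_spk_b).normal(
            0.0, config.observation_noise_sd, act_B.shape)

    spikes = {
        "A": _activity_to_spikes(act_A, table, config,
                                 np.random.default_rng(s_spk_a.spawn(1)[0])),
        "B": _activity_to_spikes(act_B, table, config,
                                 np.random.default_rng(s_spk_b.spawn(1)[0])),
    }

    kin, clean_speed, clean_aperture = _make_kinematics(
        config, table, latents, np.random.default_rng(s_kin))

    voltage = None
    if config.include_voltage:
        voltage = {
            "A": _activity_to_voltage(act_A, table, config,
                                      np.random.default_rng(s_volt)),
            "B": _activity_to_voltage(act_B, table, config,
                                      np.random.default_rng(s_volt.spawn(1)[0])),
        }

    gt = GroundTruth(latents=latents, loadings_A=C_A, loadings_B=C_B,
                     specs=tuple(config.latent_specs),
                     clean_speed=clean_speed, clean_aperture=clean_aperture)
    return SyntheticSession(config=config, trial_table=table,
                            spike_times=spikes, kinematics=kin,
                            ground_truth=gt, voltage=voltage)


def _draw_loadings(rng, n_channels, n_latents, scale) -> np.ndarray:
    if n_latents == 0:
        return np.zeros((n_channels, 0))
    return scale * rng.standard_normal((n_channels, n_latents)) / np.sqrt(n_latents)


def _make_trial_table(config: SyntheticSessionConfig,
                      rng: np.random.Generator) -> TrialTable:
    n = config.n_trials
    sched = config.event_schedule
    touch = sched.trial_spacing_s * (np.arange(n) + 1.0)
    jit = sched.event_jitter_ms
    reach = touch + (sched.duration_scale * sched.reach_offset_ms
                     + rng.uniform(-jit, jit, n)) / 1000.0
    retract = touch + (sched.duration_scale * sched.retract_offset_ms
                       + rng.uniform(-jit, jit, n)) / 1000.0
    df = pd.DataFrame({
        "reach_onset": reach, "touch": touch, "retract": retract,
        "max_aperture_time": np.nan,
        "well_diameter": rng.choice(WELL_DIAMETERS_MM, n),
        "success": True, "attempted": True, "grasp_attempts": 1,
    })
    return TrialTable(df)


def _activity_to_spikes(activity: np.ndarray, table: TrialTable,
                        config: SyntheticSessionConfig,
                        rng: np.random.Generator) -> List[np.ndarray]:
    """Rectified-Gaussian rate -> Poisson counts -> uniform spike times."""
    n, T, q = activity.shape
    bw_s = config.bin_width / 1000.0
    rate = config.spike_rate_base * np.clip(1.0 + activity, 0.0, None)
    counts = rng.poisson(rate * bw_s)          # trials x bins x channels
    bin_starts = (table.touch[:, None]
                  + (config.trial_window[0] + np.arange(T) * config.bin_width)
                  / 1000.0)                    # trials x bins, s
    out = []
    for c in range(q):
        k = counts[:, :, c]
        starts = np.repeat(bin_starts.ravel(), k.ravel())
        times = starts + rng.uniform(0.0, bw_s, starts.size)
        out.append(np.sort(times))
    return out


def _make_kinematics(config, table, latents, rng):
    ro = config.kinematic_readout
    end = table.touch[-1] + config.trial_window[1] / 1000.0 + 1.0
    frame_times = np.arange(0.0, end, 1.0 / VIDEO_FPS)
    F = frame_times.size
    ncf = latents.cf_A.shape[2]

    def readout(weights, base, sd):
        w = np.asarray(weights, dtype=float)
        clean = np.zeros(F)
        if ncf and np.any(w != 0):
            scale = sd / np.sqrt(np.sum(w**2))
            for i in range(len(table)):
                proj = latents.cf_A[i] @ (w * scale)    # bins
                t_abs = table.touch[i] + latents.bin_grid / 1000.0
                in_win = (frame_times >= t_abs[0]) & (frame_times <= t_abs[-1])
                clean[in_win] = np.interp(frame_times[in_win], t_abs, proj)
        noisy = base + clean + rng.normal(0.0, sd / ro.snr, F)
        return clean + base, noisy

    clean_speed, speed = readout(ro.speed_weights, ro.speed_base, ro.speed_sd)
    speed = np.clip(speed, 0.0, None)
    clean_aperture, aperture = readout(ro.aperture_weights, ro.aperture_base,
                                       ro.aperture_sd)
    aperture = np.clip(aperture, 1.0, None)

    # wrist path whose frame-to-frame displacement equals the speed series
    heading = 2.0 * np.pi * 0.05 * frame_times
    steps = np.zeros((F, 2))
    steps[1:, 0] = speed[1:] * np.cos(heading[1:])
    steps[1:, 1] = speed[1:] * np.sin(heading[1:])
    path = np.cumsum(steps, axis=0)
    offsets = np.array([[0.0, 0.0], [3.0, 1.0], [-2.0, 2.0]])
    wrist_points = path[:, None, :] + offsets[None, :, :]

    # digits: thumb mean at a fixed hand-frame point, index offset by aperture
    thumb = path + np.array([12.0, 6.0])
    digit_points = np.empty((F, 4, 2))
    digit_points[:, 0] = thumb + np.array([0.5, 0.0])
    digit_points[:, 1] = thumb - np.array([0.5, 0.0])
    index = thumb + np.column_stack([aperture, np.zeros(F)])
    digit_points[:, 2] = index + np.array([0.5, 0.0])
    digit_points[:, 3] = index - np.array([0.5, 0.0])

    kin = KinematicTrace(frame_times=frame_times, wrist_points=wrist_points,
                         digit_points=digit_points)
    return kin, clean_speed, clean_aperture


def _activity_to_voltage(activity: np.ndarray, table: TrialTable,
                         config: SyntheticSessionConfig,
                         rng: np.random.Generator) -> np.ndarray:
    """Broadband noise + 300-500 Hz carrier amplitude-modulated by activity.

    Returns samples x channels covering the whole session at 1017.25 Hz.
    Spiking-band power computed on this trace inherits a known (monotone)
    relation to the loading-weighted latent activity.
    """
    n, T, q = activity.shape
    fs = VOLTAGE_FS
    dur = table.touch[-1] + config.trial_window[1] / 1000.0 + 0.5
    nsamp = int(np.ceil(dur * fs))
    t = np.arange(nsamp) / fs
    sos = signal.butter(4, [300.0, 400.0], btype="bandpass", fs=fs, output="sos")
    volt = 0.25 * rng.standard_normal((nsamp, q))
    # envelope: 1 + rectified activity, interpolated from trial bins
    bin_t = (table.touch[:, None] + (config.bin_centers / 1000.0)[None, :]).ravel()
    order = np.argsort(bin_t)
    for c in range(q):
        carrier = signal.sosfilt(sos, rng.standard_normal(nsamp))
        carrier /= max(carrier.std(), 1e-12)
        env_bins = np.clip(1.0 + activity[:, :, c].ravel()[order], 0.0, None)
        env = np.interp(t, bin_t[order], env_bins, left=1.0, right=1.0)
        volt[:, c] += carrier * env
    return volt


# --------------------------------------------------------------------------
# recovery series

Schedule = Union[Callable[[int], float], Sequence[float]]


def _schedule_values(sched: Schedule, n: int, name: str) -> np.ndarray:
    if callable(sched):
        vals = np.array([float(sched(s)) for s in range(n)])
    else:
        vals = np.asarray(sched, dtype=float)
        if vals.size != n:
            raise ValueError(f"{name} must have one value per session")
    d = np.diff(vals)
    if not (np.all(d >= -1e-12) or np.all(d <= 1e-12)):
        raise ValueError(f"{name} schedule must be monotone")
    return vals


def generate_recovery_series(base: SyntheticSessionConfig, n_sessions: int,
                             tau_ramp: Schedule, jitter_ramp: Schedule,
                             duration_ramp: Schedule, seed: int,
                             animal_id: str = "synth",
                             ) -> List[Tuple[SyntheticSession, SessionRecord]]:
    """Generate a series of sessions emulating post-lesion recovery.

    Session ``s`` gets every CF timescale set to ``tau_ramp(s)``, CF trial
    jitter ``jitter_ramp(s)``, and nominal trial durations scaled by
    ``duration_ramp(s)`` (1.0 = pre-lesion baseline).  Within-area latents
    are untouched, so any recovery trend in WF statistics is spurious by
    construction.  Per-session seeds derive deterministically from
    ``seed`` and the session index.
    """
    if n_sessions < 2:
        raise ValueError("need at least 2 sessions")
    taus = _schedule_values(tau_ramp, n_sessions, "tau_ramp")
    jits = _schedule_values(jitter_ramp, n_sessions, "jitter_ramp")
    durs = _schedule_values(duration_ramp, n_sessions, "duration_ramp")

    out = []
    for s in range(n_sessions):
        specs = tuple(
            dataclasses.replace(sp, timescale_tau=float(taus[s]))
            if sp.kind == "CF" else sp
            for sp in base.latent_specs)
        sched = dataclasses.replace(base.event_schedule,
                                    duration_scale=float(durs[s]))
        sess_seed = int(np.random.SeedSequence([seed, s]).generate_state(1)[0]
                        % (2**31))
        cfg = dataclasses.replace(
            base, latent_specs=specs, cf_trial_jitter_sd=float(jits[s]),
            event_schedule=sched, seed=sess_seed)
        session = generate_session(cfg)
        record = SessionRecord(
            animal_id=animal_id, day_post_lesion=s + 1,
            normalized_r2g_duration=float(durs[s]),
            n_rewarded=int(session.trial_table.success.sum()))
        out.append((session, record))
    return out
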