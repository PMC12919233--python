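"""Delayed two-area Gaussian-process factor model, fit by EM.

Observation model, per area and time bin::

    y_A(t) = C_A [x_cf^A(t); x_wf^A(t)] + d_A + eps_A,   eps_A ~ N(0, diag R_A)
    y_B(t) = C_B [x_cf^B(t); x_wf^B(t)] + d_B + eps_B

Each latent is a unit-variance GP with a squared-exponential kernel of
per-factor timescale tau; a cross-area factor (CF) is one GP whose area-B
view runs on a time axis shifted by a per-factor delay D (positive D:
area B follows area A).  Within-area factors (WFs) exist in one area only.
Unit latent variance fixes the scale indeterminacy; loadings carry
amplitude.

The E-step computes the exact joint-Gaussian posterior over all latents of
a trial in precision form: with K the (block-diagonal by factor) prior Gram
over the extended latent vector and G = C~' R~^-1 C~ the per-bin
information, the posterior covariance is (K^-1 + I_T (x) G)^-1, shared
across trials of equal length.  The M-step updates loadings, offsets and
noise in closed form, and tau / delay by bounded quasi-Newton (L-BFGS-B)
on the expected complete-data log-likelihood, in log(tau) / scaled-delay
coordinates.  The marginal log-likelihood is recorded each iteration and
is non-decreasing up to numerical tolerance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
from scipy import linalg as sla
from scipy import optimize

from .containers import BinnedActivity
from .kernels import delayed_pair_gram, se_gram

__all__ = [
    "FittedLatentSpec", "DLAGModel", "LatentTrajectories", "VarianceReport",
    "fit_dlag", "infer_latents", "variance_accounted",
]

TAU_BOUNDS_MS = (10.0, 1000.0)
DELAY_BOUNDS_MS = (-250.0, 250.0)
NOISE_FLOOR = 1e-3
_DELAY_SCALE = 100.0   # optimizer works on delay / _DELAY_SCALE


@dataclass(frozen=True)
class FittedLatentSpec:
    """Fitted kernel parameters of one latent factor."""

    kind: str                       # 'CF' | 'WF_A' | 'WF_B'
    tau: float                      # ms
    delay: Optional[float] = None   # ms, CF only
    noise_floor: float = NOISE_FLOOR


@dataclass
class DLAGModel:
    """Fitted two-area factor model.

    Loadings columns are ordered [CFs..., WFs...] within each area;
    ``latent_specs`` lists CFs, then WF_A, then WF_B.
    """

    loadings_A: np.ndarray          # channels_A x (nCF + nWF_A)
    loadings_B: np.ndarray          # channels_B x (nCF + nWF_B)
    offset_A: np.ndarray
    offset_B: np.ndarray
    noise_A: np.ndarray             # per-channel noise variances
    noise_B: np.ndarray
    latent_specs: List[FittedLatentSpec]
    dims: Tuple[int, int, int]      # (nCF, nWF_A, nWF_B)
    bin_width: float                # ms
    fit_log: List[float] = field(default_factory=list)
    converged: bool = False

    @property
    def taus(self) -> np.ndarray:
        return np.array([s.tau for s in self.latent_specs])

    @property
    def delays(self) -> np.ndarray:
        return np.array([s.delay for s in self.latent_specs if s.kind == "CF"])

    def taus_by_group(self) -> dict:
        nC, nA, nB = self.dims
        t = self.taus
        return {"CF": t[:nC], "WF_A": t[nC:nC + nA], "WF_B": t[nC + nA:]}


@dataclass
class LatentTrajectories:
    """Posterior latent time courses, split by factor kind and area view."""

    cf_A: np.ndarray        # trials x bins x nCF
    cf_B: np.ndarray        # trials x bins x nCF (delay-shifted view)
    wf_A: np.ndarray
    wf_B: np.ndarray
    time_axis: np.ndarray   # ms relative to touch
    posterior_var: np.ndarray       # bins x p_ext marginal posterior variances
    posterior_cov: Optional[np.ndarray] = None  # full (T*p_ext)^2, on request

    @property
    def n_trials(self) -> int:
        return self.cf_A.shape[0]


@dataclass
class VarianceReport:
    """Percent variance accounted for per area by each factor group.

    ``residual`` is the remainder (noise plus cross-terms), so per area
    CF + WF + residual = 100 exactly.
    """

    vaf: dict            # {'A': {'CF': %, 'WF': %, 'residual': %}, 'B': ...}


# ==========================================================================
# internal parameter state

class _Params:
    def __init__(self, C_A, C_B, d_A, d_B, R_A, R_B, taus, delays, dims,
                 noise_floor=NOISE_FLOOR):
        self.C_A, self.C_B = C_A, C_B
        self.d_A, self.d_B = d_A, d_B
        self.R_A, self.R_B = R_A, R_B
        self.taus = np.asarray(taus, dtype=float)     # length nC+nA+nB
        self.delays = np.asarray(delays, dtype=float)  # length nC
        self.dims = dims
        self.noise_floor = noise_floor

    @property
    def p_ext(self):
        nC, nA, nB = self.dims
        return 2 * nC + nA + nB

    def ext_idx_A(self):
        nC, nA, nB = self.dims
        return np.r_[np.arange(nC), 2 * nC + np.arange(nA)]

    def ext_idx_B(self):
        nC, nA, nB = self.dims
        return np.r_[nC + np.arange(nC), 2 * nC + nA + np.arange(nB)]

    def c_big(self):
        nC, nA, nB = self.dims
        qA, qB = self.C_A.shape[0], self.C_B.shape[0]
        C = np.zeros((qA + qB, self.p_ext))
        C[:qA, self.ext_idx_A()] = self.C_A
        C[qA:, self.ext_idx_B()] = self.C_B
        return C

    def latent_blocks(self):
        """Yield (extended-index tuple, kernel Gram builder) per factor."""
        nC, nA, nB = self.dims
        blocks = []
        for j in range(nC):
            blocks.append(((j, nC + j), "CF", j))
        for a in range(nA):
            blocks.append(((2 * nC + a,), "WF", nC + a))
        for b in range(nB):
            blocks.append(((2 * nC + nA + b,), "WF", nC + nA + b))
        return blocks

    def gram(self, kind, lat, times):
        if kind == "CF":
            return delayed_pair_gram(times, self.taus[lat], self.delays[lat],
                                     self.noise_floor)
        return se_gram(times, self.taus[lat], self.noise_floor)


# ==========================================================================
# E-step

def _posterior(par: _Params, Y: np.ndarray, times: np.ndarray,
               need_cov: bool = True):
    """Exact joint posterior over the extended latents of each trial.

    Y: trials x T x q (areas concatenated).  Returns a dict with the
    shared posterior covariance (time-major, (T*p)^2), per-trial posterior
    means, and the total marginal log-likelihood.
    """
    n, T, q = Y.shape
    p = par.p_ext
    M = T * p
    R = np.concatenate([par.R_A, par.R_B])
    d = np.concatenate([par.d_A, par.d_B])
    C = par.c_big()

    # prior precision, block-diagonal by factor, scattered time-major
    Kinv_tm = np.zeros((M, M))
    logdet_K = 0.0
    for exts, kind, lat in par.latent_blocks():
        K = par.gram(kind, lat, times)
        cf = sla.cho_factor(K, lower=True)
        logdet_K += 2.0 * np.sum(np.log(np.diag(cf[0])))
        Kinv = sla.cho_solve(cf, np.eye(K.shape[0]))
        for vi, ei in enumerate(exts):
            for vj, ej in enumerate(exts):
                Kinv_tm[ei::p, ej::p] = Kinv[vi * T:(vi + 1) * T,
                                             vj * T:(vj + 1) * T]

    G = (C.T / R) @ C
    P = Kinv_tm
    Pr = P.reshape(T, p, T, p)
    idx = np.arange(T)
    Pr[idx, :, idx, :] += G

    cf_P = sla.cho_factor(P, lower=True)
    logdet_P = 2.0 * np.sum(np.log(np.diag(cf_P[0])))

    resid = Y - d                      # n x T x q
    W = resid / R
    H = (W @ C).reshape(n, M)          # information vectors
    Mu = sla.cho_solve(cf_P, H.T).T    # n x M posterior means

    quad = np.einsum("ntq,ntq->n", resid, W) - np.einsum("nm,nm->n", H, Mu)
    ll = -0.5 * (n * (T * q * np.log(2.0 * np.pi) + T * np.sum(np.log(R))
                      + logdet_K + logdet_P) + quad.sum())
    if not np.isfinite(ll):
        raise FloatingPointError(
            "non-finite marginal log-likelihood; noise variances: "
            f"min {R.min():.3g}, max {R.max():.3g}")

    Sigma = None
    if need_cov:
        Linv, info = sla.lapack.dpotri(cf_P[0], lower=True)
        if info != 0:
            raise FloatingPointError("posterior covariance inversion failed")
        Sigma = np.tril(Linv) + np.tril(Linv, -1).T

    return {"Sigma": Sigma, "Mu": Mu, "ll": float(ll), "C": C, "R": R, "d": d}


# ==========================================================================
# initialization

def _init_params(Y_A, Y_B, dims, noise_floor, tau_init=100.0):
    """Deterministic init: cross-covariance SVD for CF loadings, residual
    eigenvectors for WF loadings, marginal residuals for noise."""
    nC, nA, nB = dims
    n, T, qA = Y_A.shape
    qB = Y_B.shape[2]
    Ya = Y_A.reshape(-1, qA)
    Yb = Y_B.reshape(-1, qB)
    d_A, d_B = Ya.mean(0), Yb.mean(0)
    Za, Zb = Ya - d_A, Yb - d_B
    N = Za.shape[0]

    C_A = np.zeros((qA, nC + nA))
    C_B = np.zeros((qB, nC + nB))
    if nC > 0:
        Sab = Za.T @ Zb / N
        U, s, Vt = np.linalg.svd(Sab, full_matrices=False)
        k = min(nC, s.size)
        C_A[:, :k] = U[:, :k] * np.sqrt(s[:k])
        C_B[:, :k] = Vt[:k].T * np.sqrt(s[:k])

    for (Z, C, nW, nCf) in ((Za, C_A, nA, nC), (Zb, C_B, nB, nC)):
        if nW == 0:
            continue
        cov = Z.T @ Z / N - C[:, :nCf] @ C[:, :nCf].T
        evals, evecs = np.linalg.eigh(cov)
        order = np.argsort(evals)[::-1][:nW]
        C[:, nCf:nCf + nW] = evecs[:, order] * np.sqrt(np.clip(evals[order], 1e-4, None))

    var_A = Za.var(0)
    var_B = Zb.var(0)
    R_A = np.clip(var_A - np.sum(C_A**2, axis=1), 0.05 * var_A, None)
    R_B = np.clip(var_B - np.sum(C_B**2, axis=1), 0.05 * var_B, None)

    taus = np.full(nC + nA + nB, float(tau_init))
    delays = np.zeros(nC)
    return _Params(C_A, C_B, d_A, d_B, R_A, R_B, taus, delays, dims,
                   noise_floor)


# ==========================================================================
# M-step

def _mstep_observation(par: _Params, post, Y_A, Y_B):
    n, T, qA = Y_A.shape
    qB = Y_B.shape[2]
    p = par.p_ext
    N = n * T
    Sigma, Mu = post["Sigma"], post["Mu"]
    Mu3 = Mu.reshape(n, T, p)

    Sig4 = Sigma.reshape(T, p, T, p)
    idx = np.arange(T)
    Sig_tt = Sig4[idx, :, idx, :].sum(axis=0)          # sum_t Sigma_tt
    SumXX = n * Sig_tt + np.einsum("ntp,ntq->pq", Mu3, Mu3)
    SumX = Mu3.sum(axis=(0, 1))

    for (Y, ext, area) in ((Y_A, par.ext_idx_A(), "A"),
                           (Y_B, par.ext_idx_B(), "B")):
        pa = ext.size
        Sxx = SumXX[np.ix_(ext, ext)]
        Sx = SumX[ext]
        M1 = np.empty((pa + 1, pa + 1))
        M1[:pa, :pa] = Sxx
        M1[:pa, pa] = Sx
        M1[pa, :pa] = Sx
        M1[pa, pa] = N
        Syx = np.einsum("ntq,ntp->qp", Y, Mu3[:, :, ext])
        Sy = Y.sum(axis=(0, 1))
        RHS = np.concatenate([Syx, Sy[:, None]], axis=1)   # q x (pa+1)
        Cd = np.linalg.solve(M1, RHS.T).T
        C_new, d_new = Cd[:, :pa], Cd[:, pa]
        Syy = np.einsum("ntq,ntq->q", Y, Y)
        var = Y.reshape(-1, Y.shape[2]).var(0)
        R_new = (Syy - np.einsum("qp,qp->q", Cd, RHS)) / N
        R_new = np.clip(R_new, 1e-4 * np.clip(var, 1e-12, None), None)
        if area == "A":
            par.C_A, par.d_A, par.R_A = C_new, d_new, R_new
        else:
            par.C_B, par.d_B, par.R_B = C_new, d_new, R_new


def _mstep_kernels(par: _Params, post, n_trials, times, maxiter=25):
    """Per-latent conditional maximization of the *marginal* likelihood
    over (tau, delay), ECME style.

    For latent j, the rest of the model acts as correlated observation
    noise; its information about z_j is W_j = Sigma_jj^-1 - K_j^-1 with
    Sigma_jj the latent's posterior covariance block under the current
    parameters and K_j its current prior Gram.  W_j and the posterior
    means are invariant to the candidate kernel, so the conditional
    log-likelihood of new kernel parameters is an O((mT)^3) computation:

        -2 ll(theta) = const + n [logdet K(theta) + logdet(K(theta)^-1 + W)]
                       - sum_i h_i' (K(theta)^-1 + W)^-1 h_i,

    with h_i = Sigma_jj^-1 mu_ij.  This learns delays orders of magnitude
    faster than the expected-complete-data (Q-function) update, which is
    heavily damped by the prior's view coupling.
    """
    p = par.p_ext
    T = times.size
    Sigma = post["Sigma"]
    Mu3 = post["Mu"].reshape(n_trials, T, p)
    log_tau_bounds = (np.log(TAU_BOUNDS_MS[0]), np.log(TAU_BOUNDS_MS[1]))
    dscale = _DELAY_SCALE
    d_bounds = (DELAY_BOUNDS_MS[0] / dscale, DELAY_BOUNDS_MS[1] / dscale)

    for exts, kind, lat in par.latent_blocks():
        m = len(exts)
        Sjj = np.empty((m * T, m * T))
        for vi, ei in enumerate(exts):
            for vj, ej in enumerate(exts):
                Sjj[vi * T:(vi + 1) * T, vj * T:(vj + 1) * T] = \
                    Sigma[ei::p, ej::p]
        Sjj = 0.5 * (Sjj + Sjj.T)
        try:
            B = np.linalg.inv(Sjj)
        except np.linalg.LinAlgError:
            continue
        Kold = par.gram(kind, lat, times)
        W = B - np.linalg.inv(Kold)
        W = 0.5 * (W + W.T)
        Muj = np.concatenate([Mu3[:, :, e] for e in exts], axis=1)
        Ht = Muj @ B                                  # n x mT information vecs

        def obj(z):
            tau = np.exp(z[0])
            if kind == "CF":
                K = delayed_pair_gram(times, tau, z[1] * dscale,
                                      par.noise_floor)
            else:
                K = se_gram(times, tau, par.noise_floor)
            try:
                cK = sla.cho_factor(K, lower=True)
            except np.linalg.LinAlgError:
                return np.inf
            ldK = 2.0 * np.sum(np.log(np.diag(cK[0])))
            Kinv = sla.cho_solve(cK, np.eye(K.shape[0]))
            Pj = Kinv + W
            try:
                cP = sla.cho_factor(0.5 * (Pj + Pj.T), lower=True)
            except np.linalg.LinAlgError:
                return np.inf
            ldP = 2.0 * np.sum(np.log(np.diag(cP[0])))
            quad = np.sum(Ht * sla.cho_solve(cP, Ht.T).T)
            val = n_trials * (ldK + ldP) - quad
            return val if np.isfinite(val) else np.inf

        if kind == "CF":
            x0 = np.array([np.log(par.taus[lat]), par.delays[lat] / dscale])
            bounds = [log_tau_bounds, d_bounds]
        else:
            x0 = np.array([np.log(par.taus[lat])])
            bounds = [log_tau_bounds]
        f0 = obj(x0)
        res = optimize.minimize(obj, x0, method="L-BFGS-B", bounds=bounds,
                                options={"maxiter": maxiter, "eps": 1e-4})
        if np.isfinite(res.fun) and res.fun < f0:
            par.taus[lat] = float(np.exp(res.x[0]))
            if kind == "CF":
                par.delays[lat] = float(res.x[1] * dscale)


def _mstep_kernels_expected(par: _Params, post, n_trials, times, maxiter=20):
    """Expected-complete-data (Q-function) kernel update.

    Guaranteed-monotone fallback used when the faster conditional-ML
    update would decrease the likelihood (rare).
    """
    p = par.p_ext
    T = times.size
    Sigma = post["Sigma"]
    Mu3 = post["Mu"].reshape(n_trials, T, p)
    log_tau_bounds = (np.log(TAU_BOUNDS_MS[0]), np.log(TAU_BOUNDS_MS[1]))
    dscale = _DELAY_SCALE
    d_bounds = (DELAY_BOUNDS_MS[0] / dscale, DELAY_BOUNDS_MS[1] / dscale)

    for exts, kind, lat in par.latent_blocks():
        m = len(exts)
        S = np.empty((m * T, m * T))
        for vi, ei in enumerate(exts):
            mi = Mu3[:, :, ei]
            for vj, ej in enumerate(exts):
                mj = Mu3[:, :, ej]
                S[vi * T:(vi + 1) * T, vj * T:(vj + 1) * T] = (
                    n_trials * Sigma[ei::p, ej::p] + mi.T @ mj)
        S = 0.5 * (S + S.T)

        if kind == "CF":
            def obj(z):
                tau = np.exp(z[0])
                K = delayed_pair_gram(times, tau, z[1] * dscale,
                                      par.noise_floor)
                return _nll_kernel(K, S, n_trials)
            x0 = np.array([np.log(par.taus[lat]), par.delays[lat] / dscale])
            bounds = [log_tau_bounds, d_bounds]
        else:
            def obj(z):
                K = se_gram(times, np.exp(z[0]), par.noise_floor)
                return _nll_kernel(K, S, n_trials)
            x0 = np.array([np.log(par.taus[lat])])
            bounds = [log_tau_bounds]

        f0 = obj(x0)
        res = optimize.minimize(obj, x0, method="L-BFGS-B", bounds=bounds,
                                options={"maxiter": maxiter, "eps": 1e-5})
        if np.isfinite(res.fun) and res.fun < f0:
            par.taus[lat] = float(np.exp(res.x[0]))
            if kind == "CF":
                par.delays[lat] = float(res.x[1] * dscale)


def _nll_kernel(K, S, n_trials):
    """n*logdet(K) + tr(K^-1 S), the tau/delay-dependent part of -2*Q."""
    try:
        cf = sla.cho_factor(K, lower=True)
    except np.linalg.LinAlgError:
        return np.inf
    logdet = 2.0 * np.sum(np.log(np.diag(cf[0])))
    tr = np.trace(sla.cho_solve(cf, S))
    return n_trials * logdet + tr


# ==========================================================================
# public API

def _as_array(data, state_check=True):
    if isinstance(data, BinnedActivity):
        if state_check and data.normalization_state != "zscored":
            raise ValueError(
                "fit_dlag expects z-scored activity; got state "
                f"{data.normalization_state!r}")
        if state_check and data.smoothed_sd is not None:
            warnings.warn("activity was smoothed before fitting; the GP "
                          "kernel widths absorb smoothing — the model is "
                          "meant for unsmoothed input")
        return data.values
    return np.asarray(data, dtype=float)


def fit_dlag(data_A, data_B, dims: Tuple[int, int, int] = (5, 5, 5),
             max_iter: int = 200, tol: float = 1e-8,
             tau_init: float = 100.0, noise_floor: float = NOISE_FLOOR,
             kernel_opt_every: int = 1, bin_width: Optional[float] = None,
             verbose: bool = False) -> DLAGModel:
    """Fit the delayed two-area GP factor model by EM.

    Parameters
    ----------
    data_A, data_B
        ``BinnedActivity`` in the z-scored state (or plain arrays,
        trials x bins x channels) with identical trial/bin structure.
    dims
        (n cross-area, n within-A, n within-B) factor counts.
    max_iter, tol
        EM stops at ``max_iter`` iterations or when the relative change of
        the marginal log-likelihood drops below ``tol``.
    kernel_opt_every
        Run the numerical tau/delay update every k-th iteration (1 = every
        iteration); loadings/noise update every iteration regardless.
    """
    Y_A = _as_array(data_A)
    Y_B = _as_array(data_B)
    if Y_A.shape[:2] != Y_B.shape[:2]:
        raise ValueError("areas must share trial and bin structure")
    nC, nA, nB = dims
    if Y_A.shape[2] < nC + nA or Y_B.shape[2] < nC + nB:
        raise ValueError("fewer channels than requested latents in an area")
    if bin_width is None:
        bin_width = (data_A.bin_width if isinstance(data_A, BinnedActivity)
                     else 20.0)
    T = Y_A.shape[1]
    times = np.arange(T) * float(bin_width)

    par = _init_params(Y_A, Y_B, dims, noise_floor, tau_init)
    Y = np.concatenate([Y_A, Y_B], axis=2)
    n = Y.shape[0]

    fit_log: List[float] = []
    converged = False
    prev_kernels = None
    for it in range(max_iter):
        post = _posterior(par, Y, times)
        ll = post["ll"]
        kernel_step = _mstep_kernels
        if (fit_log and prev_kernels is not None
                and ll < fit_log[-1] - tol * max(abs(fit_log[-1]), 1.0)):
            # the conditional-ML kernel step overshot: revert tau/delay and
            # fall back to the guaranteed-monotone Q-function update
            par.taus[:], par.delays[:] = prev_kernels
            post = _posterior(par, Y, times)
            ll = post["ll"]
            kernel_step = _mstep_kernels_expected
        fit_log.append(ll)
        if verbose:
            print(f"EM iter {it}: ll = {ll:.4f}")
        if it > 0:
            rel = (fit_log[-1] - fit_log[-2]) / max(abs(fit_log[-2]), 1.0)
            if abs(rel) < tol:
                converged = True
                break
        _mstep_observation(par, post, Y_A, Y_B)
        if it % kernel_opt_every == 0:
            prev_kernels = (par.taus.copy(), par.delays.copy())
            kernel_step(par, post, n, times)

    model = DLAGModel(
        loadings_A=par.C_A, loadings_B=par.C_B,
        offset_A=par.d_A, offset_B=par.d_B,
        noise_A=par.R_A, noise_B=par.R_B,
        latent_specs=_specs_from(par), dims=dims, bin_width=float(bin_width),
        fit_log=fit_log, converged=converged)
    _order_and_sign(model, Y_A, Y_B, times)
    return model


def _specs_from(par: _Params) -> List[FittedLatentSpec]:
    nC, nA, nB = par.dims
    specs = [FittedLatentSpec("CF", par.taus[j], par.delays[j],
                              par.noise_floor) for j in range(nC)]
    specs += [FittedLatentSpec("WF_A", par.taus[nC + a], None,
                               par.noise_floor) for a in range(nA)]
    specs += [FittedLatentSpec("WF_B", par.taus[nC + nA + b], None,
                               par.noise_floor) for b in range(nB)]
    return specs


def _params_from_model(model: DLAGModel) -> _Params:
    nC, nA, nB = model.dims
    taus = model.taus
    delays = model.delays
    return _Params(model.loadings_A, model.loadings_B, model.offset_A,
                   model.offset_B, model.noise_A, model.noise_B, taus,
                   delays, model.dims,
                   model.latent_specs[0].noise_floor if model.latent_specs
                   else NOISE_FLOOR)


def _order_and_sign(model: DLAGModel, Y_A, Y_B, times) -> None:
    """Deterministic factor order: descending loading power within group;
    sign such that the peak of the trial-averaged (area-A view for CFs)
    trace is positive."""
    nC, nA, nB = model.dims
    lat = infer_latents(model, Y_A, Y_B, _state_check=False)

    def power(cols_A, cols_B=None):
        p = np.sum(cols_A**2, axis=0)
        if cols_B is not None:
            p = p + np.sum(cols_B**2, axis=0)
        return p

    # order
    ordC = np.argsort(power(model.loadings_A[:, :nC],
                            model.loadings_B[:, :nC]))[::-1] if nC else []
    ordA = np.argsort(power(model.loadings_A[:, nC:]))[::-1] if nA else []
    ordB = np.argsort(power(model.loadings_B[:, nC:]))[::-1] if nB else []
    model.loadings_A = np.concatenate(
        [model.loadings_A[:, :nC][:, ordC], model.loadings_A[:, nC:][:, ordA]],
        axis=1)
    model.loadings_B = np.concatenate(
        [model.loadings_B[:, :nC][:, ordC], model.loadings_B[:, nC:][:, ordB]],
        axis=1)
    specs = model.latent_specs
    model.latent_specs = ([specs[j] for j in ordC]
                          + [specs[nC + a] for a in ordA]
                          + [specs[nC + nA + b] for b in ordB])

    # sign: peak of trial-averaged trace positive
    def fix_sign(avg, cols):
        for k in range(avg.shape[1]):
            tr = avg[:, k]
            if abs(tr.min()) > abs(tr.max()):
                for c in cols:
                    c[:, k] *= -1.0
    if nC:
        avg_cf = lat.cf_A.mean(axis=0)[:, ordC]
        fix_sign(avg_cf, [model.loadings_A[:, :nC], model.loadings_B[:, :nC]])
    if nA:
        fix_sign(lat.wf_A.mean(axis=0)[:, ordA], [model.loadings_A[:, nC:]])
    if nB:
        fix_sign(lat.wf_B.mean(axis=0)[:, ordB], [model.loadings_B[:, nC:]])


def infer_latents(model: DLAGModel, data_A, data_B,
                  time_axis: Optional[np.ndarray] = None,
                  return_cov: bool = False,
                  _state_check: bool = True) -> LatentTrajectories:
    """Posterior latent trajectories for the given data under a fitted model."""
    Y_A = _as_array(data_A, _state_check)
    Y_B = _as_array(data_B, _state_check)
    if Y_A.shape[2] != model.loadings_A.shape[0] \
            or Y_B.shape[2] != model.loadings_B.shape[0]:
        raise ValueError("channel count does not match the fitted model")
    par = _params_from_model(model)
    T = Y_A.shape[1]
    times = np.arange(T) * model.bin_width
    Y = np.concatenate([Y_A, Y_B], axis=2)
    post = _posterior(par, Y, times)
    p = par.p_ext
    n = Y.shape[0]
    Mu3 = post["Mu"].reshape(n, T, p)
    nC, nA, nB = model.dims
    if time_axis is None:
        time_axis = (data_A.time_axis if isinstance(data_A, BinnedActivity)
                     else times)
    post_var = np.diag(post["Sigma"]).reshape(T, p)
    return LatentTrajectories(
        cf_A=Mu3[:, :, :nC], cf_B=Mu3[:, :, nC:2 * nC],
        wf_A=Mu3[:, :, 2 * nC:2 * nC + nA], wf_B=Mu3[:, :, 2 * nC + nA:],
        time_axis=np.asarray(time_axis, dtype=float),
        posterior_var=post_var,
        posterior_cov=post["Sigma"] if return_cov else None)


def variance_accounted(model: DLAGModel, data_A, data_B,
                       latents: Optional[LatentTrajectories] = None
                       ) -> VarianceReport:
    """Percent variance of each area reconstructed by CF vs WF latents.

    The group reconstruction is loadings x posterior latents; its variance
    is expressed as a percentage of the area's total data variance, and the
    residual is the remainder, so the three percentages sum to 100.
    """
    Y_A = _as_array(data_A, False)
    Y_B = _as_array(data_B, False)
    if latents is None:
        latents = infer_latents(model, data_A, data_B, _state_check=False)
    nC, nA, nB = model.dims
    out = {}
    for (Y, C, cf, wf, off) in (
            (Y_A, model.loadings_A, latents.cf_A, latents.wf_A, model.offset_A),
            (Y_B, model.loadings_B, latents.cf_B, latents.wf_B, model.offset_B)):
        total = np.sum((Y - off) ** 2)
        nCf = cf.shape[2]
        rec_cf = cf @ C[:, :nCf].T
        rec_wf = wf @ C[:, nCf:].T
        vaf_cf = 100.0 * np.sum(rec_cf**2) / total if total > 0 else 0.0
        vaf_wf = 100.0 * np.sum(rec_wf**2) / total if total > 0 else 0.0
        area = "A" if Y is Y_A else "B"
        out[area] = {"CF": vaf_cf, "WF": vaf_wf,
                     "residual": 100.0 - vaf_cf - vaf_wf}
    return VarianceReport(vaf=out)
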