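"""Squared-exponential Gaussian-process kernels with a white-noise floor.

The latent time courses in both the synthetic generator and the two-area
factor model are zero-mean GPs with the GPFA-family kernel

    k(dt) = (1 - sigma_n) * exp(-dt^2 / (2 tau^2)) + sigma_n * delta(dt)

where ``tau`` is the timescale (ms) and ``sigma_n`` a small white-noise
floor that keeps Gram matrices well conditioned.  Cross-area factors are a
single GP observed by the two areas on time grids offset by a delay ``D``
(positive D: area B follows area A); the white component is independent
between the two views, so the cross-view covariance carries only the
smooth term.
"""

from __future__ import annotations

import numpy as np

__all__ = ["se_kernel", "se_gram", "delayed_pair_gram"]


def se_kernel(dt, tau: float, noise_floor: float = 1e-3, amplitude: float = 1.0):
    """Evaluate the kernel at time difference(s) ``dt`` (ms).

    The delta term fires only where ``dt`` is exactly zero.
    """
    _check_params(tau, noise_floor)
    dt = np.asarray(dt, dtype=float)
    smooth = (1.0 - noise_floor) * np.exp(-(dt**2) / (2.0 * tau**2))
    return amplitude**2 * (smooth + noise_floor * (dt == 0.0))


def se_gram(times, tau: float, noise_floor: float = 1e-3,
            amplitude: float = 1.0) -> np.ndarray:
    """Gram matrix of the kernel on a grid of times (ms)."""
    t = np.asarray(times, dtype=float)
    return se_kernel(t[:, None] - t[None, :], tau, noise_floor, amplitude)


def delayed_pair_gram(times, tau: float, delay: float,
                      noise_floor: float = 1e-3,
                      amplitude: float = 1.0) -> np.ndarray:
    """Joint Gram over the (area-A view, area-B view) of one cross-area factor.

    Returns the 2T x 2T covariance of ``[x_A(t_1..t_T), x_B(t_1..t_T)]``
    where ``x_B(t) = f(t - delay)`` and ``x_A(t) = f(t)`` share the smooth
    process ``f`` but carry independent white floors.
    """
    _check_params(tau, noise_floor)
    t = np.asarray(times, dtype=float)
    T = t.size
    dt = t[:, None] - t[None, :]
    a2 = amplitude**2
    smooth = lambda d: a2 * (1.0 - noise_floor) * np.exp(-(d**2) / (2.0 * tau**2))
    K = np.empty((2 * T, 2 * T))
    diag_block = smooth(dt) + a2 * noise_floor * np.eye(T)
    K[:T, :T] = diag_block
    K[T:, T:] = diag_block
    # cov(x_A(t1), x_B(t2)) = k_smooth(t1 - (t2 - delay))
    K[:T, T:] = smooth(dt + delay)
    K[T:, :T] = K[:T, T:].T
    return K


def _check_params(tau: float, noise_floor: float) -> None:
    if not tau > 0:
        raise ValueError(f"timescale tau must be positive, got {tau}")
    if not 0.0 < noise_floor < 1.0:
        raise ValueError(f"noise floor must be in (0, 1), got {noise_floor}")
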