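"""PCA baseline on trial-concatenated activity and PC-pair correlations."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA

from .containers import BinnedActivity

__all__ = ["PCAResult", "fit_pca", "pc_pair_correlations"]


@dataclass
class PCAResult:
    components: np.ndarray    # k x channels
    vaf: np.ndarray           # percent variance per PC, non-increasing
    scores: np.ndarray        # trials x bins x k single-trial PC scores
    mean: np.ndarray


def fit_pca(data, k: int) -> PCAResult:
    """Principal components of bins x channels concatenated over trials.

    Intended input is z-scored activity smoothed with a 40-ms Gaussian
    kernel (the smoothing PCA gets in lieu of a GP prior); pass any
    trials x bins x channels array.
    """
    values = data.values if isinstance(data, BinnedActivity) else np.asarray(data)
    n, T, q = values.shape
    if k > q:
        raise ValueError(f"requested {k} components from {q} channels")
    flat = values.reshape(-1, q)
    model = PCA(n_components=k, svd_solver="full")
    scores = model.fit_transform(flat)
    return PCAResult(
        components=model.components_,
        vaf=100.0 * model.explained_variance_ratio_,
        scores=scores.reshape(n, T, k),
        mean=model.mean_,
    )


def pc_pair_correlations(scores_A: np.ndarray, scores_B: np.ndarray,
                         top_k: int = 10) -> np.ndarray:
    """Pearson r between trial-averaged PC traces of the two areas.

    ``scores_*`` are trials x bins x k (single-trial scores, averaged here)
    or bins x k trial-averaged traces.  Returns a top_k x top_k matrix of
    r over all area-A x area-B pairs; pairs with a constant trace are NaN.
    """
    A = scores_A.mean(axis=0) if scores_A.ndim == 3 else scores_A
    B = scores_B.mean(axis=0) if scores_B.ndim == 3 else scores_B
    if A.shape[0] != B.shape[0]:
        raise ValueError("trial-averaged traces must share a time axis")
    A = A[:, :top_k]
    B = B[:, :top_k]
    out = np.full((A.shape[1], B.shape[1]), np.nan)
    sa, sb = A.std(axis=0), B.std(axis=0)
    Az = A - A.mean(axis=0)
    Bz = B - B.mean(axis=0)
    valid = np.outer(sa > 0, sb > 0)
    r = (Az.T @ Bz) / A.shape[0]
    with np.errstate(invalid="ignore", divide="ignore"):
        r = r / np.outer(sa, sb)
    out[valid] = r[valid]
    return out
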