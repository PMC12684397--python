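"""Weighted linear models on log-CPM: the limma-style backend.

Divided counts are transformed to log2 counts per million, a mean-variance
trend is estimated across transcripts and converted into per-observation
precision weights (the voom recipe: sqrt residual sd regressed on average
log-count by lowess, weight = predicted sqrt-sd to the power -4), and each
transcript is fitted by weighted least squares.  When a treatment group has
all-zero counts for a transcript, its residuals are structurally zero and the
residual df is reduced by (group size - 1) to avoid understating the residual
variance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from statsmodels.nonparametric.smoothers_lowess import lowess

from .rta import DividedCounts

__all__ = ["TranscriptFit", "logcpm_transform", "voom_trend_weights", "fit_weighted_lm"]


@dataclass
class TranscriptFit:
    """Per-transcript model fits shared by both backends.

    ``beta`` is transcripts x coefficients on the backend's native log scale
    (log2 for the linear-model backend, natural log for the NB GLM backend);
    ``unscaled_cov`` is the transcripts x p x p unscaled covariance of beta,
    to be multiplied by the gene-level (quasi-)variance.  ``s2`` is the
    residual variance (linear backend) or bias-adjusted mean deviance (GLM
    backend) and ``resid_df`` the possibly-adjusted residual df.
    """

    beta: np.ndarray
    unscaled_cov: np.ndarray
    s2: np.ndarray
    resid_df: np.ndarray
    fitted: np.ndarray
    log_base: float = 2.0
    obs_weights: np.ndarray | None = None
    deviance: np.ndarray | None = None
    converged: np.ndarray | None = None

    @property
    def n_transcripts(self) -> int:
        return self.beta.shape[0]

    def unscaled_var(self, coef: int) -> np.ndarray:
        """Unscaled variance v_gt of one coefficient."""
        return self.unscaled_cov[:, coef, coef]


def logcpm_transform(z: DividedCounts) -> np.ndarray:
    """log2 counts-per-million with the standard small offsets.

    value = log2((z + 0.5) / (effective_lib + 1) * 1e6).
    """
    eff = z.effective_lib_sizes
    return np.log2((z.z + 0.5) / (eff[None, :] + 1.0) * 1e6)


def voom_trend_weights(logcpm: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Mean-variance-trend precision weights for every observation.

    Per-transcript OLS residual standard deviations (sqrt scale) are smoothed
    against average log-CPM by lowess (span 0.5); the trend evaluated at each
    fitted log-CPM, raised to the power -4, is the observation weight.
    Degenerate inputs (too few transcripts for a trend, or no variance at
    all) fall back to unit weights with a warning.
    """
    T, n = logcpm.shape
    p = X.shape[1]
    if T < 10 or n <= p:
        warnings.warn("too few transcripts for a mean-variance trend; using unit weights",
                      stacklevel=2)
        return np.ones_like(logcpm)

    pinv = np.linalg.pinv(X)
    beta = logcpm @ pinv.T
    fitted = beta @ X.T
    resid = logcpm - fitted
    s = np.sqrt((resid**2).sum(axis=1) / (n - p))
    abar = logcpm.mean(axis=1)
    sqrt_s = np.sqrt(s)
    if np.all(s == 0) or np.ptp(abar) == 0:
        warnings.warn("no residual variation across transcripts; using unit weights",
                      stacklevel=2)
        return np.ones_like(logcpm)

    trend = lowess(sqrt_s, abar, frac=0.5, it=3, return_sorted=True)
    tx, ty = trend[:, 0], trend[:, 1]
    pred = np.interp(fitted, tx, ty)
    pred = np.maximum(pred, 1e-4)
    w = pred**-4
    return np.clip(w, 1e-6, 1e6)


def fit_weighted_lm(
    logcpm: np.ndarray,
    X: np.ndarray,
    weights: np.ndarray | None = None,
    zero_counts: np.ndarray | None = None,
    groups: np.ndarray | None = None,
) -> TranscriptFit:
    """Transcript-wise weighted least squares with zero-group df adjustment.

    ``zero_counts`` (the divided-count matrix) and ``groups`` (per-sample
    treatment labels) drive the residual-df penalty: for each treatment group
    of size m whose counts are all exactly zero for a transcript, the residual
    df is reduced by m - 1, floored at 0.
    """
    logcpm = np.asarray(logcpm, dtype=float)
    X = np.asarray(X, dtype=float)
    T, n = logcpm.shape
    p = X.shape[1]
    if np.linalg.matrix_rank(X) < p:
        raise np.linalg.LinAlgError("design matrix is not of full column rank")
    if n <= p:
        raise ValueError("more coefficients than samples")
    if weights is None:
        weights = np.ones_like(logcpm)
    weights = np.asarray(weights, dtype=float)

    xtwx = np.einsum("tn,np,nq->tpq", weights, X, X)
    xtwy = np.einsum("tn,tn,np->tp", weights, logcpm, X)
    try:
        beta = np.linalg.solve(xtwx, xtwy[..., None])[..., 0]
        cov = np.linalg.inv(xtwx)
    except np.linalg.LinAlgError as err:
        dets = np.abs(np.linalg.det(xtwx))
        bad = int(np.argmin(dets))
        raise np.linalg.LinAlgError(
            f"singular weighted design for transcript index {bad}"
        ) from err
    fitted = beta @ X.T
    resid = logcpm - fitted
    wrss = (weights * resid**2).sum(axis=1)

    df = np.full(T, float(n - p))
    if zero_counts is not None and groups is not None:
        groups = np.asarray(groups)
        for g in np.unique(groups):
            members = groups == g
            m = int(members.sum())
            if m < 2:
                continue
            allzero = (np.asarray(zero_counts)[:, members] == 0).all(axis=1)
            df[allzero] -= m - 1
    df = np.maximum(df, 0.0)

    s2 = np.where(df > 0, wrss / np.maximum(df, 1e-300), 0.0)
    return TranscriptFit(
        beta=beta,
        unscaled_cov=cov,
        s2=s2,
        resid_df=df,
        fitted=fitted,
        log_base=2.0,
        obs_weights=weights,
    )
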