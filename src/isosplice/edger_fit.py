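"""Quasi-negative-binomial GLMs on divided counts: the edgeR-style backend.

The divided counts are modelled with a quadratic mean-variance relationship
var(z) = sigma^2_g (mu + phi mu^2): a single global NB dispersion phi shared
by all transcripts, and a gene-level quasi-dispersion sigma^2_g estimated
downstream from pooled mean deviances.  Each transcript gets a log-link NB GLM
with the log effective library sizes as offsets.  Residual df are adjusted
continuously for small fitted values: each observation contributes
1 - P(Y = 0 | mu, phi) effective df, so exactly-zero and nearly-zero fitted
values both reduce the df.

Coefficients are computed and stored on the natural log scale; result writers
report effects on the log2 scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

from .io_formats import TranscriptCatalog
from .limma_fit import TranscriptFit
from .rta import DividedCounts, RTAEstimate

__all__ = [
    "NBGlobal",
    "TPMTable",
    "nb_deviance",
    "estimate_common_dispersion",
    "fit_nb_glm",
    "adjusted_residual_df",
    "fitted_tpm",
]

_POISSON_PHI = 1e-10
_MU_FLOOR = 1e-8
_ETA_CLAMP = 745.0


@dataclass
class NBGlobal:
    """Global negative binomial dispersion shared by all transcripts."""

    phi: float


@dataclass
class TPMTable:
    """Fitted transcripts-per-million values and within-gene proportions."""

    tpm: np.ndarray
    proportions: np.ndarray
    transcript_id: np.ndarray | None = None
    gene_id: np.ndarray | None = None


def _unit_deviance(y: np.ndarray, mu: np.ndarray, phi: float) -> np.ndarray:
    y = np.asarray(y, dtype=float)
    mu = np.maximum(np.asarray(mu, dtype=float), _MU_FLOOR)
    with np.errstate(divide="ignore", invalid="ignore"):
        ylogy = np.where(y > 0, y * np.log(np.maximum(y, _MU_FLOOR) / mu), 0.0)
    if phi < _POISSON_PHI:
        d = 2.0 * (ylogy - (y - mu))
    else:
        d = 2.0 * (ylogy - (y + 1.0 / phi) * np.log((1.0 + phi * y) / (1.0 + phi * mu)))
    return np.maximum(d, 0.0)


def nb_deviance(y: np.ndarray, mu: np.ndarray, phi: float) -> np.ndarray:
    """Negative binomial residual deviance, summed over the last axis.

    D = 2 sum[y log(y/mu) - (y + 1/phi) log((1 + phi y)/(1 + phi mu))],
    with the convention y log(y/mu) = 0 at y = 0; the phi -> 0 limit is the
    Poisson deviance.  Accepts fractional y.
    """
    return _unit_deviance(y, mu, phi).sum(axis=-1)


def _nb_loglik(y: np.ndarray, mu: np.ndarray, phi: float) -> np.ndarray:
    """NB log-likelihood (continuous-y extension), summed over the last axis."""
    y = np.asarray(y, dtype=float)
    mu = np.maximum(np.asarray(mu, dtype=float), _MU_FLOOR)
    if phi < _POISSON_PHI:
        ll = y * np.log(mu) - mu - gammaln(y + 1.0)
    else:
        r = 1.0 / phi
        ll = (
            gammaln(y + r)
            - gammaln(r)
            - gammaln(y + 1.0)
            + r * np.log(r / (r + mu))
            + y * np.log(mu / (r + mu))
        )
    return ll.sum(axis=-1)


def _working_weights(mu: np.ndarray, phi: float) -> np.ndarray:
    return mu / (1.0 + phi * mu)


def irls_nb(
    y: np.ndarray,
    X: np.ndarray,
    offset: np.ndarray,
    phi: float,
    beta0: np.ndarray | None = None,
    max_iter: int = 50,
    tol: float = 1e-8,
):
    """Batched IRLS for log-link NB GLMs, one model per row of ``y``.

    Returns (beta, mu, deviance, xtwx, converged).  Rows that are entirely
    zero are solved directly with the linear predictor clamped at -745 on the
    natural log scale, giving essentially-zero fitted means and deviance 0.
    """
    y = np.atleast_2d(np.asarray(y, dtype=float))
    X = np.asarray(X, dtype=float)
    T, n = y.shape
    p = X.shape[1]
    offset = np.broadcast_to(np.asarray(offset, dtype=float), (T, n))

    if p == 0:
        mu = np.clip(np.exp(np.clip(offset, -_ETA_CLAMP, _ETA_CLAMP)), _MU_FLOOR, 1e15)
        dev = nb_deviance(y, mu, phi)
        return (
            np.zeros((T, 0)),
            mu,
            dev,
            np.zeros((T, 0, 0)),
            np.ones(T, dtype=bool),
        )

    allzero = (y == 0).all(axis=1)
    active = ~allzero

    beta = np.zeros((T, p))
    mu = np.full((T, n), _MU_FLOOR)
    converged = np.ones(T, dtype=bool)

    if allzero.any():
        # least-squares projection of a -745 linear predictor
        target = -_ETA_CLAMP - offset[allzero]
        beta[allzero] = (np.linalg.pinv(X) @ target.T).T

    if active.any():
        ya = y[active]
        offa = offset[active]
        if beta0 is not None:
            b = beta0[active].copy()
        else:
            mu0 = ya + ya.mean(axis=1, keepdims=True) / 6.0 + 0.1
            w0 = mu0
            z0 = np.log(mu0) - offa
            xtwx0 = np.einsum("tn,np,nq->tpq", w0, X, X)
            xtwz0 = np.einsum("tn,tn,np->tp", w0, z0, X)
            b = np.linalg.solve(xtwx0, xtwz0[..., None])[..., 0]
        dev = np.full(active.sum(), np.inf)
        conv = np.zeros(active.sum(), dtype=bool)
        mua = None
        for _ in range(max_iter):
            eta = np.clip(b @ X.T, -_ETA_CLAMP, _ETA_CLAMP) + offa
            mua = np.clip(np.exp(eta), _MU_FLOOR, 1e15)
            new_dev = nb_deviance(ya, mua, phi)
            done = np.abs(new_dev - dev) < tol * (np.abs(new_dev) + 1.0)
            conv |= done
            dev = new_dev
            if conv.all():
                break
            w = _working_weights(mua, phi)
            zwork = (eta - offa) + (ya - mua) / mua
            xtwx = np.einsum("tn,np,nq->tpq", w, X, X)
            xtwx += 1e-10 * np.eye(p)[None]
            xtwz = np.einsum("tn,tn,np->tp", w, zwork, X)
            b_new = np.linalg.solve(xtwx, xtwz[..., None])[..., 0]
            upd = ~conv
            b[upd] = b_new[upd]
        beta[active] = b
        mu[active] = mua
        converged[active] = conv

    eta = np.clip(beta @ X.T, -_ETA_CLAMP, _ETA_CLAMP) + offset
    mu = np.clip(np.exp(eta), _MU_FLOOR, 1e15)
    dev = nb_deviance(y, mu, phi)
    w = _working_weights(mu, phi)
    xtwx = np.einsum("tn,np,nq->tpq", w, X, X)
    return beta, mu, dev, xtwx, converged


def estimate_common_dispersion(
    z: DividedCounts, X: np.ndarray, offsets: np.ndarray | None = None
) -> NBGlobal:
    """Global NB dispersion by pooled adjusted profile likelihood.

    Fitted means are obtained once from Poisson fits (for group-factor
    designs they coincide with the NB fitted means at any phi); the summed NB
    log-likelihood with a Cox-Reid half-log-determinant adjustment for the
    estimated coefficients is then maximized over phi in [1e-6, 10] by
    golden-section search on the log scale.  Transcripts with mean count
    below 1 are excluded from the objective.
    """
    y = z.z
    X = np.asarray(X, dtype=float)
    if offsets is None:
        offsets = np.log(z.effective_lib_sizes)
    usable = y.mean(axis=1) >= 1.0
    n, p = X.shape
    if not usable.any() or (n - p) * int(usable.sum()) < 2:
        warnings.warn("no usable transcripts for dispersion estimation; phi set to 0",
                      stacklevel=2)
        return NBGlobal(phi=0.0)
    y = y[usable]

    _, mu, _, _, _ = irls_nb(y, X, offsets, phi=0.0)

    def objective(log_phi: float) -> float:
        phi = 10.0**log_phi
        ll = _nb_loglik(y, mu, phi).sum()
        w = _working_weights(mu, phi)
        xtwx = np.einsum("tn,np,nq->tpq", w, X, X)
        sign, logdet = np.linalg.slogdet(xtwx)
        cr = 0.5 * logdet[sign > 0].sum()
        return ll - cr

    # golden-section maximization on log10 phi in [-6, 1]
    lo, hi = -6.0, 1.0
    invphi = (np.sqrt(5.0) - 1.0) / 2.0
    a, b = hi - invphi * (hi - lo), lo + invphi * (hi - lo)
    fa, fb = objective(a), objective(b)
    for _ in range(60):
        if fa > fb:
            hi, b, fb = b, a, fa
            a = hi - invphi * (hi - lo)
            fa = objective(a)
        else:
            lo, a, fa = a, b, fb
            b = lo + invphi * (hi - lo)
            fb = objective(b)
        if hi - lo < 1e-4:
            break
    return NBGlobal(phi=float(10.0 ** ((lo + hi) / 2.0)))


def zero_probability(mu: np.ndarray, phi: float) -> np.ndarray:
    """P(Y = 0) under NB(mu, phi); the Poisson limit at phi = 0."""
    mu = np.asarray(mu, dtype=float)
    if phi < _POISSON_PHI:
        return np.exp(-mu)
    return (1.0 + phi * mu) ** (-1.0 / phi)


def adjusted_residual_df(mu: np.ndarray, phi: float, p: int) -> np.ndarray:
    """Continuously adjusted residual df.

    Each observation contributes c_i = 1 - P(Y=0 | mu_i, phi) effective df,
    so d = max(0, sum_i c_i - p).  Monotone non-decreasing in every mu_i.
    """
    c = 1.0 - zero_probability(mu, phi)
    return np.maximum(c.sum(axis=-1) - p, 0.0)


def fit_nb_glm(
    z: DividedCounts,
    X: np.ndarray,
    phi: float,
    offsets: np.ndarray | None = None,
) -> TranscriptFit:
    """Transcript-wise NB GLM fits with adjusted residual df.

    Returns coefficients on the natural log scale, unscaled covariances from
    the inverse expected information, fitted means, residual deviances, and
    bias-adjusted mean deviances s^2 = deviance / adjusted df.
    """
    y = z.z
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if np.linalg.matrix_rank(X) < p:
        raise np.linalg.LinAlgError("design matrix is not of full column rank")
    if offsets is None:
        offsets = np.log(z.effective_lib_sizes)

    beta, mu, dev, xtwx, converged = irls_nb(y, X, offsets, phi)
    if not converged.all():
        warnings.warn(
            f"{int((~converged).sum())} transcript GLM(s) did not converge; "
            "using the last iterate",
            stacklevel=2,
        )
    cov = np.linalg.inv(xtwx + 1e-10 * np.eye(p)[None])
    df = adjusted_residual_df(mu, phi, p)
    s2 = np.where(df > 0, dev / np.maximum(df, 1e-300), 0.0)
    return TranscriptFit(
        beta=beta,
        unscaled_cov=cov,
        s2=s2,
        resid_df=df,
        fitted=mu,
        log_base=np.e,
        deviance=dev,
        converged=converged,
    )


def fitted_tpm(
    fit: TranscriptFit,
    tau: np.ndarray,
    effective_length: np.ndarray,
    X: np.ndarray,
    gene_id: np.ndarray,
    transcript_id: np.ndarray | None = None,
) -> TPMTable:
    """Fitted transcripts-per-million from an NB GLM fit.

    Raw value (tau_t / L_t) exp(x_i' beta_t) per sample (library offsets
    excluded), then one global constant scales all entries so the geometric
    mean of the column totals equals 1e6.  Proportions are within-gene column
    shares; genes with all-zero fitted values get missing proportions.
    """
    eta = np.clip(fit.beta @ np.asarray(X, dtype=float).T, -_ETA_CLAMP, _ETA_CLAMP)
    raw = (np.asarray(tau, float) / np.asarray(effective_length, float))[:, None] * np.exp(eta)
    totals = raw.sum(axis=0)
    if np.any(totals <= 0):
        raise ValueError("cannot scale TPM: a sample has zero total fitted expression")
    C = 1e6 / np.exp(np.mean(np.log(totals)))
    tpm = raw * C

    gene_id = np.asarray(gene_id, dtype=object)
    prop = np.full_like(tpm, np.nan)
    import pandas as pd

    codes, _ = pd.factorize(gene_id)
    for g in np.unique(codes):
        rows = codes == g
        tot = tpm[rows].sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            prop[rows] = np.where(tot > 0, tpm[rows] / tot, np.nan)
    return TPMTable(tpm=tpm, proportions=prop, transcript_id=transcript_id, gene_id=gene_id)
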