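"""Differential transcript usage tests.

A gene shows DTU when the transcript-wise coefficients for the tested
contrast differ among its transcripts.  Both backends share the same scheme:

* pool per-transcript residual variances (or mean deviances) within genes,
* shrink the gene-level variances with unequal-df empirical Bayes moment
  matching on the log scale,
* compare each transcript's coefficient to the precision-weighted gene
  consensus, yielding moderated t (or sign-adjusted quasi-t) statistics,
* summarize per gene by a moderated F (or quasi-F from deviance differences)
  and by Simes aggregation of the transcript p-values,
* adjust for multiple testing by Benjamini-Hochberg at each level.

Only genes expressing more than one usable transcript are tested.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .edger_fit import irls_nb, nb_deviance, _working_weights
from .limma_fit import TranscriptFit

__all__ = [
    "GeneEBayes",
    "DTUResultTables",
    "squeeze_variances",
    "limma_diffsplice",
    "edger_diffsplice",
    "simes_p",
    "bh_adjust",
    "top_splice",
]

_LN2 = np.log(2.0)
_MAX_PRIOR_DF = 1e7


@dataclass
class GeneEBayes:
    """Empirical Bayes squeeze of gene-level variances.

    ``posterior_s2`` follows (d0 s0^2 + d s^2) / (d0 + d); an infinite prior
    df collapses every posterior onto the prior variance.
    """

    df: np.ndarray
    s2: np.ndarray
    prior_df: float
    prior_s2: float
    posterior_s2: np.ndarray

    @property
    def total_df(self) -> np.ndarray:
        return np.minimum(self.prior_df, _MAX_PRIOR_DF) + self.df


@dataclass
class DTUResultTables:
    """Gene- and transcript-level DTU results."""

    genes: pd.DataFrame
    transcripts: pd.DataFrame
    backend: str = ""
    ebayes: "GeneEBayes | None" = None


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 by Newton iteration."""
    if x <= 0:
        return np.inf
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif) < 1e-10 * y:
            break
    return float(y)


def squeeze_variances(
    s2: np.ndarray, df: np.ndarray, winsorize: bool = False
) -> GeneEBayes:
    """Estimate (prior df, prior variance) by moment matching on log variances.

    Under a scaled-F model, e = log s^2 - psi(d/2) + log(d/2) has mean
    log s0^2 - psi(d0/2) + log(d0/2) and excess variance psi'(d0/2) beyond
    the known mean(psi'(d/2)).  The trigamma equation is inverted by Newton;
    a non-positive excess variance gives an infinite prior df.  With
    ``winsorize``, e is 90%-winsorized before moment matching for outlier
    protection.
    """
    s2 = np.asarray(s2, dtype=float)
    df = np.asarray(df, dtype=float)
    ok = (df > 0) & (s2 > 0) & np.isfinite(s2)
    if ok.sum() < 2:
        raise ValueError("need at least 2 genes with positive df and variance")
    e = np.log(s2[ok]) - special.digamma(df[ok] / 2.0) + np.log(df[ok] / 2.0)
    if winsorize:
        lo, hi = np.quantile(e, [0.05, 0.95])
        e = np.clip(e, lo, hi)
    emean = float(e.mean())
    evar = float(e.var(ddof=1)) if e.size > 1 else 0.0
    excess = evar - float(np.mean(special.polygamma(1, df[ok] / 2.0)))
    if excess <= 0:
        d0 = np.inf
        s0 = float(np.exp(emean))
    else:
        d0 = 2.0 * _trigamma_inverse(excess)
        if d0 > _MAX_PRIOR_DF:
            d0 = np.inf
            s0 = float(np.exp(emean))
        else:
            s0 = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    if np.isinf(d0):
        post = np.full_like(s2, s0)
    else:
        post = (d0 * s0 + df * s2) / (d0 + df)
    return GeneEBayes(df=df, s2=s2, prior_df=d0, prior_s2=s0, posterior_s2=post)


def _pool_by_gene(gene_codes: np.ndarray, n_genes: int, values: np.ndarray) -> np.ndarray:
    return np.bincount(gene_codes, weights=values, minlength=n_genes)


def _gene_tables(gene_id: np.ndarray, usable: np.ndarray):
    """Factorize genes over usable transcripts, keeping genes with >= 2."""
    codes_all, uniques = pd.factorize(pd.Series(gene_id), sort=True)
    counts = np.bincount(codes_all[usable], minlength=len(uniques))
    multi = counts >= 2
    keep_tx = usable & multi[codes_all]
    # re-factorize over kept genes only
    kept_gene = gene_id[keep_tx]
    codes, genes = pd.factorize(pd.Series(kept_gene), sort=True)
    return keep_tx, codes, np.asarray(genes, dtype=object)


def simes_p(p: np.ndarray) -> float:
    """Simes combination: min over i of m p_(i) / i, capped at 1."""
    p = np.sort(np.asarray(p, dtype=float))
    m = p.size
    if m == 0:
        raise ValueError("empty p-value vector")
    return float(min(1.0, np.min(m * p / np.arange(1, m + 1))))


def _grouped_simes(p: np.ndarray, codes: np.ndarray, n_genes: int) -> np.ndarray:
    out = np.ones(n_genes)
    order = np.argsort(codes, kind="stable")
    pc, cc = p[order], codes[order]
    starts = np.searchsorted(cc, np.arange(n_genes))
    ends = np.searchsorted(cc, np.arange(n_genes), side="right")
    for g in range(n_genes):
        out[g] = simes_p(pc[starts[g]: ends[g]])
    return out


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(ranked, 1.0)
    return out


def _f_sf(x, dfn, dfd):
    dfd = np.minimum(dfd, _MAX_PRIOR_DF)
    return stats.f.sf(x, dfn, dfd)


def _t_sf2(x, dfd):
    dfd = np.minimum(dfd, _MAX_PRIOR_DF)
    return 2.0 * stats.t.sf(np.abs(x), dfd)


def limma_diffsplice(
    fit: TranscriptFit,
    gene_id: np.ndarray,
    coef: int,
    transcript_id: np.ndarray | None = None,
    eb: GeneEBayes | None = None,
    winsorize: bool = False,
) -> DTUResultTables:
    """Moderated-t / moderated-F DTU tests for a weighted-linear-model fit.

    For each multi-transcript gene, transcript coefficients are compared to
    the precision-weighted consensus: with leverage h = u / sum(u),

        t = (beta_t - beta_bar) / sqrt(1 - h) / (s_tilde sqrt(v)),
        F = sum((1 - h) t^2) / (T - 1),

    referred to t and F distributions on prior-plus-pooled residual df.
    """
    gene_id = np.asarray(gene_id, dtype=object)
    beta = fit.beta[:, coef]
    v = fit.unscaled_var(coef)
    usable = np.isfinite(v) & (v > 0) & np.isfinite(beta)
    if (~usable).any():
        warnings.warn(
            f"{int((~usable).sum())} transcript(s) with non-positive unscaled variance "
            "excluded from DTU tests",
            stacklevel=2,
        )
    keep_tx, codes, genes = _gene_tables(gene_id, usable)
    G = len(genes)
    if G == 0:
        raise ValueError("no genes with at least 2 usable transcripts")

    b = beta[keep_tx]
    vv = v[keep_tx]
    d = fit.resid_df[keep_tx]
    s2 = fit.s2[keep_tx]

    d_g = _pool_by_gene(codes, G, d)
    with np.errstate(invalid="ignore", divide="ignore"):
        s2_g = np.where(d_g > 0, _pool_by_gene(codes, G, d * s2) / np.maximum(d_g, 1e-300), 0.0)
    if eb is None:
        eb = squeeze_variances(s2_g, d_g, winsorize=winsorize)
    total_df = eb.total_df

    u = 1.0 / vv
    u_g = _pool_by_gene(codes, G, u)
    beta_bar = _pool_by_gene(codes, G, u * b) / u_g
    h = u / u_g[codes]
    n_tx = np.bincount(codes, minlength=G)

    s_tilde = np.sqrt(eb.posterior_s2)
    t_stat = (b - beta_bar[codes]) / np.sqrt(1.0 - h) / (s_tilde[codes] * np.sqrt(vv))
    p_t = _t_sf2(t_stat, total_df[codes])

    F = _pool_by_gene(codes, G, (1.0 - h) * t_stat**2) / (n_tx - 1)
    p_F = _f_sf(F, n_tx - 1, total_df)
    p_simes = _grouped_simes(p_t, codes, G)

    rel_logfc = (b - beta_bar[codes]) / (_LN2 if fit.log_base == np.e else 1.0)

    genes_df = pd.DataFrame(
        {
            "gene_id": genes,
            "n_transcripts": n_tx,
            "F": F,
            "df1": n_tx - 1,
            "df2": total_df,
            "p_F": p_F,
            "fdr_F": bh_adjust(p_F),
            "p_simes": p_simes,
            "fdr_simes": bh_adjust(p_simes),
        }
    )
    tx_ids = (
        np.asarray(transcript_id, dtype=object)[keep_tx]
        if transcript_id is not None
        else np.array([f"tx{i}" for i in np.flatnonzero(keep_tx)], dtype=object)
    )
    tx_df = pd.DataFrame(
        {
            "transcript_id": tx_ids,
            "gene_id": genes[codes],
            "rel_logFC": rel_logfc,
            "leverage": h,
            "t": t_stat,
            "p": p_t,
            "fdr": bh_adjust(p_t),
        }
    )
    return DTUResultTables(genes=genes_df, transcripts=tx_df, backend="lm", ebayes=eb)


def _consensus_null_fit(
    y: np.ndarray,
    X: np.ndarray,
    offsets: np.ndarray,
    coef: int,
    phi: float,
    b_init: float,
    beta_init: np.ndarray,
    tol: float = 1e-6,
    max_rounds: int = 50,
):
    """Fit per-transcript NB GLMs with coefficient ``coef`` shared.

    Block-iterates: the nuisance coefficients of every transcript are refitted
    (one batched IRLS pass per round) with the shared value absorbed into the
    offset, then the shared value takes a damped Fisher-scoring step from the
    pooled per-transcript scores.  Returns (total deviance, per-transcript
    deviances, shared value, converged flag).
    """
    T, n = y.shape
    p = X.shape[1]
    rest = [k for k in range(p) if k != coef]
    Xr = X[:, rest]
    xj = X[:, coef]
    b = float(b_init)
    beta_r = beta_init[:, rest].copy()
    dev = None
    converged = False
    for _ in range(max_rounds):
        off = offsets + xj[None, :] * b
        beta_r, mu, dev, _, _ = irls_nb(y, Xr, off, phi, beta0=beta_r, max_iter=4)
        w = _working_weights(mu, phi)
        score = float(np.sum(xj[None, :] * (y - mu) / (1.0 + phi * mu)))
        info = float(np.sum((xj**2)[None, :] * w))
        if info <= 0:
            break
        step = score / info
        b += 0.5 * step if abs(step) > 1.0 else step
        if abs(step) < tol:
            converged = True
            break
    off = offsets + xj[None, :] * b
    beta_r, mu, dev, _, _ = irls_nb(y, Xr, off, phi, beta0=beta_r, max_iter=20)
    return float(dev.sum()), dev, b, converged


def edger_diffsplice(
    z_matrix: np.ndarray,
    X: np.ndarray,
    offsets: np.ndarray,
    fit: TranscriptFit,
    gene_id: np.ndarray,
    coef: int,
    phi: float,
    transcript_id: np.ndarray | None = None,
    eb: GeneEBayes | None = None,
    winsorize: bool = False,
    fast_threshold: int = 10,
) -> DTUResultTables:
    """Quasi-F DTU tests from NB deviance differences.

    Gene level: F = dD / ((T - 1) s_tilde^2), where dD is the deviance
    difference between the full fit and the null fit with the tested
    coefficient shared across the gene's transcripts.  Transcript level:
    F_t = dD_t / s_tilde^2 with dD_t the difference between the all-equal
    null and the one-removed null that frees transcript t; the sign of
    beta_t minus the consensus converts sqrt(F_t) to a t-statistic.  Genes
    with more than ``fast_threshold`` transcripts use a per-transcript fast
    approximation (full fit versus coefficient pinned at the consensus).
    """
    gene_id = np.asarray(gene_id, dtype=object)
    beta = fit.beta[:, coef]
    v = fit.unscaled_var(coef)
    usable = np.isfinite(v) & (v > 0) & np.isfinite(beta)
    keep_tx, codes, genes = _gene_tables(gene_id, usable)
    G = len(genes)
    if G == 0:
        raise ValueError("no genes with at least 2 usable transcripts")

    idx = np.flatnonzero(keep_tx)
    b = beta[keep_tx]
    vv = v[keep_tx]
    d = fit.resid_df[keep_tx]
    s2 = fit.s2[keep_tx]
    dev_full = fit.deviance[keep_tx]

    d_g = _pool_by_gene(codes, G, d)
    with np.errstate(invalid="ignore", divide="ignore"):
        s2_g = np.where(d_g > 0, _pool_by_gene(codes, G, d * s2) / np.maximum(d_g, 1e-300), 0.0)
    if eb is None:
        eb = squeeze_variances(s2_g, d_g, winsorize=winsorize)
    total_df = eb.total_df
    s2_tilde = eb.posterior_s2

    u = 1.0 / vv
    u_g = _pool_by_gene(codes, G, u)
    beta_bar = _pool_by_gene(codes, G, u * b) / u_g
    n_tx = np.bincount(codes, minlength=G)

    offsets = np.broadcast_to(np.asarray(offsets, float), z_matrix.shape)
    order = np.argsort(codes, kind="stable")
    starts = np.searchsorted(codes[order], np.arange(G))
    ends = np.searchsorted(codes[order], np.arange(G), side="right")

    dD_g = np.zeros(G)
    dD_t = np.zeros(b.size)
    beta_kept = fit.beta[keep_tx]

    for g in range(G):
        members = order[starts[g]: ends[g]]
        rows = idx[members]
        yg = z_matrix[rows]
        og = offsets[rows]
        bg = beta_kept[members]
        consensus = beta_bar[g]
        dev_full_g = dev_full[members]

        D_null, dev_null_t, b_null, _ = _consensus_null_fit(
            yg, X, og, coef, phi, consensus, bg
        )
        dD_g[g] = max(0.0, D_null - float(dev_full_g.sum()))

        Tg = len(members)
        if Tg == 2:
            # the one-removed null frees one transcript and leaves a single
            # unconstrained transcript, so it equals the full model
            dD_t[members] = dD_g[g]
        elif Tg > fast_threshold:
            # fast approximation: pin each transcript's coefficient at the
            # consensus, refit its nuisance coefficients, difference vs full
            _, dev_pinned, _, _ = _consensus_null_fit(
                yg, X, og, coef, phi, consensus, bg, max_rounds=0
            )
            dD_t[members] = np.maximum(0.0, dev_pinned - dev_full_g)
        else:
            for local_k, k in enumerate(members):
                others = [m for m in members if m != k]
                yo = z_matrix[idx[others]]
                oo = offsets[idx[others]]
                bo = beta_kept[others]
                other_bar = float(
                    np.sum(u[others] * b[others]) / np.sum(u[others])
                )
                if len(others) == 1:
                    D_one = float(dev_full[others[0]] + dev_full[k])
                else:
                    D_oth, _, _, _ = _consensus_null_fit(
                        yo, X, oo, coef, phi, other_bar, bo
                    )
                    D_one = D_oth + float(dev_full[k])
                dD_t[k] = max(0.0, D_null - D_one)

    F_g = dD_g / ((n_tx - 1) * s2_tilde)
    p_F = _f_sf(F_g, n_tx - 1, total_df)

    F_t = dD_t / s2_tilde[codes]
    sign = np.sign(b - beta_bar[codes])
    sign[sign == 0] = 1.0
    t_stat = np.sqrt(F_t) * sign
    p_t = _f_sf(F_t, 1.0, total_df[codes])
    p_simes = _grouped_simes(p_t, codes, G)

    rel_logfc = (b - beta_bar[codes]) / _LN2  # natural log -> log2

    genes_df = pd.DataFrame(
        {
            "gene_id": genes,
            "n_transcripts": n_tx,
            "F": F_g,
            "df1": n_tx - 1,
            "df2": total_df,
            "p_F": p_F,
            "fdr_F": bh_adjust(p_F),
            "p_simes": p_simes,
            "fdr_simes": bh_adjust(p_simes),
        }
    )
    tx_ids = (
        np.asarray(transcript_id, dtype=object)[keep_tx]
        if transcript_id is not None
        else np.array([f"tx{i}" for i in idx], dtype=object)
    )
    tx_df = pd.DataFrame(
        {
            "transcript_id": tx_ids,
            "gene_id": genes[codes],
            "rel_logFC": rel_logfc,
            "F": F_t,
            "t": t_stat,
            "p": p_t,
            "fdr": bh_adjust(p_t),
        }
    )
    return DTUResultTables(genes=genes_df, transcripts=tx_df, backend="nbglm", ebayes=eb)


def top_splice(
    tables: DTUResultTables,
    level: str = "gene-F",
    n: int | None = None,
    fdr_cutoff: float | None = None,
) -> pd.DataFrame:
    """Ranked results: ascending raw p with deterministic id tie-break."""
    if level == "gene-F":
        df, pcol, fcol, idcol = tables.genes, "p_F", "fdr_F", "gene_id"
    elif level == "gene-Simes":
        df, pcol, fcol, idcol = tables.genes, "p_simes", "fdr_simes", "gene_id"
    elif level == "transcript":
        df, pcol, fcol, idcol = tables.transcripts, "p", "fdr", "transcript_id"
    else:
        raise ValueError(f"unknown level {level!r}")
    out = df.sort_values([pcol, idcol], kind="stable").reset_index(drop=True)
    if fdr_cutoff is not None:
        out = out[out[fcol] <= fdr_cutoff]
    if n is not None:
        out = out.head(n)
    return out.reset_index(drop=True)
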