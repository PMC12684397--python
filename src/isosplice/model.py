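"""Model/Results interface tying the pipeline stages together.

``DTUModel`` holds the data (counts or a quantification bundle with technical
resamples, the transcript catalog, and a design matrix); ``fit`` runs RTA
estimation and division, expression filtering, TMM normalization, the chosen
per-transcript modelling backend, empirical Bayes moderation, and the DTU
tests, returning a ``DTUResults`` object with the gene- and transcript-level
tables, diagnostics, and a ``summary()``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import diffsplice_core, edger_fit, limma_fit, preprocess
from .io_formats import QuantBundle, TranscriptCatalog
from .preprocess import FilterSpec
from .rta import DividedCounts, RTAEstimate, divide_counts, estimate_rta_dispersion

__all__ = ["DTUModel", "DTUResults"]


@dataclass
class DTUResults:
    """Fitted DTU analysis: ranked tables, estimates, and diagnostics."""

    genes: pd.DataFrame
    transcripts: pd.DataFrame
    backend: str
    coef: int
    rta: RTAEstimate | None
    divided: DividedCounts
    keep_mask: np.ndarray
    fit: limma_fit.TranscriptFit
    ebayes: diffsplice_core.GeneEBayes
    phi: float | None = None
    tables: diffsplice_core.DTUResultTables | None = None

    def top_genes(self, n: int = 10, by: str = "F") -> pd.DataFrame:
        level = "gene-F" if by == "F" else "gene-Simes"
        return diffsplice_core.top_splice(self.tables, level=level, n=n)

    def top_transcripts(self, n: int = 10) -> pd.DataFrame:
        return diffsplice_core.top_splice(self.tables, level="transcript", n=n)

    def summary(self, fdr: float = 0.05) -> str:
        eb = self.ebayes
        lines = [
            "Differential transcript usage" ,
            "=" * 46,
            f"backend:               {self.backend}",
            f"transcripts tested:    {len(self.transcripts)}",
            f"genes tested:          {len(self.genes)}",
            f"prior df (eBayes):     {eb.prior_df:.4g}",
            f"prior variance:        {eb.prior_s2:.4g}",
        ]
        if self.phi is not None:
            lines.append(f"global NB dispersion:  {self.phi:.4g}")
        n_f = int((self.genes["fdr_F"] <= fdr).sum())
        n_s = int((self.genes["fdr_simes"] <= fdr).sum())
        n_t = int((self.transcripts["fdr"] <= fdr).sum())
        lines += [
            f"DTU genes (F, FDR<={fdr:g}):     {n_f}",
            f"DTU genes (Simes, FDR<={fdr:g}): {n_s}",
            f"DTU transcripts (FDR<={fdr:g}):  {n_t}",
            "-" * 46,
            "Top genes by moderated F:",
            self.top_genes(5).to_string(index=False),
        ]
        return "\n".join(lines)


class DTUModel:
    """Transcript-usage model for a two-or-more group RNA-seq experiment.

    Parameters
    ----------
    bundle : QuantBundle
        Estimated counts and (optionally) per-sample technical resamples.
    catalog : TranscriptCatalog
        Transcript-to-gene mapping, aligned to the bundle's rows.
    design : array-like, n_samples x p, full column rank
    groups : array-like of per-sample labels, optional
        Drives expression filtering and the zero-group residual-df penalty.
        Defaults to the design's second column when it is two-valued.
    tau : array-like, optional
        Known RTA dispersions; skips estimation from resamples.
    """

    def __init__(self, bundle: QuantBundle, catalog: TranscriptCatalog, design,
                 groups=None, tau=None):
        if bundle.n_transcripts != catalog.n_transcripts:
            raise ValueError("bundle and catalog have different numbers of transcripts")
        self.bundle = bundle
        self.catalog = catalog
        self.design = np.asarray(design, dtype=float)
        if self.design.ndim != 2 or self.design.shape[0] != bundle.n_samples:
            raise ValueError("design must be n_samples x p")
        if groups is None:
            col = self.design[:, -1]
            groups = col if len(np.unique(col)) <= max(2, self.design.shape[1]) else None
        self.groups = None if groups is None else np.asarray(groups)
        self.tau = None if tau is None else np.asarray(tau, dtype=float)

    @classmethod
    def from_dataframes(cls, counts: pd.DataFrame, catalog: pd.DataFrame, design, **kw):
        cat = TranscriptCatalog(
            transcript_id=catalog["transcript_id"].to_numpy(dtype=object),
            gene_id=catalog["gene_id"].to_numpy(dtype=object),
            length=catalog.get("length", pd.Series(np.full(len(catalog), 1000.0))).to_numpy(),
            effective_length=catalog.get(
                "effective_length", pd.Series(np.full(len(catalog), 1000.0))
            ).to_numpy(),
        )
        counts = counts.loc[list(cat.transcript_id)]
        bundle = QuantBundle(counts=counts.to_numpy(float),
                             sample_ids=[str(c) for c in counts.columns])
        return cls(bundle, cat, design, **kw)

    def fit(
        self,
        backend: str = "nbglm",
        coef: int = -1,
        filter_spec: FilterSpec | None = None,
        rta_prior_df: float = 3.0,
        rta_floor: float = 1.0,
        normalize: bool = True,
        winsorize: bool = False,
    ) -> DTUResults:
        if backend not in ("lm", "nbglm"):
            raise ValueError("backend must be 'lm' or 'nbglm'")
        X = self.design
        p = X.shape[1]
        coef = coef % p

        rta = self.rta_estimate(prior_df=rta_prior_df, floor=rta_floor)
        divided = divide_counts(self.bundle, rta) if rta is not None else DividedCounts(
            self.bundle.counts.copy(),
            self.bundle.counts.sum(axis=0),
            np.ones(self.bundle.n_samples),
        )

        if filter_spec is None:
            filter_spec = FilterSpec(group_labels=self.groups)
        elif filter_spec.group_labels is None and self.groups is not None:
            filter_spec = FilterSpec(
                min_count=filter_spec.min_count,
                min_total_count=filter_spec.min_total_count,
                group_labels=self.groups,
            )
        keep = preprocess.expression_filter(divided, filter_spec)

        if normalize:
            divided = preprocess.normalize(divided)
        kept = divided.subset(keep)
        gene_ids = self.catalog.gene_id[keep]
        tx_ids = self.catalog.transcript_id[keep]

        phi = None
        if backend == "lm":
            logcpm = limma_fit.logcpm_transform(kept)
            weights = limma_fit.voom_trend_weights(logcpm, X)
            fit = limma_fit.fit_weighted_lm(
                logcpm, X, weights, zero_counts=kept.z, groups=self.groups
            )
            tables = diffsplice_core.limma_diffsplice(
                fit, gene_ids, coef, transcript_id=tx_ids, winsorize=winsorize
            )
        else:
            phi = edger_fit.estimate_common_dispersion(kept, X).phi
            offsets = np.log(kept.effective_lib_sizes)
            fit = edger_fit.fit_nb_glm(kept, X, phi, offsets=offsets)
            tables = diffsplice_core.edger_diffsplice(
                kept.z, X, offsets, fit, gene_ids, coef, phi,
                transcript_id=tx_ids, winsorize=winsorize,
            )

        eb = tables.ebayes
        return DTUResults(
            genes=tables.genes,
            transcripts=tables.transcripts,
            backend=backend,
            coef=coef,
            rta=rta,
            divided=divided,
            keep_mask=keep,
            fit=fit,
            ebayes=eb,
            phi=phi,
            tables=tables,
        )

    def rta_estimate(self, prior_df: float = 3.0, floor: float = 1.0) -> RTAEstimate | None:
        if self.tau is not None:
            return RTAEstimate(
                tau_hat=self.tau,
                resample_df=np.zeros_like(self.tau),
                prior_df=prior_df,
                floored=np.zeros(self.tau.size, dtype=bool),
            )
        if self.bundle.resamples:
            return estimate_rta_dispersion(self.bundle, prior_df=prior_df, floor=floor)
        return None
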