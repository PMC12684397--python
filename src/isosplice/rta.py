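"""Read-to-transcript-ambiguity (RTA) overdispersion estimation and divided counts.

Estimated transcript counts are overdispersed relative to Poisson even under
pure technical resampling, because each read is compatible with several
overlapping transcripts and is assigned probabilistically.  That technical
overdispersion is quasi-Poisson: for transcript t the resampled counts satisfy
var = tau_t * mean with tau_t >= 1.  Dividing the counts by an estimate of
tau_t removes the technical component and restores negative-binomial-like
behaviour, so the divided counts can enter standard count pipelines.

The estimator here is a pooled Pearson-type quasi-Poisson statistic over
samples and resamples, shrunk towards 1 (no ambiguity) with a small prior df
and floored at 1 so that division never inflates counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_formats import QuantBundle

__all__ = ["RTAEstimate", "DividedCounts", "estimate_rta_dispersion", "divide_counts"]


@dataclass
class RTAEstimate:
    """Per-transcript RTA overdispersions with their resample degrees of freedom."""

    tau_hat: np.ndarray
    resample_df: np.ndarray
    prior_df: float
    floored: np.ndarray

    def to_frame(self, transcript_id=None):
        import pandas as pd

        df = pd.DataFrame(
            {"tau_hat": self.tau_hat, "resample_df": self.resample_df, "floored": self.floored}
        )
        if transcript_id is not None:
            df.insert(0, "transcript_id", np.asarray(transcript_id, dtype=object))
        return df


@dataclass
class DividedCounts:
    """RTA-divided counts z = y / tau with library-size bookkeeping.

    ``norm_factors`` start at 1 and are set by TMM normalization; the
    effective library size (the CPM denominator and GLM offset) is
    ``lib_sizes * norm_factors``.
    """

    z: np.ndarray
    lib_sizes: np.ndarray
    norm_factors: np.ndarray

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        self.lib_sizes = np.asarray(self.lib_sizes, dtype=float)
        self.norm_factors = np.asarray(self.norm_factors, dtype=float)

    @property
    def effective_lib_sizes(self) -> np.ndarray:
        return self.lib_sizes * self.norm_factors

    @property
    def n_samples(self) -> int:
        return self.z.shape[1]

    def subset(self, mask: np.ndarray) -> "DividedCounts":
        """Row-subset the count matrix, keeping library sizes fixed.

        Library sizes deliberately stay those of the full transcriptome so
        that filtering does not change the CPM scale.
        """
        return DividedCounts(self.z[mask], self.lib_sizes.copy(), self.norm_factors.copy())


def estimate_rta_dispersion(
    bundle: QuantBundle, prior_df: float = 3.0, floor: float = 1.0
) -> RTAEstimate:
    """Estimate per-transcript RTA overdispersions from technical resamples.

    For transcript t, pooling over samples i with positive resample mean::

        D_t = sum_i sum_b (y_tib - ybar_ti)^2 / ybar_ti
        r_t = sum_i (B - 1) * 1[ybar_ti > 0]
        tau_t = max(floor, (D_t + prior_df * 1) / (r_t + prior_df))

    Samples whose resample mean is zero for a transcript carry no information
    (the Pearson term is 0/0) and contribute no df.  Transcripts with r_t = 0
    get tau = floor.
    """
    if not bundle.resamples:
        raise ValueError("bundle has no resample matrices; RTA estimation impossible")
    B = bundle.n_resamples
    if B < 2:
        raise ValueError("at least 2 resamples per sample are required")
    T = bundle.n_transcripts
    D = np.zeros(T)
    r = np.zeros(T)
    for mat in bundle.resamples:
        mat = np.asarray(mat, dtype=float)
        if np.any(mat < 0):
            raise ValueError("negative resample values")
        mean = mat.mean(axis=1)
        pos = mean > 0
        ss = ((mat[pos] - mean[pos, None]) ** 2).sum(axis=1)
        D[pos] += ss / mean[pos]
        r[pos] += B - 1
    raw = (D + prior_df * 1.0) / (r + prior_df)
    tau = np.maximum(floor, raw)
    return RTAEstimate(
        tau_hat=tau, resample_df=r, prior_df=prior_df, floored=raw < floor
    )


def divide_counts(bundle: QuantBundle, rta: RTAEstimate) -> DividedCounts:
    """Divide estimated counts row-wise by the RTA overdispersions."""
    tau = np.asarray(rta.tau_hat, dtype=float)
    if tau.shape[0] != bundle.n_transcripts:
        raise ValueError("tau vector does not match number of transcripts")
    if np.any(tau <= 0):
        raise ValueError("tau must be positive")
    z = bundle.counts / tau[:, None]
    lib = z.sum(axis=0)
    return DividedCounts(z=z, lib_sizes=lib, norm_factors=np.ones(bundle.n_samples))
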