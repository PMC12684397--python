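"""Expression filtering and TMM library-size normalization on divided counts.

Filtering keeps a transcript when it is expressed at a worthwhile level in at
least as many samples as the smallest experimental group, plus a minimum total
count; the worthwhile level is a CPM cutoff derived from the median library
size so that the rule is expressed on the count scale.  Normalization uses the
trimmed mean of M-values (TMM): per-sample log-ratio means against a reference
sample after trimming extreme log-ratios and extreme-abundance rows, weighted
by delta-method precisions, then rescaled so the factors have geometric mean 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .rta import DividedCounts

__all__ = ["FilterSpec", "expression_filter", "tmm_norm_factors", "effective_lib_sizes"]

_EPS = 1e-10


@dataclass
class FilterSpec:
    """Low-expression filtering rule.

    ``lenient()`` gives the relaxed rule (min_count=1, min_total_count=5)
    that retains transcripts with at least 1 count in at least half the
    samples of a balanced two-group design.
    """

    min_count: float = 10.0
    min_total_count: float = 15.0
    group_labels: np.ndarray | None = field(default=None)

    @classmethod
    def lenient(cls, group_labels=None) -> "FilterSpec":
        return cls(min_count=1.0, min_total_count=5.0, group_labels=group_labels)


def expression_filter(z: DividedCounts, spec: FilterSpec) -> np.ndarray:
    """Boolean keep-mask over transcripts.

    Keep a transcript iff its CPM (on effective library sizes) reaches the
    cutoff ``min_count * 1e6 / median(effective lib)`` in at least ``n_min``
    samples, where n_min is the smallest group size, and its total divided
    count is at least ``min_total_count``.
    """
    if spec.group_labels is None:
        labels = np.zeros(z.n_samples, dtype=int)
    else:
        labels = np.asarray(spec.group_labels)
        if labels.shape[0] != z.n_samples:
            raise ValueError("group labels do not cover all samples")
    _, counts_per_group = np.unique(labels, return_counts=True)
    n_min = int(counts_per_group.min())

    eff = z.effective_lib_sizes
    med = np.median(eff)
    cutoff = spec.min_count * 1e6 / med
    cpm = z.z / eff[None, :] * 1e6
    enough_samples = (cpm >= cutoff * (1 - _EPS)).sum(axis=1) >= n_min
    enough_total = z.z.sum(axis=1) >= spec.min_total_count * (1 - _EPS)
    keep = enough_samples & enough_total
    if not keep.any():
        warnings.warn("expression filter removed every transcript", stacklevel=2)
    return keep


def tmm_norm_factors(z: DividedCounts, trim_m: float = 0.30, trim_a: float = 0.05) -> np.ndarray:
    """Trimmed-mean-of-M-values normalization factors, geometric mean 1.

    The reference is the sample whose upper-quartile CPM is closest to the
    mean upper-quartile.  For each sample, rows positive in both the sample
    and the reference contribute M = log2 CPM ratio and A = mean log2 CPM;
    the top/bottom ``trim_m`` of M and ``trim_a`` of A are discarded and the
    remaining M are averaged with inverse delta-method variances as weights.
    """
    y = z.z
    lib = z.lib_sizes
    n = y.shape[1]
    if n < 2:
        raise ValueError("TMM requires at least 2 samples")
    if np.any(lib <= 0):
        raise ValueError("library sizes must be positive")

    cpm = y / lib[None, :] * 1e6
    uq = np.array([np.quantile(cpm[:, i], 0.75) for i in range(n)])
    ref = int(np.argmin(np.abs(uq - uq.mean())))

    log_factors = np.zeros(n)
    for s in range(n):
        if s == ref:
            continue
        pos = (y[:, s] > 0) & (y[:, ref] > 0)
        if not pos.any():
            warnings.warn(
                f"sample {s} shares no positive transcripts with the reference; factor set to 1",
                stacklevel=2,
            )
            continue
        ys, yr = y[pos, s], y[pos, ref]
        ps, pr = ys / lib[s], yr / lib[ref]
        m = np.log2(ps / pr)
        a = 0.5 * np.log2(ps * pr)
        # asymptotic binomial delta-method variance of M
        v = (lib[s] - ys) / (lib[s] * ys) + (lib[ref] - yr) / (lib[ref] * yr)

        k = m.size
        rank_m = np.argsort(np.argsort(m, kind="stable"), kind="stable")
        rank_a = np.argsort(np.argsort(a, kind="stable"), kind="stable")
        lo_m, hi_m = np.floor(k * trim_m), np.ceil(k * (1 - trim_m))
        lo_a, hi_a = np.floor(k * trim_a), np.ceil(k * (1 - trim_a))
        keep = (rank_m >= lo_m) & (rank_m < hi_m) & (rank_a >= lo_a) & (rank_a < hi_a)
        if not keep.any():
            continue
        w = 1.0 / np.maximum(v[keep], 1e-12)
        f = np.sum(w * m[keep]) / np.sum(w)
        if np.isfinite(f) and abs(f) > 1e-10:
            log_factors[s] = f
    factors = 2.0 ** (log_factors - log_factors.mean())
    return factors


def effective_lib_sizes(z: DividedCounts) -> np.ndarray:
    """Library sizes times normalization factors."""
    return z.lib_sizes * z.norm_factors


def normalize(z: DividedCounts) -> DividedCounts:
    """Return a copy of ``z`` with TMM normalization factors set."""
    factors = tmm_norm_factors(z)
    return DividedCounts(z.z.copy(), z.lib_sizes.copy(), factors)
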