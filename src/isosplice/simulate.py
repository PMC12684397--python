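"""Count-level synthetic data with known differential-transcript-usage truth.

The generator emulates a two-group bulk RNA-seq experiment at the transcript
level.  True per-sample TPMs are gamma distributed around each transcript's
expected TPM with a transcript-specific squared coefficient of variation
(squared BCV) drawn from a scaled inverse chi-squared distribution
(scale prior_bcv^2, df bcv_df).  Expected read counts follow from the
library size and the TPM-times-effective-length nucleotide shares.  Technical
read-to-transcript ambiguity is emulated at the count level: each transcript
has a quasi-Poisson factor tau (1 for unambiguous transcripts) and observed
counts are tau times a Poisson draw with mean mu/tau, so var = tau * mu given
mu.  Technical resamples re-draw counts the same way around the observed
count.

Three differential configurations plus a null are supported: DTU-only genes
swap the expected TPM of two transcripts between groups (each changes exactly
two-fold; the gene total is conserved), DGE+DTU genes change one transcript
two-fold, and DGE-only genes change every transcript two-fold (no usage
change).  Up- and down-regulation are assigned in balance.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io_formats import QuantBundle, TranscriptCatalog

__all__ = [
    "SimConfig",
    "SimTruth",
    "SimDataset",
    "build_catalog",
    "draw_dispersions",
    "assign_truth",
    "simulate_counts_and_resamples",
    "simulate_dataset",
    "write_fixture_bundle",
    "evaluate_performance",
]


@dataclass
class SimConfig:
    """Simulation settings.

    Defaults mirror a full-scale two-group experiment: 12715 genes, 4500
    genes carrying differential signal split equally between DTU-only,
    DGE+DTU, and DGE-only, two-fold changes, prior BCV 0.25 with 40 df, and
    unbalanced library sizes alternating between 25 and 100 million reads.
    ``desk_scale()`` gives a proportionally scaled-down configuration (3000
    genes, 1 million reads) suitable for laptop-sized runs.
    """

    n_genes: int = 12715
    n_de_genes: int = 4500
    split: tuple[int, int, int] = (1500, 1500, 1500)  # dtu_only, dge_dtu, dge_only
    fold_change: float = 2.0
    prior_bcv: float = 0.25
    bcv_df: float = 40.0
    samples_per_group: int = 5
    lib_sizes: tuple[float, float] = (25e6, 100e6)
    resamples: int = 100
    seed: int = 0
    # transcript catalog shape
    mean_transcripts: float = 3.3
    max_transcripts: int = 10
    tpm_lognorm_mean: float = 1.5
    tpm_lognorm_sigma: float = 2.0
    efflen_range: tuple[float, float] = (300.0, 10000.0)
    # RTA emulation: tau = 1 with prob_unambiguous, else 1 + Gamma(shape, scale)
    prob_unambiguous: float = 0.5
    tau_gamma_shape: float = 1.0
    tau_gamma_scale: float = 1.5

    def __post_init__(self) -> None:
        if sum(self.split) != self.n_de_genes:
            raise ValueError("split must sum to n_de_genes")
        if self.fold_change <= 1:
            raise ValueError("fold_change must exceed 1")

    @classmethod
    def desk_scale(cls, seed: int = 0, **kwargs) -> "SimConfig":
        n_genes = kwargs.pop("n_genes", 3000)
        frac = n_genes / 12715
        per = int(round(1500 * frac))
        defaults = dict(
            n_genes=n_genes,
            n_de_genes=3 * per,
            split=(per, per, per),
            lib_sizes=(1e6, 1e6),
            seed=seed,
        )
        defaults.update(kwargs)
        return cls(**defaults)


@dataclass
class SimTruth:
    """Ground-truth bookkeeping for one simulated dataset.

    DTU-only genes flag exactly the two swapped transcripts as differentially
    used; DGE+DTU genes flag all their transcripts (changing one transcript's
    absolute level changes every transcript's proportion); DGE-only genes
    flag none.
    """

    gene_category: pd.Series  # index gene_id, values in {null, dtu_only, dge_dtu, dge_only}
    is_de: np.ndarray  # per transcript
    is_dtu: np.ndarray  # per transcript
    direction: np.ndarray  # per transcript, +1 up in group B, -1 down, 0 unchanged
    expected_tpm: np.ndarray  # transcripts x 2 (group A, group B)

    def dtu_genes(self) -> set:
        return set(self.gene_category.index[self.gene_category.isin(["dtu_only", "dge_dtu"])])


@dataclass
class SimDataset:
    """Everything downstream stages need from one simulated experiment."""

    config: SimConfig
    catalog: TranscriptCatalog
    truth: SimTruth
    bundle: QuantBundle
    tau: np.ndarray
    groups: np.ndarray
    design: np.ndarray
    phi_t: np.ndarray


def build_catalog(config: SimConfig, rng: np.random.Generator):
    """Transcript catalog plus baseline expected TPM per transcript.

    Transcripts per gene follow a zero-truncated geometric distribution with
    mean ~= ``mean_transcripts``, capped at ``max_transcripts``; baseline
    TPMs are heavy-tailed log-normal draws normalized to total 1e6;
    effective lengths are log-uniform over ``efflen_range``.
    """
    q = 1.0 / config.mean_transcripts
    per_gene = np.minimum(rng.geometric(q, size=config.n_genes), config.max_transcripts)
    gene_ids = np.repeat(
        np.array([f"gene{i + 1:06d}" for i in range(config.n_genes)], dtype=object), per_gene
    )
    T = int(per_gene.sum())
    tx_ids = np.array([f"tx{i + 1:07d}" for i in range(T)], dtype=object)
    efflen = np.exp(
        rng.uniform(np.log(config.efflen_range[0]), np.log(config.efflen_range[1]), size=T)
    )
    length = np.round(efflen + 200.0)
    catalog = TranscriptCatalog(
        transcript_id=tx_ids, gene_id=gene_ids, length=length, effective_length=efflen
    )
    baseline = rng.lognormal(config.tpm_lognorm_mean, config.tpm_lognorm_sigma, size=T)
    baseline *= 1e6 / baseline.sum()
    return catalog, baseline


def draw_dispersions(config: SimConfig, n: int, rng: np.random.Generator) -> np.ndarray:
    """Per-transcript squared BCV from a scaled inverse chi-squared law.

    phi_t = bcv_df * prior_bcv^2 / X with X ~ chi^2_{bcv_df}, i.e.
    bcv_df * prior_bcv^2 / phi_t is chi-squared on bcv_df df.
    """
    x = rng.chisquare(config.bcv_df, size=n)
    return config.bcv_df * config.prior_bcv**2 / x


def assign_truth(
    catalog: TranscriptCatalog,
    baseline_tpm: np.ndarray,
    config: SimConfig,
    rng: np.random.Generator,
    null_mode: bool = False,
) -> SimTruth:
    """Assign differential categories and build per-group expected TPMs."""
    T = catalog.n_transcripts
    baseline = np.asarray(baseline_tpm, dtype=float)
    expected = np.column_stack([baseline.copy(), baseline.copy()])
    is_de = np.zeros(T, dtype=bool)
    is_dtu = np.zeros(T, dtype=bool)
    direction = np.zeros(T, dtype=int)

    genes, codes = np.unique(catalog.gene_id, return_inverse=True)
    category = pd.Series("null", index=genes, dtype=object)

    if not null_mode:
        tx_count = np.bincount(codes)
        multi = np.flatnonzero(tx_count >= 2)
        n_needed = config.n_de_genes
        if multi.size < n_needed:
            raise ValueError(
                f"split requires {n_needed} multi-transcript genes; only {multi.size} available"
            )
        chosen = rng.choice(multi, size=n_needed, replace=False)
        n_dtu, n_both, n_dge = config.split
        cat_codes = (["dtu_only"] * n_dtu + ["dge_dtu"] * n_both + ["dge_only"] * n_dge)
        fc = config.fold_change

        tx_by_gene = pd.Series(np.arange(T)).groupby(codes).apply(lambda s: s.to_numpy())

        for gi, cat in zip(chosen, cat_codes):
            category.iloc[gi] = cat
            members = tx_by_gene[gi]
            up = rng.random() < 0.5
            if cat == "dtu_only":
                pair = rng.choice(members, size=2, replace=False)
                t1, t2 = int(pair[0]), int(pair[1])
                s = baseline[t1] + baseline[t2]
                lo, hi = s / (1.0 + fc), s * fc / (1.0 + fc)
                expected[t1, 0], expected[t2, 0] = lo, hi
                expected[t1, 1], expected[t2, 1] = hi, lo  # swapped in group B
                is_dtu[[t1, t2]] = True
                is_de[[t1, t2]] = True
                direction[t1], direction[t2] = 1, -1
            elif cat == "dge_dtu":
                t1 = int(rng.choice(members))
                mult = fc if up else 1.0 / fc
                expected[t1, 1] = baseline[t1] * mult
                is_de[t1] = True
                is_dtu[members] = True
                direction[t1] = 1 if up else -1
            else:  # dge_only
                mult = fc if up else 1.0 / fc
                expected[members, 1] = baseline[members] * mult
                is_de[members] = True
                direction[members] = 1 if up else -1

    return SimTruth(
        gene_category=category,
        is_de=is_de,
        is_dtu=is_dtu,
        direction=direction,
        expected_tpm=expected,
    )


def simulate_counts_and_resamples(
    truth: SimTruth,
    catalog: TranscriptCatalog,
    phi_t: np.ndarray,
    config: SimConfig,
    rng: np.random.Generator,
):
    """Generate the count matrix, per-sample resample stacks, and true taus.

    Per sample: TPM* ~ Gamma(shape 1/phi_t, mean = group expected TPM);
    expected reads mu = lib * TPM*-length share; observed count
    y = tau * Poisson(mu / tau); resamples redraw tau * Poisson(y / tau).
    Counts stay fractional (quantifier-style), no re-rounding of the
    tau-scaled draws.
    """
    T = catalog.n_transcripts
    n_per = config.samples_per_group
    n = 2 * n_per
    groups = np.repeat([0, 1], n_per)
    libs = np.array([config.lib_sizes[i % 2] for i in range(n)], dtype=float)

    unamb = rng.random(T) < config.prob_unambiguous
    tau = np.where(
        unamb,
        1.0,
        1.0 + rng.gamma(config.tau_gamma_shape, config.tau_gamma_scale, size=T),
    )

    shape = 1.0 / np.maximum(phi_t, 1e-12)
    counts = np.empty((T, n))
    resamples = []
    efflen = catalog.effective_length
    for i in range(n):
        exp_tpm = truth.expected_tpm[:, groups[i]]
        tpm_star = np.where(
            exp_tpm > 0, rng.gamma(shape, 1.0) / shape * exp_tpm, 0.0
        )
        nt = tpm_star * efflen
        mu = libs[i] * nt / nt.sum()
        y = tau * rng.poisson(mu / tau)
        counts[:, i] = y
        res = tau[:, None] * rng.poisson(
            np.broadcast_to((y / tau)[:, None], (T, config.resamples))
        )
        resamples.append(res.astype(float))
    bundle = QuantBundle(
        counts=counts,
        resamples=resamples,
        sample_ids=[f"sample{i + 1:02d}" for i in range(n)],
    )
    return bundle, tau, groups


def simulate_dataset(config: SimConfig, null_mode: bool = False) -> SimDataset:
    """Run the whole generator for one seed."""
    rng = np.random.default_rng(config.seed)
    catalog, baseline = build_catalog(config, rng)
    phi_t = draw_dispersions(config, catalog.n_transcripts, rng)
    truth = assign_truth(catalog, baseline, config, rng, null_mode=null_mode)
    bundle, tau, groups = simulate_counts_and_resamples(truth, catalog, phi_t, config, rng)
    design = np.column_stack([np.ones(groups.size), groups.astype(float)])
    return SimDataset(
        config=config,
        catalog=catalog,
        truth=truth,
        bundle=bundle,
        tau=tau,
        groups=groups,
        design=design,
        phi_t=phi_t,
    )


def write_fixture_bundle(
    data: SimDataset, out_dir: str | Path, force: bool = False
) -> list[Path]:
    """Write the dataset as quant tables, resample TSVs, catalog, truth, config."""
    out_dir = Path(out_dir)
    if out_dir.exists() and any(out_dir.iterdir()) and not force:
        raise FileExistsError(f"{out_dir} is not empty (use force=True to overwrite)")
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    cat = data.catalog
    counts = data.bundle.counts
    efflen = cat.effective_length
    for i, sample in enumerate(data.bundle.sample_ids):
        y = counts[:, i]
        nt = y / efflen
        tpm = nt / nt.sum() * 1e6 if nt.sum() > 0 else nt
        qdf = pd.DataFrame(
            {
                "Name": cat.transcript_id,
                "Length": cat.length.astype(int),
                "EffectiveLength": efflen,
                "TPM": tpm,
                "NumReads": y,
            }
        )
        qpath = out_dir / f"{sample}.sf"
        qdf.to_csv(qpath, sep="\t", index=False, float_format="%.6f")
        written.append(qpath)
        res = data.bundle.resamples[i]
        rdf = pd.DataFrame(res, columns=[f"rep{b + 1}" for b in range(res.shape[1])])
        rdf.insert(0, "Name", cat.transcript_id)
        rpath = out_dir / f"{sample}_boot.tsv"
        rdf.to_csv(rpath, sep="\t", index=False, float_format="%.6f")
        written.append(rpath)
    cpath = out_dir / "catalog.tsv"
    cat.to_frame().to_csv(cpath, sep="\t", index=False, float_format="%.6f")
    written.append(cpath)
    tpath = out_dir / "truth.tsv"
    pd.DataFrame(
        {
            "transcript_id": cat.transcript_id,
            "gene_id": cat.gene_id,
            "category": data.truth.gene_category.loc[cat.gene_id].to_numpy(),
            "is_de": data.truth.is_de.astype(int),
            "is_dtu": data.truth.is_dtu.astype(int),
            "direction": data.truth.direction,
            "true_tau": data.tau,
        }
    ).to_csv(tpath, sep="\t", index=False, float_format="%.6f")
    written.append(tpath)
    jpath = out_dir / "config.json"
    jpath.write_text(json.dumps(dataclasses.asdict(data.config), indent=2, sort_keys=True))
    written.append(jpath)
    return written


def evaluate_performance(
    results, truth: SimTruth, cutoffs=(0.05,), catalog: TranscriptCatalog | None = None
) -> pd.DataFrame:
    """Observed FDR, power, and type I error against the simulation truth.

    For each level (gene-F, gene-Simes, transcript) and cutoff: discoveries
    are features with BH-adjusted p <= cutoff; FDR = FP / max(1, TP + FP),
    power = TP / positives; the type I error is the fraction of raw p <=
    cutoff among features that are truly null at that level.  ``catalog``
    (or a prior :func:`attach_transcript_index` call) aligns transcript ids.
    """
    dtu_genes = truth.dtu_genes()
    gene_cat = truth.gene_category
    if catalog is not None:
        attach_transcript_index(truth, catalog)

    rows = []
    for level in ("gene-F", "gene-Simes", "transcript"):
        if level == "transcript":
            df = results.transcripts
            ids = df["transcript_id"].to_numpy()
            truth_tx = getattr(truth, "_tx_index", None)
            if truth_tx is None:
                raise ValueError(
                    "transcript-level evaluation needs a catalog to align transcript ids"
                )
            aligned = truth_tx.reindex(ids)["is_dtu"]
            if aligned.isna().any():
                raise ValueError("result/truth transcript id mismatch")
            pos_mask = aligned.to_numpy(dtype=bool)
            praw = df["p"].to_numpy()
            padj = df["fdr"].to_numpy()
            n_pos_total = int(truth.is_dtu.sum())
        else:
            df = results.genes
            ids = df["gene_id"].to_numpy()
            missing = [g for g in ids if g not in gene_cat.index]
            if missing:
                raise ValueError(f"gene id {missing[0]!r} absent from truth")
            pos_mask = np.array([g in dtu_genes for g in ids])
            pcol, fcol = ("p_F", "fdr_F") if level == "gene-F" else ("p_simes", "fdr_simes")
            praw = df[pcol].to_numpy()
            padj = df[fcol].to_numpy()
            n_pos_total = int(gene_cat.isin(["dtu_only", "dge_dtu"]).sum())
        null_mask = ~pos_mask
        for cutoff in cutoffs:
            called = padj <= cutoff
            tp = int((called & pos_mask).sum())
            fp = int((called & null_mask).sum())
            type1 = float((praw[null_mask] <= cutoff).mean()) if null_mask.any() else np.nan
            rows.append(
                {
                    "level": level,
                    "cutoff": cutoff,
                    "TP": tp,
                    "FP": fp,
                    "FDR": fp / max(1, tp + fp),
                    "power": tp / n_pos_total if n_pos_total else np.nan,
                    "type1": type1,
                }
            )
    return pd.DataFrame(rows)


def attach_transcript_index(truth: SimTruth, catalog: TranscriptCatalog) -> SimTruth:
    """Attach a transcript-id index so transcript-level evaluation can align ids."""
    truth._tx_index = pd.DataFrame(
        {"is_dtu": truth.is_dtu}, index=pd.Index(catalog.transcript_id)
    )
    return truth


def cumulative_false_discoveries(results, truth: SimTruth, level: str = "gene-F") -> np.ndarray:
    """Cumulative count of false discoveries down the p-ranked feature list."""
    if level == "transcript":
        df = results.transcripts.sort_values(["p", "transcript_id"], kind="stable")
        truth_tx = getattr(truth, "_tx_index", None)
        if truth_tx is None:
            raise ValueError("call attach_transcript_index first")
        is_false = ~truth_tx.reindex(df["transcript_id"])["is_dtu"].to_numpy(dtype=bool)
    else:
        pcol = "p_F" if level == "gene-F" else "p_simes"
        df = results.genes.sort_values([pcol, "gene_id"], kind="stable")
        dtu = truth.dtu_genes()
        is_false = np.array([g not in dtu for g in df["gene_id"]])
    return np.cumsum(is_false)
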