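"""Readers and writers for the external file formats the pipeline touches.

Transcript quantifications arrive as the quantifier's standard five-column
tab-separated table (``Name``, ``Length``, ``EffectiveLength``, ``TPM``,
``NumReads``); technical resamples as plain TSV matrices with one file per
sample (first column ``Name``, then ``rep1..repB``); the transcript-to-gene
catalog as a two-column TSV with optional length columns.  Compressed binary
resample serializations are deliberately not parsed -- users convert upstream.

All matrices are oriented transcripts-in-rows, samples-in-columns.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "TranscriptCatalog",
    "QuantBundle",
    "FormatError",
    "read_quant_table",
    "read_resample_matrix",
    "read_catalog",
    "read_design",
    "load_quant_bundle",
    "write_result_table",
]

QUANT_COLUMNS = ["Name", "Length", "EffectiveLength", "TPM", "NumReads"]


class FormatError(ValueError):
    """Raised when an input file does not follow the expected dialect."""


@dataclass
class TranscriptCatalog:
    """Transcript-to-gene mapping with annotation and effective lengths.

    Every transcript maps to exactly one gene; transcript ids are unique and
    effective lengths are strictly positive.
    """

    transcript_id: np.ndarray
    gene_id: np.ndarray
    length: np.ndarray
    effective_length: np.ndarray

    def __post_init__(self) -> None:
        self.transcript_id = np.asarray(self.transcript_id, dtype=object)
        self.gene_id = np.asarray(self.gene_id, dtype=object)
        self.length = np.asarray(self.length, dtype=float)
        self.effective_length = np.asarray(self.effective_length, dtype=float)
        if len(set(self.transcript_id)) != self.n_transcripts:
            raise FormatError("duplicate transcript ids in catalog")
        if np.any(self.effective_length <= 0):
            raise FormatError("effective lengths must be positive")

    @property
    def n_transcripts(self) -> int:
        return len(self.transcript_id)

    @property
    def n_genes(self) -> int:
        return len(set(self.gene_id))

    def transcripts_per_gene(self) -> pd.Series:
        return pd.Series(1, index=self.gene_id).groupby(level=0).sum()

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "transcript_id": self.transcript_id,
                "gene_id": self.gene_id,
                "length": self.length,
                "effective_length": self.effective_length,
            }
        )


@dataclass
class QuantBundle:
    """Estimated transcript counts plus per-sample technical resample stacks.

    ``counts`` is transcripts x samples (estimated counts may be fractional);
    ``resamples`` holds one transcripts x B matrix per sample in the same
    transcript order.
    """

    counts: np.ndarray
    resamples: list[np.ndarray] = field(default_factory=list)
    sample_ids: list[str] = field(default_factory=list)
    lib_sizes: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D transcripts x samples matrix")
        if not np.all(np.isfinite(self.counts)) or np.any(self.counts < 0):
            raise ValueError("counts must be finite and non-negative")
        if not self.sample_ids:
            self.sample_ids = [f"sample{i + 1}" for i in range(self.counts.shape[1])]
        if self.lib_sizes is None:
            self.lib_sizes = self.counts.sum(axis=0)
        self.lib_sizes = np.asarray(self.lib_sizes, dtype=float)

    @property
    def n_transcripts(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    @property
    def n_resamples(self) -> int:
        if not self.resamples:
            return 0
        return self.resamples[0].shape[1]


def _read_tsv(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    return pd.read_csv(path, sep="\t")


def read_quant_table(path: str | Path) -> pd.DataFrame:
    """Read one sample's quantification table.

    Returns a DataFrame with the five standard columns in file row order.
    ``NumReads`` may be fractional.  Missing or renamed columns raise
    :class:`FormatError` naming the first offending column; non-numeric cells
    raise :class:`FormatError` with the 1-based data row number.
    """
    df = _read_tsv(path)
    for col in QUANT_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    df = df[QUANT_COLUMNS].copy()
    for col in QUANT_COLUMNS[1:]:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0]) + 1
            raise FormatError(f"{path}: non-numeric value in column {col!r} at row {row}")
        df[col] = coerced.astype(float)
    df["Name"] = df["Name"].astype(str)
    return df.reset_index(drop=True)


def read_resample_matrix(path: str | Path, expected_ids) -> np.ndarray:
    """Read a transcripts x B resample matrix and align rows to ``expected_ids``.

    The first column holds transcript ids; the remaining B >= 2 columns are
    numeric resampled counts.
    """
    df = _read_tsv(path)
    if df.shape[1] < 3:
        raise FormatError(
            f"{path}: at least 2 resample columns required for RTA estimation, "
            f"found {df.shape[1] - 1}"
        )
    ids = df.iloc[:, 0].astype(str)
    expected = list(expected_ids)
    index = pd.Index(ids)
    missing = [t for t in expected if t not in index]
    if missing or len(index) != len(expected):
        name = missing[0] if missing else "(extra rows present)"
        raise FormatError(f"{path}: transcript ids do not match catalog; first missing: {name}")
    values = df.iloc[:, 1:].to_numpy(dtype=float)
    order = index.get_indexer(expected)
    return values[order]


def read_catalog(path: str | Path, strip_versions: bool = False) -> TranscriptCatalog:
    """Read a transcript-to-gene catalog TSV.

    Columns: ``transcript_id``, ``gene_id``, optional ``length`` and
    ``effective_length`` (both default to 1000 nt when absent).  With
    ``strip_versions`` a trailing ``.N`` version suffix is removed from
    transcript ids; the default is exact string matching.
    """
    df = _read_tsv(path)
    if df.shape[1] < 2:
        raise FormatError(f"{path}: catalog needs at least transcript_id and gene_id columns")
    cols = list(df.columns)
    tx = df[cols[0]].astype(str)
    if strip_versions:
        tx = tx.map(lambda s: re.sub(r"\.\d+$", "", s))
    length = df[cols[2]].to_numpy(float) if len(cols) > 2 else np.full(len(df), 1000.0)
    efflen = df[cols[3]].to_numpy(float) if len(cols) > 3 else np.full(len(df), 1000.0)
    return TranscriptCatalog(
        transcript_id=tx.to_numpy(dtype=object),
        gene_id=df[cols[1]].astype(str).to_numpy(dtype=object),
        length=length,
        effective_length=efflen,
    )


def read_design(path: str | Path, formula: str | None = None) -> pd.DataFrame:
    """Read a design matrix.

    Without ``formula`` the TSV is taken to be a prebuilt numeric matrix
    (sample rows, coefficient columns).  With ``formula`` the TSV is a
    covariate table and the design is built with patsy-style dmatrix via
    statsmodels' formula machinery.
    """
    df = _read_tsv(path)
    if formula is None:
        return df.apply(pd.to_numeric)
    import patsy  # statsmodels dependency

    mat = patsy.dmatrix(formula, df, return_type="dataframe")
    return mat


def load_quant_bundle(
    quant_dir: str | Path,
    catalog: TranscriptCatalog,
    resample_suffix: str = "_boot.tsv",
    quant_suffix: str = ".sf",
    strip_versions: bool = False,
) -> QuantBundle:
    """Assemble a :class:`QuantBundle` from a directory of per-sample files.

    For every quant table ``<sample><quant_suffix>`` a matching resample file
    ``<sample><resample_suffix>`` is read if present.  Rows are aligned to the
    catalog's transcript order.
    """
    quant_dir = Path(quant_dir)
    quant_files = sorted(quant_dir.glob(f"*{quant_suffix}"))
    if not quant_files:
        raise FileNotFoundError(f"no *{quant_suffix} files under {quant_dir}")
    expected = list(catalog.transcript_id)
    counts, resamples, sample_ids = [], [], []
    for qf in quant_files:
        sample = qf.name[: -len(quant_suffix)]
        df = read_quant_table(qf)
        names = df["Name"]
        if strip_versions:
            names = names.map(lambda s: re.sub(r"\.\d+$", "", s))
        index = pd.Index(names)
        order = index.get_indexer(expected)
        if (order < 0).any():
            missing = expected[int(np.flatnonzero(order < 0)[0])]
            raise FormatError(f"{qf}: transcript {missing!r} absent from quantification")
        counts.append(df["NumReads"].to_numpy(float)[order])
        sample_ids.append(sample)
        rf = quant_dir / f"{sample}{resample_suffix}"
        if rf.exists():
            resamples.append(read_resample_matrix(rf, expected))
    if resamples and len(resamples) != len(counts):
        raise FormatError("resample files present for only a subset of samples")
    return QuantBundle(
        counts=np.column_stack(counts), resamples=resamples, sample_ids=sample_ids
    )


def write_result_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write a ranked result table as TSV with 12 significant digits."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, sep="\t", index=False, float_format="%.12g")
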