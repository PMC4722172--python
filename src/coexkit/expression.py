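"""From mapped-read counts to a Mutual-Rank coexpression table.

The pipeline follows the ATTED-II RNA-seq construction recipe:

1. drop sequencing runs with fewer than ten million mapped reads,
2. drop genes whose highest count across the surviving runs is below 100,
3. ``log2(count + 0.125)``,
4. quantile normalization within each experiment's runs,
5. mean-center every gene row,
6. Pearson correlation between all gene pairs,
7. convert correlations to Mutual Ranks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .coextable import CoexpressionTable

__all__ = [
    "CountMatrix",
    "ExpressionMatrix",
    "EmptyResultError",
    "preprocess_counts",
    "quantile_normalize",
    "correlation_matrix",
    "mutual_rank",
]


class EmptyResultError(ValueError):
    """Raised when filtering removes every run (or every gene)."""


@dataclass
class CountMatrix:
    """Gene x run matrix of non-negative mapped-read counts.

    ``experiment_of_run`` assigns every sequencing run to an experiment;
    quantile normalization later operates within these groups.
    """

    counts: pd.DataFrame
    experiment_of_run: Mapping[str, str]

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            raise ValueError("duplicate gene identifiers in count matrix")
        if self.counts.columns.has_duplicates:
            raise ValueError("duplicate run identifiers in count matrix")
        missing = [r for r in self.counts.columns if r not in self.experiment_of_run]
        if missing:
            raise ValueError(f"runs without an experiment label: {missing}")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def run_ids(self) -> list[str]:
        return list(self.counts.columns)

    def to_tsv(self, matrix_path, run_meta_path=None) -> None:
        self.counts.to_csv(matrix_path, sep="\t", index_label="gene")
        if run_meta_path is not None:
            meta = pd.DataFrame(
                {"run_id": self.run_ids,
                 "experiment_id": [self.experiment_of_run[r] for r in self.run_ids]}
            )
            meta.to_csv(run_meta_path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, matrix_path, run_meta_path=None) -> "CountMatrix":
        df = pd.read_csv(matrix_path, sep="\t", index_col=0)
        df.index = df.index.astype(str)
        if run_meta_path is not None:
            meta = pd.read_csv(run_meta_path, sep="\t", dtype=str)
            mapping = dict(zip(meta["run_id"], meta["experiment_id"]))
        else:
            mapping = {r: "exp1" for r in df.columns}
        return cls(counts=df, experiment_of_run=mapping)


@dataclass
class ExpressionMatrix:
    """Normalized log2 expression, mean-centered per gene."""

    values: pd.DataFrame

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def to_tsv(self, path) -> None:
        self.values.to_csv(path, sep="\t", index_label="gene", float_format="%.6g")

    @classmethod
    def from_tsv(cls, path) -> "ExpressionMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        df.index = df.index.astype(str)
        return cls(values=df)


def quantile_normalize(values: pd.DataFrame) -> pd.DataFrame:
    """Quantile-normalize columns against the mean-of-sorted-columns reference.

    After the step every column carries exactly the same sorted multiset of
    values.  Ties within a column are assigned reference values by stable
    ordinal rank so that exact multiset equality holds even with ties.
    """
    arr = values.to_numpy(dtype=float)
    ref = np.sort(arr, axis=0).mean(axis=1)
    out = np.empty_like(arr)
    for j in range(arr.shape[1]):
        order = np.argsort(arr[:, j], kind="stable")
        out[order, j] = ref
    return pd.DataFrame(out, index=values.index, columns=values.columns)


def preprocess_counts(
    counts: CountMatrix,
    min_total_mapped: int = 10_000_000,
    min_peak_count: int = 100,
    pseudocount: float = 0.125,
) -> ExpressionMatrix:
    """Filter, log-transform, quantile-normalize and center a count matrix.

    Runs whose total mapped count is below ``min_total_mapped`` are removed
    first; genes whose maximum count across the surviving runs is below
    ``min_peak_count`` are removed next.  The remaining counts become
    ``log2(count + pseudocount)``, are quantile-normalized within each
    experiment's runs, and every gene row is mean-centered over all
    surviving runs.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    df = counts.counts
    if df.empty:
        raise EmptyResultError("empty count matrix")

    totals = df.sum(axis=0)
    good_runs = [r for r in df.columns if totals[r] >= min_total_mapped]
    if not good_runs:
        raise EmptyResultError(
            f"all {df.shape[1]} runs fall below {min_total_mapped} mapped counts"
        )
    df = df[good_runs]

    peaks = df.max(axis=1)
    good_genes = peaks[peaks >= min_peak_count].index
    if len(good_genes) == 0:
        raise EmptyResultError("all genes fall below the peak-count filter")
    df = df.loc[good_genes]

    logged = np.log2(df.to_numpy(dtype=float) + pseudocount)
    logged = pd.DataFrame(logged, index=df.index, columns=df.columns)

    groups: dict[str, list[str]] = {}
    for run in logged.columns:
        groups.setdefault(counts.experiment_of_run[run], []).append(run)
    normed = logged.copy()
    for runs in groups.values():
        normed[runs] = quantile_normalize(logged[runs])

    centered = normed.sub(normed.mean(axis=1), axis=0)
    return ExpressionMatrix(values=centered)


def _weighted_corr(x: np.ndarray, w: np.ndarray) -> np.ndarray:
    w = w / w.sum()
    mean = x @ w
    xc = x - mean[:, None]
    cov = (xc * w) @ xc.T
    sd = np.sqrt(np.diag(cov))
    corr = cov / np.outer(sd, sd)
    return np.clip(corr, -1.0, 1.0)


def correlation_matrix(
    expr: ExpressionMatrix,
    sample_weights: Sequence[float] | None = None,
) -> pd.DataFrame:
    """Pearson correlation between all gene pairs (optionally sample-weighted).

    Genes with zero variance across samples carry no correlation signal and
    are excluded with a warning.
    """
    df = expr.values
    if df.shape[1] < 3:
        raise ValueError("need at least 3 samples to correlate")
    x = df.to_numpy(dtype=float)
    var = x.var(axis=1)
    flat = var <= 1e-300
    if flat.any():
        dropped = list(df.index[flat])
        warnings.warn(
            f"excluding {len(dropped)} zero-variance gene(s): {dropped[:5]}...",
            stacklevel=2,
        )
        df = df.loc[~flat]
        x = x[~flat]
    if sample_weights is not None:
        w = np.asarray(sample_weights, dtype=float)
        if w.shape[0] != x.shape[1]:
            raise ValueError("one weight per sample required")
        if (w < 0).any() or w.sum() <= 0:
            raise ValueError("weights must be non-negative with positive sum")
        corr = _weighted_corr(x, w)
    else:
        corr = np.clip(np.corrcoef(x), -1.0, 1.0)
    return pd.DataFrame(corr, index=df.index, columns=df.index)


def mutual_rank(corr: pd.DataFrame) -> CoexpressionTable:
    """Convert a symmetric correlation matrix to a Mutual-Rank table.

    For the ordered pair ``(a, b)``, ``rank_a(b)`` is the midrank of *b*
    among all genes other than *a* sorted by descending correlation with
    *a* (best = 1); ``mr(a, b) = sqrt(rank_a(b) * rank_b(a))``.
    """
    if corr.shape[0] != corr.shape[1] or list(corr.index) != list(corr.columns):
        raise ValueError("correlation matrix must be square with matching labels")
    n = corr.shape[0]
    if n < 3:
        raise ValueError("need at least 3 genes")
    c = corr.to_numpy(dtype=float)
    if not np.allclose(c, c.T, atol=1e-8):
        raise ValueError("correlation matrix must be symmetric")

    ranks = np.full((n, n), np.nan)
    idx = np.arange(n)
    for i in range(n):
        others = idx != i
        # descending correlation: rank 1 = strongest correlate
        ranks[i, others] = rankdata(-c[i, others], method="average")
    mr = np.sqrt(ranks * ranks.T)
    return CoexpressionTable(pd.DataFrame(mr, index=corr.index, columns=corr.columns))
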