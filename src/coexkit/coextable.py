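"""Mutual-Rank coexpression tables and ranked coexpressed-gene lists.

The Mutual Rank (MR) table is the universal currency of the toolkit: a
symmetric gene x gene matrix where ``mr(a, b) = sqrt(rank_a(b) * rank_b(a))``
and ``rank_a(b)`` is the position of *b* when all genes other than *a* are
sorted by descending correlation with *a*.  Lower MR means stronger
coexpression; values lie in ``[1, n_genes - 1]`` and the diagonal is
undefined (stored as NaN).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = ["CoexpressionTable", "RankedGeneList", "CoexDataset"]


@dataclass(frozen=True)
class RankedGeneList:
    """A guide gene's coexpressed genes, strongest (lowest MR) first.

    The guide itself is never a member of its own list.  Ordering is total:
    ascending MR with ties broken by gene identifier, so a list built twice
    from the same table is identical.
    """

    guide: str
    genes: tuple[str, ...]
    dataset: str | None = None

    def __post_init__(self) -> None:
        if self.guide in self.genes:
            raise ValueError(f"guide {self.guide!r} contained in its own list")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate genes in ranked list")

    def __len__(self) -> int:
        return len(self.genes)

    def top(self, k: int) -> tuple[str, ...]:
        return self.genes[:k]

    def restricted_to(self, keep: Iterable[str]) -> "RankedGeneList":
        keep = set(keep)
        return RankedGeneList(
            guide=self.guide,
            genes=tuple(g for g in self.genes if g in keep),
            dataset=self.dataset,
        )


class CoexpressionTable:
    """Square, symmetric MR matrix keyed by gene identifiers."""

    def __init__(self, mr: pd.DataFrame, *, validate: bool = True):
        if validate:
            if mr.shape[0] != mr.shape[1]:
                raise ValueError("MR table must be square")
            if list(mr.index) != list(mr.columns):
                raise ValueError("MR table row and column labels must match")
            if mr.index.has_duplicates:
                raise ValueError("duplicate gene identifiers in MR table")
            vals = mr.to_numpy(dtype=float, copy=True)
            np.fill_diagonal(vals, np.nan)
            off = vals[~np.isnan(vals)]
            if off.size and off.min() < 1.0 - 1e-9:
                raise ValueError("MR values must be >= 1")
            if not np.allclose(vals, vals.T, equal_nan=True):
                raise ValueError("MR table must be symmetric")
            mr = pd.DataFrame(vals, index=mr.index, columns=mr.columns)
        self._mr = mr
        self._ranked_cache: dict[str, RankedGeneList] = {}

    # -- basic access -----------------------------------------------------

    @property
    def mr(self) -> pd.DataFrame:
        return self._mr

    @property
    def gene_ids(self) -> list[str]:
        return list(self._mr.index)

    @property
    def n_genes(self) -> int:
        return self._mr.shape[0]

    def __contains__(self, gene: str) -> bool:
        return gene in self._mr.index

    def value(self, a: str, b: str) -> float:
        if a == b:
            raise KeyError("MR undefined for a self pair")
        return float(self._mr.at[a, b])

    # -- ranked lists -----------------------------------------------------

    def ranked_list(self, guide: str, dataset: str | None = None) -> RankedGeneList:
        """All other genes ordered by ascending MR to *guide* (ties: gene id)."""
        cached = self._ranked_cache.get(guide)
        if cached is not None:
            return cached
        if guide not in self._mr.index:
            raise KeyError(f"guide gene {guide!r} not in table")
        col = self._mr[guide].drop(labels=[guide])
        order = sorted(col.index, key=lambda g: (col[g], g))
        lst = RankedGeneList(guide=guide, genes=tuple(order), dataset=dataset)
        self._ranked_cache[guide] = lst
        return lst

    # -- serialization (ATTED bulk-download layout: gene x gene TSV) ------

    def to_tsv(self, path) -> None:
        self._mr.to_csv(path, sep="\t", index_label="gene", float_format="%.6g")

    @classmethod
    def from_tsv(cls, path) -> "CoexpressionTable":
        df = pd.read_csv(path, sep="\t", index_col=0)
        df.index = df.index.astype(str)
        df.columns = df.columns.astype(str)
        return cls(df)

    def __repr__(self) -> str:  # pragma: no cover
        return f"CoexpressionTable({self.n_genes} genes)"


@dataclass
class CoexDataset:
    """One coexpression dataset: an MR table tagged with its species."""

    id: str
    species: str
    table: CoexpressionTable

    @property
    def gene_ids(self) -> list[str]:
        return self.table.gene_ids

    @property
    def universe(self) -> frozenset[str]:
        return frozenset(self.table.gene_ids)

    def ranked_list(self, guide: str) -> RankedGeneList:
        return self.table.ranked_list(guide, dataset=self.id)
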