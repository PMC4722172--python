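"""COXSIM: prefix-weighted concordance of two ranked coexpressed-gene lists.

For a guide gene *g* with ranked list ``list_g`` and a reference guide *r*
with ranked list ``list_r``::

    COXSIM_gr = sum_{i=1..k} n(i, list_g, list_r) / sum_{i=1..k} i

where ``n(i)`` counts genes among the top *i* of ``list_g`` whose
corresponding gene (via a cross-dataset correspondence map) lies in the top
*i* of ``list_r``.  The depth *k* defaults to the top 1% of ``list_g``.

``maxCOXSIM_g`` is the best COXSIM over a reference guide set *R* (best-hit
genes in every other dataset, plus the identical gene in other same-species
datasets).  Significance comes from an empirical null of COXSIM values
between arbitrary cross-species gene pairings, Bonferroni-corrected for the
number of reference lists.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .coextable import CoexDataset, RankedGeneList
from .orthology import BitscoreTable, best_hit

__all__ = [
    "CorrespondenceMap",
    "CoxsimValue",
    "NullDistribution",
    "SignificanceResult",
    "default_k",
    "restrict_lists",
    "coxsim",
    "coxsim_between",
    "build_reference_set",
    "max_coxsim",
    "build_null",
    "null_thresholds",
    "significance",
]


@dataclass(frozen=True)
class CorrespondenceMap:
    """Directed gene mapping between two datasets (best hit, RBH or identity)."""

    source_dataset: str
    target_dataset: str
    pairs: Mapping[str, str]

    def get(self, gene: str) -> str | None:
        return self.pairs.get(gene)

    @classmethod
    def identity(cls, genes, source_dataset: str = "", target_dataset: str = "") -> "CorrespondenceMap":
        return cls(source_dataset, target_dataset, {g: g for g in genes})

    @classmethod
    def from_pairs(cls, pairs, source_dataset: str = "", target_dataset: str = "") -> "CorrespondenceMap":
        return cls(source_dataset, target_dataset, dict(pairs))

    @classmethod
    def from_tsv(cls, path, source_dataset: str = "", target_dataset: str = "") -> "CorrespondenceMap":
        import pandas as pd

        df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
        return cls(source_dataset, target_dataset, dict(zip(df[0], df[1])))

    def inverted(self) -> "CorrespondenceMap":
        inv = {}
        for k, v in self.pairs.items():
            if v not in inv:  # first (sorted insertion) wins on collision
                inv[v] = k
        return CorrespondenceMap(self.target_dataset, self.source_dataset, inv)


@dataclass(frozen=True)
class CoxsimValue:
    guide: str
    reference: str
    value: float
    k: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.value <= 1.0 + 1e-12):
            raise ValueError("COXSIM must lie in [0, 1]")
        if self.k < 1:
            raise ValueError("k must be >= 1")


@dataclass
class NullDistribution:
    """Sorted empirical COXSIM values from unrelated guide/reference pairings."""

    samples: np.ndarray
    source: str = ""

    def __post_init__(self) -> None:
        s = np.asarray(self.samples, dtype=float)
        if s.size and (s.min() < -1e-12 or s.max() > 1 + 1e-12):
            raise ValueError("null samples must lie in [0, 1]")
        self.samples = np.sort(s)
        if s.size < 1000:
            warnings.warn(
                f"only {s.size} null samples; tail quantiles are unstable",
                stacklevel=2,
            )

    def survival(self, x: float) -> float:
        """Empirical P(COXSIM >= x)."""
        n = self.samples.size
        return float(n - np.searchsorted(self.samples, x, side="left")) / n

    def quantile(self, q: float) -> float:
        return float(np.quantile(self.samples, q))


@dataclass
class SignificanceResult:
    """maxCOXSIM of a guide with its best reference and star-level significance."""

    guide: str
    best_reference: tuple[str, str] | None  # (dataset id, reference gene)
    max_coxsim: float | None
    per_reference: dict[tuple[str, str], float] = field(default_factory=dict)
    thresholds: tuple[float, ...] | None = None
    alphas: tuple[float, ...] | None = None
    stars: int | None = None

    @property
    def assessable(self) -> bool:
        return self.max_coxsim is not None


def default_k(list_length: int) -> int:
    """Top 1% of the guide's list, never empty: ``max(1, ceil(0.01 * L))``."""
    return max(1, math.ceil(0.01 * list_length))


def restrict_lists(
    list_g0: RankedGeneList,
    list_r0: RankedGeneList,
    fwd: CorrespondenceMap,
    rev: CorrespondenceMap,
) -> tuple[RankedGeneList, RankedGeneList]:
    """Drop genes lacking a counterpart in the other dataset's gene universe.

    The universe of each side is its full list plus its guide.  Original
    ordering is preserved; either result may be empty (COXSIM undefined
    downstream).
    """
    universe_g = set(list_g0.genes) | {list_g0.guide}
    universe_r = set(list_r0.genes) | {list_r0.guide}
    keep_g = tuple(
        g for g in list_g0.genes
        if fwd.get(g) is not None and fwd.get(g) in universe_r
    )
    keep_r = tuple(
        r for r in list_r0.genes
        if rev.get(r) is not None and rev.get(r) in universe_g
    )
    return (
        replace(list_g0, genes=keep_g),
        replace(list_r0, genes=keep_r),
    )


def coxsim(
    list_g: RankedGeneList,
    list_r: RankedGeneList,
    fwd: CorrespondenceMap,
    k: int | None = None,
) -> CoxsimValue:
    """Prefix-weighted overlap of two restricted ranked lists.

    A gene at position *p* (1-based) in ``list_g`` whose counterpart sits at
    position *q* in ``list_r`` contributes to ``n(i)`` for every depth
    ``i >= max(p, q)``, so the numerator is ``sum over such genes of
    (k - max(p, q) + 1)`` and the denominator ``k (k + 1) / 2``.
    """
    if len(list_g) == 0 or len(list_r) == 0:
        raise ValueError("COXSIM undefined for empty gene lists")
    if k is None:
        k = default_k(len(list_g))
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > len(list_g):
        raise ValueError(f"k={k} exceeds guide list length {len(list_g)}")

    pos_r = {gene: i for i, gene in enumerate(list_r.genes, start=1)}
    numer = 0
    for p, gene in enumerate(list_g.genes[:k], start=1):
        counterpart = fwd.get(gene)
        q = pos_r.get(counterpart) if counterpart is not None else None
        if q is not None and max(p, q) <= k:
            numer += k - max(p, q) + 1
    denom = k * (k + 1) // 2
    return CoxsimValue(guide=list_g.guide, reference=list_r.guide,
                       value=numer / denom, k=k)


def coxsim_between(
    dataset_g: CoexDataset,
    dataset_r: CoexDataset,
    guide: str,
    reference: str,
    fwd: CorrespondenceMap,
    rev: CorrespondenceMap,
    k: int | None = None,
    k_fraction: float = 0.01,
) -> CoxsimValue:
    """Full COXSIM between a guide in one dataset and a reference in another.

    Builds both ranked lists from the MR tables, restricts them to mapped
    genes, then applies the prefix statistic at depth ``k`` (default:
    ``ceil(k_fraction * |list_g|)`` after restriction).
    """
    lg0 = dataset_g.ranked_list(guide)
    lr0 = dataset_r.ranked_list(reference)
    lg, lr = restrict_lists(lg0, lr0, fwd, rev)
    if len(lg) == 0 or len(lr) == 0:
        return CoxsimValue(guide=guide, reference=reference, value=0.0, k=1)
    if k is None:
        k = max(1, math.ceil(k_fraction * len(lg)))
        k = min(k, len(lg))
    return coxsim(lg, lr, fwd, k=k)


def build_reference_set(
    g: str,
    dataset: CoexDataset,
    all_datasets: Sequence[CoexDataset],
    bitscores: Mapping[tuple[str, str], BitscoreTable],
) -> list[tuple[str, str]]:
    """Reference guide genes for *g*: one per other dataset where available.

    Same-species datasets contribute the identical gene; other species
    contribute the Blastp best hit from *g*'s species.  A dataset whose
    candidate gene is absent from its table is skipped.
    Returns (dataset id, reference gene) pairs sorted by dataset id.
    """
    refs: list[tuple[str, str]] = []
    for other in all_datasets:
        if other.id == dataset.id:
            continue
        if other.species == dataset.species:
            candidate: str | None = g
        else:
            table = bitscores.get((dataset.species, other.species))
            if table is None:
                raise KeyError(
                    f"missing bitscore table {dataset.species} -> {other.species}"
                )
            candidate = best_hit(g, table)
        if candidate is not None and candidate in other.universe:
            refs.append((other.id, candidate))
    return sorted(refs)


def max_coxsim(
    g: str,
    references: Sequence[tuple[str, str]],
    dataset: CoexDataset,
    datasets_by_id: Mapping[str, CoexDataset],
    maps: Mapping[tuple[str, str], CorrespondenceMap],
    k_fraction: float = 0.01,
) -> SignificanceResult:
    """COXSIM against every reference; the maximum and its arg-max are kept.

    Ties are broken by (dataset id, gene) lexicographic order.  An empty
    reference set yields an unassessable result (rendered blank downstream).
    """
    if not references:
        return SignificanceResult(guide=g, best_reference=None, max_coxsim=None)
    per: dict[tuple[str, str], float] = {}
    for ds_id, r in sorted(references):
        other = datasets_by_id[ds_id]
        fwd = maps[(dataset.id, ds_id)]
        rev = maps[(ds_id, dataset.id)]
        per[(ds_id, r)] = coxsim_between(
            dataset, other, g, r, fwd, rev, k_fraction=k_fraction
        ).value
    # deterministic: highest value, then lexicographically smallest key
    best_key = sorted(per, key=lambda key: (-per[key], key))[0]
    return SignificanceResult(
        guide=g,
        best_reference=best_key,
        max_coxsim=per[best_key],
        per_reference=per,
    )


def build_null(
    dataset_a: CoexDataset,
    dataset_b: CoexDataset,
    fwd: CorrespondenceMap,
    rev: CorrespondenceMap,
    max_pairs: int | None = 1_000_000,
    seed: int = 0,
    k_fraction: float = 0.01,
    exclude_mapped_pairs: bool = False,
) -> NullDistribution:
    """Empirical COXSIM null from arbitrary cross-dataset gene pairings.

    Almost all gene pairs are functionally unrelated, so COXSIM values over
    all (or a seeded uniform subsample of) guide x reference combinations
    form the null.  ``max_pairs=None`` enumerates every combination.  With
    ``exclude_mapped_pairs`` the pairings related through ``fwd`` (putative
    orthologs) are left out; at genome scale their contribution is
    negligible, so the default keeps every combination.
    """
    genes_a = sorted(dataset_a.gene_ids)
    genes_b = sorted(dataset_b.gene_ids)
    n_total = len(genes_a) * len(genes_b)
    rng = np.random.default_rng(seed)
    if max_pairs is None or n_total <= max_pairs:
        pairs = [(a, b) for a in genes_a for b in genes_b]
    else:
        flat = rng.choice(n_total, size=max_pairs, replace=False)
        pairs = [(genes_a[i // len(genes_b)], genes_b[i % len(genes_b)]) for i in flat]
    if exclude_mapped_pairs:
        pairs = [(a, b) for a, b in pairs if fwd.get(a) != b]
    values = [
        coxsim_between(dataset_a, dataset_b, a, b, fwd, rev, k_fraction=k_fraction).value
        for a, b in pairs
    ]
    return NullDistribution(
        samples=np.asarray(values),
        source=f"{dataset_a.id} x {dataset_b.id} ({len(values)} pairs)",
    )


def null_thresholds(
    null: NullDistribution,
    n_reference_lists: int,
    alphas: Sequence[float] = (0.1, 0.01, 0.001),
) -> tuple[float, ...]:
    """COXSIM value thresholds for each level after Bonferroni correction.

    The threshold for level ``a`` is the smallest null sample ``x`` with
    empirical survival ``P(COXSIM >= x) <= a / n_reference_lists``.  When no
    sample is extreme enough the threshold is set just above the largest
    sample, with a warning.
    """
    if n_reference_lists < 1:
        raise ValueError("n_reference_lists must be >= 1")
    s = null.samples
    n = s.size
    if n == 0:
        raise ValueError("empty null distribution")
    thresholds = []
    # survival at s[i] (ascending, ties counted) = (n - first_index_of(s[i])) / n
    first_index = np.searchsorted(s, s, side="left")
    surv = (n - first_index) / n
    for a in alphas:
        target = a / n_reference_lists
        ok = np.nonzero(surv <= target)[0]
        if ok.size == 0:
            warnings.warn(
                f"alpha/m = {target:.3g} below null resolution 1/{n}; "
                "threshold set above the largest null sample",
                stacklevel=2,
            )
            thresholds.append(float(s[-1]) + 1e-9)
        else:
            thresholds.append(float(s[ok[0]]))
    return tuple(thresholds)


def significance(
    result: SignificanceResult,
    null: NullDistribution,
    n_reference_lists: int,
    alphas: Sequence[float] = (0.1, 0.01, 0.001),
) -> SignificanceResult:
    """Attach Bonferroni-corrected thresholds and a 0-3 star level.

    Stars count the significance levels the guide's maxCOXSIM reaches
    (one star for p < 0.1, two for p < 0.01, three for p < 0.001 under the
    default levels).  Unassessable guides stay starless.
    """
    thresholds = null_thresholds(null, n_reference_lists, alphas)
    stars = None
    if result.max_coxsim is not None:
        stars = sum(result.max_coxsim >= t for t in thresholds)
    return replace(
        result,
        thresholds=thresholds,
        alphas=tuple(alphas),
        stars=stars,
    )
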