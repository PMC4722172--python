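"""Dataset-quality scores: GO score, codon score, reproducibility score.

Three independent assessments of a coexpression dataset, each reported on
its conventional scale:

* GO score — partial ROC AUC at false-positive rate <= 0.01 for predicting
  shared GO biological-process membership from MR, reported in 1E-04 units.
* codon score — median COXSIM between each guide's coexpression list and
  its codon-usage-similarity list, reported in 1E-02 units.  Codon usage is
  annotation-free, so this score applies to any species.
* reproducibility score — median over guides of maxCOXSIM normalized by the
  adequateness of the chosen reference (a Blastp bitscore ratio), reported
  in 1E-01 units.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_curve

from .coextable import CoexDataset, CoexpressionTable
from .collection import StudyCollection
from .coxsim import CorrespondenceMap, coxsim_between
from .expression import correlation_matrix, mutual_rank, ExpressionMatrix
from .orthology import BitscoreTable

__all__ = [
    "SENSE_CODONS",
    "STOP_CODONS",
    "CodonUsageVector",
    "GOAnnotationSet",
    "codon_usage",
    "codon_usage_from_fasta",
    "codon_mr_table",
    "codon_score",
    "select_go_terms",
    "partial_roc_auc",
    "go_score",
    "reference_adequateness",
    "reproducibility_score",
]

STOP_CODONS = ("TAA", "TAG", "TGA")
SENSE_CODONS: tuple[str, ...] = tuple(
    c for c in (
        a + b + d
        for a in "ACGT" for b in "ACGT" for d in "ACGT"
    )
    if c not in STOP_CODONS
)
_CODON_INDEX = {c: i for i, c in enumerate(SENSE_CODONS)}


@dataclass(frozen=True)
class CodonUsageVector:
    """Counts of the 61 sense codons in a gene's protein-coding sequence."""

    gene: str
    counts: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.counts) != 61:
            raise ValueError("codon usage vector must have 61 entries")
        if any(c < 0 for c in self.counts):
            raise ValueError("codon counts must be non-negative")

    @property
    def total(self) -> int:
        return sum(self.counts)


def codon_usage(cds: str, gene: str = "") -> CodonUsageVector:
    """Count non-overlapping codons of a CDS; stop codons are excluded.

    A trailing partial codon is dropped with a warning, as are codons
    containing ambiguous bases.
    """
    seq = cds.upper()
    if len(seq) < 3:
        raise ValueError("CDS shorter than one codon")
    if len(seq) % 3 != 0:
        warnings.warn(
            f"{gene or 'CDS'}: length {len(seq)} not a multiple of 3; "
            "trailing partial codon dropped",
            stacklevel=2,
        )
    counts = [0] * 61
    for i in range(0, len(seq) - len(seq) % 3, 3):
        codon = seq[i:i + 3]
        idx = _CODON_INDEX.get(codon)
        if idx is not None:
            counts[idx] += 1
        elif codon not in STOP_CODONS:
            warnings.warn(
                f"{gene or 'CDS'}: ambiguous codon {codon!r} skipped",
                stacklevel=2,
            )
    return CodonUsageVector(gene=gene, counts=tuple(counts))


def codon_usage_from_fasta(path, isoform_of: Mapping[str, str] | None = None) -> dict[str, CodonUsageVector]:
    """Per-gene codon usage from a CDS FASTA; longest isoform per gene wins.

    The gene id is the first whitespace-delimited token of each record
    header, optionally collapsed through an isoform -> gene mapping.
    """
    from Bio import SeqIO

    longest: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        gene = rec.id
        if isoform_of is not None:
            gene = isoform_of.get(rec.id, rec.id)
        seq = str(rec.seq)
        if gene not in longest or len(seq) > len(longest[gene]):
            longest[gene] = seq
    return {g: codon_usage(s, gene=g) for g, s in sorted(longest.items())}


def codon_mr_table(vectors: Iterable[CodonUsageVector]) -> CoexpressionTable:
    """MR table of pairwise Pearson correlations between codon-usage vectors.

    Same Mutual-Rank construction as for expression data; constant
    (zero-variance) vectors are excluded with a warning.
    """
    vectors = list(vectors)
    if len(vectors) < 3:
        raise ValueError("need at least 3 genes")
    genes = [v.gene for v in vectors]
    mat = pd.DataFrame(
        np.asarray([v.counts for v in vectors], dtype=float),
        index=genes,
    )
    corr = correlation_matrix(ExpressionMatrix(values=mat))
    return mutual_rank(corr)


def codon_score(
    coex: CoexpressionTable,
    codon_table: CoexpressionTable,
    k_fraction: float = 0.01,
    guides: Sequence[str] | None = None,
) -> float:
    """Median guide-wise COXSIM between coexpression and codon-similarity lists.

    The two tables share a gene universe (identity correspondence); the
    comparison runs over their intersection, or over the ``guides`` subset
    when given.  Reported in 1E-02 units (median x 100).
    """
    shared = sorted(set(coex.gene_ids) & set(codon_table.gene_ids))
    if guides is not None:
        shared = sorted(set(shared) & set(guides))
    if len(shared) < 3:
        raise ValueError("fewer than 3 shared genes between the tables")
    if len(shared) < 10:
        warnings.warn("fewer than 10 guide genes; median is unstable", stacklevel=2)
    ds_a = CoexDataset(id="coex", species="self", table=coex)
    ds_b = CoexDataset(id="codon", species="self", table=codon_table)
    ident_ab = CorrespondenceMap.identity(coex.gene_ids, "coex", "codon")
    ident_ba = CorrespondenceMap.identity(codon_table.gene_ids, "codon", "coex")
    values = [
        coxsim_between(ds_a, ds_b, g, g, ident_ab, ident_ba, k_fraction=k_fraction).value
        for g in shared
    ]
    return float(np.median(values)) * 100.0


@dataclass(frozen=True)
class GOAnnotationSet:
    """gene -> set of GO biological-process term ids."""

    annotations: Mapping[str, frozenset[str]]

    def __post_init__(self) -> None:
        for g, terms in self.annotations.items():
            if not terms:
                raise ValueError(f"gene {g} annotated with an empty term set")

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]]) -> "GOAnnotationSet":
        ann: dict[str, set[str]] = {}
        for gene, term in pairs:
            ann.setdefault(gene, set()).add(term)
        return cls({g: frozenset(t) for g, t in ann.items()})

    @classmethod
    def from_tsv(cls, path) -> "GOAnnotationSet":
        df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
        return cls.from_pairs(zip(df[0], df[1]))

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            for gene in sorted(self.annotations):
                for term in sorted(self.annotations[gene]):
                    fh.write(f"{gene}\t{term}\n")

    def restricted_to(self, genes: Iterable[str]) -> "GOAnnotationSet":
        keep = set(genes)
        return GOAnnotationSet(
            {g: t for g, t in self.annotations.items() if g in keep}
        )

    def genes_with(self, terms: Iterable[str]) -> list[str]:
        terms = set(terms)
        return sorted(g for g, t in self.annotations.items() if t & terms)


def select_go_terms(
    annotations: GOAnnotationSet,
    min_genes: int = 5,
    max_genes: int = 20,
) -> set[str]:
    """Terms annotating 5-20 genes: specific enough to be informative,
    broad enough to form gene pairs."""
    counts: dict[str, int] = {}
    for terms in annotations.annotations.values():
        for t in terms:
            counts[t] = counts.get(t, 0) + 1
    return {t for t, c in counts.items() if min_genes <= c <= max_genes}


def partial_roc_auc(
    labels: Sequence[bool],
    scores: Sequence[float],
    fpr_cap: float = 0.01,
) -> float:
    """Unnormalized partial ROC area for FPR in [0, fpr_cap] (max = fpr_cap)."""
    y = np.asarray(labels, dtype=int)
    s = np.asarray(scores, dtype=float)
    if y.all() or not y.any():
        raise ValueError("need both positive and negative pairs")
    fpr, tpr, _ = roc_curve(y, s, drop_intermediate=False)
    if fpr_cap < fpr[-1]:
        tpr_at_cap = float(np.interp(fpr_cap, fpr, tpr))
        keep = fpr <= fpr_cap
        fpr = np.append(fpr[keep], fpr_cap)
        tpr = np.append(tpr[keep], tpr_at_cap)
    return float(np.trapezoid(tpr, fpr))


def go_score(
    coex: CoexpressionTable,
    annotations: GOAnnotationSet,
    fpr_cap: float = 0.01,
    min_genes: int = 5,
    max_genes: int = 20,
) -> float:
    """Partial ROC AUC (FPR <= fpr_cap) for recovering shared-GO gene pairs.

    Terms are first filtered to those annotating ``min_genes``-``max_genes``
    genes within the table's universe; genes carrying at least one selected
    term enter the evaluation.  Every unordered pair of those genes is
    positive iff the two genes share a selected term; pairs are ranked by
    ascending MR.  Reported in 1E-04 units (pAUC x 10^4).
    """
    ann = annotations.restricted_to(coex.gene_ids)
    terms = select_go_terms(ann, min_genes, max_genes)
    if not terms:
        raise ValueError("no GO terms in the size window")
    genes = sorted(
        g for g, t in ann.annotations.items() if t & terms
    )
    if len(genes) < 2:
        raise ValueError("fewer than 2 annotated genes")
    sel = {g: ann.annotations[g] & terms for g in genes}
    labels: list[bool] = []
    scores: list[float] = []
    mr = coex.mr
    for a, b in combinations(genes, 2):
        labels.append(bool(sel[a] & sel[b]))
        scores.append(-float(mr.at[a, b]))  # low MR = strong coexpression
    return partial_roc_auc(labels, scores, fpr_cap) * 1e4


def reference_adequateness(
    g: str,
    r_hat: str,
    bitscores: BitscoreTable,
    self_scores: BitscoreTable | None = None,
) -> float:
    """Bitscore ratio score(g -> r_hat) / score(g -> g).

    Approximates the evolutionary proximity of the chosen reference; the
    identical gene gives 1.  ``bitscores`` is oriented from g's species to
    the reference's; ``self_scores`` (defaults to the same table) supplies
    the self score for same-species comparisons.
    """
    if self_scores is None:
        self_scores = bitscores
    cross = bitscores.score(g, r_hat)
    own = self_scores.score(g, g)
    if cross is None or own is None:
        raise KeyError(
            f"missing bitscore for ({g}, {r_hat}) or self score for {g}"
        )
    ratio = cross / own
    if ratio > 1:
        warnings.warn(
            f"bitscore({g}->{r_hat}) exceeds the self score; ratio {ratio:.3f} > 1",
            stacklevel=2,
        )
    return ratio


def reproducibility_score(
    dataset_id: str,
    collection: StudyCollection,
    k_fraction: float = 0.01,
    guides: Sequence[str] | None = None,
) -> float:
    """Median over guides of maxCOXSIM / reference adequateness, x 10.

    Each guide gene with a non-empty reference set contributes its best
    COXSIM normalized by how adequate the chosen reference is (1 for a
    same-species identical gene, a bitscore ratio across species).  Guides
    without any reference are excluded from the median.  ``guides``
    restricts the median to a subset (default: every gene in the dataset).
    Reported in 1E-01 units.
    """
    dataset = collection.datasets[dataset_id]
    sp = dataset.species
    values: list[float] = []
    if guides is None:
        guides = sorted(dataset.gene_ids)
    for g in guides:
        result = collection.max_coxsim(g, dataset_id, k_fraction=k_fraction)
        if not result.assessable:
            continue
        ref_ds, r_hat = result.best_reference
        ref_sp = collection.species_of(ref_ds)
        if ref_sp == sp and r_hat == g:
            adequateness = 1.0
        else:
            table = collection.bitscores.get((sp, ref_sp))
            if table is None:
                raise KeyError(f"missing bitscore table {sp} -> {ref_sp}")
            self_table = collection.bitscores.get((sp, sp), table)
            adequateness = reference_adequateness(g, r_hat, table, self_table)
        values.append(result.max_coxsim / adequateness)
    if not values:
        raise ValueError(f"no assessable guide genes in dataset {dataset_id}")
    return float(np.median(values)) * 10.0
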