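"""Whole-dataset comparison, clustering and lineage-specific coexpression.

Dataset similarity is the median COXSIM over all corresponding guide-gene
pairs.  COXSIM is not exactly symmetric, so the symmetric similarity of a
dataset pair averages the two directions, and ``1 - similarity`` is the
distance used for complete-linkage clustering.  Ortholog-pair coexpression
strength across a set of datasets is summarized by the geometric average of
the pair's MR values, and pairs are classified as conserved, clade-specific
or not coexpressed from the two clade averages.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage, to_tree
from scipy.spatial.distance import squareform

from .coextable import CoexpressionTable
from .collection import StudyCollection
from .coxsim import coxsim_between

__all__ = [
    "dataset_similarity",
    "similarity_matrix",
    "symmetrize",
    "cluster_datasets",
    "geometric_avg_mr",
    "classify_lineage",
]


def dataset_similarity(
    collection: StudyCollection,
    target_id: str,
    reference_id: str,
    k_fraction: float = 0.01,
    guides: list[str] | None = None,
) -> float:
    """Median COXSIM over corresponding guide pairs (target vs reference)."""
    a = collection.datasets[target_id]
    b = collection.datasets[reference_id]
    fwd = collection.map_between(target_id, reference_id)
    rev = collection.map_between(reference_id, target_id)
    if guides is None:
        guides = sorted(a.gene_ids)
    values = []
    for g in guides:
        r = fwd.get(g)
        if r is None or r not in b.universe:
            continue
        values.append(
            coxsim_between(a, b, g, r, fwd, rev, k_fraction=k_fraction).value
        )
    if not values:
        raise ValueError(
            f"no corresponding guide genes between {target_id} and {reference_id}"
        )
    return float(np.median(values))


def similarity_matrix(
    collection: StudyCollection,
    k_fraction: float = 0.01,
    max_guides: int | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Directed median-COXSIM similarity for every ordered dataset pair.

    Diagonal entries are 1 (self-comparison under the identity map).  With
    ``max_guides`` set, each directed comparison uses a seeded subsample of
    guide genes for tractability.
    """
    ids = collection.dataset_ids
    rng = np.random.default_rng(seed)
    sim = pd.DataFrame(np.eye(len(ids)), index=ids, columns=ids)
    for a in ids:
        genes = sorted(collection.datasets[a].gene_ids)
        if max_guides is not None and len(genes) > max_guides:
            genes = sorted(rng.choice(genes, size=max_guides, replace=False))
        for b in ids:
            if a == b:
                continue
            sim.at[a, b] = dataset_similarity(
                collection, a, b, k_fraction=k_fraction, guides=genes
            )
    return sim


def symmetrize(sim: pd.DataFrame) -> pd.DataFrame:
    """Average the two directions of a similarity matrix."""
    return (sim + sim.T) / 2.0


def _to_newick(node, parent_height: float, labels: list[str]) -> str:
    if node.is_leaf():
        return f"{labels[node.id]}:{parent_height:.6g}"
    left = _to_newick(node.get_left(), node.dist, labels)
    right = _to_newick(node.get_right(), node.dist, labels)
    return f"({left},{right}):{parent_height - node.dist:.6g}"


def cluster_datasets(sim: pd.DataFrame) -> str:
    """Complete-linkage dendrogram (Newick) on distance = 1 - similarity.

    The similarity matrix is symmetrized first; datasets are ordered by id
    so that merge order is deterministic under ties.
    """
    if sim.shape[0] < 2:
        raise ValueError("need at least 2 datasets to cluster")
    sym = symmetrize(sim).sort_index(axis=0).sort_index(axis=1)
    dist = 1.0 - sym.to_numpy(dtype=float)
    np.fill_diagonal(dist, 0.0)
    if not np.isfinite(dist).all():
        raise ValueError("non-finite distances")
    z = linkage(squareform(dist, checks=False), method="complete")
    tree = to_tree(z)
    labels = list(sym.index)
    left = _to_newick(tree.get_left(), tree.dist, labels)
    right = _to_newick(tree.get_right(), tree.dist, labels)
    return f"({left},{right});"


def geometric_avg_mr(
    gene_pairs: list[tuple[str, str]],
    tables: list[CoexpressionTable],
) -> float:
    """Geometric mean of a gene pair's MR across datasets.

    ``gene_pairs[i]`` names the pair in ``tables[i]``'s gene space (ortholog
    projection).  A pair absent from any table makes the average undefined
    and raises; callers exclude such ortholog groups.
    """
    if len(gene_pairs) != len(tables):
        raise ValueError("one gene pair per table required")
    logs = []
    for (a, b), table in zip(gene_pairs, tables):
        if a not in table or b not in table:
            raise KeyError(f"pair ({a}, {b}) missing from a table")
        logs.append(np.log(table.value(a, b)))
    return float(np.exp(np.mean(logs)))


def classify_module_lineage(
    pair_averages: list[tuple[float, float]],
    strong_mr: float = 500.0,
    weak_mr: float = 5000.0,
) -> str:
    """Classify a gene module from its pairs' (dicot_avg, monocot_avg) values.

    A module's coexpression strength in a clade is summarized by the median
    of its gene pairs' geometric-average MRs; the classification rule is
    then the same as for a single pair.  The median damps the background
    MR noise of individual pairs.
    """
    if not pair_averages:
        raise ValueError("no pair averages supplied")
    d = float(np.median([a for a, _ in pair_averages]))
    m = float(np.median([b for _, b in pair_averages]))
    return classify_lineage(d, m, strong_mr, weak_mr)


def classify_lineage(
    dicot_avg: float,
    monocot_avg: float,
    strong_mr: float = 500.0,
    weak_mr: float = 5000.0,
) -> str:
    """Classify an ortholog pair's coexpression pattern across two clades.

    * ``conserved`` — strongly coexpressed (avg MR < strong_mr) in both;
    * ``dicot-specific`` / ``monocot-specific`` — strong in one clade,
      absent (avg MR > weak_mr) in the other;
    * ``not-coexpressed`` — absent in both;
    * ``indeterminate`` — anything in the gap between the two thresholds.

    The default thresholds suit genome-scale tables (~2 x 10^4 genes,
    background geometric-average MR near half the gene count); for smaller
    tables scale them with gene count.
    """
    if strong_mr >= weak_mr:
        raise ValueError("strong_mr must be below weak_mr")
    d_strong, m_strong = dicot_avg < strong_mr, monocot_avg < strong_mr
    d_weak, m_weak = dicot_avg > weak_mr, monocot_avg > weak_mr
    if d_strong and m_strong:
        return "conserved"
    if d_strong and m_weak:
        return "dicot-specific"
    if m_strong and d_weak:
        return "monocot-specific"
    if d_weak and m_weak:
        return "not-coexpressed"
    return "indeterminate"
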