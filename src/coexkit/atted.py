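"""Published ATTED-II version 8.0 dataset assessments, as reference data.

Two published score tables ship with the toolkit so that cross-score
consistency can be recomputed without the full expression compendia:

* ``DATASET_SCORES`` — the 14 coexpression datasets of ATTED-II v8.0 with
  their codon score (1E-02 units) and reproducibility score (1E-01 units).
  Mtr-m has no reproducibility score (it was withheld from the parallel
  view and excluded from reference sets).
* ``ARABIDOPSIS_VERSION_SCORES`` — the Arabidopsis coexpression versions
  (six microarray, two RNA-seq) with GO score (1E-04 units), codon score
  and reproducibility score.

``PUBLISHED_MAXCOXSIM_THRESHOLDS`` are the maxCOXSIM significance cutoffs
for p < 0.1 / 0.01 / 0.001 derived from the Arabidopsis-vs-rice RNA-seq
COXSIM null with Bonferroni correction over 13 reference lists.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "DATASET_SCORES",
    "ARABIDOPSIS_VERSION_SCORES",
    "PUBLISHED_MAXCOXSIM_THRESHOLDS",
    "cross_score_agreement",
]

# dataset id -> (n_genes, n_samples, codon score, reproducibility score)
_DATASETS = [
    ("Ath-m", 20836, 15275, 2.29, 2.57),
    ("Ath-r", 25296, 1401, 1.67, 2.20),
    ("Bra-r", 35431, 257, 1.63, 1.25),
    ("Gma-m", 15902, 1115, 1.63, 1.61),
    ("Gma-r", 42787, 410, 1.73, 1.48),
    ("Mtr-m", 6226, 909, 1.08, np.nan),
    ("Osa-m", 20625, 2098, 1.59, 1.79),
    ("Osa-r", 17548, 222, 1.49, 1.64),
    ("Ppo-m", 21909, 404, 1.29, 1.59),
    ("Sly-m", 5786, 401, 1.07, 1.51),
    ("Sly-r", 23195, 288, 1.34, 1.27),
    ("Vvi-m", 9564, 245, 1.18, 1.32),
    ("Zma-m", 11069, 755, 1.62, 1.94),
    ("Zma-r", 22592, 1571, 2.55, 1.85),
]

DATASET_SCORES = pd.DataFrame(
    [row[1:] for row in _DATASETS],
    index=[row[0] for row in _DATASETS],
    columns=["n_genes", "n_samples", "codon_score", "reproducibility_score"],
)

# (dataset, version) -> (n_genes, n_samples, GO score, codon, reproducibility)
_VERSIONS = [
    ("Ath-m", "c6.0", 20836, 15275, 7.08, 2.29, 2.57),
    ("Ath-m", "c5.0", 20836, 11171, 7.02, 2.24, 2.55),
    ("Ath-m", "c4.1", 20906, 1388, 5.48, 1.56, 2.08),
    ("Ath-m", "c4.0", 20906, 1388, 5.06, 1.59, 1.82),
    ("Ath-m", "c3.1", 20703, 771, 4.96, 1.46, 2.14),
    ("Ath-m", "c3.0", 22263, 771, 4.96, 1.46, 2.10),
    ("Ath-r", "c2.0", 25296, 1401, 4.81, 1.67, 2.20),
    ("Ath-r", "c1.0", 25838, 328, 4.27, 1.59, 1.67),
]

ARABIDOPSIS_VERSION_SCORES = pd.DataFrame(
    [row[2:] for row in _VERSIONS],
    index=pd.MultiIndex.from_tuples(
        [(d, v) for d, v, *_ in _VERSIONS], names=["dataset", "version"]
    ),
    columns=["n_genes", "n_samples", "go_score", "codon_score",
             "reproducibility_score"],
)

# maxCOXSIM cutoffs for one, two and three stars (p < 0.1, 0.01, 0.001)
PUBLISHED_MAXCOXSIM_THRESHOLDS: tuple[float, float, float] = (0.081, 0.189, 0.377)


def cross_score_agreement() -> dict[str, float]:
    """Pearson correlations between the three quality scores.

    GO vs codon and GO vs reproducibility run over the eight Arabidopsis
    version rows; codon vs reproducibility runs over the 13 datasets that
    have both scores (Mtr-m lacks a reproducibility score).
    """
    v = ARABIDOPSIS_VERSION_SCORES
    d = DATASET_SCORES.dropna(subset=["reproducibility_score"])
    return {
        "go_vs_codon": float(np.corrcoef(v["go_score"], v["codon_score"])[0, 1]),
        "go_vs_reproducibility": float(
            np.corrcoef(v["go_score"], v["reproducibility_score"])[0, 1]
        ),
        "codon_vs_reproducibility": float(
            np.corrcoef(d["codon_score"], d["reproducibility_score"])[0, 1]
        ),
    }
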