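"""Codon usage, codon score, GO score (partial ROC AUC) and reproducibility."""

import numpy as np
import pandas as pd
import pytest

from coexkit import (
    BitscoreTable,
    CoexpressionTable,
    GOAnnotationSet,
    StudyCollection,
    codon_mr_table,
    codon_score,
    codon_usage,
    go_score,
    partial_roc_auc,
    reference_adequateness,
    reproducibility_score,
    select_go_terms,
)
from coexkit.coextable import CoexDataset
from coexkit.scores import SENSE_CODONS, codon_usage_from_fasta
from conftest import random_mr_table


class TestCodonUsage:
    def test_direct_count_excluding_stop(self):
        v = codon_usage("ATGAAATAA", gene="g")
        counts = dict(zip(SENSE_CODONS, v.counts))
        assert counts["ATG"] == 1 and counts["AAA"] == 1
        assert v.total == 2  # TAA excluded, vector has 61 entries
        assert "TAA" not in counts

    def test_valid_cds_has_nonempty_vector(self):
        assert codon_usage("ATGTAA").total >= 1

    def test_partial_codon_dropped_with_warning(self):
        with pytest.warns(UserWarning, match="partial codon"):
            v = codon_usage("ATGAA")
        assert v.total == 1

    def test_ambiguous_codon_skipped_with_warning(self):
        with pytest.warns(UserWarning, match="ambiguous"):
            v = codon_usage("ATGNNNAAA")
        assert v.total == 2

    def test_longest_isoform_used(self, tmp_path):
        fa = tmp_path / "cds.fa"
        fa.write_text(
            ">iso1 gene=g1\nATGAAA\n>iso2\nATGAAACCCGGG\n>other\nATGTTT\n"
        )
        vectors = codon_usage_from_fasta(
            fa, isoform_of={"iso1": "g1", "iso2": "g1", "other": "g2"}
        )
        assert vectors["g1"].total == 4  # from the 12-nt isoform
        assert vectors["g2"].total == 2


class TestCodonMrTable:
    def test_identical_vectors_rank_one(self):
        rng = np.random.default_rng(0)
        vs = [codon_usage("".join(SENSE_CODONS[c] for c in rng.integers(0, 61, 50)),
                          gene=f"g{i}") for i in range(5)]
        twin = type(vs[0])(gene="twin", counts=vs[0].counts)
        table = codon_mr_table(vs + [twin])
        assert table.value("g0", "twin") == pytest.approx(1.0)

    def test_symmetric_and_at_least_one(self):
        rng = np.random.default_rng(1)
        vs = [codon_usage("".join(SENSE_CODONS[c] for c in rng.integers(0, 61, 60)),
                          gene=f"g{i}") for i in range(8)]
        t = codon_mr_table(vs)
        arr = t.mr.to_numpy()
        assert np.allclose(arr, arr.T, equal_nan=True)
        assert np.nanmin(arr) >= 1.0 - 1e-9


class TestCodonScore:
    def test_identical_tables_score_100(self):
        table = random_mr_table(30, seed=2)
        assert codon_score(table, table) == pytest.approx(100.0)

    def test_independent_tables_near_permutation_null(self):
        """Independent random tables score near the analytic null median.

        At k=ceil(0.01 * 999)=10 on 1,000 genes the null COXSIM per guide
        is usually 0, so the median is 0."""
        a = random_mr_table(60, seed=3)
        b = random_mr_table(60, seed=4)
        # k = 1 at this size: COXSIM is 1 iff the top genes match, so the
        # median over 60 guides is almost surely 0 under independence.
        assert codon_score(a, b) == pytest.approx(0.0)

    def test_invariant_to_consistent_relabeling(self):
        a = random_mr_table(25, seed=5)
        b = random_mr_table(25, seed=6)
        s1 = codon_score(a, b)
        relabel = {g: f"x_{g}" for g in a.gene_ids}
        ra = CoexpressionTable(a.mr.rename(index=relabel, columns=relabel))
        rb = CoexpressionTable(b.mr.rename(index=relabel, columns=relabel))
        assert codon_score(ra, rb) == pytest.approx(s1)


class TestSelectGoTerms:
    @pytest.mark.parametrize("size,kept", [(4, False), (5, True),
                                           (20, True), (21, False)])
    def test_size_window_boundaries(self, size, kept):
        ann = GOAnnotationSet.from_pairs(
            [(f"g{i}", "T") for i in range(size)]
        )
        assert ("T" in select_go_terms(ann)) is kept

    def test_empty_annotations(self):
        assert select_go_terms(GOAnnotationSet(annotations={})) == set()

    def test_selection_respects_table_universe(self):
        """Counting happens after restriction to the table's genes."""
        ann = GOAnnotationSet.from_pairs(
            [(f"g{i}", "T") for i in range(6)]
        )
        restricted = ann.restricted_to([f"g{i}" for i in range(4)])
        assert select_go_terms(restricted) == set()


def brute_force_pauc(labels, scores, cap):
    """Trapezoidal partial ROC oracle built from explicit threshold sweeps."""
    labels = np.asarray(labels, bool)
    scores = np.asarray(scores, float)
    n_pos, n_neg = labels.sum(), (~labels).sum()
    pts = [(0.0, 0.0)]
    for t in sorted(set(scores), reverse=True):
        sel = scores >= t
        pts.append(((sel & ~labels).sum() / n_neg, (sel & labels).sum() / n_pos))
    pts.append((1.0, 1.0))
    fpr = np.array([p[0] for p in pts])
    tpr = np.array([p[1] for p in pts])
    tpr_cap = np.interp(cap, fpr, tpr)
    keep = fpr <= cap
    return np.trapezoid(np.append(tpr[keep], tpr_cap),
                        np.append(fpr[keep], cap))


class TestPartialRocAuc:
    def test_perfect_separation_attains_cap(self):
        labels = [True] * 5 + [False] * 200
        scores = list(np.linspace(10, 9, 5)) + list(np.linspace(5, 1, 200))
        assert partial_roc_auc(labels, scores, 0.01) == pytest.approx(0.01)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(50, 200))
        labels = rng.random(n) < 0.3
        if labels.all() or not labels.any():
            labels[0] = True
            labels[1] = False
        scores = rng.normal(size=n)
        cap = 0.05
        assert partial_roc_auc(labels, scores, cap) == pytest.approx(
            brute_force_pauc(labels, scores, cap)
        )

    def test_degenerate_labels_rejected(self):
        with pytest.raises(ValueError):
            partial_roc_auc([True, True], [1.0, 2.0], 0.01)


class TestGoScore:
    def _annotated_table(self, seed, n=40):
        table = random_mr_table(n, seed=seed)
        genes = table.gene_ids
        ann = GOAnnotationSet.from_pairs(
            [(g, "GO:A") for g in genes[:6]] + [(g, "GO:B") for g in genes[6:12]]
        )
        return table, ann

    def test_perfect_separation_scores_100(self):
        """When every shared-term pair has lower MR than every other pair,
        the partial area is maximal: 0.01 x 10^4 = 100 units."""
        n = 40
        genes = [f"g{i:03d}" for i in range(n)]
        rng = np.random.default_rng(7)
        base = rng.uniform(10, 30, size=(n, n))
        mr = (base + base.T) / 2
        np.fill_diagonal(mr, np.nan)
        ann_pairs = [(g, "GO:A") for g in genes[:6]]
        ann_pairs += [(g, "GO:B") for g in genes[6:12]]
        for block in (genes[:6], genes[6:12]):
            for i, a in enumerate(block):
                for b in block[i + 1:]:
                    ia, ib = genes.index(a), genes.index(b)
                    mr[ia, ib] = mr[ib, ia] = rng.uniform(1, 2)
        table = CoexpressionTable(pd.DataFrame(mr, index=genes, columns=genes))
        score = go_score(table, GOAnnotationSet.from_pairs(ann_pairs))
        assert score == pytest.approx(100.0)

    def test_random_ranking_matches_analytic_expectation(self):
        """Exchangeable rankings give E[pAUC] = cap^2 / 2, i.e. 0.5 units."""
        rng = np.random.default_rng(8)
        n_pos, n_neg, reps = 60, 1500, 200
        labels = np.array([True] * n_pos + [False] * n_neg)
        vals = []
        for _ in range(reps):
            scores = rng.permutation(n_pos + n_neg).astype(float)
            vals.append(partial_roc_auc(labels, scores, 0.01) * 1e4)
        se = np.std(vals, ddof=1) / np.sqrt(reps)
        assert abs(np.mean(vals) - 0.5) < 3 * se

    def test_all_pairs_positive_is_error(self):
        table = random_mr_table(10, seed=9)
        ann = GOAnnotationSet.from_pairs(
            [(g, "GO:A") for g in table.gene_ids[:5]]
        )
        with pytest.raises(ValueError):
            go_score(table, ann)


class TestReferenceAdequateness:
    def test_self_reference_is_one(self):
        t = BitscoreTable.from_records([("g", "g", 400)], "A", "A")
        assert reference_adequateness("g", "g", t) == pytest.approx(1.0)

    def test_bitscore_ratio(self):
        cross = BitscoreTable.from_records([("g", "r", 200)], "A", "B")
        own = BitscoreTable.from_records([("g", "g", 400)], "A", "A")
        assert reference_adequateness("g", "r", cross, own) == pytest.approx(0.5)

    def test_ratio_above_one_warns(self):
        cross = BitscoreTable.from_records([("g", "r", 500)], "A", "B")
        own = BitscoreTable.from_records([("g", "g", 400)], "A", "A")
        with pytest.warns(UserWarning, match="exceeds"):
            assert reference_adequateness("g", "r", cross, own) > 1

    def test_missing_score_is_error(self):
        cross = BitscoreTable.from_records([("g", "r", 200)], "A", "B")
        with pytest.raises(KeyError):
            reference_adequateness("g", "x", cross)


class TestReproducibilityScore:
    def _duplicate_collection(self, n=30, seed=10):
        table = random_mr_table(n, seed=seed)
        a = CoexDataset("d1", "sp", table)
        b = CoexDataset("d2", "sp", table)
        self_scores = BitscoreTable.from_records(
            [(g, g, 400.0) for g in table.gene_ids], "sp", "sp"
        )
        return StudyCollection.from_datasets([a, b], {("sp", "sp"): self_scores})

    def test_duplicate_dataset_scores_ten(self):
        """A dataset reproduced by an identical same-species copy: every
        guide has COXSIM 1 and adequateness 1, so the score is 10."""
        collection = self._duplicate_collection()
        assert reproducibility_score("d1", collection) == pytest.approx(10.0)

    def test_single_guide_arithmetic(self):
        """maxCOXSIM 0.3 at adequateness 0.6 normalizes to 0.5 -> score 5.0."""
        assert 0.3 / 0.6 * 10 == pytest.approx(5.0)

    def test_noisier_reference_does_not_increase_score(self, study):
        """Degrading the reference tables (random relabeling of a clade's
        counterpart tables) cannot raise the median normalized maxCOXSIM
        for planted module guides."""
        collection, truth, cfg = study
        guides = [
            g for m in truth.modules if m.scope in ("conserved", "dicot")
            for g in [cfg.gene_name("dsp1", i) for i in m.gene_indices]
        ]
        guides = [g for g in guides if g in collection.datasets["dsp1-x"].universe]
        baseline = reproducibility_score("dsp1-x", collection, guides=guides)

        rng = np.random.default_rng(0)
        degraded_sets = []
        for ds_id in collection.dataset_ids:
            ds = collection.datasets[ds_id]
            if ds_id == "dsp1-x":
                degraded_sets.append(ds)
                continue
            genes = ds.table.gene_ids
            shuffled = list(rng.permutation(genes))
            relabel = dict(zip(genes, shuffled))
            mr = ds.table.mr.rename(index=relabel, columns=relabel)
            mr = mr.loc[genes, genes]
            degraded_sets.append(
                CoexDataset(ds_id, ds.species, CoexpressionTable(mr))
            )
        degraded = StudyCollection.from_datasets(degraded_sets,
                                                 collection.bitscores)
        worse = reproducibility_score("dsp1-x", degraded, guides=guides)
        assert worse <= baseline + 1e-9

    def test_no_assessable_guides_is_error(self):
        table = random_mr_table(10, seed=11)
        lone = StudyCollection.from_datasets(
            [CoexDataset("only", "sp", table)], {}
        )
        with pytest.raises(ValueError):
            reproducibility_score("only", lone)
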