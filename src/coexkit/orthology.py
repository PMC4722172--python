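"""Best hits, reciprocal best hits and one-gene-per-species ortholog groups.

Works from pairwise Blastp bitscore tables in blast tabular form
(qseqid, sseqid, bitscore).  Running the alignment search itself is out of
scope; the toolkit consumes its tabular output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "BitscoreTable",
    "OrthologGroup",
    "best_hit",
    "rbh_pairs",
    "orthologous_groups",
]


@dataclass
class BitscoreTable:
    """Pairwise Blastp bitscores oriented query-species -> subject-species.

    Duplicate (query, subject) records keep the maximum bitscore.  Self
    records (g, g) are allowed and carry the self-score used by the
    reference-adequateness ratio.
    """

    query_species: str
    subject_species: str
    scores: dict[str, dict[str, float]] = field(default_factory=dict)

    def add(self, query: str, subject: str, bitscore: float) -> None:
        if bitscore <= 0:
            raise ValueError("bitscores must be positive")
        row = self.scores.setdefault(query, {})
        if subject not in row or bitscore > row[subject]:
            row[subject] = float(bitscore)

    @classmethod
    def from_records(
        cls,
        records: Iterable[tuple[str, str, float]],
        query_species: str,
        subject_species: str,
    ) -> "BitscoreTable":
        table = cls(query_species, subject_species)
        for q, s, b in records:
            table.add(q, s, b)
        return table

    @classmethod
    def from_blast_tsv(
        cls, path, query_species: str, subject_species: str
    ) -> "BitscoreTable":
        """Read an outfmt-6-like table; only qseqid, sseqid, bitscore are used.

        Accepts either the full 12-column layout (bitscore last) or a
        reduced 3-column (qseqid, sseqid, bitscore) file.
        """
        df = pd.read_csv(path, sep="\t", header=None, dtype=str)
        if df.shape[1] < 3:
            raise ValueError("blast tabular input needs at least 3 columns")
        bit_col = 2 if df.shape[1] == 3 else 11
        recs = zip(df[0], df[1], df[bit_col].astype(float))
        return cls.from_records(recs, query_species, subject_species)

    def score(self, query: str, subject: str) -> float | None:
        return self.scores.get(query, {}).get(subject)

    def queries(self) -> list[str]:
        return sorted(self.scores)


def best_hit(g: str, table: BitscoreTable) -> str | None:
    """Highest-bitscore subject for *g*; ties broken lexicographically.

    For a same-species table the gene itself is excluded so the hit is the
    closest paralog rather than the trivial self match.  Returns ``None``
    when *g* has no (non-self) records.
    """
    row = table.scores.get(g)
    if not row:
        return None
    same_species = table.query_species == table.subject_species
    candidates = [(s, b) for s, b in row.items() if not (same_species and s == g)]
    if not candidates:
        return None
    # max bitscore, then lexicographically smallest subject
    return min(candidates, key=lambda sb: (-sb[1], sb[0]))[0]


def rbh_pairs(
    table_ab: BitscoreTable, table_ba: BitscoreTable
) -> set[tuple[str, str]]:
    """Reciprocal best hits: (a, b) with best_hit(a)=b and best_hit(b)=a.

    Pairs are returned oriented (gene of ``table_ab``'s query species,
    gene of its subject species) regardless of argument order semantics.
    """
    pairs: set[tuple[str, str]] = set()
    for a in table_ab.scores:
        b = best_hit(a, table_ab)
        if b is not None and best_hit(b, table_ba) == a:
            pairs.add((a, b))
    return pairs


@dataclass(frozen=True)
class OrthologGroup:
    """One gene per species; every cross-species pair is a reciprocal best hit."""

    genes: tuple[tuple[str, str], ...]  # (species, gene), species-sorted

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, str]) -> "OrthologGroup":
        return cls(tuple(sorted(mapping.items())))

    def gene_of(self, species: str) -> str:
        return dict(self.genes)[species]

    @property
    def species(self) -> tuple[str, ...]:
        return tuple(s for s, _ in self.genes)


def orthologous_groups(
    species: Sequence[str],
    tables: Mapping[tuple[str, str], BitscoreTable],
) -> list[OrthologGroup]:
    """Maximal one-gene-per-species RBH cliques across all species pairs.

    Because best hits are unique (deterministic tie-break), each gene has at
    most one RBH partner in every other species, so a group is determined by
    its member in the first species and validated by checking that all
    pairwise partner assignments agree.
    """
    species = list(species)
    if len(species) < 2:
        raise ValueError("need at least two species")
    for s1 in species:
        for s2 in species:
            if s1 != s2 and (s1, s2) not in tables:
                raise KeyError(f"missing bitscore table for pair ({s1}, {s2})")

    partner: dict[tuple[str, str], dict[str, str]] = {}
    for i, s1 in enumerate(species):
        for s2 in species[i + 1:]:
            for a, b in rbh_pairs(tables[(s1, s2)], tables[(s2, s1)]):
                partner.setdefault((s1, s2), {})[a] = b
                partner.setdefault((s2, s1), {})[b] = a

    anchor = species[0]
    groups: list[OrthologGroup] = []
    for a in sorted(tables[(anchor, species[1])].scores):
        members = {anchor: a}
        ok = True
        for s in species[1:]:
            m = partner.get((anchor, s), {}).get(a)
            if m is None:
                ok = False
                break
            members[s] = m
        if not ok:
            continue
        # every cross pair among non-anchor species must also be an RBH
        for i, s1 in enumerate(species[1:], start=1):
            for s2 in species[i + 1:]:
                if partner.get((s1, s2), {}).get(members[s1]) != members[s2]:
                    ok = False
                    break
            if not ok:
                break
        if ok:
            groups.append(OrthologGroup.from_mapping(members))
    return groups
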