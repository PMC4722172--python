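"""A collection of coexpression datasets with cross-dataset gene maps.

Bundles every dataset's MR table with the pairwise Blastp bitscore tables
and derives dataset-to-dataset correspondence maps: identity within a
species, reciprocal-best-hit partial bijections across species.  The
higher-level operations (maxCOXSIM, reproducibility score, dataset
similarity) all work from this object.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .coextable import CoexDataset
from .coxsim import (
    CorrespondenceMap,
    SignificanceResult,
    build_reference_set,
    max_coxsim,
)
from .orthology import BitscoreTable, rbh_pairs

__all__ = ["StudyCollection"]


@dataclass
class StudyCollection:
    datasets: dict[str, CoexDataset]
    bitscores: dict[tuple[str, str], BitscoreTable] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._species_maps: dict[tuple[str, str], dict[str, str]] = {}
        self._dataset_maps: dict[tuple[str, str], CorrespondenceMap] = {}

    # -- construction -----------------------------------------------------

    @classmethod
    def from_datasets(
        cls,
        datasets: Sequence[CoexDataset],
        bitscores: Mapping[tuple[str, str], BitscoreTable] | None = None,
    ) -> "StudyCollection":
        return cls(
            datasets={d.id: d for d in datasets},
            bitscores=dict(bitscores or {}),
        )

    @property
    def dataset_ids(self) -> list[str]:
        return sorted(self.datasets)

    def species_of(self, dataset_id: str) -> str:
        return self.datasets[dataset_id].species

    # -- gene correspondence ----------------------------------------------

    def _species_map(self, sp_a: str, sp_b: str) -> dict[str, str]:
        """RBH gene mapping between two species, cached."""
        key = (sp_a, sp_b)
        if key not in self._species_maps:
            tab_ab = self.bitscores.get((sp_a, sp_b))
            tab_ba = self.bitscores.get((sp_b, sp_a))
            if tab_ab is None or tab_ba is None:
                raise KeyError(f"missing bitscore tables between {sp_a} and {sp_b}")
            fwd = dict(rbh_pairs(tab_ab, tab_ba))
            self._species_maps[key] = fwd
            self._species_maps[(sp_b, sp_a)] = {b: a for a, b in fwd.items()}
        return self._species_maps[key]

    def map_between(self, ds_a: str, ds_b: str) -> CorrespondenceMap:
        """Correspondence map from dataset ``ds_a``'s genes to ``ds_b``'s.

        Identity within a species; RBH across species.  The map covers the
        source universe; list restriction handles genes whose counterpart
        is absent from the target table.
        """
        key = (ds_a, ds_b)
        if key not in self._dataset_maps:
            a, b = self.datasets[ds_a], self.datasets[ds_b]
            if a.species == b.species:
                pairs = {g: g for g in a.gene_ids}
            else:
                pairs = self._species_map(a.species, b.species)
            self._dataset_maps[key] = CorrespondenceMap(ds_a, ds_b, pairs)
        return self._dataset_maps[key]

    def all_maps(self) -> dict[tuple[str, str], CorrespondenceMap]:
        ids = self.dataset_ids
        return {
            (a, b): self.map_between(a, b)
            for a in ids for b in ids if a != b
        }

    # -- per-guide assessment ----------------------------------------------

    def reference_set(self, g: str, dataset_id: str) -> list[tuple[str, str]]:
        dataset = self.datasets[dataset_id]
        others = [self.datasets[i] for i in self.dataset_ids]
        return build_reference_set(g, dataset, others, self.bitscores)

    def max_coxsim(
        self, g: str, dataset_id: str, k_fraction: float = 0.01
    ) -> SignificanceResult:
        dataset = self.datasets[dataset_id]
        refs = self.reference_set(g, dataset_id)
        maps = {
            key: self.map_between(*key)
            for key in [(dataset_id, ds) for ds, _ in refs]
            + [(ds, dataset_id) for ds, _ in refs]
        }
        return max_coxsim(g, refs, dataset, self.datasets, maps, k_fraction)
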