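"""Seeded synthetic fixtures with planted ground truth for every input type.

The generator emulates the study design the toolkit targets: two clades
(dicot-like and monocot-like) with two species each, and two expression
datasets ("platforms") per species.  Genes form planted coexpression
modules driven by shared latent factors; modules are either conserved
across all species or active in one clade only.  Counts follow a
log-normal-then-Poisson scheme, with some sequencing runs planted below
the 10M mapped-count bar and some genes below the 100 peak-count bar to
exercise the filters.  Companion generators emit CDS and promoter FASTA
records (with module-aligned codon bias and a planted promoter heptamer),
pairwise Blastp-like bitscore tables whose reciprocal best hits recover the
planted orthology, and GO annotations aligned with the modules.

Everything is a pure function of the seed: the same config yields
byte-identical outputs.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .coextable import CoexDataset
from .collection import StudyCollection
from .expression import CountMatrix, preprocess_counts, correlation_matrix, mutual_rank
from .orthology import BitscoreTable
from .scores import SENSE_CODONS, GOAnnotationSet

__all__ = [
    "PlantedModule",
    "FixtureConfig",
    "PlantedTruth",
    "gen_expression_datasets",
    "gen_sequences",
    "gen_bitscores",
    "gen_go",
    "build_mr_tables",
    "default_collection",
    "scaled_lineage_thresholds",
    "write_fixture",
]


@dataclass(frozen=True)
class PlantedModule:
    """A planted coexpression module: member gene indices and where it is active."""

    name: str
    scope: str  # "conserved", "dicot" or "monocot"
    gene_indices: tuple[int, ...]


def _default_modules() -> tuple[PlantedModule, ...]:
    scopes = ["conserved"] * 4 + ["dicot"] * 3 + ["monocot"] * 3
    return tuple(
        PlantedModule(
            name=f"M{j}",
            scope=scope,
            gene_indices=tuple(range(j * 5, j * 5 + 5)),
        )
        for j, scope in enumerate(scopes)
    )


@dataclass(frozen=True)
class FixtureConfig:
    """All knobs of the synthetic study; the seed fixes every draw."""

    seed: int = 17
    n_genes: int = 200
    n_runs: int = 30              # per dataset, incl. planted low-depth runs
    n_experiments: int = 3
    clades: tuple[tuple[str, tuple[str, str]], ...] = (
        ("dicot", ("dsp1", "dsp2")),
        ("monocot", ("msp1", "msp2")),
    )
    platforms: tuple[str, ...] = ("x", "y")
    modules: tuple[PlantedModule, ...] = field(default_factory=_default_modules)
    module_loading: float = 2.0   # latent-factor loading (log2 units)
    noise_sd: float = 0.4         # per-gene log2 noise
    base_log2_range: tuple[float, float] = (13.0, 18.0)
    run_depth: float = 15e6       # expected mapped reads per good run
    n_low_depth_runs: int = 2     # planted runs below the 10M filter
    n_low_expression_genes: int = 10  # planted genes below the peak filter
    low_expression_log2: float = 1.0
    cds_codon_range: tuple[int, int] = (100, 300)
    promoter_length: int = 300
    planted_heptamer: str = "CACGTGT"
    carrier_module: int = 0       # module whose genes carry the heptamer
    self_bitscore: float = 450.0
    rbh_noise: float = 0.0        # fraction of ortholog pairs with broken reciprocity
    n_decoys: int = 2

    def __post_init__(self) -> None:
        used = [i for m in self.modules for i in m.gene_indices]
        if len(used) != len(set(used)):
            raise ValueError("modules overlap")
        if used and max(used) >= self.n_genes - self.n_low_expression_genes:
            raise ValueError("modules collide with planted low-expression genes")
        if len(self.planted_heptamer) != 7:
            raise ValueError("planted motif must be a heptamer")
        if not 0 <= self.rbh_noise <= 1:
            raise ValueError("rbh_noise must lie in [0, 1]")

    # -- naming -----------------------------------------------------------

    @property
    def species(self) -> list[str]:
        return [sp for _, pair in self.clades for sp in pair]

    def clade_of(self, species: str) -> str:
        for clade, pair in self.clades:
            if species in pair:
                return clade
        raise KeyError(species)

    @property
    def dataset_ids(self) -> list[str]:
        return [f"{sp}-{p}" for sp in self.species for p in self.platforms]

    def species_of_dataset(self, dataset_id: str) -> str:
        return dataset_id.rsplit("-", 1)[0]

    def gene_name(self, species: str, index: int) -> str:
        return f"{species}_g{index:03d}"

    def gene_names(self, species: str) -> list[str]:
        return [self.gene_name(species, i) for i in range(self.n_genes)]


@dataclass
class PlantedTruth:
    """Ground truth mirrored from the generator, for tests and recall checks."""

    modules: tuple[PlantedModule, ...]
    species: list[str]
    low_expression_genes: dict[str, list[str]]   # species -> gene names
    low_depth_runs: dict[str, list[str]]         # dataset id -> run ids
    carriers: dict[str, list[str]]               # species -> heptamer carriers
    planted_heptamer: str
    codon_aligned_modules: tuple[str, ...]
    broken_rbh: dict[str, list[int]]             # "spA|spB" -> gene indices

    def module_genes(self, species: str, cfg: FixtureConfig) -> dict[str, list[str]]:
        return {
            m.name: [cfg.gene_name(species, i) for i in m.gene_indices]
            for m in self.modules
        }

    def to_json(self, path) -> None:
        payload = asdict(self)
        payload["modules"] = [asdict(m) for m in self.modules]
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


# ---------------------------------------------------------------------------
# expression counts


def _base_log2(cfg: FixtureConfig, species_index: int) -> np.ndarray:
    rng = np.random.default_rng([cfg.seed, 1000 + species_index])
    lo, hi = cfg.base_log2_range
    base = rng.uniform(lo, hi, size=cfg.n_genes)
    if cfg.n_low_expression_genes:
        base[-cfg.n_low_expression_genes:] = cfg.low_expression_log2
    return base


def gen_expression_datasets(
    cfg: FixtureConfig,
) -> tuple[dict[str, CountMatrix], PlantedTruth]:
    """Counts for every dataset plus the planted truth.

    Genes in a module active in the dataset's clade share a per-run latent
    factor; counts are Poisson draws around ``2 ** log2-intensity``.  The
    first ``n_low_depth_runs`` runs of each dataset are scaled to a few
    thousand total counts so the depth filter removes them.
    """
    datasets: dict[str, CountMatrix] = {}
    low_depth: dict[str, list[str]] = {}
    runs_per_exp = max(1, math.ceil(cfg.n_runs / cfg.n_experiments))
    for di, ds_id in enumerate(cfg.dataset_ids):
        sp = cfg.species_of_dataset(ds_id)
        sp_index = cfg.species.index(sp)
        clade = cfg.clade_of(sp)
        base = _base_log2(cfg, sp_index)
        rng = np.random.default_rng([cfg.seed, 2000 + di])
        active = [m for m in cfg.modules if m.scope in ("conserved", clade)]
        x = base[:, None] + rng.normal(0.0, cfg.noise_sd,
                                       size=(cfg.n_genes, cfg.n_runs))
        exp_of_run = {}
        run_ids = [f"{ds_id}_run{j:02d}" for j in range(cfg.n_runs)]
        for j, run in enumerate(run_ids):
            exp_of_run[run] = f"{ds_id}_exp{j // runs_per_exp}"
        offsets = rng.normal(0.0, 0.25, size=cfg.n_experiments)
        for j in range(cfg.n_runs):
            x[:, j] += offsets[min(j // runs_per_exp, cfg.n_experiments - 1)]
        for m in active:
            factor = rng.normal(0.0, 1.0, size=cfg.n_runs)
            for i in m.gene_indices:
                x[i] += cfg.module_loading * factor
        abundance = np.power(2.0, x)
        # library size is a run property: scale abundances to the target depth
        lam = abundance / abundance.sum(axis=0, keepdims=True) * cfg.run_depth
        if cfg.n_low_depth_runs:
            lam[:, : cfg.n_low_depth_runs] *= 1e-4
        counts = rng.poisson(lam).astype(np.int64)
        datasets[ds_id] = CountMatrix(
            counts=pd.DataFrame(counts, index=cfg.gene_names(sp), columns=run_ids),
            experiment_of_run=exp_of_run,
        )
        low_depth[ds_id] = run_ids[: cfg.n_low_depth_runs]

    n_aligned = max(1, len(cfg.modules) // 2)
    truth = PlantedTruth(
        modules=cfg.modules,
        species=cfg.species,
        low_expression_genes={
            sp: [cfg.gene_name(sp, i)
                 for i in range(cfg.n_genes - cfg.n_low_expression_genes,
                                cfg.n_genes)]
            for sp in cfg.species
        },
        low_depth_runs=low_depth,
        carriers={
            sp: ([cfg.gene_name(sp, i)
                  for i in cfg.modules[cfg.carrier_module].gene_indices]
                 if cfg.modules else [])
            for sp in cfg.species
        },
        planted_heptamer=cfg.planted_heptamer,
        codon_aligned_modules=tuple(m.name for m in cfg.modules[:n_aligned]),
        broken_rbh={},
    )
    return datasets, truth


# ---------------------------------------------------------------------------
# sequences


def gen_sequences(
    cfg: FixtureConfig, species: str
) -> tuple[dict[str, str], dict[str, str]]:
    """CDS and promoter sequences for one species's genes.

    CDS are stop-free internally (ATG + sense codons + TAA) with per-module
    codon bias for the codon-aligned modules, so codon-usage similarity
    mirrors part of the planted module structure.  Promoters are uniform
    random except that carrier genes receive the planted heptamer at
    positions [-150, -144].
    """
    sp_index = cfg.species.index(species)
    rng = np.random.default_rng([cfg.seed, 3000 + sp_index])
    n_aligned = max(1, len(cfg.modules) // 2)
    bias_of_gene: dict[int, np.ndarray] = {}
    for m in cfg.modules[:n_aligned]:
        z = np.random.default_rng(
            [cfg.seed, 4000 + cfg.modules.index(m)]
        ).normal(0.0, 1.2, size=61)  # shared across species: orthologs match
        for i in m.gene_indices:
            bias_of_gene[i] = z

    cds: dict[str, str] = {}
    promoters: dict[str, str] = {}
    lo, hi = cfg.cds_codon_range
    motif_at = 150  # bases upstream of the start for the planted heptamer
    carrier_idx = (
        set(cfg.modules[cfg.carrier_module].gene_indices) if cfg.modules else set()
    )
    for i in range(cfg.n_genes):
        gene = cfg.gene_name(species, i)
        z = bias_of_gene.get(i)
        if z is None:
            z = rng.normal(0.0, 0.3, size=61)
        p = np.exp(z)
        p /= p.sum()
        n_codons = int(rng.integers(lo, hi + 1))
        body = rng.choice(61, size=n_codons, p=p)
        cds[gene] = "ATG" + "".join(SENSE_CODONS[c] for c in body) + "TAA"
        prom = rng.choice(list("ACGT"), size=cfg.promoter_length)
        seq = "".join(prom)
        if i in carrier_idx:
            pos = cfg.promoter_length - motif_at
            seq = seq[:pos] + cfg.planted_heptamer + seq[pos + 7:]
        promoters[gene] = seq
    return cds, promoters


def write_fasta(seqs: Mapping[str, str], path) -> None:
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord
    from Bio import SeqIO

    records = [SeqRecord(Seq(s), id=g, description="") for g, s in sorted(seqs.items())]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# bitscores


def gen_bitscores(
    cfg: FixtureConfig,
) -> tuple[dict[tuple[str, str], BitscoreTable], dict[str, list[int]]]:
    """Pairwise bitscore tables whose RBHs recover the planted orthology.

    Gene *i* of one species is the planted ortholog of gene *i* of every
    other.  Self tables carry maximal self-scores; cross tables give the
    planted pair the top score in both directions plus lower-scoring decoy
    hits.  With ``rbh_noise > 0`` a fraction of pairs per species pair get
    one direction's decoy boosted above the ortholog, breaking reciprocity.
    """
    tables: dict[tuple[str, str], BitscoreTable] = {}
    broken: dict[str, list[int]] = {}
    species = cfg.species
    rng_self = np.random.default_rng([cfg.seed, 5000])
    self_scores = {
        sp: cfg.self_bitscore + rng_self.uniform(0, 50, size=cfg.n_genes)
        for sp in species
    }
    for sp in species:
        t = BitscoreTable(sp, sp)
        for i in range(cfg.n_genes):
            t.add(cfg.gene_name(sp, i), cfg.gene_name(sp, i), self_scores[sp][i])
        tables[(sp, sp)] = t

    for a_idx, sp_a in enumerate(species):
        for sp_b in species[a_idx + 1:]:
            pair_rng = np.random.default_rng(
                [cfg.seed, 6000 + a_idx * 10 + species.index(sp_b)]
            )
            ortho = pair_rng.uniform(250, 380, size=cfg.n_genes)
            t_ab = BitscoreTable(sp_a, sp_b)
            t_ba = BitscoreTable(sp_b, sp_a)
            n_broken = int(round(cfg.rbh_noise * cfg.n_genes))
            broken_idx = sorted(
                pair_rng.choice(cfg.n_genes, size=n_broken, replace=False)
            ) if n_broken else []
            broken[f"{sp_a}|{sp_b}"] = [int(i) for i in broken_idx]
            broken_set = set(broken_idx)
            for i in range(cfg.n_genes):
                ga, gb = cfg.gene_name(sp_a, i), cfg.gene_name(sp_b, i)
                t_ab.add(ga, gb, ortho[i])
                t_ba.add(gb, ga, ortho[i])
                decoys = pair_rng.choice(cfg.n_genes, size=cfg.n_decoys, replace=False)
                for d in decoys:
                    if d == i:
                        continue
                    s = pair_rng.uniform(50, ortho[i] - 20)
                    t_ab.add(ga, cfg.gene_name(sp_b, int(d)), s)
                    t_ba.add(gb, cfg.gene_name(sp_a, int(d)), s)
                if i in broken_set:
                    # boost one decoy above the ortholog in the A -> B direction
                    d = int((i + 1) % cfg.n_genes)
                    t_ab.add(ga, cfg.gene_name(sp_b, d), ortho[i] + 10)
            tables[(sp_a, sp_b)] = t_ab
            tables[(sp_b, sp_a)] = t_ba
    return tables, broken


# ---------------------------------------------------------------------------
# GO annotations


def gen_go(cfg: FixtureConfig, species: str) -> GOAnnotationSet:
    """Module-aligned GO terms plus filter-exercising and background terms.

    Every planted module gets a term covering its members (plus one random
    extra gene, keeping sizes inside the 5-20 selection window); one term
    of size 4 and one of size 21 straddle the window; a few background
    terms annotate random genes.
    """
    sp_index = cfg.species.index(species)
    rng = np.random.default_rng([cfg.seed, 7000 + sp_index])
    pairs: list[tuple[str, str]] = []
    usable = cfg.n_genes - cfg.n_low_expression_genes
    for m in cfg.modules:
        term = f"GO:{m.name}"
        members = list(m.gene_indices)
        extra = int(rng.integers(0, usable))
        if extra not in members:
            members.append(extra)
        for i in members:
            pairs.append((cfg.gene_name(species, i), term))
    tiny = rng.choice(usable, size=4, replace=False)
    pairs += [(cfg.gene_name(species, int(i)), "GO:TINY") for i in tiny]
    big = rng.choice(usable, size=21, replace=False)
    pairs += [(cfg.gene_name(species, int(i)), "GO:BIG") for i in big]
    for b in range(5):
        size = int(rng.integers(6, 16))
        genes = rng.choice(usable, size=size, replace=False)
        pairs += [(cfg.gene_name(species, int(i)), f"GO:BG{b}") for i in genes]
    return GOAnnotationSet.from_pairs(pairs)


# ---------------------------------------------------------------------------
# assembled study


def build_mr_tables(
    cfg: FixtureConfig,
) -> tuple[dict[str, CoexDataset], PlantedTruth]:
    """Run every generated count matrix through the full MR pipeline."""
    counts, truth = gen_expression_datasets(cfg)
    datasets = {}
    for ds_id, cm in counts.items():
        expr = preprocess_counts(cm)
        table = mutual_rank(correlation_matrix(expr))
        datasets[ds_id] = CoexDataset(
            id=ds_id, species=cfg.species_of_dataset(ds_id), table=table
        )
    return datasets, truth


def default_collection(
    seed: int = 17, cfg: FixtureConfig | None = None
) -> tuple[StudyCollection, PlantedTruth, FixtureConfig]:
    """The default synthetic study: MR tables, bitscores and gene maps."""
    if cfg is None:
        cfg = FixtureConfig(seed=seed)
    datasets, truth = build_mr_tables(cfg)
    bitscores, broken = gen_bitscores(cfg)
    truth.broken_rbh = broken
    collection = StudyCollection.from_datasets(list(datasets.values()), bitscores)
    return collection, truth, cfg


def scaled_lineage_thresholds(n_genes: int) -> tuple[int, int]:
    """Lineage thresholds proportional to table size.

    The genome-scale defaults (strong MR < 500, weak MR > 5000 at roughly
    2 x 10^4 genes) map to 5% and 15% of the gene count at fixture scale;
    the background geometric-average MR sits near ``n / e``, comfortably
    above the weak bound.
    """
    return max(2, round(0.05 * n_genes)), max(3, round(0.15 * n_genes))


def write_fixture(cfg: FixtureConfig, outdir) -> None:
    """Emit every fixture file (TSVs, FASTAs, bitscores, GO, truth JSON)."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    counts, truth = gen_expression_datasets(cfg)
    for ds_id, cm in counts.items():
        cm.to_tsv(out / f"counts_{ds_id}.tsv", out / f"runs_{ds_id}.tsv")
    bitscores, broken = gen_bitscores(cfg)
    truth.broken_rbh = broken
    for (sp_a, sp_b), table in bitscores.items():
        with open(out / f"bitscores_{sp_a}_{sp_b}.tsv", "w") as fh:
            for q in table.queries():
                for s, b in sorted(table.scores[q].items()):
                    fh.write(f"{q}\t{s}\t{b:.1f}\n")
    for sp in cfg.species:
        cds, promoters = gen_sequences(cfg, sp)
        write_fasta(cds, out / f"cds_{sp}.fasta")
        write_fasta(promoters, out / f"promoters_{sp}.fasta")
        gen_go(cfg, sp).to_tsv(out / f"go_{sp}.tsv")
    truth.to_json(out / "truth.json")
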