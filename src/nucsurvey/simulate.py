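"""Synthetic datasets with planted probe homologs.

The generator emulates, at desk scale, a complete-genomes database keyed to
a taxonomy: a rank-complete toy tree (phylum -> ... -> species), a genome
manifest with type-material flags, and per-genome replicons (a random
chromosome, optionally a plasmid) in which divergence-controlled homologs
of synthetic probe proteins are planted by back-translation, on either
strand.  Decoy ORFs unrelated to any probe are planted as well.  Every
draw is fixed by the seed, so two runs with the same configuration are
byte-identical.

Each species is assigned a presence plan ``(fraction of genomes with a
U-family gene, fraction with a C-family gene)`` from a fixed cycle that
covers the four joint categories and all presence levels; the ground truth
(which probe was planted where, and the expected per-genome U/C status
under perfect recovery) is recorded in a :class:`TruthManifest`.

Background composition is uniform over ACGT with no repeat or gene-model
structure; the datasets exercise the pipeline's bookkeeping and scoring,
not the statistics of real genomes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Iterable, Mapping

import numpy as np
from Bio.Data import CodonTable
from Bio.Seq import Seq

from .alignment import reverse_complement
from .panel import ProbeRecord
from .search import GenomeRecord, Replicon
from .survey import PresenceLevel, SurveyConfig, classify_presence, eligible_genomes, is_complete
from .taxonomy import (
    GenomeManifestEntry,
    TaxonNode,
    TaxonomyTree,
    genomes_of,
)

__all__ = [
    "SyntheticConfig",
    "PlantedGene",
    "TruthManifest",
    "SyntheticDataset",
    "PlacementError",
    "random_protein",
    "mutate_protein",
    "back_translate",
    "plant_orf",
    "generate_dataset",
    "write_dataset",
    "expected_survey",
    "PLAN_CYCLE",
]

_AA20 = "ACDEFGHIKLMNPQRSTVWY"


class PlacementError(ValueError):
    """A planted ORF does not fit or overlaps a previous plant."""


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator configuration.

    The default scale - 2 phyla x 2 classes x 2 orders x 2 families x
    2 genera x 3 species x 4 genomes = 384 genomes of 20 kb - is the
    standard study condition for full-pipeline runs; smaller configurations
    are used for unit tests.
    """

    seed: int = 0
    n_phyla: int = 2
    classes_per_phylum: int = 2
    orders_per_class: int = 2
    families_per_order: int = 2
    genera_per_family: int = 2
    species_per_genus: int = 3
    genomes_per_species: int = 4
    probe_length: int = 250
    n_ushA_probes: int = 5
    n_cpdB_probes: int = 2
    planted_identity: float = 1.0
    background_length: int = 20_000
    plasmid_length: int = 5_000
    plasmid_fraction: float = 0.25
    plant_on_plasmid: bool = False
    reverse_strand_fraction: float = 0.5
    type_material_fraction: float = 0.5
    n_decoy_orfs: int = 2
    decoy_length: int = 150
    genetic_code_id: int = 11

    def __post_init__(self) -> None:
        for name in (
            "planted_identity",
            "plasmid_fraction",
            "reverse_strand_fraction",
            "type_material_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.probe_length < 200:
            raise ValueError("probe_length must be >= 200 aa")


#: Per-species (U fraction, C fraction) plans, cycled in species order.
#: The cycle covers double positive/negative, discordant, and low/partial
#: presence levels at the default four genomes per species.
PLAN_CYCLE: tuple[tuple[float, float], ...] = (
    (1.0, 1.0),
    (0.0, 0.0),
    (1.0, 0.0),
    (0.0, 1.0),
    (1.0, 0.25),
    (0.25, 1.0),
    (0.75, 0.25),
    (0.25, 0.0),
    (0.0, 0.75),
    (1.0, 0.75),
    (0.5, 0.5),
    (0.75, 1.0),
)


@dataclass(frozen=True)
class PlantedGene:
    probe_accession: str
    kind: str
    identity: float
    strand: int  # +1 / -1
    replicon_id: str
    on_plasmid: bool
    position: int  # 0-based start of the CDS on the forward strand
    length_nt: int


@dataclass
class TruthManifest:
    """Ground truth of a generated dataset."""

    #: per genome accession: planted genes
    plants: dict[str, list[PlantedGene]] = field(default_factory=dict)
    #: per species taxid: (U fraction, C fraction) plan
    species_plan: dict[int, tuple[float, float]] = field(default_factory=dict)

    def expected_status(self, accession: str, exclude_plasmids: bool = True) -> tuple[bool, bool]:
        """Expected (has_U, has_C) under 100%-recovery assumptions."""
        has_u = has_c = False
        for g in self.plants.get(accession, []):
            if exclude_plasmids and g.on_plasmid:
                continue
            if g.kind == "UshA-like":
                has_u = True
            elif g.kind == "CpdB-like":
                has_c = True
        return has_u, has_c

    def to_json(self) -> str:
        return json.dumps(
            {
                "plants": {
                    acc: [asdict(g) for g in genes] for acc, genes in self.plants.items()
                },
                "species_plan": {str(t): list(p) for t, p in self.species_plan.items()},
            },
            indent=1,
        )


@dataclass
class SyntheticDataset:
    config: SyntheticConfig
    tree: TaxonomyTree
    manifest: list[GenomeManifestEntry]
    genomes: dict[str, GenomeRecord]
    probes: list[ProbeRecord]
    truth: TruthManifest

    def store(self):
        from .survey import InMemoryGenomeStore

        return InMemoryGenomeStore(self.genomes)


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def random_protein(length: int, seed) -> str:
    rng = _rng(seed)
    return "".join(rng.choice(list(_AA20), size=length))


def mutate_protein(sequence: str, target_identity: float, seed) -> str:
    """Substitute uniformly chosen positions with uniformly chosen
    different residues so the realized identity matches the target within
    one residue.  Length is preserved; deterministic per seed."""
    if not sequence:
        raise ValueError("empty sequence")
    if not 0.0 < target_identity <= 1.0:
        raise ValueError("target_identity must lie in (0, 1]")
    rng = _rng(seed)
    n_sub = int(round((1.0 - target_identity) * len(sequence)))
    if n_sub == 0:
        return sequence
    positions = rng.choice(len(sequence), size=n_sub, replace=False)
    chars = list(sequence)
    for pos in positions:
        alternatives = [a for a in _AA20 if a != chars[pos]]
        chars[pos] = alternatives[rng.integers(len(alternatives))]
    return "".join(chars)


def _codon_choices(genetic_code_id: int) -> tuple[dict[str, list[str]], list[str]]:
    table = CodonTable.unambiguous_dna_by_id[genetic_code_id]
    by_aa: dict[str, list[str]] = {}
    for codon, aa in sorted(table.forward_table.items()):
        by_aa.setdefault(aa, []).append(codon)
    return by_aa, sorted(table.stop_codons)


def back_translate(protein: str, seed, genetic_code_id: int = 11) -> str:
    """Map each residue to a uniformly chosen synonymous codon and append a
    terminal stop codon; re-translation recovers the protein."""
    rng = _rng(seed)
    by_aa, stops = _codon_choices(genetic_code_id)
    codons = [by_aa[aa][rng.integers(len(by_aa[aa]))] for aa in protein]
    codons.append(stops[rng.integers(len(stops))])
    return "".join(codons)


def plant_orf(
    replicon_sequence: str,
    cds: str,
    strand: int,
    position: int,
    occupied: list[tuple[int, int]] | None = None,
) -> str:
    """Overwrite ``replicon_sequence[position : position+len(cds)]`` with
    the CDS (reverse-complemented on the minus strand).

    ``occupied`` is a mutable list of half-open intervals of previous
    plants; an overlap raises :class:`PlacementError` and the new interval
    is appended on success.
    """
    end = position + len(cds)
    if position < 0 or end > len(replicon_sequence):
        raise PlacementError(
            f"CDS of {len(cds)} nt does not fit at {position} "
            f"(replicon {len(replicon_sequence)} nt)"
        )
    if occupied is not None:
        for a, b in occupied:
            if position < b and a < end:
                raise PlacementError(f"plant [{position},{end}) overlaps [{a},{b})")
        occupied.append((position, end))
    insert = cds if strand > 0 else reverse_complement(cds)
    return replicon_sequence[:position] + insert + replicon_sequence[end:]


def _random_nt(length: int, rng: np.random.Generator) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


def _free_position(
    rng: np.random.Generator, replicon_len: int, cds_len: int, occupied: list[tuple[int, int]]
) -> int:
    if cds_len > replicon_len:
        raise PlacementError("replicon too short for the requested plants")
    for _ in range(200):
        pos = int(rng.integers(0, replicon_len - cds_len + 1))
        if all(not (pos < b and a < pos + cds_len) for a, b in occupied):
            return pos
    raise PlacementError("could not place ORF without overlap; replicon too crowded")


def generate_dataset(config: SyntheticConfig | None = None) -> SyntheticDataset:
    """Generate taxonomy, manifest, probes, genomes and ground truth."""
    config = config or SyntheticConfig()
    rng = np.random.default_rng(config.seed)

    # --- probes ----------------------------------------------------------
    probes = []
    for i in range(config.n_ushA_probes):
        probes.append(
            ProbeRecord(
                accession=f"SYNU{i + 1:02d}",
                kind="UshA-like",
                sequence=random_protein(config.probe_length, rng),
            )
        )
    for i in range(config.n_cpdB_probes):
        probes.append(
            ProbeRecord(
                accession=f"SYNC{i + 1:02d}",
                kind="CpdB-like",
                sequence=random_protein(config.probe_length, rng),
            )
        )
    decoys = [
        random_protein(config.decoy_length, rng) for _ in range(config.n_decoy_orfs)
    ]

    # --- taxonomy --------------------------------------------------------
    nodes = [
        TaxonNode(1, "root", "no_rank", 1),
        TaxonNode(2, "Bacteria", "superkingdom", 1),
    ]
    next_taxid = 3
    species_taxids: list[int] = []

    def add_level(parents: list[int], rank: str, count: int, label: str) -> list[int]:
        nonlocal next_taxid
        created = []
        for parent in parents:
            for k in range(count):
                taxid = next_taxid
                next_taxid += 1
                nodes.append(TaxonNode(taxid, f"{label}_{taxid}", rank, parent))
                created.append(taxid)
        return created

    phyla = add_level([2], "phylum", config.n_phyla, "Phylum")
    classes = add_level(phyla, "class", config.classes_per_phylum, "Class")
    orders = add_level(classes, "order", config.orders_per_class, "Order")
    families = add_level(orders, "family", config.families_per_order, "Family")
    genera = add_level(families, "genus", config.genera_per_family, "Genus")
    species_taxids = add_level(genera, "species", config.species_per_genus, "Species")
    tree = TaxonomyTree(nodes)

    # --- genomes ---------------------------------------------------------
    truth = TruthManifest()
    manifest: list[GenomeManifestEntry] = []
    genomes: dict[str, GenomeRecord] = {}
    u_probes = [p for p in probes if p.kind == "UshA-like"]
    c_probes = [p for p in probes if p.kind == "CpdB-like"]
    genome_counter = 0

    for s_index, sp_taxid in enumerate(species_taxids):
        plan_u, plan_c = PLAN_CYCLE[s_index % len(PLAN_CYCLE)]
        truth.species_plan[sp_taxid] = (plan_u, plan_c)
        n = config.genomes_per_species
        k_u = int(round(plan_u * n))
        k_c = int(round(plan_c * n))
        order_u = rng.permutation(n)
        order_c = rng.permutation(n)
        with_u = set(int(x) for x in order_u[:k_u])
        with_c = set(int(x) for x in order_c[:k_c])
        probe_u = u_probes[s_index % len(u_probes)] if u_probes else None
        probe_c = c_probes[s_index % len(c_probes)] if c_probes else None

        for g_index in range(n):
            genome_counter += 1
            accession = f"SYN{genome_counter:05d}.1"
            is_type = g_index == 0 or rng.random() < config.type_material_fraction
            has_plasmid = config.plant_on_plasmid or rng.random() < config.plasmid_fraction

            chromosome = _random_nt(config.background_length, rng)
            plasmid = _random_nt(config.plasmid_length, rng) if has_plasmid else None
            occupied: dict[str, list[tuple[int, int]]] = {"chr": [], "pls": []}
            replicon_seqs = {"chr": chromosome, "pls": plasmid}
            plants: list[PlantedGene] = []

            def plant(probe: ProbeRecord) -> None:
                target = "pls" if config.plant_on_plasmid else "chr"
                protein = probe.sequence
                if config.planted_identity < 1.0:
                    protein = mutate_protein(protein, config.planted_identity, rng)
                cds = back_translate(protein, rng, config.genetic_code_id)
                strand = -1 if rng.random() < config.reverse_strand_fraction else 1
                pos = _free_position(
                    rng, len(replicon_seqs[target]), len(cds), occupied[target]
                )
                replicon_seqs[target] = plant_orf(
                    replicon_seqs[target], cds, strand, pos, occupied[target]
                )
                plants.append(
                    PlantedGene(
                        probe_accession=probe.accession,
                        kind=probe.kind,
                        identity=config.planted_identity,
                        strand=strand,
                        replicon_id=f"{accession}_{target}",
                        on_plasmid=target == "pls",
                        position=pos,
                        length_nt=len(cds),
                    )
                )

            if g_index in with_u and probe_u is not None:
                plant(probe_u)
            if g_index in with_c and probe_c is not None:
                plant(probe_c)
            for decoy in decoys:
                cds = back_translate(decoy, rng, config.genetic_code_id)
                strand = -1 if rng.random() < config.reverse_strand_fraction else 1
                pos = _free_position(rng, len(replicon_seqs["chr"]), len(cds), occupied["chr"])
                replicon_seqs["chr"] = plant_orf(
                    replicon_seqs["chr"], cds, strand, pos, occupied["chr"]
                )

            replicons = [Replicon(f"{accession}_chr", replicon_seqs["chr"], False)]
            if replicon_seqs["pls"] is not None:
                replicons.append(Replicon(f"{accession}_pls", replicon_seqs["pls"], True))
            genomes[accession] = GenomeRecord(
                accession=accession,
                replicons=replicons,
                taxid=sp_taxid,
                is_type_material=is_type,
            )
            manifest.append(GenomeManifestEntry(accession, sp_taxid, is_type))
            truth.plants[accession] = plants

    return SyntheticDataset(config, tree, manifest, genomes, probes, truth)


def write_dataset(dataset: SyntheticDataset, directory) -> None:
    """Write the dataset in the formats the pipeline consumes: one FASTA
    per genome, taxdump-dialect nodes/names, a manifest TSV, a probe FASTA
    and the truth manifest as JSON."""
    from pathlib import Path

    from .search import write_genome_fasta
    from .taxonomy import write_manifest, write_taxonomy

    directory = Path(directory)
    (directory / "genomes").mkdir(parents=True, exist_ok=True)
    for accession, genome in dataset.genomes.items():
        write_genome_fasta(genome, directory / "genomes" / f"{accession}.fasta")
    with open(directory / "nodes.dmp", "w") as nfh, open(directory / "names.dmp", "w") as mfh:
        write_taxonomy(dataset.tree, nfh, mfh)
    with open(directory / "manifest.tsv", "w") as fh:
        write_manifest(dataset.manifest, fh)
    with open(directory / "probes.fasta", "w") as fh:
        for p in dataset.probes:
            fh.write(f">{p.accession} kind={p.kind}\n{p.sequence}\n")
    with open(directory / "truth.json", "w") as fh:
        fh.write(dataset.truth.to_json())


def expected_survey(
    dataset: SyntheticDataset, survey_config: SurveyConfig | None = None
) -> dict[int, tuple[PresenceLevel, PresenceLevel, bool]]:
    """Planted ground truth projected through the survey bookkeeping.

    Walks the taxonomy exactly as the hierarchical survey does, but derives
    each genome's U/C status from the truth manifest instead of alignment,
    yielding the per-taxon ``(level_U, level_C, complete)`` the pipeline
    must reproduce when planted identity is 1.0.
    """
    survey_config = survey_config or SurveyConfig()
    tree, manifest = dataset.tree, dataset.manifest
    out: dict[int, tuple[PresenceLevel, PresenceLevel, bool]] = {}

    def levels_for(taxid: int):
        rank = tree.rank(taxid)
        entries = eligible_genomes(genomes_of(tree, manifest, taxid), rank, survey_config)
        if not entries:
            return None
        k_u = k_c = 0
        for e in entries:
            has_u, has_c = dataset.truth.expected_status(
                e.genome_accession, survey_config.exclude_plasmids
            )
            k_u += has_u
            k_c += has_c
        level_u = classify_presence(k_u, len(entries))
        level_c = classify_presence(k_c, len(entries))
        return level_u, level_c, is_complete(level_u, level_c)

    from .taxonomy import RANK_LADDER, descendant_taxa

    ladder = [r for r in RANK_LADDER if r != "superkingdom"]
    frontier = [tree.root]
    for rank in ladder:
        taxa = sorted({t for parent in frontier for t in descendant_taxa(tree, parent, rank)})
        frontier = []
        for taxid in taxa:
            res = levels_for(taxid)
            if res is None:
                continue
            out[taxid] = res
            if not res[2] and rank != "species":
                frontier.append(taxid)
        if not frontier:
            break
    return out
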