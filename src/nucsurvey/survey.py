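"""Hierarchical gene presence/absence survey.

For a taxon, the survey runs every probe against every eligible genome,
counts genomes hit per probe, and classifies the per-family presence of
UshA-like (U) and CpdB-like (C) genes into four levels based on the
fraction of analyzed genomes with at least one passing hit of that family:

* ``ABSENT``   - no genome hit,
* ``LOW``      - at most 50% of genomes hit,
* ``PARTIAL``  - more than 50% but fewer than 100%,
* ``FULL``     - every analyzed genome hit.

A taxon whose U and C levels are each either ``ABSENT`` or ``FULL`` is
*complete*: its result cannot change by descending, so the hierarchical
traversal (phylum -> class -> order -> family -> genus -> species) prunes
it and only the non-complete taxa are surveyed at the next rank.  Species
are terminal.

Genome eligibility follows the type-material rule: above genus rank, only
type-material genomes are analyzed unless fewer than five are available,
in which case (and always at genus and species rank) all genomes are used.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Protocol, Sequence

from .alignment import COVERAGE_THRESHOLD, SCORE_THRESHOLD
from .panel import ProbeRecord
from .search import GenomeRecord, SearchEngine
from .taxonomy import (
    RANK_LADDER,
    GenomeManifestEntry,
    TaxonomyTree,
    descendant_taxa,
    genomes_of,
)

__all__ = [
    "PresenceLevel",
    "SurveyConfig",
    "TaxonSurveyResult",
    "classify_presence",
    "is_complete",
    "eligible_genomes",
    "survey_taxon",
    "hierarchical_survey",
    "survey_taxon_list",
    "write_survey_table",
    "LEVEL_SYMBOLS",
]


class PresenceLevel(enum.Enum):
    ABSENT = "ABSENT"
    LOW = "LOW"          # (0, 50%]
    PARTIAL = "PARTIAL"  # (50%, 100%)
    FULL = "FULL"        # 100%


#: Textual stand-ins for the published colour code: green (<=50%),
#: orange (>50% but <100%), red (100%).
LEVEL_SYMBOLS = {
    PresenceLevel.ABSENT: "-",
    PresenceLevel.LOW: "+<=50",
    PresenceLevel.PARTIAL: "+<100",
    PresenceLevel.FULL: "+100",
}


@dataclass(frozen=True)
class SurveyConfig:
    """Survey policy knobs; thresholds default to the published values."""

    min_type_material: int = 5
    restrict_to_type_material_above_genus: bool = True
    exclude_plasmids: bool = True
    score_threshold: float = SCORE_THRESHOLD
    coverage_threshold: float = COVERAGE_THRESHOLD


@dataclass
class TaxonSurveyResult:
    taxid: int
    rank: str
    name: str = ""
    n_genomes_analyzed: int = 0
    per_probe_hits: dict[str, int] = field(default_factory=dict)
    n_genomes_U: int = 0
    n_genomes_C: int = 0
    level_U: PresenceLevel | None = None
    level_C: PresenceLevel | None = None
    complete: bool = False
    #: genome accessions with at least one passing hit per family
    genomes_U: set[str] = field(default_factory=set)
    genomes_C: set[str] = field(default_factory=set)

    @property
    def analyzed(self) -> bool:
        """A taxon is analyzed when it has at least one eligible genome;
        probed taxa without genomes are recorded but excluded from level
        and completeness statistics."""
        return self.n_genomes_analyzed > 0


def classify_presence(k_hit_genomes: int, n_genomes: int) -> PresenceLevel:
    """Three-tier presence level (plus absence) of a gene family in a taxon."""
    if n_genomes < 1:
        raise ValueError("presence level undefined for zero genomes")
    if not 0 <= k_hit_genomes <= n_genomes:
        raise ValueError("need 0 <= k <= n")
    if k_hit_genomes == 0:
        return PresenceLevel.ABSENT
    if k_hit_genomes == n_genomes:
        return PresenceLevel.FULL
    if k_hit_genomes * 2 <= n_genomes:
        return PresenceLevel.LOW
    return PresenceLevel.PARTIAL


def is_complete(level_U: PresenceLevel, level_C: PresenceLevel) -> bool:
    """A taxon is complete when each family is either absent or present in
    100% of analyzed genomes; such taxa are not pursued at lower ranks."""
    terminal = {PresenceLevel.ABSENT, PresenceLevel.FULL}
    return level_U in terminal and level_C in terminal


def eligible_genomes(
    entries: Sequence[GenomeManifestEntry], rank: str, config: SurveyConfig
) -> list[GenomeManifestEntry]:
    """Apply the type-material restriction.

    At genus and species rank, or when fewer than ``min_type_material``
    type-material genomes exist, every genome is eligible; otherwise only
    type-material genomes are.
    """
    if not config.restrict_to_type_material_above_genus or rank in ("genus", "species"):
        return list(entries)
    type_material = [e for e in entries if e.is_type_material]
    if len(type_material) < config.min_type_material:
        return list(entries)
    return type_material


class GenomeStore(Protocol):
    def get(self, accession: str) -> GenomeRecord: ...


class DirectoryGenomeStore:
    """Genome FASTA files named ``<accession>.fasta`` under one directory."""

    def __init__(self, directory) -> None:
        from pathlib import Path

        self.directory = Path(directory)

    def get(self, accession: str) -> GenomeRecord:
        from .search import read_genome_fasta

        return read_genome_fasta(self.directory / f"{accession}.fasta", accession)


class InMemoryGenomeStore:
    def __init__(self, genomes: Mapping[str, GenomeRecord] | Iterable[GenomeRecord]):
        if isinstance(genomes, Mapping):
            self._genomes = dict(genomes)
        else:
            self._genomes = {g.accession: g for g in genomes}

    def get(self, accession: str) -> GenomeRecord:
        return self._genomes[accession]


def survey_taxon(
    tree: TaxonomyTree,
    manifest: Sequence[GenomeManifestEntry],
    genomes_store: GenomeStore,
    probes: Sequence[ProbeRecord],
    taxid: int,
    config: SurveyConfig | None = None,
    engine: SearchEngine | None = None,
) -> TaxonSurveyResult:
    """Survey one taxon: run every probe over every eligible genome and
    classify per-family presence.

    A taxon with zero eligible genomes is returned with
    ``n_genomes_analyzed == 0`` and undefined levels; callers exclude it
    from analysis counts.
    """
    config = config or SurveyConfig()
    engine = engine or SearchEngine()
    rank = tree.rank(taxid)
    result = TaxonSurveyResult(taxid=taxid, rank=rank, name=tree.name(taxid))
    entries = eligible_genomes(genomes_of(tree, manifest, taxid), rank, config)
    result.n_genomes_analyzed = len(entries)
    if not entries:
        return result
    result.per_probe_hits = {p.accession: 0 for p in probes}
    for entry in entries:
        genome = genomes_store.get(entry.genome_accession)
        for probe in probes:
            hit = engine.search(probe, genome, exclude_plasmids=config.exclude_plasmids)
            if hit.passes_filter:
                result.per_probe_hits[probe.accession] += 1
                target = result.genomes_U if probe.kind == "UshA-like" else result.genomes_C
                target.add(entry.genome_accession)
    result.n_genomes_U = len(result.genomes_U)
    result.n_genomes_C = len(result.genomes_C)
    result.level_U = classify_presence(result.n_genomes_U, len(entries))
    result.level_C = classify_presence(result.n_genomes_C, len(entries))
    result.complete = is_complete(result.level_U, result.level_C)
    return result


def hierarchical_survey(
    tree: TaxonomyTree,
    manifest: Sequence[GenomeManifestEntry],
    genomes_store: GenomeStore,
    probes: Sequence[ProbeRecord],
    root: int | None = None,
    config: SurveyConfig | None = None,
    engine: SearchEngine | None = None,
) -> dict[int, TaxonSurveyResult]:
    """Level-by-level survey with completeness pruning.

    Starting from the root's phyla, each rank of the ladder is surveyed in
    ascending-taxid order; a taxon's sub-taxa are surveyed only when the
    taxon was analyzed and found non-complete (taxa without genomes have
    genome-free subtrees and are not descended).  Species are terminal.
    """
    config = config or SurveyConfig()
    engine = engine or SearchEngine()
    root = tree.root if root is None else root
    results: dict[int, TaxonSurveyResult] = {}
    ladder = [r for r in RANK_LADDER if r != "superkingdom"]
    frontier = [root]
    for i, rank in enumerate(ladder):
        taxa = sorted({t for parent in frontier for t in descendant_taxa(tree, parent, rank)})
        frontier = []
        for taxid in taxa:
            res = survey_taxon(tree, manifest, genomes_store, probes, taxid, config, engine)
            results[taxid] = res
            if res.analyzed and not res.complete and rank != "species":
                frontier.append(taxid)
        if not frontier:
            break
    return results


def survey_taxon_list(
    tree: TaxonomyTree,
    manifest: Sequence[GenomeManifestEntry],
    genomes_store: GenomeStore,
    probes: Sequence[ProbeRecord],
    taxids: Sequence[int],
    config: SurveyConfig | None = None,
    engine: SearchEngine | None = None,
) -> dict[int, TaxonSurveyResult]:
    """Survey an explicitly chosen taxon set (e.g. a curated species list)
    instead of systematic descent."""
    config = config or SurveyConfig()
    engine = engine or SearchEngine()
    return {
        t: survey_taxon(tree, manifest, genomes_store, probes, t, config, engine)
        for t in taxids
    }


def write_survey_table(results: Mapping[int, TaxonSurveyResult], fh) -> None:
    """Per-taxon TSV with the presence levels encoded textually."""
    fh.write("taxid\trank\tname\tn_genomes\tU\tC\tcomplete\n")
    for taxid in sorted(results):
        r = results[taxid]
        u = LEVEL_SYMBOLS[r.level_U] if r.level_U else "no_genomes"
        c = LEVEL_SYMBOLS[r.level_C] if r.level_C else "no_genomes"
        fh.write(
            f"{r.taxid}\t{r.rank}\t{r.name}\t{r.n_genomes_analyzed}\t{u}\t{c}\t{int(r.complete)}\n"
        )
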