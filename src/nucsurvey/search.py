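"""Probe-vs-genome translated search.

A genome is a set of replicons (chromosome and optional plasmids).  Each
probe protein is aligned against all six translated frames of every
non-excluded replicon; the best local alignment per (replicon, frame) is
kept as an HSP when its bit score clears the reporting floor.  Replicon
results are merged into a single :class:`~nucsurvey.alignment.Hit` per
(probe, genome): the best bit score is the maximum over replicons and the
query coverage is computed from the union of HSP query ranges on the
best-scoring replicon only (a gene is not split across replicons).

Plasmid exclusion mirrors the "NOT plasmid [Title]" restriction used when
querying a complete-genomes database: replicons flagged as plasmids
contribute nothing when exclusion is on.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from Bio import SeqIO

from .alignment import (
    AlignmentParams,
    Hit,
    Hsp,
    SubstitutionMatrix,
    bit_score,
    make_aligner,
    passes_filter,
    six_frame_translate,
    union_size,
)

__all__ = [
    "Replicon",
    "GenomeRecord",
    "search_genome",
    "SearchEngine",
    "read_genome_fasta",
    "write_genome_fasta",
    "write_hit_table",
    "write_hsp_table",
]

#: HSPs below this bit score are not reported; the floor only affects
#: coverage aggregation, never the best score test (150 >> 50).
HSP_FLOOR_BITS = 50.0


@dataclass
class Replicon:
    """One replicon of a genome; ``is_plasmid`` mirrors a 'plasmid' tag in
    the FASTA description line."""

    id: str
    sequence: str
    is_plasmid: bool = False


@dataclass
class GenomeRecord:
    accession: str
    replicons: list[Replicon] = field(default_factory=list)
    taxid: int | None = None
    is_type_material: bool = False


def _genomic_coords(prot_start: int, prot_end: int, frame: int, nt_len: int) -> tuple[int, int]:
    """Map 1-based aa positions within a translated frame to 1-based
    forward-strand nt positions on the replicon."""
    off = abs(frame) - 1
    nt_a = off + 3 * (prot_start - 1) + 1
    nt_b = off + 3 * prot_end
    if frame > 0:
        return nt_a, nt_b
    # positions were on the reverse complement; flip to forward strand
    return nt_len - nt_b + 1, nt_len - nt_a + 1


class SearchEngine:
    """Reusable search context: matrix, parameters and a configured aligner.

    Reusing one engine across many (probe, genome) pairs avoids rebuilding
    the aligner and allows an optional per-(probe, genome) hit cache, which
    the hierarchical survey relies on so that a genome surveyed at several
    taxonomic levels is aligned only once.
    """

    def __init__(
        self,
        matrix: SubstitutionMatrix | None = None,
        params: AlignmentParams | None = None,
        hsp_floor_bits: float = HSP_FLOOR_BITS,
        cache: bool = True,
    ) -> None:
        self.matrix = matrix or SubstitutionMatrix.load()
        self.params = params or AlignmentParams()
        self.hsp_floor_bits = hsp_floor_bits
        self._aligner = make_aligner(self.matrix, self.params)
        self._cache: dict[tuple[str, str, bool], Hit] | None = {} if cache else None

    def search(
        self, probe, genome: GenomeRecord, exclude_plasmids: bool = True
    ) -> Hit:
        key = (probe.accession, genome.accession, exclude_plasmids)
        if self._cache is not None and key in self._cache:
            return self._cache[key]
        hit = search_genome(
            probe,
            genome,
            self.matrix,
            self.params,
            exclude_plasmids=exclude_plasmids,
            hsp_floor_bits=self.hsp_floor_bits,
            aligner=self._aligner,
        )
        if self._cache is not None:
            self._cache[key] = hit
        return hit


def search_genome(
    probe,
    genome: GenomeRecord,
    matrix: SubstitutionMatrix | None = None,
    params: AlignmentParams | None = None,
    exclude_plasmids: bool = True,
    hsp_floor_bits: float = HSP_FLOOR_BITS,
    aligner=None,
) -> Hit:
    """Align one probe against all six frames of every non-excluded replicon.

    ``probe`` is any object with ``accession`` and ``sequence`` attributes
    (see :class:`nucsurvey.panel.ProbeRecord`).  A genome with zero
    non-excluded replicons yields an HSP-free hit that fails the filter.
    """
    matrix = matrix or SubstitutionMatrix.load()
    params = params or AlignmentParams()
    if aligner is None:
        aligner = make_aligner(matrix, params)
    query = probe.sequence
    if not query:
        raise ValueError(f"probe {probe.accession} has no sequence")
    raw_floor = _raw_floor(hsp_floor_bits, params)

    hsps_by_replicon: dict[str, list[Hsp]] = {}
    for rep in genome.replicons:
        if exclude_plasmids and rep.is_plasmid:
            continue
        nt_len = len(rep.sequence)
        for frame, prot in six_frame_translate(rep.sequence, params.genetic_code_id):
            if len(prot) == 0:
                continue
            score = aligner.score(query, prot)
            if score < raw_floor:
                continue
            aln = aligner.align(query, prot)[0]
            q_blocks, s_blocks = aln.aligned
            n_id = sum(
                1
                for (qs, qe), (ss, _) in zip(q_blocks, s_blocks)
                for k in range(qe - qs)
                if query[qs + k] == prot[ss + k]
            )
            sub_start, sub_end = _genomic_coords(
                int(s_blocks[0][0]) + 1, int(s_blocks[-1][1]), frame, nt_len
            )
            hsps_by_replicon.setdefault(rep.id, []).append(
                Hsp(
                    query_start=int(q_blocks[0][0]) + 1,
                    query_end=int(q_blocks[-1][1]),
                    subject_start=sub_start,
                    subject_end=sub_end,
                    frame=frame,
                    raw_score=int(round(score)),
                    bit_score=bit_score(score, params),
                    n_identities=n_id,
                    subject_id=rep.id,
                )
            )

    all_hsps = [h for hs in hsps_by_replicon.values() for h in hs]
    if not all_hsps:
        return Hit(genome.accession, probe.accession, 0.0, 0.0, [], False)
    best = max(all_hsps, key=lambda h: h.bit_score)
    best_rep_hsps = hsps_by_replicon[best.subject_id]
    coverage = union_size(
        [(h.query_start, h.query_end) for h in best_rep_hsps]
    ) / len(query)
    return Hit(
        genome_accession=genome.accession,
        probe_accession=probe.accession,
        best_bit_score=best.bit_score,
        query_coverage=coverage,
        hsps=sorted(all_hsps, key=lambda h: -h.bit_score),
        passes_filter=passes_filter(best.bit_score, coverage),
    )


def _raw_floor(bits: float, params: AlignmentParams) -> float:
    """Smallest raw score whose bit score reaches ``bits``."""
    import math

    return (bits * math.log(2) + math.log(params.karlin_k)) / params.karlin_lambda


# ---------------------------------------------------------------------------
# FASTA I/O

def read_genome_fasta(path, accession: str | None = None) -> GenomeRecord:
    """Read one genome from a multi-record FASTA file.

    Each record is a replicon; a replicon is plasmid-flagged when the word
    'plasmid' appears in its description line.  The genome accession
    defaults to the file stem.
    """
    import os

    replicons = [
        Replicon(
            id=rec.id,
            sequence=str(rec.seq).upper(),
            is_plasmid="plasmid" in rec.description.lower(),
        )
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    acc = accession or os.path.splitext(os.path.basename(str(path)))[0]
    return GenomeRecord(accession=acc, replicons=replicons)


def write_genome_fasta(genome: GenomeRecord, path) -> None:
    with open(path, "w") as fh:
        for rep in genome.replicons:
            tag = " plasmid" if rep.is_plasmid else ""
            fh.write(f">{rep.id} {genome.accession}{tag}\n")
            seq = rep.sequence
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def write_hit_table(hits: Iterable[Hit], fh) -> None:
    """One row per (probe, genome), tab-separated."""
    fh.write(
        "probe_accession\tgenome_accession\tbest_bit_score\tquery_coverage_pct\tn_hsps\tpasses_filter\n"
    )
    for h in hits:
        fh.write(
            f"{h.probe_accession}\t{h.genome_accession}\t{h.best_bit_score:.2f}\t"
            f"{100 * h.query_coverage:.1f}\t{len(h.hsps)}\t{int(h.passes_filter)}\n"
        )


def write_hsp_table(hits: Iterable[Hit], fh) -> None:
    """Per-HSP table in the style of BLAST tabular output (outfmt 6) with
    an extra frame column."""
    fh.write(
        "qseqid\tsseqid\tpident\tlength\tqstart\tqend\tsstart\tsend\tframe\tbitscore\n"
    )
    for h in hits:
        for s in h.hsps:
            length = s.query_end - s.query_start + 1
            pident = 100.0 * s.n_identities / max(length, 1)
            fh.write(
                f"{h.probe_accession}\t{s.subject_id}\t{pident:.1f}\t{length}\t"
                f"{s.query_start}\t{s.query_end}\t{s.subject_start}\t{s.subject_end}\t"
                f"{s.frame:+d}\t{s.bit_score:.1f}\n"
            )
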