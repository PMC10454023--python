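"""Protein local alignment primitives for the translated genome search.

This module provides the desk-scale equivalent of the alignment core of a
translated BLAST search: six-frame translation of nucleotide replicons,
Smith-Waterman local alignment of a protein probe against each translated
frame (affine gap penalties, BLOSUM62 by default), and Karlin-Altschul
normalisation of raw scores to bit scores.  The dynamic programming itself
is delegated to :class:`Bio.Align.PairwiseAligner`; this module fixes the
scoring conventions and the data model around it.

Scoring conventions
-------------------
* A gap of length ``k`` costs ``gap_open + k * gap_extend`` (the BLAST
  convention), i.e. 12, 13, 14, ... with the default 11/1 penalties.
* Stop codons translate to ``'*'`` and score -4 against every residue
  (+1 against another stop), so an alignment may cross a stop at a penalty.
* ``bits = (lambda * raw - ln K) / ln 2`` with gapped BLOSUM62-11/1
  constants ``lambda = 0.267`` and ``K = 0.041``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterator

from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Data import CodonTable
from Bio.Seq import Seq

__all__ = [
    "SubstitutionMatrix",
    "AlignmentParams",
    "Hsp",
    "Hit",
    "reverse_complement",
    "six_frame_translate",
    "local_align",
    "bit_score",
    "passes_filter",
    "SCORE_THRESHOLD",
    "COVERAGE_THRESHOLD",
]

#: Hit thresholds: a genomic hit requires bit score > 150 and query
#: coverage > 70%, both strict.
SCORE_THRESHOLD = 150.0
COVERAGE_THRESHOLD = 0.70

_NT_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_PROTEIN_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX*")


class AlignmentInputError(ValueError):
    """Raised when a sequence contains characters outside the alphabet."""


class SubstitutionMatrix:
    """A symmetric residue substitution matrix over the 20 amino acids,
    ``'X'`` and the stop character ``'*'``.

    Wraps a :class:`Bio.Align.substitution_matrices.Array` so it can be fed
    directly to the pairwise aligner while exposing a plain mapping
    interface.
    """

    def __init__(self, name: str, array) -> None:
        self.name = name
        self.array = array
        self.alphabet = str(array.alphabet)

    @classmethod
    def load(cls, name: str = "BLOSUM62") -> "SubstitutionMatrix":
        """Load one of the matrices shipped with Biopython (NCBI set)."""
        return cls(name, substitution_matrices.load(name))

    @classmethod
    def from_file(cls, path, name: str | None = None) -> "SubstitutionMatrix":
        """Read a matrix in NCBI text format."""
        return cls(name or str(path), substitution_matrices.read(str(path)))

    def score(self, a: str, b: str) -> float:
        return float(self.array[a, b])

    def __getitem__(self, pair) -> float:
        a, b = pair
        return float(self.array[a, b])

    def is_symmetric(self) -> bool:
        arr = self.array
        n = len(arr.alphabet)
        return all(
            arr[i, j] == arr[j, i] for i in range(n) for j in range(n)
        )


@dataclass(frozen=True)
class AlignmentParams:
    """Alignment and score-normalisation parameters.

    Defaults are the web TBlastN defaults: BLOSUM62 with gap open 11 /
    extend 1, bacterial genetic code (11), and the gapped Karlin-Altschul
    constants for that scoring system.
    """

    gap_open_penalty: int = 11
    gap_extend_penalty: int = 1
    karlin_lambda: float = 0.267
    karlin_k: float = 0.041
    genetic_code_id: int = 11

    def __post_init__(self) -> None:
        if self.gap_extend_penalty > self.gap_open_penalty:
            raise ValueError("gap_extend_penalty must not exceed gap_open_penalty")
        if self.karlin_lambda <= 0:
            raise ValueError("lambda must be positive")
        if not (0 < self.karlin_k < 1):
            raise ValueError("K must lie in (0, 1)")


@dataclass(frozen=True)
class Hsp:
    """One high-scoring segment pair.

    Coordinates are 1-based inclusive.  For genomic HSPs produced by
    :func:`nucsurvey.search.search_genome`, ``subject_start``/``subject_end``
    are forward-strand nucleotide positions on the replicon and ``frame`` is
    in ``{+1,+2,+3,-1,-2,-3}``; for protein-vs-protein alignments they are
    positions on the subject protein and ``frame`` is ``+1``.
    """

    query_start: int
    query_end: int
    subject_start: int
    subject_end: int
    frame: int
    raw_score: int
    bit_score: float
    n_identities: int
    subject_id: str = ""

    @property
    def is_empty(self) -> bool:
        return self.raw_score <= 0


@dataclass
class Hit:
    """Best filtered result of one probe against one genome."""

    genome_accession: str
    probe_accession: str
    best_bit_score: float
    query_coverage: float
    hsps: list[Hsp] = field(default_factory=list)
    passes_filter: bool = False


def _check_nt(sequence: str) -> str:
    s = sequence.upper()
    if set(s) - set("ACGTN"):
        bad = sorted(set(s) - set("ACGTN"))
        raise AlignmentInputError(f"non-nucleotide characters: {bad}")
    return s


def reverse_complement(nt_sequence: str) -> str:
    """Watson-Crick reverse complement over ``{A,C,G,T,N}``."""
    return _check_nt(nt_sequence).translate(_NT_COMPLEMENT)[::-1]


@lru_cache(maxsize=4)
def _codon_map(genetic_code_id: int) -> dict[str, str]:
    table = CodonTable.unambiguous_dna_by_id[genetic_code_id]
    mapping = dict(table.forward_table)
    for stop in table.stop_codons:
        mapping[stop] = "*"
    return mapping


def six_frame_translate(
    nt_sequence: str, genetic_code_id: int = 11
) -> list[tuple[int, str]]:
    """Translate all six reading frames.

    Returns ``[(frame, protein), ...]`` for frames ``+1,+2,+3,-1,-2,-3``.
    Frame ``+k`` translates the forward strand starting at offset ``k-1``;
    frame ``-k`` translates the reverse complement at offset ``k-1``.  Stop
    codons emit ``'*'``; a trailing partial codon is dropped.  Sequences
    shorter than one codon yield empty frames.
    """
    s = _check_nt(nt_sequence)
    rc = s.translate(_NT_COMPLEMENT)[::-1]
    frames: list[tuple[int, str]] = []
    for strand, seq in ((1, s), (-1, rc)):
        for off in range(3):
            sub = seq[off : off + 3 * ((len(seq) - off) // 3)]
            if sub:
                prot = str(Seq(sub).translate(table=genetic_code_id))
            else:
                prot = ""
            frames.append((strand * (off + 1), prot))
    return frames


def bit_score(raw_score: float, params: AlignmentParams) -> float:
    """Karlin-Altschul normalised score in bits.

    ``bits = (lambda * raw - ln K) / ln 2``; strictly increasing in the
    raw score.
    """
    if raw_score < 0:
        raise ValueError("raw_score must be non-negative")
    return (params.karlin_lambda * raw_score - math.log(params.karlin_k)) / math.log(2)


def passes_filter(
    best_bit_score: float,
    query_coverage: float,
    score_threshold: float = SCORE_THRESHOLD,
    coverage_threshold: float = COVERAGE_THRESHOLD,
) -> bool:
    """Hit criterion: bit score strictly above 150 and query coverage
    strictly above 70%."""
    if not 0.0 <= query_coverage <= 1.0:
        raise ValueError("coverage must lie in [0, 1]")
    return best_bit_score > score_threshold and query_coverage > coverage_threshold


def make_aligner(matrix: SubstitutionMatrix, params: AlignmentParams) -> PairwiseAligner:
    """Configure a local aligner with BLAST-style affine gap costs.

    PairwiseAligner charges ``open_gap_score`` on the first gapped column
    and ``extend_gap_score`` afterwards, whereas BLAST charges
    ``open + k * extend`` for a length-``k`` gap; the conversion below makes
    the two identical.
    """
    aligner = PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = matrix.array
    aligner.open_gap_score = -(params.gap_open_penalty + params.gap_extend_penalty)
    aligner.extend_gap_score = -params.gap_extend_penalty
    return aligner


def _check_protein(seq: str, matrix: SubstitutionMatrix) -> str:
    s = seq.upper()
    bad = set(s) - set(matrix.alphabet)
    if bad:
        raise AlignmentInputError(f"residues outside matrix alphabet: {sorted(bad)}")
    return s


_EMPTY = dict(query_start=0, query_end=0, subject_start=0, subject_end=0,
              raw_score=0, n_identities=0)


def local_align(
    query: str,
    subject: str,
    matrix: SubstitutionMatrix | None = None,
    params: AlignmentParams | None = None,
    aligner: PairwiseAligner | None = None,
) -> Hsp:
    """Optimal Smith-Waterman local alignment of two protein sequences.

    Returns the maximum-scoring local alignment under affine gap penalties
    as a single :class:`Hsp` with 1-based protein coordinates (frame ``+1``).
    When no residue pair scores positively the result is an empty HSP with
    raw score 0.  Traceback is deterministic (the aligner's first optimal
    path).
    """
    matrix = matrix or SubstitutionMatrix.load()
    params = params or AlignmentParams()
    q = _check_protein(query, matrix)
    s = _check_protein(subject, matrix)
    if not q or not s:
        raise AlignmentInputError("sequences must be non-empty")
    if aligner is None:
        aligner = make_aligner(matrix, params)
    score = aligner.score(q, s)
    if score <= 0:
        return Hsp(frame=1, bit_score=bit_score(0, params), **_EMPTY)
    aln = aligner.align(q, s)[0]
    q_blocks, s_blocks = aln.aligned
    n_id = sum(
        1
        for (qs, qe), (ss, _) in zip(q_blocks, s_blocks)
        for k in range(qe - qs)
        if q[qs + k] == s[ss + k]
    )
    return Hsp(
        query_start=int(q_blocks[0][0]) + 1,
        query_end=int(q_blocks[-1][1]),
        subject_start=int(s_blocks[0][0]) + 1,
        subject_end=int(s_blocks[-1][1]),
        frame=1,
        raw_score=int(round(score)),
        bit_score=bit_score(score, params),
        n_identities=n_id,
    )


def union_size(intervals: list[tuple[int, int]]) -> int:
    """Total number of integers covered by a set of 1-based inclusive
    intervals (used for query coverage over HSP query ranges)."""
    covered = 0
    last_end = 0
    for start, end in sorted(intervals):
        if end <= last_end:
            continue
        covered += end - max(start - 1, last_end)
        last_end = end
    return covered
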