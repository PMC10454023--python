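"""Probe panel management.

The survey's probes are drawn from a 21-protein candidate panel of
periplasmic or cell-wall-bound bacterial nucleotidases (5'-nucleotidases of
the UshA family and 2',3'-cyclic-nucleotide phosphodiesterase /
3'-nucleotidases of the CpdB family).  This module computes the all-vs-all
relatedness matrix of a panel by local-alignment bit scores, partitions the
panel into relatedness groups, and selects a minimal covering probe set by
greedy set cover.  A packaged fixture transcribes the published panel
metadata (accessions, descriptions, lengths, kinds, selected flags); the
actual protein sequences are not packaged, so sequence-bearing operations
are exercised on synthetic panels.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Sequence

import numpy as np

from .alignment import AlignmentParams, SubstitutionMatrix, local_align, make_aligner

__all__ = [
    "ProbeRecord",
    "PanelMatrix",
    "ValidationReport",
    "load_panel_fixture",
    "read_probe_fasta",
    "pairwise_matrix",
    "relatedness_groups",
    "select_probe_set",
    "validate_panel_fixture",
    "NSS_THRESHOLD_BITS",
]

#: Bit-score threshold below which two panel members are considered to show
#: no significant similitude.  Configurable; 50 bits separates synthetic
#: clusters cleanly.
NSS_THRESHOLD_BITS = 50.0

#: The seven probes used for the genome survey: five UshA-like and two
#: CpdB-like.
SELECTED_PROBES = {
    "P07024": "UshA-like",
    "P44569": "UshA-like",
    "WP_000726911": "UshA-like",
    "WP_011837008": "UshA-like",
    "O32133": "UshA-like",
    "P08331": "CpdB-like",
    "AYV64543": "CpdB-like",
}

_EXPECTED_LENGTHS = {
    "P07024": 550,
    "P44569": 603,
    "WP_000726911": 690,
    "WP_011837008": 719,
    "O32133": 462,
    "P08331": 647,
    "AYV64543": 813,
}


@dataclass
class ProbeRecord:
    """A query protein, optionally carrying panel metadata.

    ``kind`` distinguishes the two probe families whose union defines the
    per-genome U and C statuses.
    """

    accession: str
    kind: str = "unknown"  # UshA-like | CpdB-like | unknown
    sequence: str | None = None
    length_aa: int | None = None
    description: str = ""
    panel_no: int | None = None
    selected: bool = False

    def __post_init__(self) -> None:
        if self.sequence is not None:
            if self.length_aa is None:
                self.length_aa = len(self.sequence)
            elif self.length_aa != len(self.sequence):
                raise ValueError(
                    f"{self.accession}: sequence length {len(self.sequence)} "
                    f"!= declared length {self.length_aa}"
                )


@dataclass
class PanelMatrix:
    """All-vs-all bit-score grid over a panel.

    Symmetric by construction; the diagonal holds each protein's self
    score, which is its row maximum.
    """

    members: list[ProbeRecord]
    scores: np.ndarray
    nss_threshold: float = NSS_THRESHOLD_BITS

    @property
    def n(self) -> int:
        return len(self.members)


@dataclass
class ValidationReport:
    ok: bool
    errors: list[str] = field(default_factory=list)


def load_panel_fixture() -> list[ProbeRecord]:
    """The packaged 21-member panel (metadata only, no sequences)."""
    out = []
    with resources.files("nucsurvey.data").joinpath("panel_table.tsv").open() as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            out.append(
                ProbeRecord(
                    accession=row["accession"],
                    kind=row["kind"],
                    length_aa=int(row["length_aa"]),
                    description=row["description"],
                    panel_no=int(row["no"]),
                    selected=row["selected"] == "1",
                )
            )
    return out


def read_probe_fasta(path) -> list[ProbeRecord]:
    """Probes from FASTA; a ``kind=UshA-like`` / ``kind=CpdB-like`` token in
    the description sets the probe family."""
    from Bio import SeqIO

    probes = []
    for rec in SeqIO.parse(str(path), "fasta"):
        kind = "unknown"
        for token in rec.description.split():
            if token.startswith("kind="):
                kind = token[5:]
        probes.append(ProbeRecord(accession=rec.id, kind=kind, sequence=str(rec.seq)))
    return probes


def pairwise_matrix(
    panel: Sequence[ProbeRecord],
    matrix: SubstitutionMatrix | None = None,
    params: AlignmentParams | None = None,
    nss_threshold: float = NSS_THRESHOLD_BITS,
) -> PanelMatrix:
    """Bit scores of all pairwise local alignments of the panel.

    The upper triangle is computed and mirrored, so the grid is symmetric
    by construction.
    """
    missing = [p.panel_no or p.accession for p in panel if not p.sequence]
    if missing:
        raise ValueError(f"panel members without sequences: {missing}")
    matrix = matrix or SubstitutionMatrix.load()
    params = params or AlignmentParams()
    aligner = make_aligner(matrix, params)
    n = len(panel)
    grid = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            hsp = local_align(
                panel[i].sequence, panel[j].sequence, matrix, params, aligner=aligner
            )
            grid[i, j] = grid[j, i] = hsp.bit_score
    return PanelMatrix(members=list(panel), scores=grid, nss_threshold=nss_threshold)


def relatedness_groups(matrix: PanelMatrix) -> list[list[int]]:
    """Partition the panel into connected components of the relatedness
    graph (edge where off-diagonal score >= threshold).

    Returns groups as lists of 0-based member indices, each group sorted,
    groups ordered by smallest member.  Singletons are allowed.
    """
    n = matrix.n
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n):
        for j in range(i + 1, n):
            if matrix.scores[i, j] >= matrix.nss_threshold:
                parent[find(i)] = find(j)
    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    return sorted((sorted(g) for g in groups.values()), key=lambda g: g[0])


def select_probe_set(matrix: PanelMatrix) -> list[int]:
    """Greedy set cover: repeatedly pick the member covering the most
    uncovered members (coverage = score >= threshold, self included), ties
    broken by the lowest panel number / index.  The returned indices always
    cover the whole panel.
    """
    n = matrix.n
    covers = [
        {
            j
            for j in range(n)
            if j == i or matrix.scores[i, j] >= matrix.nss_threshold
        }
        for i in range(n)
    ]
    uncovered = set(range(n))
    chosen: list[int] = []
    while uncovered:
        best = min(range(n), key=lambda i: (-len(covers[i] & uncovered), _order(matrix, i)))
        chosen.append(best)
        uncovered -= covers[best]
    return sorted(chosen, key=lambda i: _order(matrix, i))


def _order(matrix: PanelMatrix, i: int):
    m = matrix.members[i]
    return m.panel_no if m.panel_no is not None else i


def validate_panel_fixture(panel: Sequence[ProbeRecord]) -> ValidationReport:
    """Check the packaged panel: 21 records; the seven selected probes
    present with the published accessions, kinds (5 UshA-like, 2 CpdB-like)
    and lengths."""
    errors: list[str] = []
    if len(panel) != 21:
        errors.append(f"panel size {len(panel)} != 21")
    by_acc = {p.accession: p for p in panel}
    selected = [p for p in panel if p.selected]
    if len(selected) != 7:
        errors.append(f"selected probes {len(selected)} != 7")
    missing = sorted(set(SELECTED_PROBES) - {p.accession for p in selected})
    if missing:
        errors.append(f"missing selected probes: {missing}")
    for acc, kind in SELECTED_PROBES.items():
        p = by_acc.get(acc)
        if p is None:
            continue
        if not p.selected:
            errors.append(f"{acc}: not flagged selected")
        if p.kind != kind:
            errors.append(f"{acc}: kind {p.kind} != {kind}")
        if p.length_aa != _EXPECTED_LENGTHS[acc]:
            errors.append(
                f"{acc}: length {p.length_aa} != {_EXPECTED_LENGTHS[acc]}"
            )
    kinds = sorted(p.kind for p in selected)
    if selected and kinds != ["CpdB-like"] * 2 + ["UshA-like"] * 5:
        errors.append(f"selected kinds {kinds} != 5 UshA-like + 2 CpdB-like")
    return ValidationReport(ok=not errors, errors=errors)
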