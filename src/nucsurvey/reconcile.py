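"""Cross-probe reconciliation and correlation tabulation.

Given per-genome hit results for the two probe families, a genome is
U-positive when at least one UshA-like probe passes the hit filter and
C-positive likewise for CpdB-like probes.  Genomes (and complete taxa)
fall into four joint categories - double positive, U-only, C-only,
double negative - whose counts always conserve the total.

When a survey of a species is complete for one family only, the joint
breakdown can still be inferred from the marginal counts: with ``n_U``
U-positive genomes, ``n_C`` C-positive and ``n_both`` double positive,
``u_only = n_U - n_both``, ``c_only = n_C - n_both`` and
``neither = n_total - n_U - n_C + n_both``.

Packaged fixtures transcribe the published per-genome score tables and the
four complete-taxon category lists, so the reconciliation arithmetic can be
exercised on the original data without any database access.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

from .alignment import SCORE_THRESHOLD
from .survey import PresenceLevel, TaxonSurveyResult

__all__ = [
    "GenomeStatus",
    "CorrelationSummary",
    "LevelBreakdown",
    "genome_status",
    "categorize_genomes",
    "infer_categories_from_counts",
    "categorize_complete_taxa",
    "aggregate_levels",
    "correlation_percentages",
    "load_complete_taxa_fixture",
    "load_score_table_fixture",
    "load_count_vignettes",
    "statuses_from_score_rows",
    "InconsistentCountsError",
]


class InconsistentCountsError(ValueError):
    """Marginal counts that cannot come from any genome set."""


@dataclass(frozen=True)
class GenomeStatus:
    genome_accession: str
    has_U: bool
    has_C: bool


@dataclass(frozen=True)
class CorrelationSummary:
    """Counts of the four joint U/C categories; they sum to ``n_total``."""

    n_both: int
    n_u_only: int
    n_c_only: int
    n_neither: int

    @property
    def n_total(self) -> int:
        return self.n_both + self.n_u_only + self.n_c_only + self.n_neither

    def __add__(self, other: "CorrelationSummary") -> "CorrelationSummary":
        return CorrelationSummary(
            self.n_both + other.n_both,
            self.n_u_only + other.n_u_only,
            self.n_c_only + other.n_c_only,
            self.n_neither + other.n_neither,
        )


@dataclass
class LevelBreakdown:
    """Bookkeeping for one taxonomic rank: probed vs analyzed vs complete,
    and the category breakdown of the complete taxa."""

    rank: str
    n_probed: int
    n_without_genomes: int
    n_complete: int
    complete_by_category: CorrelationSummary

    @property
    def n_analyzed(self) -> int:
        return self.n_probed - self.n_without_genomes


def genome_status(hits: Iterable, probe_kinds: Mapping[str, str]) -> GenomeStatus:
    """Per-family OR over passing hits of one genome."""
    has_u = has_c = False
    accession = ""
    for hit in hits:
        accession = hit.genome_accession
        if not hit.passes_filter:
            continue
        kind = probe_kinds.get(hit.probe_accession, "unknown")
        if kind == "UshA-like":
            has_u = True
        elif kind == "CpdB-like":
            has_c = True
    return GenomeStatus(accession, has_u, has_c)


def categorize_genomes(statuses: Iterable[GenomeStatus]) -> CorrelationSummary:
    both = u_only = c_only = neither = 0
    for s in statuses:
        if s.has_U and s.has_C:
            both += 1
        elif s.has_U:
            u_only += 1
        elif s.has_C:
            c_only += 1
        else:
            neither += 1
    return CorrelationSummary(both, u_only, c_only, neither)


def infer_categories_from_counts(
    n_total: int, n_U: int, n_C: int, n_both: int
) -> CorrelationSummary:
    """Joint breakdown from marginal counts (inclusion-exclusion)."""
    if n_both > min(n_U, n_C):
        raise InconsistentCountsError(f"n_both {n_both} exceeds a marginal ({n_U}, {n_C})")
    if max(n_U, n_C) > n_total:
        raise InconsistentCountsError(f"marginal exceeds total {n_total}")
    neither = n_total - n_U - n_C + n_both
    if neither < 0:
        raise InconsistentCountsError(
            f"marginals {n_U}+{n_C}-{n_both} exceed total {n_total}"
        )
    return CorrelationSummary(n_both, n_U - n_both, n_C - n_both, neither)


_CATEGORY_KEYS = ("both", "u_only", "c_only", "neither")


def _taxon_category(res: TaxonSurveyResult) -> str:
    u = res.level_U != PresenceLevel.ABSENT
    c = res.level_C != PresenceLevel.ABSENT
    return {(True, True): "both", (True, False): "u_only",
            (False, True): "c_only", (False, False): "neither"}[(u, c)]


def categorize_complete_taxa(
    results: Iterable[TaxonSurveyResult],
) -> dict[str, list[TaxonSurveyResult]]:
    """Partition the complete taxa into the four joint categories
    (U present iff level not absent).  Non-complete and unanalyzed taxa
    are excluded; every complete taxon lands in exactly one list."""
    out: dict[str, list[TaxonSurveyResult]] = {k: [] for k in _CATEGORY_KEYS}
    for res in results:
        if not (res.analyzed and res.complete):
            continue
        out[_taxon_category(res)].append(res)
    return out


def aggregate_levels(
    results: Iterable[TaxonSurveyResult],
    ranks: Sequence[str] = ("phylum", "class", "order", "family", "genus", "species"),
) -> tuple[list[LevelBreakdown], LevelBreakdown]:
    """Per-rank probed/analyzed/complete counts plus a grand total row."""
    by_rank: dict[str, list[TaxonSurveyResult]] = {r: [] for r in ranks}
    for res in results:
        if res.rank in by_rank:
            by_rank[res.rank].append(res)
    rows = []
    for rank in ranks:
        group = by_rank[rank]
        complete = [r for r in group if r.analyzed and r.complete]
        cats = {k: 0 for k in _CATEGORY_KEYS}
        for r in complete:
            cats[_taxon_category(r)] += 1
        rows.append(
            LevelBreakdown(
                rank=rank,
                n_probed=len(group),
                n_without_genomes=sum(1 for r in group if not r.analyzed),
                n_complete=len(complete),
                complete_by_category=CorrelationSummary(
                    cats["both"], cats["u_only"], cats["c_only"], cats["neither"]
                ),
            )
        )
    total = LevelBreakdown(
        rank="total",
        n_probed=sum(r.n_probed for r in rows),
        n_without_genomes=sum(r.n_without_genomes for r in rows),
        n_complete=sum(r.n_complete for r in rows),
        complete_by_category=sum(
            (r.complete_by_category for r in rows),
            CorrelationSummary(0, 0, 0, 0),
        ),
    )
    return rows, total


def correlation_percentages(summary: CorrelationSummary) -> dict[str, float]:
    """Category percentages to one decimal, plus the combined
    both-or-neither concordance.

    Rounding is sum-preserving (largest-remainder apportionment in tenths
    of a percent): each category gets the floor of its exact percentage
    and the leftover tenths go to the largest fractional remainders, so
    the four percentages always sum to exactly 100.0.  The concordance is
    the sum of the rounded both and neither shares.
    """
    n = summary.n_total
    if n <= 0:
        raise ValueError("percentages undefined for an empty summary")
    counts = [summary.n_both, summary.n_u_only, summary.n_c_only, summary.n_neither]
    tenths = [(1000 * c) // n for c in counts]
    remainders = [(1000 * c) % n for c in counts]
    for i in sorted(range(4), key=lambda i: (-remainders[i], i))[: 1000 - sum(tenths)]:
        tenths[i] += 1
    pct = [t / 10.0 for t in tenths]
    return {
        "pct_both": pct[0],
        "pct_u_only": pct[1],
        "pct_c_only": pct[2],
        "pct_neither": pct[3],
        "pct_concordant": round(pct[0] + pct[3], 1),
    }


# ---------------------------------------------------------------------------
# Packaged fixtures (transcriptions of the published tables)

def _open_fixture(name: str):
    return resources.files("nucsurvey.data").joinpath(name).open()


@dataclass(frozen=True)
class CompleteTaxonRow:
    rank: str
    name: str
    taxid: int
    category: str  # both | u_only | c_only | neither


def load_complete_taxa_fixture() -> list[CompleteTaxonRow]:
    """The 590 complete taxa with their joint U/C category, as published."""
    with _open_fixture("complete_taxa.tsv") as fh:
        return [
            CompleteTaxonRow(r["rank"], r["name"], int(r["taxid"]), r["category"])
            for r in csv.DictReader(fh, delimiter="\t")
        ]


@dataclass(frozen=True)
class ScoreRow:
    accession: str
    description: str
    ushA_score: float
    cpdB_score: float


_SCORE_TABLES = {
    "ecoli": "ecoli_exceptions.tsv",
    "apec": "apec_genomes.tsv",
    "pmultocida": "pmultocida_exceptions.tsv",
}


def load_score_table_fixture(name: str) -> list[ScoreRow]:
    """Per-genome best-score tables: ``ecoli`` (E. coli genomes lacking one
    family), ``apec`` (avian pathogenic E. coli) and ``pmultocida``."""
    with _open_fixture(_SCORE_TABLES[name]) as fh:
        return [
            ScoreRow(
                r["accession"], r["description"],
                float(r["ushA_score"]), float(r["cpdB_score"]),
            )
            for r in csv.DictReader(fh, delimiter="\t")
        ]


def statuses_from_score_rows(
    rows: Iterable[ScoreRow], score_threshold: float = SCORE_THRESHOLD
) -> list[GenomeStatus]:
    """Apply the strict score filter to a per-genome score table.

    The published tables filter on score only (coverage already passed),
    so a family is present iff its best score exceeds the threshold.
    """
    return [
        GenomeStatus(r.accession, r.ushA_score > score_threshold, r.cpdB_score > score_threshold)
        for r in rows
    ]


@dataclass(frozen=True)
class CountVignette:
    species: str
    n_total: int
    n_U: int
    n_C: int
    n_both: int


def load_count_vignettes() -> list[CountVignette]:
    """Species-level marginal-count vignettes for the inference arithmetic."""
    with _open_fixture("count_vignettes.tsv") as fh:
        return [
            CountVignette(
                r["species"], int(r["n_total"]), int(r["n_U"]), int(r["n_C"]), int(r["n_both"])
            )
            for r in csv.DictReader(fh, delimiter="\t")
        ]


def write_breakdown_table(rows: list[LevelBreakdown], total: LevelBreakdown, fh) -> None:
    fh.write(
        "rank\tn_probed\tn_without_genomes\tn_analyzed\tn_complete\t"
        "both\tu_only\tc_only\tneither\n"
    )
    for r in rows + [total]:
        c = r.complete_by_category
        fh.write(
            f"{r.rank}\t{r.n_probed}\t{r.n_without_genomes}\t{r.n_analyzed}\t"
            f"{r.n_complete}\t{c.n_both}\t{c.n_u_only}\t{c.n_c_only}\t{c.n_neither}\n"
        )


def write_category_lists(
    categories: Mapping[str, list[TaxonSurveyResult]], fh
) -> None:
    fh.write("category\trank\ttaxid\tname\n")
    for key in _CATEGORY_KEYS:
        for res in categories.get(key, []):
            fh.write(f"{key}\t{res.rank}\t{res.taxid}\t{res.name}\n")
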