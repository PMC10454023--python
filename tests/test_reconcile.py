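"""Cross-probe reconciliation: joint categories, count inference,
aggregation and correlation percentages."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nucsurvey.alignment import Hit
from nucsurvey.reconcile import (
    CorrelationSummary,
    GenomeStatus,
    InconsistentCountsError,
    aggregate_levels,
    categorize_complete_taxa,
    categorize_genomes,
    correlation_percentages,
    genome_status,
    infer_categories_from_counts,
    load_complete_taxa_fixture,
    load_count_vignettes,
    load_score_table_fixture,
    statuses_from_score_rows,
)
from nucsurvey.survey import PresenceLevel, TaxonSurveyResult

KINDS = {"U1": "UshA-like", "U2": "UshA-like", "C1": "CpdB-like"}


def hit(probe, passes):
    return Hit("G", probe, 200.0 if passes else 10.0, 0.9 if passes else 0.1,
               [], passes)


class TestGenomeStatus:
    def test_all_fail(self):
        s = genome_status([hit("U1", False), hit("C1", False)], KINDS)
        assert (s.has_U, s.has_C) == (False, False)

    def test_single_ushA_probe_pass(self):
        s = genome_status([hit("U2", True), hit("C1", False)], KINDS)
        assert (s.has_U, s.has_C) == (True, False)

    def test_union_over_probes(self):
        s = genome_status([hit("U1", False), hit("U2", True), hit("C1", True)], KINDS)
        assert (s.has_U, s.has_C) == (True, True)


class TestCategorizeGenomes:
    def test_empty(self):
        assert categorize_genomes([]) == CorrelationSummary(0, 0, 0, 0)

    def test_mixed(self):
        statuses = [
            GenomeStatus("a", True, True),
            GenomeStatus("b", True, False),
            GenomeStatus("c", False, False),
        ]
        assert categorize_genomes(statuses) == CorrelationSummary(1, 1, 0, 1)

    @given(
        st.lists(st.tuples(st.booleans(), st.booleans()), max_size=60),
    )
    @settings(deadline=None)
    def test_conservation(self, flags):
        statuses = [GenomeStatus(str(i), u, c) for i, (u, c) in enumerate(flags)]
        summary = categorize_genomes(statuses)
        assert summary.n_total == len(flags)

    @given(st.lists(st.tuples(st.booleans(), st.booleans()), min_size=1, max_size=60))
    @settings(deadline=None)
    def test_inference_matches_direct_categorisation(self, flags):
        """Inferring the joint breakdown from marginal counts agrees with
        counting the genomes directly."""
        statuses = [GenomeStatus(str(i), u, c) for i, (u, c) in enumerate(flags)]
        direct = categorize_genomes(statuses)
        inferred = infer_categories_from_counts(
            len(statuses),
            sum(s.has_U for s in statuses),
            sum(s.has_C for s in statuses),
            sum(s.has_U and s.has_C for s in statuses),
        )
        assert inferred == direct


class TestInferCategories:
    def test_full_U_deduction(self):
        # all genomes U-positive, a minority C-positive: the C-positives
        # must be double positive and nothing can be double negative
        s = infer_categories_from_counts(17, 17, 4, 4)
        assert (s.n_u_only, s.n_c_only, s.n_neither) == (13, 0, 0)

    def test_equal_marginals_full_overlap(self):
        s = infer_categories_from_counts(350, 219, 219, 219)
        assert s.n_neither == 131 and s.n_u_only == 0

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(InconsistentCountsError):
            infer_categories_from_counts(10, 8, 3, 5)
        with pytest.raises(InconsistentCountsError):
            infer_categories_from_counts(10, 8, 8, 2)


def result(taxid, rank, u, c, complete=True, n=5):
    r = TaxonSurveyResult(taxid=taxid, rank=rank, n_genomes_analyzed=n)
    r.level_U, r.level_C, r.complete = u, c, complete
    return r


class TestCategorizeCompleteTaxa:
    def test_partition(self):
        L = PresenceLevel
        results = [
            result(1, "phylum", L.FULL, L.FULL),
            result(2, "phylum", L.FULL, L.ABSENT),
            result(3, "phylum", L.ABSENT, L.FULL),
            result(4, "phylum", L.ABSENT, L.ABSENT),
            result(5, "phylum", L.FULL, L.LOW, complete=False),
            result(6, "phylum", None, None, complete=False, n=0),
        ]
        cats = categorize_complete_taxa(results)
        assert [r.taxid for r in cats["both"]] == [1]
        assert [r.taxid for r in cats["u_only"]] == [2]
        assert [r.taxid for r in cats["c_only"]] == [3]
        assert [r.taxid for r in cats["neither"]] == [4]
        listed = [r.taxid for lst in cats.values() for r in lst]
        assert sorted(listed) == [1, 2, 3, 4]  # complete taxa only, once each


class TestAggregateLevels:
    def test_counts_and_conservation(self):
        L = PresenceLevel
        results = [
            result(1, "phylum", L.FULL, L.FULL),
            result(2, "phylum", L.PARTIAL, L.ABSENT, complete=False),
            result(3, "class", None, None, complete=False, n=0),
            result(4, "class", L.ABSENT, L.ABSENT),
        ]
        rows, total = aggregate_levels(results)
        by_rank = {r.rank: r for r in rows}
        assert by_rank["phylum"].n_probed == 2
        assert by_rank["phylum"].n_complete == 1
        assert by_rank["class"].n_without_genomes == 1
        assert by_rank["class"].n_analyzed == 1
        assert by_rank["order"].n_probed == 0
        assert total.n_probed == 4 and total.n_complete == 2
        assert total.complete_by_category.n_total == total.n_complete


class TestCorrelationPercentages:
    def test_single_category(self):
        pct = correlation_percentages(CorrelationSummary(1, 0, 0, 0))
        assert pct["pct_both"] == 100.0 and pct["pct_concordant"] == 100.0

    def test_empty_undefined(self):
        with pytest.raises(ValueError):
            correlation_percentages(CorrelationSummary(0, 0, 0, 0))

    @given(st.tuples(*[st.integers(0, 500)] * 4))
    @settings(deadline=None)
    def test_rounded_percentages_sum_to_100(self, counts):
        summary = CorrelationSummary(*counts)
        if summary.n_total == 0:
            return
        pct = correlation_percentages(summary)
        four = pct["pct_both"] + pct["pct_u_only"] + pct["pct_c_only"] + pct["pct_neither"]
        assert four == pytest.approx(100.0, abs=1e-9)
        for key, count in zip(
            ("pct_both", "pct_u_only", "pct_c_only", "pct_neither"), counts
        ):
            # each rounded share stays within one tenth of the exact value
            assert abs(pct[key] - 100.0 * count / summary.n_total) <= 0.1 + 1e-9


class TestFixtures:
    def test_score_tables_have_published_shapes(self):
        assert len(load_score_table_fixture("ecoli")) == 18
        assert len(load_score_table_fixture("apec")) == 5
        assert len(load_score_table_fixture("pmultocida")) == 5

    def test_borderline_score_counts_as_positive(self):
        """A best score of exactly 151 clears the strict >150 rule."""
        rows = load_score_table_fixture("pmultocida")
        statuses = {s.genome_accession: s for s in statuses_from_score_rows(rows)}
        assert statuses["NZ_CP038871.1"].has_U and statuses["NZ_CP038871.1"].has_C

    def test_complete_taxa_fixture_spans_all_ranks(self):
        rows = load_complete_taxa_fixture()
        assert len(rows) == 590
        assert {r.category for r in rows} == {"both", "u_only", "c_only", "neither"}
        assert {r.rank for r in rows} == {
            "phylum", "class", "order", "family", "genus", "species"
        }

    def test_vignettes_are_self_consistent(self):
        for v in load_count_vignettes():
            s = infer_categories_from_counts(v.n_total, v.n_U, v.n_C, v.n_both)
            assert s.n_total == v.n_total
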