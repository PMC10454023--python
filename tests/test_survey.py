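"""Survey engine: presence levels, completeness, eligibility and the
pruned hierarchical traversal."""

import itertools

import pytest

from nucsurvey.panel import ProbeRecord
from nucsurvey.search import SearchEngine
from nucsurvey.simulate import generate_dataset, random_protein
from nucsurvey.survey import (
    PresenceLevel,
    SurveyConfig,
    classify_presence,
    eligible_genomes,
    hierarchical_survey,
    is_complete,
    survey_taxon,
)
from nucsurvey.taxonomy import GenomeManifestEntry, descendant_taxa

from conftest import tiny_config

L = PresenceLevel


class TestClassifyPresence:
    @pytest.mark.parametrize(
        "k,n,expected",
        [
            (0, 17, L.ABSENT),
            (4, 17, L.LOW),          # 4/17 hit genomes: minority presence
            (135, 138, L.PARTIAL),   # nearly but not fully widespread
            (138, 138, L.FULL),
            (5, 10, L.LOW),          # exactly 50% is still the low tier
            (6, 10, L.PARTIAL),
            (1, 1, L.FULL),
        ],
    )
    def test_levels(self, k, n, expected):
        assert classify_presence(k, n) is expected

    def test_zero_genomes_undefined(self):
        with pytest.raises(ValueError):
            classify_presence(0, 0)

    @pytest.mark.parametrize("n", [1, 2, 5, 12])
    def test_monotone_and_exhaustive(self, n):
        order = [L.ABSENT, L.LOW, L.PARTIAL, L.FULL]
        levels = [classify_presence(k, n) for k in range(n + 1)]
        indices = [order.index(lv) for lv in levels]
        assert indices == sorted(indices)
        assert levels[0] is L.ABSENT and levels[-1] is L.FULL


class TestIsComplete:
    @pytest.mark.parametrize("u,c", list(itertools.product(list(L), repeat=2)))
    def test_terminal_iff_both_absent_or_full(self, u, c):
        expected = u in (L.ABSENT, L.FULL) and c in (L.ABSENT, L.FULL)
        assert is_complete(u, c) is expected


def entries(n_total, n_type):
    return [
        GenomeManifestEntry(f"G{i}", 1000, i < n_type) for i in range(n_total)
    ]


class TestEligibleGenomes:
    def test_type_material_restriction_at_phylum(self):
        chosen = eligible_genomes(entries(40, 10), "phylum", SurveyConfig())
        assert len(chosen) == 10 and all(e.is_type_material for e in chosen)

    def test_restriction_removed_below_five(self):
        assert len(eligible_genomes(entries(40, 4), "phylum", SurveyConfig())) == 40

    def test_all_genomes_at_species(self):
        assert len(eligible_genomes(entries(17, 3), "species", SurveyConfig())) == 17
        assert len(eligible_genomes(entries(17, 7), "genus", SurveyConfig())) == 17


@pytest.fixture(scope="module")
def surveyed_tiny():
    """Tiny dataset surveyed once; species plans cycle (1,1), (0,0),
    (1,0), (0,1) across its four species."""
    ds = generate_dataset(tiny_config())
    engine = SearchEngine()
    results = hierarchical_survey(
        ds.tree, ds.manifest, ds.store(), ds.probes, engine=engine
    )
    return ds, engine, results


class TestSurveyTaxon:
    def test_double_planted_species_is_complete(self, surveyed_tiny):
        ds, engine, _ = surveyed_tiny
        species = next(
            t for t, plan in ds.truth.species_plan.items() if plan == (1.0, 1.0)
        )
        res = survey_taxon(
            ds.tree, ds.manifest, ds.store(), ds.probes, species, engine=engine
        )
        assert (res.level_U, res.level_C, res.complete) == (L.FULL, L.FULL, True)

    def test_union_counts_bound_per_probe_counts(self, surveyed_tiny):
        ds, _, results = surveyed_tiny
        u_accs = {p.accession for p in ds.probes if p.kind == "UshA-like"}
        for res in results.values():
            if not res.analyzed:
                continue
            assert res.n_genomes_U <= res.n_genomes_analyzed
            per_u = [v for k, v in res.per_probe_hits.items() if k in u_accs]
            if per_u:
                assert res.n_genomes_U >= max(per_u)

    def test_u_full_c_minority_species(self):
        """A species with U planted everywhere and C in a minority is
        FULL / LOW and not complete."""
        ds = generate_dataset(
            tiny_config(seed=9, genomes_per_species=4, species_per_genus=3)
        )
        species = next(
            t for t, plan in ds.truth.species_plan.items() if plan == (1.0, 0.25)
        )
        res = survey_taxon(ds.tree, ds.manifest, ds.store(), ds.probes, species)
        assert (res.level_U, res.level_C) == (L.FULL, L.LOW)
        assert not res.complete

    def test_zero_genome_taxon_not_analyzed(self, surveyed_tiny):
        ds, engine, _ = surveyed_tiny
        from nucsurvey.taxonomy import TaxonNode, TaxonomyTree

        nodes = list(ds.tree.nodes.values()) + [
            TaxonNode(9999, "Empty phylum", "phylum", 2)
        ]
        tree = TaxonomyTree(nodes)
        res = survey_taxon(tree, ds.manifest, ds.store(), ds.probes, 9999, engine=engine)
        assert not res.analyzed and res.level_U is None and not res.complete


class TestHierarchicalSurvey:
    def test_all_absent_prunes_at_phylum(self, surveyed_tiny):
        """Probes unrelated to anything planted give double-absent phyla,
        so nothing below phylum rank is surveyed."""
        ds, _, _ = surveyed_tiny
        foreign = [
            ProbeRecord(accession="FORU", kind="UshA-like", sequence=random_protein(220, 77)),
            ProbeRecord(accession="FORC", kind="CpdB-like", sequence=random_protein(220, 78)),
        ]
        results = hierarchical_survey(ds.tree, ds.manifest, ds.store(), foreign)
        assert {r.rank for r in results.values()} == {"phylum"}
        assert all(
            (r.level_U, r.level_C) == (L.ABSENT, L.ABSENT) for r in results.values()
        )

    def test_partial_taxon_descends_into_its_children_only(self, surveyed_tiny):
        ds, _, results = surveyed_tiny
        surveyed = set(results)
        for res in results.values():
            if res.rank == "species" or not res.analyzed:
                continue
            children_rank = {"phylum": "class", "class": "order", "order": "family",
                             "family": "genus", "genus": "species"}[res.rank]
            children = set(descendant_taxa(ds.tree, res.taxid, children_rank))
            if res.complete:
                assert not children & surveyed
            else:
                assert children <= surveyed

    def test_matches_independent_recursive_walk(self, surveyed_tiny):
        """The taxa surveyed equal those of a plain recursive reference
        walk applying the same pruning rule."""
        ds, engine, results = surveyed_tiny
        ladder = ["phylum", "class", "order", "family", "genus", "species"]
        reference: set[int] = set()

        def walk(taxid, depth):
            if depth >= len(ladder):
                return
            for child in descendant_taxa(ds.tree, taxid, ladder[depth]):
                res = survey_taxon(
                    ds.tree, ds.manifest, ds.store(), ds.probes, child, engine=engine
                )
                reference.add(child)
                if res.analyzed and not res.complete:
                    walk(child, depth + 1)

        walk(ds.tree.root, 0)
        assert reference == set(results)

    def test_pruning_soundness(self, surveyed_tiny):
        """No surveyed taxon has an analyzed complete ancestor."""
        ds, _, results = surveyed_tiny
        complete = {t for t, r in results.items() if r.analyzed and r.complete}
        for taxid in results:
            node = ds.tree.nodes[taxid]
            while node.taxid != node.parent_taxid:
                node = ds.tree.nodes[node.parent_taxid]
                assert node.taxid not in complete
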