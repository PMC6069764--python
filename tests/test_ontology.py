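"""Hierarchy loading, validation, traversal and label search."""

import random

import networkx as nx
import pytest

from mirmesh.ontology import (
    LabelQueryMode,
    MatchMode,
    OntologyStructureError,
    UnknownTermError,
    ancestors,
    descendants,
    expand,
    find_terms,
    load_ontology,
    parse_edge_list,
    parse_obo,
    slugify,
    write_edge_list,
)

from conftest import make_random_dag

OBO_MINI = """\
[Term]
id: leukemia
name: Leukemia
synonym: "Leucocythaemia" EXACT []
xref: D007938
is_a: neoplasms ! Neoplasms

[Term]
id: neoplasms
name: Neoplasms

[Typedef]
id: part_of
name: part of
"""


class TestLoading:
    def test_two_node_cycle_is_rejected(self):
        doc = "child_id\tchild_label\tparent_id\na\tA\tb\nb\tB\ta\n"
        with pytest.raises(OntologyStructureError, match="cycle"):
            load_ontology(doc)

    def test_dangling_parent_names_missing_id(self):
        doc = "child_id\tchild_label\tparent_id\na\tA\tghost\n"
        with pytest.raises(OntologyStructureError, match="ghost"):
            load_ontology(doc)

    def test_duplicate_case_folded_label_rejected(self):
        doc = "child_id\tchild_label\tparent_id\na\tLeukemia\t\nb\tLEUKEMIA\t\n"
        with pytest.raises(OntologyStructureError, match="duplicate preferred label"):
            load_ontology(doc)

    def test_empty_document_yields_empty_ontology(self):
        assert len(load_ontology("")) == 0

    def test_obo_subset_parses_synonyms_and_skips_other_tags(self):
        onto = parse_obo(OBO_MINI)
        assert len(onto) == 2
        assert onto["leukemia"].synonyms == ("Leucocythaemia",)
        assert onto["leukemia"].parent_ids == ("neoplasms",)

    def test_edge_list_round_trips_through_writer(self, onto):
        assert parse_edge_list(write_edge_list(onto)).terms == onto.terms

    def test_self_parent_rejected(self):
        doc = "child_id\tchild_label\tparent_id\na\tA\ta\n"
        with pytest.raises(OntologyStructureError):
            load_ontology(doc)


class TestPaperMiniOntology:
    def test_t_cell_leukemia_has_exactly_three_descendants(self, onto):
        assert descendants(onto, "leukemia-t-cell") == [
            "leukemia-large-granular-lymphocytic",
            "leukemia-lymphoma-adult-t-cell",
            "leukemia-prolymphocytic-t-cell",
        ]

    def test_direct_parent_of_b_cell_leukemia(self, onto):
        assert ancestors(onto, "leukemia-b-cell", max_depth=1) == ["leukemia-lymphoid"]

    def test_root_has_no_ancestors_and_leaf_no_descendants(self, onto):
        assert ancestors(onto, "neoplasms-by-histologic-type") == []
        assert descendants(onto, "leukemia-b-cell") == []

    def test_broader_expansion_depth_one(self, onto):
        assert expand(onto, "leukemia-b-cell", MatchMode.BROADER, 1) == [
            "leukemia-b-cell",
            "leukemia-lymphoid",
        ]

    def test_narrower_expansion_of_t_cell_leukemia_has_four_terms(self, onto):
        got = expand(onto, "leukemia-t-cell", MatchMode.NARROWER)
        assert len(got) == 4 and "leukemia-t-cell" in got

    def test_exact_expansion_is_the_singleton(self, onto):
        for tid in onto.terms:
            assert expand(onto, tid, MatchMode.EXACT) == [tid]

    def test_unknown_term_raises_lookup_error(self, onto):
        with pytest.raises(UnknownTermError):
            ancestors(onto, "no-such-term")
        with pytest.raises(UnknownTermError):
            expand(onto, "no-such-term", MatchMode.EXACT)


class TestTraversalAgainstReachabilityOracle:
    """Hand-written BFS vs networkx reachability on random DAGs."""

    @pytest.mark.parametrize("case", range(200))
    def test_closures_match_oracle(self, case):
        rng = random.Random(10_000 + case)
        onto = make_random_dag(rng)
        graph = nx.DiGraph()
        graph.add_nodes_from(onto.terms)
        for term in onto.terms.values():
            for pid in term.parent_ids:
                graph.add_edge(term.term_id, pid)  # child -> parent
        node = rng.choice(sorted(onto.terms))
        depth = rng.choice([1, 2, 3, None])

        def oracle(g, src, cutoff):
            dist = nx.single_source_shortest_path_length(g, src, cutoff=cutoff)
            return sorted(set(dist) - {src})

        assert ancestors(onto, node, depth) == oracle(graph, node, depth)
        assert descendants(onto, node, depth) == oracle(graph.reverse(), node, depth)
        # duality at unbounded depth, checked for every node pair
        for x in onto.terms:
            for y in onto.terms:
                assert (x in descendants(onto, y)) == (y in ancestors(onto, x))

    @pytest.mark.parametrize("case", range(30))
    def test_depth_monotonicity_and_mode_containment(self, case):
        rng = random.Random(20_000 + case)
        onto = make_random_dag(rng)
        node = rng.choice(sorted(onto.terms))
        prev_up, prev_down = set(), set()
        for depth in [1, 2, 3, len(onto), None]:
            up = set(ancestors(onto, node, depth))
            down = set(descendants(onto, node, depth))
            assert prev_up <= up and prev_down <= down
            prev_up, prev_down = up, down
        # unbounded equals depth = number of terms
        assert set(ancestors(onto, node)) == set(ancestors(onto, node, len(onto)))
        for depth in [1, None]:
            exact = set(expand(onto, node, MatchMode.EXACT))
            assert exact <= set(expand(onto, node, MatchMode.BROADER, depth))
            assert exact <= set(expand(onto, node, MatchMode.NARROWER, depth))


class TestFindTerms:
    def test_prefix_query_resolves_t_cell_leukemia(self, onto):
        hits = find_terms(onto, "Leukemia, T", LabelQueryMode.FROM_BEGINNING)
        assert [t.term_id for t in hits] == ["leukemia-t-cell"]

    def test_anywhere_query_matches_exhaustive_label_scan(self, onto):
        hits = find_terms(onto, "lymph", LabelQueryMode.ANYWHERE)
        expected = sorted(
            (
                t.preferred_label
                for t in onto.terms.values()
                if "lymph" in t.preferred_label.casefold()
            ),
        )
        assert [t.preferred_label for t in hits] == expected
        assert expected  # the scan is not vacuous

    def test_no_match_returns_empty_list(self, onto):
        assert find_terms(onto, "zzz", LabelQueryMode.ANYWHERE) == []

    def test_empty_query_is_an_argument_error(self, onto):
        with pytest.raises(ValueError):
            find_terms(onto, "   ", LabelQueryMode.ANYWHERE)

    def test_prefix_hits_are_subset_of_anywhere_hits(self, onto):
        for query in ["leu", "Lymphocytic", "cell", "neo"]:
            begin = {t.term_id for t in find_terms(onto, query, LabelQueryMode.FROM_BEGINNING)}
            anywhere = {t.term_id for t in find_terms(onto, query, LabelQueryMode.ANYWHERE)}
            assert begin <= anywhere

    def test_synonyms_are_searched(self):
        onto = parse_obo(OBO_MINI)
        hits = find_terms(onto, "leucocyt", LabelQueryMode.FROM_BEGINNING)
        assert [t.term_id for t in hits] == ["leukemia"]


def test_slugify_is_lowercase_punctuation_stripped_hyphenated():
    assert slugify("Leukemia, T-Cell") == "leukemia-t-cell"
    assert slugify("Neoplasms by Histologic Type") == "neoplasms-by-histologic-type"
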