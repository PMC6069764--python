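"""Study fixture construction and randomized corpus generation."""

from importlib import resources

import pydantic
import pytest

from mirmesh.filtering import mesh_filter, tally
from mirmesh.ontology import MatchMode, write_edge_list
from mirmesh.pipeline import dump_plan
from mirmesh.records import write_corpus, write_roster
from mirmesh.synthetic import (
    PARENT_TERM_ID,
    QUERY_TERM_ID,
    UNRELATED_TERM_ID,
    CorpusSpec,
    GenerationError,
    StratumCounts,
    study_corpus,
    study_ontology,
    study_plan,
    study_spec,
    random_corpus,
    random_spec,
)


class TestPaperOntology:
    def test_parent_chain(self, onto):
        assert onto.parents_of("leukemia-b-cell") == ("leukemia-lymphoid",)
        assert onto.parents_of(QUERY_TERM_ID) == (PARENT_TERM_ID,)

    def test_t_cell_leukemia_has_three_children(self, onto):
        assert len(onto.children_of("leukemia-t-cell")) == 3

    def test_unrelated_term_is_disjoint_from_leukemia_branch(self, onto):
        from mirmesh.ontology import ancestors, descendants

        branch = {QUERY_TERM_ID, *ancestors(onto, QUERY_TERM_ID),
                  *descendants(onto, QUERY_TERM_ID)}
        assert UNRELATED_TERM_ID in onto
        assert UNRELATED_TERM_ID not in branch


class TestPaperCorpus:
    def test_total_records_is_232(self, corpus):
        assert len(corpus) == 232 and len(corpus.roster) == 18

    def test_named_validated_genes_for_mir_17_5p(self, corpus):
        genes = {
            r.gene_symbol
            for r in corpus.records
            if r.mirna_id == "hsa-miR-17-5p"
            and r.evidence == "validated"
            and QUERY_TERM_ID in r.mesh_term_ids
        }
        assert genes == {"E2F1", "RUNX1", "TP53"}

    def test_named_predicted_genes_for_mir_142_3p(self, corpus):
        genes = {
            r.gene_symbol
            for r in corpus.records
            if r.mirna_id == "hsa-miR-142-3p"
            and r.evidence == "predicted"
            and QUERY_TERM_ID in r.mesh_term_ids
        }
        assert genes == {"ASH1L", "CP", "MLLT1", "MLLT4", "SAG"}

    def test_zero_target_mirna_is_roster_only(self, corpus):
        assert "hsa-miR-15b-3p" in corpus.roster
        assert not any(r.mirna_id == "hsa-miR-15b-3p" for r in corpus.records)

    def test_every_record_has_one_supporting_publication(self, corpus):
        assert all(len(r.pmids) == 1 for r in corpus.records)

    def test_stratum_arithmetic_is_internally_consistent(self):
        # per miRNA: exact <= round-1 <= total, by construction
        for s in study_spec().strata:
            assert min(
                s.exact_predicted, s.exact_validated,
                s.broader_only_predicted, s.broader_only_validated,
                s.unrelated_total,
            ) >= 0

    def test_construction_is_deterministic(self):
        a, b = study_corpus(), study_corpus()
        assert write_corpus(a, "tsv") == write_corpus(b, "tsv")
        assert a == b


class TestBundledDataFiles:
    """The files shipped under mirmesh/data must equal generator output."""

    @pytest.mark.parametrize(
        "name,produce",
        [
            ("study_ontology.tsv", lambda: write_edge_list(study_ontology())),
            ("study_corpus.tsv", lambda: write_corpus(study_corpus(), "tsv")),
            ("study_corpus.json", lambda: write_corpus(study_corpus(), "json")),
            ("study_roster.tsv", lambda: write_roster(study_corpus())),
            ("study_plan.yaml", lambda: dump_plan(study_plan())),
        ],
    )
    def test_bundled_file_matches_generator(self, name, produce):
        bundled = (resources.files("mirmesh") / "data" / name).read_text()
        assert bundled == produce()


class TestRandomCorpus:
    def test_all_zero_spec_yields_empty_corpus_with_roster(self, onto):
        spec = random_spec(1, n_mirnas=3, max_per_stratum=0)
        corpus = random_corpus(spec, onto)
        assert len(corpus) == 0 and len(corpus.roster) == 3

    def test_exact_stratum_recovered_by_filtering(self, onto):
        spec = CorpusSpec(
            strata=(StratumCounts(mirna_id="m1", exact_predicted=3),), seed=0
        )
        corpus = random_corpus(spec, onto)
        kept = mesh_filter(corpus, onto, QUERY_TERM_ID, MatchMode.EXACT)
        (t,) = [x for x in tally(kept) if x.mirna_id == "m1"]
        assert (t.predicted_count, t.validated_count) == (3, 0)

    def test_same_spec_is_byte_deterministic(self, onto):
        spec = random_spec(9, n_mirnas=4)
        a, b = random_corpus(spec, onto), random_corpus(spec, onto)
        assert write_corpus(a, "json") == write_corpus(b, "json")

    def test_seed_changes_leave_stratum_tallies_invariant(self, onto):
        base = random_spec(11, n_mirnas=4)
        reseeded = base.model_copy(update={"seed": 12})
        for spec_variant in (base, reseeded):
            corpus = random_corpus(spec_variant, onto)
            r1 = tally(mesh_filter(corpus, onto, QUERY_TERM_ID, MatchMode.BROADER, 1))
            by_id = {t.mirna_id: t for t in r1}
            for s in spec_variant.strata:
                t = by_id[s.mirna_id]
                assert t.predicted_count == s.exact_predicted + s.broader_only_predicted
                assert t.validated_count == s.exact_validated + s.broader_only_validated

    def test_invalid_term_layout_is_a_generation_error(self, onto):
        bad_parent = CorpusSpec(
            strata=(StratumCounts(mirna_id="m"),),
            broader_annotation_term_id="leukemia-b-cell",
        )
        with pytest.raises(GenerationError, match="ancestor"):
            random_corpus(bad_parent, onto)
        bad_unrelated = CorpusSpec(
            strata=(StratumCounts(mirna_id="m"),),
            unrelated_term_id=QUERY_TERM_ID,
        )
        with pytest.raises(GenerationError, match="disjoint"):
            random_corpus(bad_unrelated, onto)

    def test_negative_stratum_count_is_rejected(self):
        with pytest.raises(pydantic.ValidationError):
            StratumCounts(mirna_id="m", exact_predicted=-1)


class TestRandomSpec:
    def test_fixed_seed_reproduces_the_spec(self):
        assert random_spec(5) == random_spec(5)

    def test_zero_max_gives_all_zero_counts(self):
        spec = random_spec(3, n_mirnas=4, max_per_stratum=0)
        assert all(
            s.exact_predicted == s.exact_validated == s.broader_only_predicted
            == s.broader_only_validated == s.unrelated_total == 0
            for s in spec.strata
        )

    @pytest.mark.parametrize("seed", range(100))
    def test_specs_are_valid_against_the_companion_ontology(self, seed, onto):
        random_spec(seed, n_mirnas=3).validate_against(onto)

    def test_at_least_one_mirna_required(self):
        with pytest.raises(ValueError):
            random_spec(0, n_mirnas=0)
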