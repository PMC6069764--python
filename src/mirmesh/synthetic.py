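"""Study fixtures and randomized corpora from count specifications.

The study corpus cannot be re-downloaded: the original system federated
several target databases live and deposited no accession.  What the study
*published* is per-miRNA counts (total annotated targets; predicted and
validated survivors of each filtering round) plus the named genes of the
final survivors.  :func:`study_corpus` rebuilds a corpus with exactly
that arithmetic — every count stratified into

* **exact** records annotated with the query disease term (Leukemia),
  using the published gene names where available;
* **broader-only** records annotated with the direct parent term
  (Neoplasms by Histologic Type) only;
* **unrelated** records annotated with a disjoint disease term,

so that the two-round Broader-then-Exact plan reproduces the published
tallies.  Synthetic gene symbols (``<miRNA>-Tn``) and publication ids
(``SYNn``) are deliberately non-real.

:func:`random_corpus` generates the same structure from an arbitrary
:class:`CorpusSpec`, which is the substrate for generator-recovery
property tests: the pipeline's round tallies must equal the spec's
stratum sums exactly.
"""

from __future__ import annotations

import random

from pydantic import BaseModel, ConfigDict, field_validator

from mirmesh.ontology import MeshOntology, MeshTerm, ancestors, slugify
from mirmesh.pipeline import FilterRound, PipelinePlan
from mirmesh.records import TargetCorpus, TargetRecord

__all__ = [
    "StratumCounts",
    "CorpusSpec",
    "GenerationError",
    "study_ontology",
    "study_corpus",
    "study_plan",
    "study_spec",
    "random_corpus",
    "random_spec",
    "QUERY_TERM_ID",
    "PARENT_TERM_ID",
    "UNRELATED_TERM_ID",
]


class GenerationError(ValueError):
    """A count specification is internally inconsistent."""


# --------------------------------------------------------------------------
# The mini-ontology: the Leukemia neighbourhood plus one disjoint disease
# --------------------------------------------------------------------------

_ONTOLOGY_EDGES: tuple[tuple[str, str | None], ...] = (
    ("Neoplasms by Histologic Type", None),
    ("Leukemia", "Neoplasms by Histologic Type"),
    ("Leukemia, Lymphoid", "Leukemia"),
    ("Leukemia, B-Cell", "Leukemia, Lymphoid"),
    ("Leukemia, T-Cell", "Leukemia, Lymphoid"),
    ("Leukemia, Large Granular Lymphocytic", "Leukemia, T-Cell"),
    ("Leukemia, Prolymphocytic, T-Cell", "Leukemia, T-Cell"),
    ("Leukemia-Lymphoma, Adult T-Cell", "Leukemia, T-Cell"),
    ("Nervous System Diseases", None),
)

QUERY_TERM_ID = slugify("Leukemia")
PARENT_TERM_ID = slugify("Neoplasms by Histologic Type")
UNRELATED_TERM_ID = slugify("Nervous System Diseases")


def study_ontology() -> MeshOntology:
    """The fixed mini-hierarchy used throughout: the Leukemia subtree
    (root Neoplasms by Histologic Type, down through Leukemia, Lymphoid
    to the B-/T-Cell leaves and the three T-Cell subtypes) plus one
    disjoint disease term for unrelated annotations.  Term ids are
    deterministic slugs of the labels."""
    terms = {}
    for label, parent in _ONTOLOGY_EDGES:
        tid = slugify(label)
        terms[tid] = MeshTerm(
            term_id=tid,
            preferred_label=label,
            parent_ids=(slugify(parent),) if parent else (),
        )
    return MeshOntology(terms=terms)


# --------------------------------------------------------------------------
# Published per-miRNA counts
# --------------------------------------------------------------------------
# Columns: total annotated targets; round-1 (broader) predicted/validated
# survivors; round-2 (exact) predicted/validated survivors.

_STUDY_COUNTS: tuple[tuple[str, int, int, int, int, int], ...] = (
    ("hsa-miR-124-3p", 15, 0, 7, 0, 0),
    ("hsa-miR-124-5p", 0, 0, 0, 0, 0),
    ("hsa-miR-128-3p", 5, 4, 0, 1, 0),
    ("hsa-miR-142-3p", 69, 12, 11, 5, 4),
    ("hsa-miR-15b-3p", 0, 0, 0, 0, 0),
    ("hsa-miR-17-5p", 84, 7, 11, 3, 3),
    ("hsa-miR-18a-3p", 4, 2, 2, 2, 0),
    ("hsa-miR-182-5p", 16, 4, 4, 0, 0),
    ("hsa-miR-193a-3p", 17, 4, 1, 0, 1),
    ("hsa-miR-218-5p", 2, 1, 0, 0, 0),
    ("hsa-miR-221-3p", 1, 0, 0, 0, 0),
    ("hsa-miR-335-5p", 8, 1, 0, 0, 0),
    ("hsa-miR-532-5p", 5, 0, 1, 0, 0),
    ("hsa-miR-550a-3p", 0, 0, 0, 0, 0),
    ("hsa-miR-625-5p", 1, 1, 0, 0, 0),
    ("hsa-miR-633", 0, 0, 0, 0, 0),
    ("hsa-miR-638", 3, 0, 0, 0, 0),
    ("hsa-miR-708-5p", 2, 0, 1, 0, 0),
)

# Named genes of the final (exact-match) survivors, with formal gene names.
_NAMED_GENES: dict[tuple[str, str], tuple[tuple[str, str], ...]] = {
    ("hsa-miR-142-3p", "predicted"): (
        ("ASH1L", "ash1 (absent, small, or homeotic)-like (Drosophila)"),
        ("CP", "ceruloplasmin (ferroxidase)"),
        ("MLLT1", "myeloid/lymphoid or mixed-lineage leukemia; translocated to, 1"),
        ("MLLT4", "myeloid/lymphoid or mixed-lineage leukemia; translocated to, 4"),
        ("SAG", "S-antigen; retina and pineal gland (arrestin)"),
    ),
    ("hsa-miR-142-3p", "validated"): (
        ("CCNT2", "cyclin T2"),
        ("EGR2", "early growth response 2"),
        ("HOXA10", "homeobox A10"),
        ("HOXA7", "homeobox A7"),
    ),
    ("hsa-miR-17-5p", "predicted"): (
        ("AGO2", "argonaute 2, RISC catalytic component"),
        ("BCR", "breakpoint cluster region"),
        ("NPM1", "nucleophosmin (nucleolar phosphoprotein B23, nunatrin)"),
    ),
    ("hsa-miR-17-5p", "validated"): (
        ("E2F1", "E2F transcription factor 1"),
        ("RUNX1", "runt related transcription factor 1"),
        ("TP53", "tumor protein p53"),
    ),
    ("hsa-miR-18a-3p", "predicted"): (
        ("ARHGAP26", "Rho GTPase activating protein 26"),
        ("IMPACT", "impact RWD domain protein"),
    ),
    ("hsa-miR-128-3p", "predicted"): (("PHF6", "PHD finger protein 6"),),
    ("hsa-miR-193a-3p", "validated"): (("MCL1", "myeloid cell leukemia 1"),),
}

_SOURCE_DBS = ("db-alpha", "db-beta", "db-gamma", "db-delta")


class StratumCounts(BaseModel):
    """Per-miRNA record counts by annotation stratum."""

    model_config = ConfigDict(frozen=True)

    mirna_id: str
    exact_predicted: int = 0
    exact_validated: int = 0
    broader_only_predicted: int = 0
    broader_only_validated: int = 0
    unrelated_total: int = 0

    @field_validator(
        "exact_predicted",
        "exact_validated",
        "broader_only_predicted",
        "broader_only_validated",
        "unrelated_total",
    )
    @classmethod
    def _non_negative(cls, v: int, info) -> int:
        if v < 0:
            raise GenerationError(f"{info.field_name} must be non-negative, got {v}")
        return v


class CorpusSpec(BaseModel):
    """A corpus blueprint: strata counts plus the three annotation terms
    and a seed.  Validity against a companion ontology requires the
    broader-annotation term to be an ancestor of the query term and the
    unrelated term to be outside {query} ∪ ancestors(query)."""

    model_config = ConfigDict(frozen=True)

    strata: tuple[StratumCounts, ...]
    query_term_id: str = QUERY_TERM_ID
    broader_annotation_term_id: str = PARENT_TERM_ID
    unrelated_term_id: str = UNRELATED_TERM_ID
    seed: int = 0

    def validate_against(self, ontology: MeshOntology) -> None:
        anc = set(ancestors(ontology, self.query_term_id))
        if self.broader_annotation_term_id not in anc:
            raise GenerationError(
                f"broader_annotation_term_id {self.broader_annotation_term_id!r} "
                f"is not an ancestor of {self.query_term_id!r}"
            )
        if self.unrelated_term_id == self.query_term_id or self.unrelated_term_id in anc:
            raise GenerationError(
                f"unrelated_term_id {self.unrelated_term_id!r} must be disjoint "
                f"from the query term and its ancestors"
            )
        if self.unrelated_term_id not in ontology:
            raise GenerationError(
                f"unrelated_term_id {self.unrelated_term_id!r} not in ontology"
            )
        seen = set()
        for s in self.strata:
            if s.mirna_id in seen:
                raise GenerationError(f"duplicate stratum for {s.mirna_id!r}")
            seen.add(s.mirna_id)


def study_plan() -> PipelinePlan:
    """The study's two-round plan: Broader-Match on Leukemia at depth 1
    (the term plus its direct parent), then Exact-Match on Leukemia;
    publication support ≥ 1; zero-target miRNAs excluded each round."""
    return PipelinePlan(
        label="leukemia-two-round",
        rounds=(
            FilterRound(
                round_label="round1-broader",
                term_id=QUERY_TERM_ID,
                mode="broader",
                max_depth=1,
            ),
            FilterRound(
                round_label="round2-exact",
                term_id=QUERY_TERM_ID,
                mode="exact",
                max_depth=None,
            ),
        ),
        min_publications=1,
        exclude_zero_target_mirnas=True,
    )


class _RecordFactory:
    """Deterministic synthetic symbols/pmids with per-miRNA numbering."""

    def __init__(self) -> None:
        self._gene_n: dict[str, int] = {}
        self._pmid_n = 0
        self._db_n = 0

    def gene(self, mirna_id: str) -> str:
        n = self._gene_n.get(mirna_id, 0) + 1
        self._gene_n[mirna_id] = n
        return f"{mirna_id}-T{n}"

    def pmid(self) -> str:
        self._pmid_n += 1
        return f"SYN{self._pmid_n}"

    def source_db(self) -> str:
        db = _SOURCE_DBS[self._db_n % len(_SOURCE_DBS)]
        self._db_n += 1
        return db

    def record(
        self,
        mirna_id: str,
        evidence: str,
        term_id: str,
        gene: str | None = None,
        gene_name: str | None = None,
    ) -> TargetRecord:
        return TargetRecord(
            mirna_id=mirna_id,
            gene_symbol=gene or self.gene(mirna_id),
            gene_name=gene_name,
            evidence=evidence,
            source_db=self.source_db(),
            pmids=(self.pmid(),),
            mesh_term_ids=(term_id,),
        )


def _build_corpus(
    spec: CorpusSpec,
    named: dict[tuple[str, str], tuple[tuple[str, str], ...]],
    rng: random.Random | None,
) -> TargetCorpus:
    factory = _RecordFactory()
    records: list[TargetRecord] = []
    for s in spec.strata:
        for evidence, count in (
            ("predicted", s.exact_predicted),
            ("validated", s.exact_validated),
        ):
            names = named.get((s.mirna_id, evidence), ())
            if len(names) > count:
                raise GenerationError(
                    f"{s.mirna_id}/{evidence}: {len(names)} named genes exceed "
                    f"the exact stratum count {count}"
                )
            for gene, gene_name in names:
                records.append(
                    factory.record(
                        s.mirna_id, evidence, spec.query_term_id, gene, gene_name
                    )
                )
            for _ in range(count - len(names)):
                records.append(
                    factory.record(s.mirna_id, evidence, spec.query_term_id)
                )
        for evidence, count in (
            ("predicted", s.broader_only_predicted),
            ("validated", s.broader_only_validated),
        ):
            for _ in range(count):
                records.append(
                    factory.record(
                        s.mirna_id, evidence, spec.broader_annotation_term_id
                    )
                )
        for _ in range(s.unrelated_total):
            evidence = "predicted" if rng is None else rng.choice(
                ("predicted", "validated")
            )
            records.append(
                factory.record(s.mirna_id, evidence, spec.unrelated_term_id)
            )
    return TargetCorpus(
        records=tuple(records), roster=tuple(s.mirna_id for s in spec.strata)
    )


def study_spec() -> CorpusSpec:
    """Stratum counts implied by the published tables (exact = round-2
    survivors; broader-only = round-1 minus round-2; unrelated = total
    minus round-1)."""
    strata = []
    for mirna, total, r1p, r1v, r2p, r2v in _STUDY_COUNTS:
        if r2p > r1p or r2v > r1v or r1p + r1v > total:
            raise GenerationError(f"inconsistent published counts for {mirna!r}")
        strata.append(
            StratumCounts(
                mirna_id=mirna,
                exact_predicted=r2p,
                exact_validated=r2v,
                broader_only_predicted=r1p - r2p,
                broader_only_validated=r1v - r2v,
                unrelated_total=total - (r1p + r1v),
            )
        )
    return CorpusSpec(strata=tuple(strata), seed=0)


def study_corpus() -> TargetCorpus:
    """The deterministic 18-miRNA study corpus: 232 publication-supported
    records whose strata reproduce the published round tallies, with the
    named genes of the final survivors in the exact stratum.  Unrelated-
    stratum records are uniformly 'predicted' (the published totals do
    not split that stratum by evidence)."""
    return _build_corpus(study_spec(), _NAMED_GENES, rng=None)


def random_corpus(spec: CorpusSpec, ontology: MeshOntology) -> TargetCorpus:
    """Generate a corpus realizing *spec* exactly; identical output for
    identical spec (the seed drives only the unrelated-stratum evidence
    split)."""
    spec.validate_against(ontology)
    return _build_corpus(spec, {}, rng=random.Random(spec.seed))


def random_spec(
    seed: int, n_mirnas: int = 8, max_per_stratum: int = 6
) -> CorpusSpec:
    """Reproducible random spec over the bundled mini-ontology terms with
    stratum counts uniform on [0, max_per_stratum]."""
    if n_mirnas < 1:
        raise ValueError("n_mirnas must be at least 1")
    if max_per_stratum < 0:
        raise ValueError("max_per_stratum must be non-negative")
    rng = random.Random(seed)
    strata = tuple(
        StratumCounts(
            mirna_id=f"syn-miR-{i + 1}",
            exact_predicted=rng.randint(0, max_per_stratum),
            exact_validated=rng.randint(0, max_per_stratum),
            broader_only_predicted=rng.randint(0, max_per_stratum),
            broader_only_validated=rng.randint(0, max_per_stratum),
            unrelated_total=rng.randint(0, max_per_stratum),
        )
        for i in range(n_mirnas)
    )
    return CorpusSpec(strata=strata, seed=seed)
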