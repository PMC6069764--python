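"""Record filters and per-miRNA tallies.

Two orthogonal filters act on a corpus, both leaving the roster intact:

* :func:`support_filter` keeps records backed by a minimum number of
  distinct publications;
* :func:`mesh_filter` keeps records whose disease annotations intersect
  the query term's expansion set under a match mode.

A record "contains" a term only if the term id is listed literally in its
annotations — no subsumption inference is applied to the record side, so
a record annotated with a subtype does not survive an exact match on the
parent disease.
"""

from __future__ import annotations

from dataclasses import dataclass

from mirmesh.ontology import MatchMode, MeshOntology, expand
from mirmesh.records import TargetCorpus

__all__ = ["MirnaTally", "support_filter", "mesh_filter", "tally"]


@dataclass(frozen=True)
class MirnaTally:
    """Distinct predicted/validated target counts for one miRNA."""

    mirna_id: str
    predicted_count: int
    validated_count: int

    @property
    def total(self) -> int:
        return self.predicted_count + self.validated_count


def support_filter(corpus: TargetCorpus, min_publications: int = 1) -> TargetCorpus:
    """Retain records with at least *min_publications* distinct supporting
    publication ids; ``min_publications=0`` is the identity."""
    if min_publications < 0:
        raise ValueError("min_publications must be non-negative")
    kept = tuple(r for r in corpus.records if len(set(r.pmids)) >= min_publications)
    return TargetCorpus(records=kept, roster=corpus.roster)


def mesh_filter(
    corpus: TargetCorpus,
    ontology: MeshOntology,
    term_id: str,
    mode: MatchMode,
    max_depth: int | None = None,
) -> TargetCorpus:
    """Retain records whose annotations intersect the expansion of
    *term_id* under *mode* (records without annotations never survive)."""
    expansion = set(expand(ontology, term_id, mode, max_depth))
    kept = tuple(
        r for r in corpus.records if expansion.intersection(r.mesh_term_ids)
    )
    return TargetCorpus(records=kept, roster=corpus.roster)


def tally(corpus: TargetCorpus) -> list[MirnaTally]:
    """One tally per roster miRNA (zero-record members included), ordered
    by descending total, ties by descending validated count, then by
    miRNA id."""
    counts: dict[str, dict[str, set[str]]] = {
        m: {"predicted": set(), "validated": set()} for m in corpus.roster
    }
    for rec in corpus.records:
        counts[rec.mirna_id][rec.evidence].add(rec.gene_symbol)
    tallies = [
        MirnaTally(
            mirna_id=m,
            predicted_count=len(c["predicted"]),
            validated_count=len(c["validated"]),
        )
        for m, c in counts.items()
    ]
    tallies.sort(key=lambda t: (-t.total, -t.validated_count, t.mirna_id))
    return tallies
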