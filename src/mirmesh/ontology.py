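"""MeSH-style is_a hierarchies: loading, validation and query expansion.

A :class:`MeshOntology` is a DAG of disease terms connected by is_a
(subsumption) links.  MeSH proper is a poly-hierarchy — one descriptor may
sit under several parents — so the model is a DAG, not a tree, even though
small illustrative subtrees usually look like trees.

Query expansion follows the three classical match modes used by
ontology-backed search interfaces over annotated records:

* **exact** — the query term only;
* **broader** — the query term plus its ancestors (records annotated with
  a more general disease survive);
* **narrower** — the query term plus its descendants (records annotated
  with a subtype survive).

Broader/narrower accept an optional depth cap so that "direct parent only"
and "all ancestors" are both expressible.
"""

from __future__ import annotations

import logging
import re
from collections import deque
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx

logger = logging.getLogger(__name__)

__all__ = [
    "MatchMode",
    "LabelQueryMode",
    "MeshTerm",
    "MeshOntology",
    "OntologyStructureError",
    "UnknownTermError",
    "load_ontology",
    "parse_obo",
    "parse_edge_list",
    "write_edge_list",
    "ancestors",
    "descendants",
    "expand",
    "find_terms",
    "slugify",
]


class OntologyStructureError(ValueError):
    """The document describes a structurally invalid ontology."""


class UnknownTermError(KeyError):
    """A term identifier does not resolve in the ontology."""

    def __init__(self, term_id: str):
        super().__init__(term_id)
        self.term_id = term_id

    def __str__(self) -> str:  # KeyError quotes its arg; keep the message plain
        return f"unknown term id: {self.term_id!r}"


class MatchMode(str, Enum):
    """Expansion mode for term-based record filtering."""

    EXACT = "exact"
    BROADER = "broader"
    NARROWER = "narrower"


class LabelQueryMode(str, Enum):
    """How a free-text query is matched against term labels."""

    FROM_BEGINNING = "from_beginning"
    ANYWHERE = "anywhere"


def _normalize(text: str) -> str:
    """Case-fold and collapse runs of whitespace, for label comparison."""
    return re.sub(r"\s+", " ", text.strip()).casefold()


def slugify(label: str) -> str:
    """Deterministic identifier from a label: lowercase, punctuation
    stripped, hyphen-joined (``"Leukemia, T-Cell"`` → ``"leukemia-t-cell"``)."""
    words = re.findall(r"[a-z0-9]+", label.casefold())
    return "-".join(words)


@dataclass(frozen=True)
class MeshTerm:
    """One descriptor: an identifier, a preferred label, optional synonyms,
    and identifiers of its is_a parents (empty for roots)."""

    term_id: str
    preferred_label: str
    synonyms: tuple[str, ...] = ()
    parent_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.term_id:
            raise OntologyStructureError("term_id must be non-empty")
        if not self.preferred_label:
            raise OntologyStructureError(
                f"term {self.term_id!r} has an empty preferred label"
            )
        if self.term_id in self.parent_ids:
            raise OntologyStructureError(
                f"term {self.term_id!r} lists itself as a parent"
            )


@dataclass(frozen=True)
class MeshOntology:
    """A validated DAG of :class:`MeshTerm` keyed by identifier.

    Construction validates referential integrity (every parent resolves),
    acyclicity, and case-insensitive uniqueness of preferred labels.
    A child index is derived once so descendant traversal is O(edges).
    """

    terms: Mapping[str, MeshTerm]
    _children: Mapping[str, tuple[str, ...]] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        children: dict[str, list[str]] = {tid: [] for tid in self.terms}
        seen_labels: dict[str, str] = {}
        graph = nx.DiGraph()
        graph.add_nodes_from(self.terms)
        for term in self.terms.values():
            folded = _normalize(term.preferred_label)
            if folded in seen_labels:
                raise OntologyStructureError(
                    f"duplicate preferred label (case-insensitive): "
                    f"{term.preferred_label!r} on {seen_labels[folded]!r} "
                    f"and {term.term_id!r}"
                )
            seen_labels[folded] = term.term_id
            for pid in term.parent_ids:
                if pid not in self.terms:
                    raise OntologyStructureError(
                        f"term {term.term_id!r} references undeclared parent {pid!r}"
                    )
                children[pid].append(term.term_id)
                graph.add_edge(term.term_id, pid)  # edge: child -> parent
        try:
            cycle = nx.find_cycle(graph)
        except nx.NetworkXNoCycle:
            cycle = None
        if cycle:
            member = cycle[0][0]
            raise OntologyStructureError(
                f"is_a hierarchy contains a cycle through {member!r}"
            )
        object.__setattr__(
            self,
            "_children",
            {tid: tuple(sorted(kids)) for tid, kids in children.items()},
        )

    def __len__(self) -> int:
        return len(self.terms)

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.terms

    def __getitem__(self, term_id: str) -> MeshTerm:
        try:
            return self.terms[term_id]
        except KeyError:
            raise UnknownTermError(term_id) from None

    def parents_of(self, term_id: str) -> tuple[str, ...]:
        return tuple(sorted(self[term_id].parent_ids))

    def children_of(self, term_id: str) -> tuple[str, ...]:
        if term_id not in self.terms:
            raise UnknownTermError(term_id)
        return self._children[term_id]

    @property
    def roots(self) -> tuple[str, ...]:
        return tuple(sorted(t for t, term in self.terms.items() if not term.parent_ids))


def _build(terms: Iterable[MeshTerm]) -> MeshOntology:
    mapping: dict[str, MeshTerm] = {}
    for term in terms:
        if term.term_id in mapping:
            raise OntologyStructureError(f"duplicate term id {term.term_id!r}")
        mapping[term.term_id] = term
    return MeshOntology(terms=mapping)


# --------------------------------------------------------------------------
# Parsers
# --------------------------------------------------------------------------

_OBO_SYNONYM = re.compile(r'^"(?P<text>(?:[^"\\]|\\.)*)"')
_HANDLED_OBO_TAGS = {"id", "name", "synonym", "is_a"}


def parse_obo(text: str) -> MeshOntology:
    """Parse the OBO subset: ``[Term]`` stanzas with ``id:``, ``name:``,
    ``synonym:`` (quoted string; scope tokens ignored) and ``is_a:``
    (trailing ``! comment`` ignored).  Any other tag is skipped with a
    logged notice."""
    terms: list[MeshTerm] = []
    stanza: dict | None = None

    def flush() -> None:
        if stanza is None:
            return
        if "id" not in stanza:
            raise OntologyStructureError("[Term] stanza without an id tag")
        if "name" not in stanza:
            raise OntologyStructureError(
                f"term {stanza['id']!r} has no name tag"
            )
        terms.append(
            MeshTerm(
                term_id=stanza["id"],
                preferred_label=stanza["name"],
                synonyms=tuple(stanza.get("synonyms", ())),
                parent_ids=tuple(stanza.get("is_a", ())),
            )
        )

    in_term = False
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("["):
            flush()
            in_term = line == "[Term]"
            stanza = {} if in_term else None
            if not in_term and line != "[Term]":
                logger.info("skipping stanza %s at line %d", line, lineno)
            continue
        if not in_term or stanza is None:
            continue
        tag, _, value = line.partition(":")
        tag = tag.strip()
        value = value.strip()
        if tag not in _HANDLED_OBO_TAGS:
            logger.info("skipping OBO tag %r at line %d", tag, lineno)
            continue
        if tag == "id":
            stanza["id"] = value
        elif tag == "name":
            stanza["name"] = value
        elif tag == "synonym":
            m = _OBO_SYNONYM.match(value)
            if not m:
                raise OntologyStructureError(
                    f"malformed synonym at line {lineno}: {raw!r}"
                )
            stanza.setdefault("synonyms", []).append(
                m.group("text").replace('\\"', '"')
            )
        elif tag == "is_a":
            target = value.split("!", 1)[0].strip()
            if not target:
                raise OntologyStructureError(
                    f"empty is_a target at line {lineno}"
                )
            stanza.setdefault("is_a", []).append(target)
    flush()
    return _build(terms)


_EDGE_HEADER = ["child_id", "child_label", "parent_id"]


def parse_edge_list(text: str) -> MeshOntology:
    """Parse the edge-list dialect: header-bearing TSV with columns
    child_id, child_label, parent_id.  One row per parent link; empty
    parent_id marks a root; the first row for a child carries its label."""
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        return _build([])
    header = lines[0].split("\t")
    if header != _EDGE_HEADER:
        raise OntologyStructureError(
            f"edge-list header must be {_EDGE_HEADER}, got {header}"
        )
    labels: dict[str, str] = {}
    parents: dict[str, list[str]] = {}
    for lineno, raw in enumerate(lines[1:], start=2):
        cells = raw.split("\t")
        if len(cells) != 3:
            raise OntologyStructureError(
                f"line {lineno}: expected 3 tab-separated cells, got {len(cells)}"
            )
        child_id, child_label, parent_id = (c.strip() for c in cells)
        if not child_id:
            raise OntologyStructureError(f"line {lineno}: empty child_id")
        if child_id not in labels:
            if not child_label:
                raise OntologyStructureError(
                    f"line {lineno}: first row for {child_id!r} must carry its label"
                )
            labels[child_id] = child_label
            parents[child_id] = []
        if parent_id:
            parents[child_id].append(parent_id)
    return _build(
        MeshTerm(
            term_id=tid,
            preferred_label=labels[tid],
            parent_ids=tuple(parents[tid]),
        )
        for tid in labels
    )


def load_ontology(source: str | Path) -> MeshOntology:
    """Load an ontology from a file path or from document text.

    The dialect is auto-detected: documents containing a ``[Term]`` stanza
    are parsed as the OBO subset, anything else as the edge-list TSV.
    """
    if isinstance(source, Path):
        text = source.read_text()
    elif "\n" not in source and "\t" not in source and Path(source).is_file():
        text = Path(source).read_text()
    else:
        text = source
    if "[Term]" in text:
        return parse_obo(text)
    return parse_edge_list(text)


def write_edge_list(ontology: MeshOntology) -> str:
    """Serialize to the edge-list dialect; ``load_ontology`` inverts this
    (synonyms, which the dialect cannot carry, are dropped)."""
    lines = ["\t".join(_EDGE_HEADER)]
    for tid in sorted(ontology.terms):
        term = ontology.terms[tid]
        parents = sorted(term.parent_ids) or [""]
        first = True
        for pid in parents:
            label = term.preferred_label if first else ""
            lines.append(f"{tid}\t{label}\t{pid}")
            first = False
    return "\n".join(lines) + "\n"


# --------------------------------------------------------------------------
# Traversal and expansion
# --------------------------------------------------------------------------

def _reachable(
    start: str,
    neighbours,
    max_depth: int | None,
) -> list[str]:
    """Breadth-first reachability from *start* (excluded), capped at
    *max_depth* link steps (None = unbounded)."""
    seen: dict[str, int] = {start: 0}
    queue: deque[str] = deque([start])
    while queue:
        node = queue.popleft()
        depth = seen[node]
        if max_depth is not None and depth >= max_depth:
            continue
        for nxt in neighbours(node):
            if nxt not in seen:
                seen[nxt] = depth + 1
                queue.append(nxt)
    seen.pop(start)
    return sorted(seen)


def _check_depth(max_depth: int | None) -> None:
    if max_depth is not None and max_depth < 1:
        raise ValueError(f"max_depth must be positive or None, got {max_depth}")


def ancestors(
    ontology: MeshOntology, term_id: str, max_depth: int | None = None
) -> list[str]:
    """All terms reachable by following parent links from *term_id* within
    *max_depth* steps, excluding *term_id* itself; sorted by identifier."""
    _check_depth(max_depth)
    ontology[term_id]  # raises UnknownTermError
    return _reachable(term_id, lambda t: ontology.terms[t].parent_ids, max_depth)


def descendants(
    ontology: MeshOntology, term_id: str, max_depth: int | None = None
) -> list[str]:
    """Mirror of :func:`ancestors` over child links."""
    _check_depth(max_depth)
    ontology[term_id]
    return _reachable(term_id, ontology.children_of, max_depth)


def expand(
    ontology: MeshOntology,
    term_id: str,
    mode: MatchMode,
    max_depth: int | None = None,
) -> list[str]:
    """Expansion set for a query term under a match mode.

    exact → {term}; broader → {term} ∪ ancestors; narrower → {term} ∪
    descendants.  ``max_depth`` caps the traversal for broader/narrower
    and is ignored for exact.  Sorted by identifier.
    """
    mode = MatchMode(mode)
    ontology[term_id]
    if mode is MatchMode.EXACT:
        return [term_id]
    if mode is MatchMode.BROADER:
        related = ancestors(ontology, term_id, max_depth)
    else:
        related = descendants(ontology, term_id, max_depth)
    return sorted({term_id, *related})


def find_terms(
    ontology: MeshOntology, query: str, mode: LabelQueryMode
) -> list[MeshTerm]:
    """Resolve free text to terms by label or synonym.

    ``from_beginning`` requires the label/synonym to start with the query;
    ``anywhere`` accepts any occurrence.  Matching is case-insensitive and
    whitespace-normalized.  Results are sorted by preferred label.
    """
    mode = LabelQueryMode(mode)
    needle = _normalize(query)
    if not needle:
        raise ValueError("query must be non-empty")
    hits = []
    for term in ontology.terms.values():
        candidates = (term.preferred_label, *term.synonyms)
        if mode is LabelQueryMode.FROM_BEGINNING:
            ok = any(_normalize(c).startswith(needle) for c in candidates)
        else:
            ok = any(needle in _normalize(c) for c in candidates)
        if ok:
            hits.append(term)
    return sorted(hits, key=lambda t: t.preferred_label)
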