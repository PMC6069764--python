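"""Data model and I/O for miRNA:target evidence records.

A :class:`TargetRecord` is one assertion that a miRNA targets a gene,
either *predicted* (computational prediction database) or *validated*
(biological experiment reported in publications), annotated with zero or
more disease terms from a companion ontology.  A :class:`TargetCorpus`
bundles the records with the roster of miRNAs under study — roster
members may have no records at all, which is exactly the situation
zero-target exclusion acts on downstream.

Two interchange dialects are supported:

* **TSV** — one row per record, columns ``mirna_id, gene_symbol,
  gene_name, evidence, source_db, pmids, mesh_term_ids``; multi-valued
  cells joined with ``|``; the roster travels in a companion
  single-column TSV.
* **JSON** — one object with ``roster`` and ``records`` keys.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Literal, Sequence

from pydantic import BaseModel, ConfigDict, field_validator, model_validator

__all__ = [
    "TargetRecord",
    "TargetCorpus",
    "CorpusFormatError",
    "read_corpus",
    "write_corpus",
    "write_roster",
    "read_roster",
    "validate_against_ontology",
    "TSV_COLUMNS",
]

TSV_COLUMNS = (
    "mirna_id",
    "gene_symbol",
    "gene_name",
    "evidence",
    "source_db",
    "pmids",
    "mesh_term_ids",
)

_FORBIDDEN = ("\t", "\n", "|")


class CorpusFormatError(ValueError):
    """A corpus document is malformed or violates corpus invariants."""


class TargetRecord(BaseModel):
    """One (miRNA, gene, evidence) assertion with provenance."""

    model_config = ConfigDict(frozen=True)

    mirna_id: str
    gene_symbol: str
    gene_name: str | None = None
    evidence: Literal["predicted", "validated"]
    source_db: str = ""
    pmids: tuple[str, ...] = ()
    mesh_term_ids: tuple[str, ...] = ()

    @field_validator("mirna_id", "gene_symbol")
    @classmethod
    def _non_empty(cls, v: str) -> str:
        if not v:
            raise ValueError("must be non-empty")
        return v

    @field_validator(
        "mirna_id", "gene_symbol", "gene_name", "source_db", "pmids", "mesh_term_ids"
    )
    @classmethod
    def _serializable(cls, v):
        values = v if isinstance(v, tuple) else (v,) if v else ()
        for item in values:
            if any(ch in item for ch in _FORBIDDEN):
                raise ValueError(f"field value {item!r} contains a reserved character")
        return v

    @field_validator("pmids")
    @classmethod
    def _unique_pmids(cls, v: tuple[str, ...]) -> tuple[str, ...]:
        if len(set(v)) != len(v):
            raise ValueError("pmids must be unique")
        return v

    @property
    def triple(self) -> tuple[str, str, str]:
        return (self.mirna_id, self.gene_symbol, self.evidence)


class TargetCorpus(BaseModel):
    """An ordered record collection plus the miRNA roster under study.

    Invariants: the roster covers every miRNA appearing in the records
    (zero-record roster members are allowed) and (miRNA, gene, evidence)
    triples are unique.
    """

    model_config = ConfigDict(frozen=True)

    records: tuple[TargetRecord, ...] = ()
    roster: tuple[str, ...] = ()

    @model_validator(mode="after")
    def _invariants(self) -> "TargetCorpus":
        if len(set(self.roster)) != len(self.roster):
            raise ValueError("roster entries must be unique")
        roster = set(self.roster)
        triples = set()
        for rec in self.records:
            if rec.mirna_id not in roster:
                raise ValueError(
                    f"record miRNA {rec.mirna_id!r} missing from roster"
                )
            if rec.triple in triples:
                raise ValueError(
                    f"duplicate (miRNA, gene, evidence) triple: {rec.triple}"
                )
            triples.add(rec.triple)
        return self

    def __len__(self) -> int:
        return len(self.records)


# --------------------------------------------------------------------------
# Serialization
# --------------------------------------------------------------------------

def _cell(values: Sequence[str]) -> str:
    return "|".join(values)


def _uncell(cell: str) -> tuple[str, ...]:
    return tuple(cell.split("|")) if cell else ()


def _records_to_tsv(records: Iterable[TargetRecord]) -> str:
    lines = ["\t".join(TSV_COLUMNS)]
    for rec in records:
        lines.append(
            "\t".join(
                (
                    rec.mirna_id,
                    rec.gene_symbol,
                    rec.gene_name or "",
                    rec.evidence,
                    rec.source_db,
                    _cell(rec.pmids),
                    _cell(rec.mesh_term_ids),
                )
            )
        )
    return "\n".join(lines) + "\n"


def write_roster(corpus: TargetCorpus) -> str:
    """Companion roster document for the TSV dialect (one miRNA per line)."""
    return "\n".join(("mirna_id", *corpus.roster)) + "\n"


def read_roster(text: str) -> tuple[str, ...]:
    lines = [ln.strip() for ln in text.splitlines() if ln.strip()]
    if not lines or lines[0] != "mirna_id":
        raise CorpusFormatError("roster document must start with a 'mirna_id' header")
    return tuple(lines[1:])


def write_corpus(corpus: TargetCorpus, dialect: Literal["tsv", "json"] = "tsv") -> str:
    """Serialize a corpus; ``read_corpus`` inverts this exactly.

    The TSV dialect covers the records only — pair it with
    :func:`write_roster` to carry zero-record roster members.
    """
    if dialect == "tsv":
        return _records_to_tsv(corpus.records)
    if dialect == "json":
        payload = {
            "roster": list(corpus.roster),
            "records": [
                {
                    "mirna_id": r.mirna_id,
                    "gene_symbol": r.gene_symbol,
                    "gene_name": r.gene_name,
                    "evidence": r.evidence,
                    "source_db": r.source_db,
                    "pmids": list(r.pmids),
                    "mesh_term_ids": list(r.mesh_term_ids),
                }
                for r in corpus.records
            ],
        }
        return json.dumps(payload, indent=1) + "\n"
    raise ValueError(f"unknown dialect {dialect!r}")


def _read_tsv(text: str, roster: tuple[str, ...] | None) -> TargetCorpus:
    lines = text.splitlines()
    body = [(i + 1, ln) for i, ln in enumerate(lines) if ln.strip()]
    if not body or body[0][1].split("\t") != list(TSV_COLUMNS):
        raise CorpusFormatError(
            f"TSV corpus must start with header {list(TSV_COLUMNS)}"
        )
    records = []
    for lineno, line in body[1:]:
        cells = line.split("\t")
        if len(cells) != len(TSV_COLUMNS):
            raise CorpusFormatError(
                f"line {lineno}: expected {len(TSV_COLUMNS)} cells, got {len(cells)}"
            )
        mirna, gene, gene_name, evidence, source_db, pmids, mesh = cells
        if evidence not in ("predicted", "validated"):
            raise CorpusFormatError(
                f"line {lineno}: unknown evidence class {evidence!r}"
            )
        try:
            records.append(
                TargetRecord(
                    mirna_id=mirna,
                    gene_symbol=gene,
                    gene_name=gene_name or None,
                    evidence=evidence,
                    source_db=source_db,
                    pmids=_uncell(pmids),
                    mesh_term_ids=_uncell(mesh),
                )
            )
        except ValueError as exc:
            raise CorpusFormatError(f"line {lineno}: {exc}") from exc
    if roster is None:
        seen = []
        for rec in records:
            if rec.mirna_id not in seen:
                seen.append(rec.mirna_id)
        roster = tuple(seen)
    try:
        return TargetCorpus(records=tuple(records), roster=roster)
    except ValueError as exc:
        raise CorpusFormatError(str(exc)) from exc


def _read_json(text: str) -> TargetCorpus:
    try:
        payload = json.loads(text)
    except json.JSONDecodeError as exc:
        raise CorpusFormatError(f"invalid JSON corpus: {exc}") from exc
    if not isinstance(payload, dict) or "records" not in payload:
        raise CorpusFormatError("JSON corpus must be an object with a 'records' key")
    records = []
    for i, obj in enumerate(payload["records"]):
        try:
            records.append(
                TargetRecord(
                    mirna_id=obj["mirna_id"],
                    gene_symbol=obj["gene_symbol"],
                    gene_name=obj.get("gene_name"),
                    evidence=obj["evidence"],
                    source_db=obj.get("source_db", ""),
                    pmids=tuple(obj.get("pmids", ())),
                    mesh_term_ids=tuple(obj.get("mesh_term_ids", ())),
                )
            )
        except (KeyError, ValueError, TypeError) as exc:
            raise CorpusFormatError(f"record {i}: {exc}") from exc
    try:
        return TargetCorpus(
            records=tuple(records), roster=tuple(payload.get("roster", ()))
        )
    except ValueError as exc:
        raise CorpusFormatError(str(exc)) from exc


def read_corpus(
    source: str | Path,
    roster_source: str | Path | None = None,
) -> TargetCorpus:
    """Read a corpus from a file path or document text (dialect
    auto-detected).  For the TSV dialect an optional companion roster
    document supplies zero-record roster members; without it the roster
    defaults to the miRNAs present, in order of first appearance.
    """
    text = _load_text(source)
    if roster_source is not None:
        roster = read_roster(_load_text(roster_source))
    else:
        roster = None
    stripped = text.lstrip()
    if stripped.startswith("{"):
        corpus = _read_json(text)
        if roster is not None:
            corpus = TargetCorpus(records=corpus.records, roster=roster)
        return corpus
    return _read_tsv(text, roster)


def _load_text(source: str | Path) -> str:
    if isinstance(source, Path):
        return source.read_text()
    if "\n" not in source and "\t" not in source and Path(source).is_file():
        return Path(source).read_text()
    return source


def validate_against_ontology(corpus: TargetCorpus, ontology) -> list[str]:
    """Diagnostics (not failures) for annotation term ids that do not
    resolve in the ontology; one message per unresolvable occurrence.
    An empty list means every annotation is resolvable."""
    out = []
    for idx, rec in enumerate(corpus.records):
        for tid in rec.mesh_term_ids:
            if tid not in ontology:
                out.append(
                    f"record {idx} ({rec.mirna_id} -> {rec.gene_symbol}, "
                    f"{rec.evidence}): unresolvable term id {tid!r}"
                )
    return out
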