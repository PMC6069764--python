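"""Multi-round filter pipelines with zero-target miRNA exclusion.

A :class:`PipelinePlan` is a declarative description of a run: a
publication-support threshold applied once up front, then an ordered list
of :class:`FilterRound` term filters.  After each round, miRNAs left with
no surviving targets are removed from the working roster (the rationale:
if none of a miRNA's targets are annotated to the disease context, the
miRNA is unlikely to act in it) and recorded in the round report.

The headline statistic is the reduction in miRNA:target pairs a curator
must examine, ``100 × (1 − final/initial)``, rounded half-up to one
decimal place.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Literal

import yaml
from pydantic import BaseModel, ConfigDict, field_validator, model_validator

from mirmesh.filtering import MirnaTally, mesh_filter, support_filter, tally
from mirmesh.ontology import MatchMode, MeshOntology
from mirmesh.records import TargetCorpus, TargetRecord

__all__ = [
    "FilterRound",
    "PipelinePlan",
    "RoundReport",
    "PipelineReport",
    "PlanConfigurationError",
    "load_plan",
    "dump_plan",
    "run_pipeline",
    "reduction_percent",
    "prioritize",
    "render_report",
]


class PlanConfigurationError(ValueError):
    """The plan cannot be executed against the given ontology."""


class FilterRound(BaseModel):
    """One term filter: a query term, a match mode, and a depth cap
    (``None`` = unbounded)."""

    model_config = ConfigDict(frozen=True)

    round_label: str
    term_id: str
    mode: MatchMode
    max_depth: int | None = None

    @field_validator("round_label", "term_id")
    @classmethod
    def _non_empty(cls, v: str) -> str:
        if not v:
            raise ValueError("must be non-empty")
        return v

    @field_validator("max_depth")
    @classmethod
    def _positive(cls, v: int | None) -> int | None:
        if v is not None and v < 1:
            raise ValueError("max_depth must be positive or null")
        return v


class PipelinePlan(BaseModel):
    """An ordered list of rounds plus global settings."""

    model_config = ConfigDict(frozen=True)

    label: str = "plan"
    rounds: tuple[FilterRound, ...]
    min_publications: int = 1
    exclude_zero_target_mirnas: bool = True

    @model_validator(mode="after")
    def _check(self) -> "PipelinePlan":
        if not self.rounds:
            raise ValueError("plan must contain at least one round")
        labels = [r.round_label for r in self.rounds]
        if len(set(labels)) != len(labels):
            raise ValueError("round labels must be unique")
        if self.min_publications < 0:
            raise ValueError("min_publications must be non-negative")
        return self


def load_plan(source: str | Path) -> PipelinePlan:
    """Load a plan from YAML text or a file path.

    Keys: ``label`` (optional; defaults to the file stem, else "plan"),
    ``min_publications``, ``exclude_zero_target_mirnas``, ``rounds`` — a
    list of ``{label, term_id, mode, max_depth}`` where ``max_depth`` is a
    positive integer or ``"unbounded"``.
    """
    default_label = "plan"
    if isinstance(source, Path) or ("\n" not in source and Path(source).is_file()):
        path = Path(source)
        text = path.read_text()
        default_label = path.stem
    else:
        text = source
    try:
        doc = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise PlanConfigurationError(f"plan is not valid YAML: {exc}") from exc
    if not isinstance(doc, dict) or "rounds" not in doc:
        raise PlanConfigurationError("plan must be a mapping with a 'rounds' list")
    rounds = []
    for i, r in enumerate(doc["rounds"]):
        if not isinstance(r, dict):
            raise PlanConfigurationError(f"round {i} must be a mapping")
        depth = r.get("max_depth", "unbounded")
        if depth in ("unbounded", None):
            depth = None
        elif not isinstance(depth, int) or isinstance(depth, bool):
            raise PlanConfigurationError(
                f"round {i}: max_depth must be an integer or 'unbounded'"
            )
        try:
            rounds.append(
                FilterRound(
                    round_label=str(r.get("label", f"round-{i + 1}")),
                    term_id=r.get("term_id", ""),
                    mode=r.get("mode", ""),
                    max_depth=depth,
                )
            )
        except ValueError as exc:
            raise PlanConfigurationError(f"round {i}: {exc}") from exc
    try:
        return PipelinePlan(
            label=str(doc.get("label", default_label)),
            rounds=tuple(rounds),
            min_publications=doc.get("min_publications", 1),
            exclude_zero_target_mirnas=doc.get("exclude_zero_target_mirnas", True),
        )
    except ValueError as exc:
        raise PlanConfigurationError(str(exc)) from exc


def dump_plan(plan: PipelinePlan) -> str:
    """Serialize a plan to the YAML layout ``load_plan`` reads."""
    doc = {
        "label": plan.label,
        "min_publications": plan.min_publications,
        "exclude_zero_target_mirnas": plan.exclude_zero_target_mirnas,
        "rounds": [
            {
                "label": r.round_label,
                "term_id": r.term_id,
                "mode": r.mode.value,
                "max_depth": "unbounded" if r.max_depth is None else r.max_depth,
            }
            for r in plan.rounds
        ],
    }
    return yaml.safe_dump(doc, sort_keys=False)


@dataclass(frozen=True)
class RoundReport:
    round_label: str
    tallies: tuple[MirnaTally, ...]
    excluded_mirnas: tuple[str, ...]
    surviving_pairs: int


@dataclass(frozen=True)
class PipelineReport:
    plan_label: str
    initial_pairs: int
    round_reports: tuple[RoundReport, ...]
    final_pairs: int
    reduction_percent: float
    surviving_roster: tuple[str, ...]
    prioritized: tuple[tuple[str, bool], ...]


def reduction_percent(initial_pairs: int, final_pairs: int) -> float:
    """Percentage of miRNA:target pairs removed, rounded half-up to one
    decimal; 0.0 for an empty starting corpus."""
    if final_pairs > initial_pairs:
        raise ValueError(
            f"final_pairs ({final_pairs}) exceeds initial_pairs ({initial_pairs})"
        )
    if initial_pairs == 0:
        return 0.0
    frac = Decimal(100) * (1 - Decimal(final_pairs) / Decimal(initial_pairs))
    return float(frac.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def prioritize(tallies: list[MirnaTally]) -> list[tuple[str, bool]]:
    """Rank miRNAs by descending total target count (ties: descending
    validated count, then id) and flag those with both predicted and
    validated support.

    The dual-evidence flag is a heuristic convention of this package —
    it marks miRNAs whose disease-annotated targets carry both kinds of
    evidence — not a reconstruction of expert judgment.
    """
    ordered = sorted(
        tallies, key=lambda t: (-t.total, -t.validated_count, t.mirna_id)
    )
    return [
        (t.mirna_id, t.predicted_count >= 1 and t.validated_count >= 1)
        for t in ordered
    ]


def run_pipeline(
    corpus: TargetCorpus, ontology: MeshOntology, plan: PipelinePlan
) -> PipelineReport:
    """Execute a plan: support filter once, then each round in order,
    excluding zero-target miRNAs after every round when enabled.

    Deterministic for fixed inputs; every plan term is resolved before
    any filtering so a bad plan fails fast.
    """
    for rnd in plan.rounds:
        if rnd.term_id not in ontology:
            raise PlanConfigurationError(
                f"round {rnd.round_label!r}: term {rnd.term_id!r} "
                f"not present in the ontology"
            )

    working = support_filter(corpus, plan.min_publications)
    initial_pairs = len(working)
    round_reports: list[RoundReport] = []

    for rnd in plan.rounds:
        filtered = mesh_filter(
            working, ontology, rnd.term_id, rnd.mode, rnd.max_depth
        )
        tallies = tuple(tally(filtered))
        if plan.exclude_zero_target_mirnas:
            excluded = tuple(sorted(t.mirna_id for t in tallies if t.total == 0))
        else:
            excluded = ()
        survivors = tuple(t.mirna_id for t in tallies if t.mirna_id not in excluded)
        working = TargetCorpus(
            records=tuple(
                r for r in filtered.records if r.mirna_id not in excluded
            ),
            roster=survivors,
        )
        round_reports.append(
            RoundReport(
                round_label=rnd.round_label,
                tallies=tallies,
                excluded_mirnas=excluded,
                surviving_pairs=len(filtered),
            )
        )

    final_pairs = round_reports[-1].surviving_pairs
    final_tallies = [t for t in round_reports[-1].tallies if t.mirna_id in working.roster]
    return PipelineReport(
        plan_label=plan.label,
        initial_pairs=initial_pairs,
        round_reports=tuple(round_reports),
        final_pairs=final_pairs,
        reduction_percent=reduction_percent(initial_pairs, final_pairs),
        surviving_roster=working.roster,
        prioritized=tuple(prioritize(final_tallies)),
    )


# --------------------------------------------------------------------------
# Rendering
# --------------------------------------------------------------------------

def _round_table(report: RoundReport) -> str:
    lines = ["mirna_id\tpredicted\tvalidated"]
    total_p = total_v = 0
    for t in report.tallies:
        lines.append(f"{t.mirna_id}\t{t.predicted_count}\t{t.validated_count}")
        total_p += t.predicted_count
        total_v += t.validated_count
    lines.append(f"total\t{total_p}\t{total_v}")
    return "\n".join(lines) + "\n"


def _summary_rows(report: PipelineReport) -> list[tuple[str, str]]:
    rows = [("initial_pairs", str(report.initial_pairs))]
    for rr in report.round_reports:
        rows.append((f"surviving_pairs.{rr.round_label}", str(rr.surviving_pairs)))
        rows.append(
            (f"excluded_mirnas.{rr.round_label}", "|".join(rr.excluded_mirnas))
        )
    rows.append(("final_pairs", str(report.final_pairs)))
    rows.append(("reduction_percent", f"{report.reduction_percent:.1f}"))
    rows.append(("surviving_roster", "|".join(report.surviving_roster)))
    rows.append(
        (
            "prioritized_heuristic",
            "|".join(
                f"{m}:dual_evidence" if flag else m
                for m, flag in report.prioritized
            ),
        )
    )
    return rows


def render_report(
    report: PipelineReport, style: Literal["tsv", "text"] = "tsv"
) -> dict[str, str]:
    """Render a report to named documents; byte-deterministic.

    ``tsv`` yields one table per round (``<plan>.<round>.tsv``) plus
    ``<plan>.summary.tsv``; ``text`` yields a single human-readable
    document.  The prioritized list is labeled as a heuristic in both.
    """
    if style == "tsv":
        docs = {
            f"{report.plan_label}.{rr.round_label}.tsv": _round_table(rr)
            for rr in report.round_reports
        }
        summary = "\n".join(f"{k}\t{v}" for k, v in _summary_rows(report))
        docs[f"{report.plan_label}.summary.tsv"] = summary + "\n"
        return docs
    if style == "text":
        parts = [f"Pipeline report: {report.plan_label}", ""]
        for rr in report.round_reports:
            parts.append(f"Round {rr.round_label}:")
            parts.append(_round_table(rr).rstrip("\n"))
            excl = ", ".join(rr.excluded_mirnas) or "(none)"
            parts.append(f"excluded: {excl}")
            parts.append("")
        parts.append("Summary:")
        for k, v in _summary_rows(report):
            parts.append(f"  {k}: {v}")
        parts.append("")
        parts.append(
            "Note: 'prioritized_heuristic' ranks survivors by target count "
            "and flags dual (predicted+validated) evidence; it is a "
            "package heuristic, not an expert assessment."
        )
        return {f"{report.plan_label}.report.txt": "\n".join(parts) + "\n"}
    raise ValueError(f"unknown style {style!r}")
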