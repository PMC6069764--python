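# Methods

## The model

`mirmesh` operates on three objects:

1. **A disease hierarchy.** MeSH-style terms connected by is_a links. The
   model is a DAG, not a tree: real MeSH descriptors can sit under several
   parents, and nothing in the algorithms assumes single inheritance.
   Acyclicity, referential integrity (every parent declared) and
   case-insensitive uniqueness of preferred labels are enforced at load
   time, so traversal never has to defend against malformed input.
2. **A target corpus.** Each record asserts that a miRNA targets a gene,
   with an evidence class (`predicted` from a computational prediction
   database, or `validated` from experiments reported in publications),
   a source database label, supporting publication ids, and zero or more
   disease-term annotations. The corpus also carries the roster of miRNAs
   under study; roster members with no records are legal and meaningful —
   they are the first candidates zero-target exclusion removes. The
   (miRNA, gene, evidence) triple is unique within a corpus, i.e. a target
   reported by several prediction databases is one record; the same gene
   may appear once per evidence class.
3. **A filter plan.** A publication-support threshold applied once, then
   an ordered list of rounds, each a (term, match mode, depth cap) triple,
   plus a switch for zero-target exclusion.

### Query expansion

For query term *t*: exact = {*t*}; broader = {*t*} ∪ ancestors(*t*);
narrower = {*t*} ∪ descendants(*t*). Ancestors/descendants are computed by
breadth-first traversal over parent/child links; an optional `max_depth`
caps the number of link steps (a node counts as within depth *d* when its
shortest parent-path is ≤ *d*). Unbounded is the default and equals depth =
|terms|. Expansion sets are returned sorted by identifier so every
downstream artifact is deterministic.

A record survives a term filter when its annotation set intersects the
expansion set. Matching is **literal containment by identifier**: a record
annotated only with a subtype (e.g. B-cell leukemia) does not survive an
exact or broader match on the parent disease. The alternative — inferring
each record's annotations upward before matching — would make Broader-Match
retain subtype-annotated records too; the study's round-2 narrative
(miRNAs excluded because their targets related to *other* neoplasms,
i.e. annotations not literally equal to the query term) indicates the
deployed system matched literally, and that reading is adopted throughout.
Free-text term lookup (`find_terms`) is the user-facing complement: labels
and synonyms are compared case-insensitively and whitespace-normalized,
with prefix (`from_beginning`) or substring (`anywhere`) semantics.

### Pipeline semantics

The support filter (default: ≥ 1 distinct publication id, matching how the
study counted its starting targets) runs once, before round 1; its output
defines `initial_pairs`. Rounds then run strictly in order. After each
round, when exclusion is enabled, every roster miRNA with zero surviving
records is removed from the working roster and its records (necessarily
none at this point) from the working corpus; exclusions are recorded per
round. Per-miRNA tallies count distinct genes per evidence class and are
ordered by descending total, ties broken by descending validated count,
then miRNA id — a total order, so reports are byte-deterministic and
invariant under permutation of input records.

`reduction_percent = 100 × (1 − final/initial)` is rounded **half-up** to
one decimal (`decimal.Decimal`, not banker's rounding: 0.05 → 0.1), and
defined as 0.0 for an empty starting corpus. Pairs means records, i.e.
(miRNA, gene, evidence) triples, not distinct genes.

### Prioritization heuristic

Survivors are ranked by the tally order above; a miRNA is flagged
`dual_evidence` when it retains at least one predicted and one validated
target. This is a package convention for ordering follow-up work — evidence
corroborated from both directions first — and every rendered output labels
it as a heuristic. On the bundled corpus it happens to flag exactly the two
top-ranked miRNAs. One wrinkle: the stated tie-break (validated count
before id) places a (0 predicted, 1 validated) miRNA above a (1, 0) one;
ties among single-evidence survivors are ranked by that rule, full stop.

## The synthetic corpus

No target corpus was deposited with the study; what is published is
per-miRNA counts — total publication-supported targets, and
predicted/validated survivors of each round — plus the named target genes
of the five final survivors. The generator therefore works from a **count
specification**: per miRNA, five stratum counts

- `exact_predicted` / `exact_validated` — records annotated with the query
  term (round-2 survivors);
- `broader_only_predicted` / `broader_only_validated` — records annotated
  with the direct parent term only (round-1 minus round-2);
- `unrelated_total` — records annotated with a disjoint disease term
  (total minus round-1).

For the study corpus these are derived from the published tables; the
derivation is validated (no stratum may go negative) for all 18 miRNAs at
construction. Named genes fill the exact strata where the study names them;
all other gene symbols are `<miRNA>-Tn` and publication ids `SYNn`,
deliberately non-real. Source databases cycle through four fixed synthetic
labels. Every record carries exactly one publication id, so the support
filter at its default threshold is the identity on this corpus — consistent
with the study counting "targets supported by at least one publication" as
its starting 232.

Choices the published counts do not constrain, fixed once:

- **Unrelated-stratum evidence class** is `predicted` in the study corpus
  (the published totals do not split that stratum; the choice is invisible
  to every filtering result). In randomized corpora it is drawn from the
  spec's seed, so property tests cover both classes.
- **Broader-only records are annotated with the direct parent only**, never
  deeper ancestors. This makes the study replication insensitive to the
  depth cap: Broader-Match at depth 1 and unbounded give the same 74
  (the published description of round 1 mentions only the term and its
  direct parent, while the general mechanism description says all parents;
  the plan pins depth 1 and the annotation scheme makes the difference
  moot on this corpus).
- **The mini-hierarchy** is the leukemia neighbourhood the study describes
  — root *Neoplasms by Histologic Type*, then *Leukemia*, *Leukemia,
  Lymphoid*, its B-/T-cell children and the three T-cell subtypes — plus
  one disjoint disease term (*Nervous System Diseases*) to carry unrelated
  annotations. Term ids are deterministic slugs of labels
  (`leukemia-t-cell`), not real MeSH descriptor UIs, which the study never
  prints.

### What the generator does and does not emulate

The generated corpus reproduces the *filtering arithmetic* of a federated
target-database snapshot: stratum counts, evidence classes, annotation
placement, roster composition. It does not emulate realistic gene identity
overlap between miRNAs, multi-database reporting of the same target,
multi-term annotations per record, or publication counts above one. Passing
tests therefore demonstrate that the filtering machinery is correct and
that the published reduction follows from the published counts — not that
the pipeline would rank the same miRNAs on today's live databases.

## Numerical and design notes

- All returned collections are sorted (ids, labels) or carry a documented
  total order; reports render byte-identically across runs and platforms.
- Depth caps must be ≥ 1; `None` means unbounded. Exact mode ignores depth.
- Randomness: `random.Random(seed)` only, seeds stored in the objects that
  used them; generated corpora are byte-identical for identical specs.
- Problem sizes: property suites use DAGs of ≤ 12 nodes (200 cases) and
  corpora of 3–6 miRNAs with ≤ 6 records per stratum (100 cases) — large
  enough to exercise multi-parent reachability and every stratum
  combination, small enough that the whole suite runs in seconds.
- Degenerate inputs: empty ontology documents parse to an empty ontology;
  an empty corpus tallies to all-zero rows for the roster; a round whose
  term annotates no record excludes the entire roster and reports a 100.0%
  reduction; `reduction_percent(0, 0) = 0.0`.
- The CLI distinguishes "term not found" (exit 3) from "valid query, no
  matches" (exit 1); usage and configuration errors exit 2. Logs go to
  stderr only, never into report files.

## Limitations

- is_a is the only relation modeled; no part-of, no OWL semantics beyond
  subsumption transitivity, no upper-level ontology reasoning.
- Annotation matching is by identifier; two ontologies with different id
  schemes for the same labels will not interoperate without re-annotation.
- The dual-evidence prioritization is a transparent heuristic; the final
  selection of candidates for wet-lab follow-up belongs to a domain expert.
- The bundled corpus is a count-faithful reconstruction, not the original
  database snapshot; per-record fields the published counts do not
  determine (gene symbols outside the named survivors, publication ids,
  source-database assignment) are synthetic.
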