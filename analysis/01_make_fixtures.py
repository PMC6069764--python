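#!/usr/bin/env python
"""Write the study fixture files: the mini disease hierarchy, the
18-miRNA / 232-record corpus, its roster, and the two-round filter plan.

Outputs go to results/fixtures/ and are byte-identical across runs.
"""

from pathlib import Path

from mirmesh.ontology import write_edge_list
from mirmesh.pipeline import dump_plan
from mirmesh.records import write_corpus, write_roster
from mirmesh.synthetic import study_corpus, study_ontology, study_plan

OUT = Path(__file__).resolve().parent.parent / "results" / "fixtures"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    ontology = study_ontology()
    corpus = study_corpus()
    files = {
        "study_ontology.tsv": write_edge_list(ontology),
        "study_corpus.tsv": write_corpus(corpus, "tsv"),
        "study_corpus.json": write_corpus(corpus, "json"),
        "study_roster.tsv": write_roster(corpus),
        "study_plan.yaml": dump_plan(study_plan()),
    }
    for name, content in files.items():
        (OUT / name).write_text(content)
        print(f"wrote {OUT / name}")
    print(
        f"\nontology: {len(ontology)} terms; corpus: {len(corpus)} records "
        f"across {len(corpus.roster)} roster miRNAs"
    )


if __name__ == "__main__":
    main()
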