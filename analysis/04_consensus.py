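#!/usr/bin/env python
"""Vote-based consensus over the three simulated matchers: compare the
union (vote >= 1), majority (vote >= 2) and unanimous (vote = 3)
alignments against both references.

Reads results/scenario/, writes results/consensus.csv.  Higher vote
thresholds trade recall for precision.
"""

import csv
import importlib.util
from pathlib import Path

from ontomatch_eval import consensus, evaluate, normalize, read_alignment_rdf
from ontomatch_eval.reporting import format_score

ROOT = Path(__file__).resolve().parent.parent
SCENARIO = ROOT / "results" / "scenario"
OUT = ROOT / "results" / "consensus.csv"
PAIR = ("SYNTH-A", "SYNTH-B")


def _load_references():
    spec = importlib.util.spec_from_file_location(
        "evaluate_matchers", Path(__file__).parent / "02_evaluate_matchers.py"
    )
    module = importlib.util.module_from_spec(spec)
    spec.loader.exec_module(module)
    return module.load_references()


def main() -> None:
    matchers = [
        normalize(read_alignment_rdf(p), PAIR)
        for p in sorted(SCENARIO.glob("matcher_*.rdf"))
    ]
    references = _load_references()
    rows = []
    for min_votes in (1, 2, 3):
        cons = consensus(matchers, min_votes=min_votes)
        for reference in references:
            result = evaluate(cons, reference, reference.provenance)
            rows.append(
                [f"vote>={min_votes}", len(cons), reference.provenance,
                 format_score(result.precision), format_score(result.recall),
                 format_score(result.f_measure)]
            )
            print(
                f"vote>={min_votes} ({len(cons)} mappings) vs "
                f"{reference.provenance}: P={format_score(result.precision)} "
                f"R={format_score(result.recall)} "
                f"F1={format_score(result.f_measure)}"
            )
    with open(OUT, "w", newline="") as handle:
        writer = csv.writer(handle, lineterminator="\n")
        writer.writerow(
            ["consensus", "mappings", "reference", "precision", "recall", "f_measure"]
        )
        writer.writerows(rows)
    print(f"wrote {OUT}")


if __name__ == "__main__":
    main()
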