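#!/usr/bin/env python
"""Evaluate the simulated matchers against two reference alignments: the
CUI-derived silver standard and a deliberately incomplete baseline.

Reads results/scenario/ (run 01_simulate.py first), writes
results/evaluation.csv and prints the mean scores per reference.
"""

import csv
from pathlib import Path

from ontomatch_eval import (
    aggregate_means,
    build_cui_reference,
    evaluate,
    normalize,
    read_alignment_rdf,
)
from ontomatch_eval.evaluation import read_cui_table_tsv
from ontomatch_eval.reporting import format_score
from ontomatch_eval.synth import degrade_reference

SEED = 20260928
ROOT = Path(__file__).resolve().parent.parent
SCENARIO = ROOT / "results" / "scenario"
OUT = ROOT / "results" / "evaluation.csv"
PAIR = ("SYNTH-A", "SYNTH-B")


def load_references():
    cui_ref = build_cui_reference(
        read_cui_table_tsv(SCENARIO / "cui_a.tsv", PAIR[0]),
        read_cui_table_tsv(SCENARIO / "cui_b.tsv", PAIR[1]),
    )
    cui_ref.provenance = "cui-reference"
    ground_truth = normalize(read_alignment_rdf(SCENARIO / "ground_truth.rdf"), PAIR)
    baseline = degrade_reference(ground_truth, completeness=0.5, seed=SEED + 1)
    baseline.provenance = "baseline-reference"
    return [normalize(cui_ref, PAIR), baseline]


def main() -> None:
    references = load_references()
    rows, results, labels = [], [], []
    for path in sorted(SCENARIO.glob("matcher_*.rdf")):
        alignment = normalize(read_alignment_rdf(path), PAIR)
        for reference in references:
            result = evaluate(alignment, reference, reference.provenance)
            results.append(result)
            labels.append(reference.provenance)
            rows.append(
                [path.name, reference.provenance, result.tp, result.fp, result.fn,
                 format_score(result.precision), format_score(result.recall),
                 format_score(result.f_measure)]
            )
    with open(OUT, "w", newline="") as handle:
        writer = csv.writer(handle, lineterminator="\n")
        writer.writerow(
            ["alignment", "reference", "tp", "fp", "fn",
             "precision", "recall", "f_measure"]
        )
        writer.writerows(rows)
    print(f"wrote {OUT}")
    means = aggregate_means(results, labels)
    for label, row in means.iterrows():
        print(
            f"{label}: mean P={row['precision']:.2f} "
            f"R={row['recall']:.2f} F1={row['f_measure']:.2f}"
        )


if __name__ == "__main__":
    main()
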