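#!/usr/bin/env python
"""Generate the study scenario: a synthetic ontology pair with ground
truth, CUI annotations, matched top-level categories, and three
simulated matcher outputs.

Writes everything under results/scenario/ in the toolkit's TSV/RDF
dialects and prints the scenario's headline sizes.
"""

from pathlib import Path

from ontomatch_eval import (
    SyntheticConfig,
    generate_scenario,
    simulate_matchers,
    top_level_classes,
    write_alignment_rdf,
    write_scenario,
)

SEED = 20260928
OUTDIR = Path(__file__).resolve().parent.parent / "results" / "scenario"


def main() -> None:
    config = SyntheticConfig(seed=SEED)
    scenario = generate_scenario(config)
    paths = write_scenario(scenario, OUTDIR)
    for i, sim in enumerate(
        simulate_matchers(scenario, config, seed=SEED, n_matchers=3), start=1
    ):
        write_alignment_rdf(sim.alignment, OUTDIR / f"matcher_{i}.rdf")

    print(f"scenario written to {OUTDIR} ({len(paths) + 3} files)")
    print(
        f"ontology A: {len(scenario.ontology_a)} classes, "
        f"{len(top_level_classes(scenario.ontology_a))} top-level categories"
    )
    print(
        f"ontology B: {len(scenario.ontology_b)} classes, "
        f"{len(top_level_classes(scenario.ontology_b))} top-level categories"
    )
    print(f"ground truth: {len(scenario.ground_truth)} equivalence mappings")
    print(
        f"matched top-level categories: {len(scenario.top_level_mappings.pairs)}"
    )


if __name__ == "__main__":
    main()
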