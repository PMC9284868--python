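"""Published summary statistics from a real-world evaluation of three
ontology matching systems (AgreementMakerLight 2.0, FCA-Map, LogMap 2.0)
over SNOMED CT, NCIt and ORDO.

The underlying terminologies and the UMLS are license-restricted and
cannot ship with this package, but the evaluation's printed summary
numbers — alignment sizes, reference-alignment sizes and overlaps, and
the counts of mappings flagged by the top-level-hierarchy analysis — are
small public tables.  They are kept here as inputs so derived quantities
(weighted harmonic-mean overlaps, inconsistency proportions, mean
alignment sizes) can be recomputed with this package's own operations
and checked against the printed values.
"""

from __future__ import annotations

from importlib.resources import files

SYSTEMS = ("AML", "FCA-Map", "LogMap")
PAIRS = ("ORDO-SNOMEDCT", "NCIt-ORDO", "NCIt-SNOMEDCT")

#: Number of mappings per matcher alignment, whole ontologies.
ALIGNMENT_SIZES_WHOLE: dict[tuple[str, str], int] = {
    ("AML", "ORDO-SNOMEDCT"): 6_463,
    ("FCA-Map", "ORDO-SNOMEDCT"): 4_973,
    ("LogMap", "ORDO-SNOMEDCT"): 5_742,
    ("AML", "NCIt-ORDO"): 2_543,
    ("FCA-Map", "NCIt-ORDO"): 4_663,
    ("LogMap", "NCIt-ORDO"): 2_679,
    ("AML", "NCIt-SNOMEDCT"): 18_887,
    ("FCA-Map", "NCIt-SNOMEDCT"): 26_630,
    ("LogMap", "NCIt-SNOMEDCT"): 23_885,
}

#: Number of mappings per matcher alignment, extracted modules.
ALIGNMENT_SIZES_MODULE: dict[tuple[str, str], int] = {
    ("AML", "ORDO-SNOMEDCT"): 42,
    ("FCA-Map", "ORDO-SNOMEDCT"): 46,
    ("LogMap", "ORDO-SNOMEDCT"): 53,
    ("AML", "NCIt-ORDO"): 36,
    ("FCA-Map", "NCIt-ORDO"): 47,
    ("LogMap", "NCIt-ORDO"): 31,
    ("AML", "NCIt-SNOMEDCT"): 193,
    ("FCA-Map", "NCIt-SNOMEDCT"): 220,
    ("LogMap", "NCIt-SNOMEDCT"): 214,
}

#: Reference-alignment sizes and their pairwise overlap:
#: (pair, scope) -> (UMLS size, BioPortal size, intersection).
REFERENCE_OVERLAPS: dict[tuple[str, str], tuple[int, int, int]] = {
    ("ORDO-SNOMEDCT", "module"): (35, 7, 3),
    ("NCIt-ORDO", "module"): (27, 18, 12),
    ("NCIt-SNOMEDCT", "module"): (127, 90, 56),
    ("ORDO-SNOMEDCT", "whole"): (3_861, 1_750, 776),
    ("NCIt-ORDO", "whole"): (1_484, 1_450, 656),
    ("NCIt-SNOMEDCT", "whole"): (19_309, 16_290, 10_195),
}

#: Hierarchy analysis, whole ontologies:
#: (system, pair) -> (inconsistent mappings, of which false positive).
INCONSISTENT_COUNTS_WHOLE: dict[tuple[str, str], tuple[int, int]] = {
    ("AML", "ORDO-SNOMEDCT"): (494, 318),
    ("FCA-Map", "ORDO-SNOMEDCT"): (489, 310),
    ("LogMap", "ORDO-SNOMEDCT"): (193, 106),
    ("AML", "NCIt-SNOMEDCT"): (3_055, 252),
    ("FCA-Map", "NCIt-SNOMEDCT"): (6_868, 3_299),
    ("LogMap", "NCIt-SNOMEDCT"): (3_790, 1_180),
    ("AML", "NCIt-ORDO"): (127, 102),
    ("FCA-Map", "NCIt-ORDO"): (1_229, 1_170),
    ("LogMap", "NCIt-ORDO"): (130, 92),
}

#: The printed whole-ontology inconsistency percentages, in the same
#: row order as ``INCONSISTENT_COUNTS_WHOLE`` (the study averages these
#: nine values when reporting how often matched classes share a matched
#: top-level category).
PRINTED_INCONSISTENT_PERCENTAGES_WHOLE: tuple[int, ...] = (
    8, 10, 3, 16, 26, 16, 5, 3, 5,
)

_TOP_LEVEL_TABLES = {
    "ORDO-SNOMEDCT": "top_level_ordo_snomedct.tsv",
    "NCIt-ORDO": "top_level_ncit_ordo.tsv",
    "NCIt-SNOMEDCT": "top_level_ncit_snomedct.tsv",
}


def curated_top_level_table(pair: str) -> str:
    """Path of the packaged manually curated top-level mapping table for
    one ontology pair (TSV, columns iri_a / iri_b)."""
    if pair not in _TOP_LEVEL_TABLES:
        raise KeyError(f"no curated table for {pair!r}; choose from {PAIRS}")
    return str(files("ontomatch_eval").joinpath("data", _TOP_LEVEL_TABLES[pair]))


#: Class counts of the ontologies and their extracted star modules.
MODULE_CLASS_COUNTS: dict[str, tuple[int, int]] = {
    # ontology -> (classes in module, total classes)
    "ORDO": (299, 14_502),
    "SNOMEDCT": (1_408, 352_449),
    "NCIt": (1_014, 156_172),
}
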