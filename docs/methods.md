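# Methods

## Problem setting

Two biomedical ontologies *O* and *O′* describe overlapping domains.
An ontology matcher outputs an alignment: a set of mappings
m = ⟨e, e′, r⟩ with e ∈ O, e′ ∈ O′ and, in everything this package
evaluates, r = ≡ (equivalence), optionally with a confidence in [0, 1].
The package assesses such alignments two ways: against reference
alignments that are known to be incomplete, and by a reference-free
plausibility check on the top-level hierarchies of the mapped classes.

## Ontology model

An ontology is a rooted DAG of named classes connected by is-a (parent)
edges. Multiple inheritance is allowed — real clinical terminologies
use it heavily — so ancestor/descendant queries are transitive closures
over the DAG, not tree walks. Construction validates acyclicity (via
networkx cycle detection), uniqueness of the root and resolvability of
every parent. Files without a single parentless class get a synthetic
`owl:Thing` root with all parentless classes attached; this keeps the
invariant that every non-root class has at least one *top-level
ancestor* (a direct child of the root under which it falls). A
top-level class is its own top-level ancestor, so mappings between
top-level classes themselves are classifiable.

Only named-class subsumption is modeled. Object properties, equivalence
axioms within one ontology and complex class expressions are ignored:
every downstream procedure consumes only the class DAG, labels and CUI
annotations. The OWL reader handles RDF/XML with configurable synonym
and CUI annotation properties (defaults cover `skos:altLabel` and the
oboInOwl exact-synonym dialect); a TSV dialect provides diffable
fixtures and intermediate files, and the two loaders produce identical
ontologies on paired files.

## Module extraction

A module is extracted from a seed signature (a set of classes of
interest): *top* = seed ∪ descendants, *bottom* = seed ∪ ancestors,
*star* = top ∩ bottom. Seeds are optionally closed under ancestors
first, which guarantees the module spans the entire top-level hierarchy
above every seed class. The root is always retained, and retained
classes whose parents were all dropped are re-attached to it, so every
module is itself a valid rooted ontology.

This is a hierarchy-level implementation, deliberately weaker than
syntactic-locality module extraction: it makes no self-containment
guarantee over arbitrary axioms (there are none in the model), and a
true star-locality module is a fixpoint of alternating top/bottom
extraction rather than a plain intersection. For evaluating alignments
over the class DAG the intersection semantics is exactly what the
downstream steps consume.

## Reference alignments and scoring

The UMLS Metathesaurus groups equivalent classes under Concept Unique
Identifiers (CUIs). Given per-class CUI tables for both ontologies,
every class pair sharing at least one CUI becomes a reference mapping;
a CUI carried by several classes on one side yields all cross pairs.
Module-level references are derived by dropping mappings whose classes
fell outside the module.

Scoring classifies on (source, target) identity — confidence is
ignored, mapping A→B equals mapping B→A after normalization — into
TP/FP/FN and computes precision, recall and F-measure. Design choices
that matter:

- **No true negatives.** No available gold standard enumerates all
  correct mappings, so specificity-style measures are undefined by
  construction.
- **Undefined ≠ 0.** An empty alignment makes precision *undefined*
  (reported as `None`/`NA`), never 0; silently scoring 0 would corrupt
  means across systems. Aggregation excludes undefined scores with a
  logged count.
- **Mean of scores, not pooled counts**, when summarizing over systems
  or ontology pairs.
- **Rounding at the reporting boundary only**: scores to two decimals,
  percentages to the nearest integer (one decimal below 1%), ties away
  from zero. Raw floats are kept internally.

Agreement between two references is the intersection size and the
size-weighted harmonic mean 2·I/(|A|+|B|), which equals the harmonic
mean of the two overlap proportions.

## Top-level-hierarchy consistency filter

Lexical matchers map classes with similar labels even when one is, say,
an anatomic structure and the other a disorder. Given a manually
curated table of matched top-level classes for an ontology pair, a
mapping is *consistent* iff some pair of its classes' top-level
ancestors is in the table. Under multiple inheritance the rule is
existential on purpose: a mapping with one plausible category match is
never discarded (the conservative choice; the alternative — requiring
all ancestor pairs to match — discards defensible mappings).

Filtering removes the mappings that are inconsistent **and** not a true
positive against any supplied reference (TPs are kept even when their
hierarchies disagree — they may instead indicate reference errors, and
are reported, not removed). Consequently recall is exactly invariant
and precision is monotonically non-decreasing; both properties are
asserted in tests rather than assumed. Mappings whose classes are
missing from the ontologies go into a separate "unresolvable" bucket
instead of being silently classified.

The packaged curated tables for the ORDO-SNOMED CT, NCIt-ORDO and
NCIt-SNOMED CT pairs contain 3, 5 and 13 pairs respectively.

## Consensus alignments

Vote-based consensus keeps the (source, target) pairs proposed by at
least *k* of *n* normalized input alignments; the output confidence is
the vote fraction. Identity ignores confidence and orientation.
Consensus is anti-monotone in *k* (property-tested), with vote ≥ 1
being the union. Confidence thresholds are applied nowhere: matchers
are taken at their default output, and cardinality (1:n, n:1) is not
filtered.

## Synthetic scenarios

Real inputs (SNOMED CT, the UMLS) are license-restricted, so the
generator emulates their statistical structure; its defaults are the
study conditions, chosen once:

| parameter | default | rationale |
|---|---|---|
| categories per ontology | 19 | the top-level class count of large clinical terminologies |
| matched category fraction | 13/19 | the size of the curated table for the largest real pair |
| classes per category | 40 | desk-scale trees, depth ≤ 5 |
| shared concept fraction | 0.4 | cross-terminology overlap in the tens of percent |
| CUI coverage | 0.8 | the CUI reference is a silver standard, incomplete by nature |
| matcher recall | 0.66 | the mean recall real matchers achieved against a CUI reference |
| planted false mappings | 200 | yields realistic (low) precision at this scale |
| cross-category fraction γ | 0.5 | half the planted errors are detectable by the filter |

Each ontology is a root plus per-category random trees; a configurable
number of extra parent edges (default 5) adds multiple inheritance,
possibly across categories. Shared concepts appear once per ontology
under semantically paired categories and constitute the ground truth;
with probability `cui_coverage` a shared pair carries a common CUI, so
`cui_coverage=1` makes the CUI reference equal the ground truth.
Incomplete references are emulated by independent Bernoulli retention
(`degrade_reference`). Labels include lexical near-duplicates across
the pair (same words, different casing) but play no computational role.

The simulated matcher recovers each ground-truth mapping with
probability `matcher_recall` and plants exactly `n_false_mappings`
false pairs; γ is applied as an exact count split (round half up), not
per-mapping sampling, so filter tests are deterministic. Planted false
pairs are validated against the classes' actual top-level ancestor sets
at planting time, which makes "the filter flags exactly the
cross-category plants" an exact property, not a statistical one. All
generators are pure functions of (config, seed).

What passing synthetic tests do **not** show: the generator models
matcher errors at the error-rate level only — no string similarity, no
correlated errors between matchers beyond shared ground truth, no
systematically biased CUI omissions, and far smaller hierarchies than
real terminologies. Results on synthetic data validate the evaluation
machinery, not any claim about real matcher quality.

## Published-summary recomputation

The derived statistics of a published real-world evaluation are
recomputed, not copied: printed primary counts (alignment sizes,
reference sizes and intersections, inconsistent-mapping counts) are
treated as inputs, equivalent in-memory alignments and minimal
two-category ontologies are constructed, and the package's own
`overlap_stats` and `analyze_alignment` produce the derived overlap
percentages and inconsistency proportions. One known quirk of the
source tables: a single row prints a percentage inconsistent with its
own counts (1,229 of 4,663 shown as 3%); proportions here always come
from the counts. The average inconsistency percentage (10%, complement
90%) averages the nine printed whole-ontology percentages, matching how
the source summarizes them.

## Numerical and formatting conventions

- Deterministic ordering everywhere (sorted IRIs) so outputs are
  byte-diffable; the Alignment-format RDF writer is byte-deterministic.
- Score deltas are printed from rounded values ("+0.0X" style), so a
  reported delta is exactly the difference of the two printed scores.
- Problem sizes in the acceptance run: synthetic recovery uses ~2,000
  planted ground-truth mappings (19 categories × 385 classes, 13
  matched pairs × 154 shared concepts), enough for the exact-binomial
  99% interval around the configured recall to be a tight check.

## Known limitations

- No reasoning, no property hierarchies, no OWL profile validation;
  RDF/XML only on the OWL side.
- The hierarchy filter needs a manually curated top-level table; it
  cannot be bootstrapped automatically, and an incomplete table makes
  the filter overly aggressive on correct mappings (mitigated by the
  keep-if-TP rule).
- Semantic (near-miss-tolerant) precision/recall variants are out of
  scope; a mapping absent from a reference counts as FP even if a
  sub/superclass mapping is present.
- BioPortal/UMLS acquisition is out of scope; references enter as
  files or CUI tables.
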