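# Methods

## Evidence model

All ingested relation records are reduced to *rules*: a directed, typed
entity pair, one of two meta-relations, and up to four optional context
terms. The two meta-relations, `increase` and `decrease`, are deliberately
coarse — they subsume quantity change (transcription up), functional
activation/inhibition (signalling by phosphorylation), and phenotype
induction/suppression (triggering apoptosis, causing a disease). Relations
that cannot be signed (binding, dissociation, generic reaction) never
become rules; they are counted and logged, not guessed at.

Entity identity is case-insensitive exact string match on a normalized
name (lower-cased, whitespace collapsed) plus the entity class. No synonym
or ontology resolution is attempted: exact match is the only choice that
is fully reproducible without committing to a particular identifier
mapping, and it keeps every downstream count auditable. Gene and protein
are merged into a single class because every pairing and mapping rule in
the meta-relation scheme treats them as one. Self-loops are admitted and
flagged in reports rather than rejected.

## Vocabulary tables

Three tables drive normalization, all shipped as TSV data files so users
can extend them; the bundled defaults are the reference vocabulary.

* **Relation stems** (64 entries: 36 increase, 28 decrease). The table
  mixes full verbs (`phosphorylate`) and truncated stems (`activat`), so
  matching is prefix-based on lower-cased tokens, with the longest matching
  stem winning. Longest-match makes the result independent of table order
  and keeps long decrease stems such as `dephosphorylat` from being
  shadowed; a brute-force enumeration over all 64 stems is the test oracle
  for the matcher.
* **KEGG subtypes** (14 names): `activation, phosphorylation,
  glycosylation, methylation, expression` → increase; `inhibition,
  dephosphorylation, repression` → decrease; the remaining six
  (`indirect effect, missing interaction, binding/association,
  dissociation, reaction, ubiquitination`) are unmapped for lack of a
  functional direction. Lookup is exact and case-insensitive; unknown
  names map to unmapped with a warning.
* **Pair whitelist** (33 typed triples: 16 increase, 17 decrease) limits
  which (acting-type, target-type) pairs a literature rule may connect.
  The asymmetries are part of the vocabulary: a biological process may
  decrease a drug but not increase one, and drugs never act on
  metabolites.

## Literature extraction

Documents arrive pre-tagged (entity spans with types); named-entity
recognition itself is out of scope, and a trivial dictionary tagger is
included only for building fixtures. For every ordered pair of entity
mentions in a sentence, the text strictly between them is tokenized
(splitting on non-alphanumerics but keeping internal hyphens, so
`up-regulat` survives) and the *first* stem match becomes the relation
word. Voice is resolved by a shallow pattern — passive iff a be-form
occurs within two tokens before the match and `by` within two tokens after
— and passive voice switches the acting/target roles. Candidates failing
the pair whitelist are dropped.

The extractor is intentionally shallow: no parsing, no negation or
speculation handling, no cross-sentence relations. Shallow extraction of
this kind produces characteristic false positives — a relation word
grammatically bound to other arguments is credited to the flanking entity
pair — and two such documented error sentences are kept as regression
fixtures. In one of them the first-matching-stem policy picks the
participle `induced` where a human (and apparently the original shallow
system) would blame the later `decreases`; the spurious edge is
reproduced either way, with the polarity depending on that tie-break. The
multiple-match policy is genuinely open; first-match is the simplest
deterministic choice and is documented as such (see Limitations).

## Context annotation

Context terms (organ, cell type, disease, drug) found anywhere in a
document annotate every rule extracted from that document. Document scope
is lossy — a term in the first sentence attaches to a relation in the
last — but it is the scope at which this kind of evidence is realistically
available, and sentence-level attribution would require the syntactic
machinery this package deliberately omits. Matching requires word
boundaries on both sides (`liver` must not hit inside `deliver`);
multi-word terms match as contiguous token sequences.

Terms of different types combine AND-like into a single assignment; two or
more terms of the same type are OR-like alternatives and spawn one rule
per term (same-type contexts are rarely jointly satisfiable — there is no
"liver and stomach" organ). Expansion is therefore a Cartesian product
across types with one-of semantics within a type; the exact count law
`|output| = Σ_rules Π_type max(1, |terms|)` and round-trip projection are
property-tested. The bundled 40-term context lexicon is synthetic,
constructed for tests and examples; the full MeSH/DrugBank-derived
lexicons are not redistributed, but any lexicon in the two-column TSV
format drops in.

## Conflict judgment and context resolution

A rule group conflicts iff both polarities are present — equivalent to the
existence of a contradictory rule pair, which the tests verify against an
O(n²) pairwise oracle. Conflicts are re-judged under each of the 16
context combinations by partitioning each group on the projected context
tuple. Null fields are ordinary key values: a context-free rule does not
join every context-specific subgroup. The wildcard alternative would make
subgroups overlap and break the partition that all counting relies on;
field equality keeps the partition law (subgroup sizes sum to group size)
exact.

Because refining a combination only ever splits subgroups, a conflicting
subgroup under `C′ ⊇ C` implies a conflicting parent under `C`; the rule
mass in conflicting subgroups is therefore non-increasing along every
chain of the subset lattice. This monotonicity is asserted for all 120
comparable combination pairs on a ~10,000-rule corpus. Both a
subgroup-weighted and a rule-weighted resolution fraction are reported:
the subgroup count answers "how many distinct contradictions remain",
the rule count answers "how much evidence is still trapped in them", and
both are legitimate summaries of the same partition.

## Balance analysis

For each surviving conflict, `MRF = min(N⁺, N⁻) / (N⁺ + N⁻)` is computed
in exact rational arithmetic and converted to float only at the end. MRF
lives in (0, 0.5]; it is symmetric and scale-invariant (both
property-tested). The dominance threshold defaults to 0.25 with strict
inequality: MRF < 0.25 is *dominating*, MRF = 0.25 is *balanced*. Balance
is computed both context-free (per conflicting group) and per
fully-contextualized subgroup, and summarized as a 10-bin histogram over
(0, 0.5] plus class fractions. The threshold is configurable but 0.25 is
the conventional default: a 3:1 evidence imbalance is where manual
inspection typically starts finding extraction errors rather than dual
biology.

## Synthetic corpora

The generator plants three population parameters per corpus and records
every per-interaction draw as ground truth:

| parameter | default | meaning |
|---|---|---|
| `conflict_fraction` | 0.194 | P(interaction holds both polarities) |
| `context_resolvable_fraction` | 0.86 | P(conflict separable by full context) |
| `dominating_fraction` | 0.057 | P(conflict has MRF < 0.25) |
| `rules_per_interaction` | geometric, p = 0.31 | evidence count per consistent interaction |
| `context_vocab_sizes` | 6 per type | synthetic context vocabulary |
| `context_null_prob` | 0.3 | P(a context field is null) |

The defaults are the regime measured in large integrated
literature+database corpora (~19.4% conflicting interactions, ~86% of
conflicts context-separable, ~5.7% dominating, mean ≈ 3.2 rules per
interaction); the geometric law is the simplest one-parameter family with
the heavy tail that evidence counts show. Conflicting interactions draw
`(N⁺, N⁻)` directly in the planted MRF class (minor 1–5, total in
`[2m, 4m]` for balanced; total ≥ `4m+1` for dominating). Separable
conflicts give the two sides context tuples differing in exactly one
randomly chosen type; non-separable conflicts share one tuple. Entity
names are synthetic tokens (`gene00001`) that cannot collide with stems or
lexicon terms. All randomness flows through one `numpy` generator, so
output is byte-identical under a fixed seed.

What the generator does **not** emulate: real PubMed language (templates
only), shared entities across interactions (each interaction gets a fresh
pair, so degree structure is absent), correlated contexts, or NER noise.
Passing tests on synthetic corpora therefore demonstrate the correctness
of the conflict/resolution/balance machinery under known ground truth, not
the end-to-end accuracy of shallow extraction on real abstracts.

Templated documents ("X activates Y in liver or lung", active and passive
variants, plus distractors with no relation word) carry their exact
expected extraction output, including role switching and context
expansion. KGML fixtures are generated with a chosen subtype mix and carry
their expected mapped/skipped counts.

## Problem sizes and numerical choices

The test suite and the acceptance script run at reduced scale chosen for
statistical adequacy: 5,000 interactions (~16k–22k rules) for parameter
recovery — large enough that three binomial standard deviations on each
planted fraction are a few percent — 3,200 interactions (~10k rules) for
the lattice monotonicity check, and 100 corpora of ≤ 200 rules for oracle
equivalence. Recovery tolerances are 3 binomial SDs of the planted
proportion at the realized denominator; MRF arithmetic is exact rational,
so no floating-point tolerance is needed at the 0.25 boundary. Ties and
degenerate inputs: empty rule sets produce empty reports with a warning;
empty balance summaries report null fractions rather than NaN; unknown
subtypes and non-whitelisted pairs are dropped with counted reasons.

## Known limitations

* Exact-string entity matching fragments evidence across synonyms; conflict
  counts on real corpora are therefore conservative per entity pair.
* Document-scope context attachment over-annotates: a context term anywhere
  in an abstract attaches to every relation in it.
* The first-matching-stem policy can select a participle that precedes the
  semantically governing verb (see the second regression sentence above).
* KGML group entries are skipped, not expanded to members, and entry
  identity is the first identifier of a multi-id entry name.
* The shallow voice pattern misses marked constructions (clefts, nominal
  passives) and treats them as active.
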