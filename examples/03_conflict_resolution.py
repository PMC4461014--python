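"""Judge conflicts and resolve them across the 16 context combinations.

Generates a synthetic corpus with planted conflict structure, judges which
interactions carry both increase and decrease evidence, and re-judges each
conflict under every subset of {CT, OG, DS, DR}: rules whose contexts
differ on a projected field fall into different subgroups, so
context-separable conflicts disappear as contexts are added.
"""

from pathconflict import (
    CorpusSpec,
    build_groups,
    context_resolution_analysis,
    generate_rule_corpus,
    is_conflicting,
)

spec = CorpusSpec(n_interactions=2000, seed=11)
rules, truths = generate_rule_corpus(spec)
groups = build_groups(rules)
n_conf = sum(1 for g in groups if is_conflicting(g))

print(f"{len(rules)} rules over {len(groups)} interactions; "
      f"{n_conf} ({100 * n_conf / len(groups):.1f}%) conflict context-free")
print()
print(f"{'combination':<14}{'conflicting subgroups':>22}{'rules in conflicts':>20}")
for s in context_resolution_analysis(groups):
    print(f"{s.combination.label:<14}{s.n_conflicting_subgroups:>22}{s.n_rules_in_conflicting:>20}")
print()
print("The rule mass trapped in conflicts shrinks monotonically as context")
print("types are added; under the full combination only the planted")
print("non-separable conflicts (true contradictions sharing one context)")
print("remain.")
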