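# pathconflict

Detection, context-based resolution, and balance scoring of semantic
conflicts in integrated biological pathway evidence.

## The problem

Pathway knowledge is integrated from heterogeneous sources — manually
curated databases (e.g. KEGG) and large-scale literature mining — and the
merged evidence frequently contradicts itself: one record says protein A
*activates* gene B, another says A *represses* B. Downstream network
inference and simulation on such a merged pathway set is unreliable unless
these conflicts are found, and either resolved or flagged.

`pathconflict` is a library (with a thin CLI) for anyone building or
auditing an integrated interaction network: it normalizes heterogeneous
relation records to two signed *meta-relations*, judges conflicts, resolves
the context-dependent ones, and scores the rest.

## The model

* A **rule** is one unit of evidence
  `r = (LEFT, RIGHT, META, CT, OG, DS, DR)` — a directed, typed entity
  pair, a meta-relation `META ∈ {increase, decrease}`, and up to four
  context terms (cell type CT, organ OG, disease DS, drug DR; each may be
  null).
* An **interaction** `i` is the directed pair (LEFT, RIGHT); its **rule
  group** `R(i)` is every rule sharing that pair, split into `R(i)⁺`
  (increase) and `R(i)⁻` (decrease).
* `i` carries **conflicting information** iff `N(R(i)⁺) > 0 and
  N(R(i)⁻) > 0`.
* For a context combination `C ⊆ {CT, OG, DS, DR}` (16 cases), the **rule
  subgroup** `R(i, C)` collects rules agreeing on every field of `C`;
  conflicts are re-judged per subgroup, so contradictory rules with
  non-overlapping effect ranges ("increases B in liver" vs "decreases B in
  adipocyte") are *resolved* rather than flagged.
* Surviving conflicts are scored with the **minor rule frequency**

  `MRF = min(N(R⁺), N(R⁻)) / (N(R⁺) + N(R⁻))  ∈ (0, 0.5]`

  A conflict is **dominating** if MRF < 0.25 (one side overwhelms the
  other — candidate text-mining or curation error) and **balanced**
  otherwise (candidate dual-function biology).

Evidence enters from three directions: KGML pathway files (14 relation
subtypes, of which 5 map to increase, 3 to decrease, 6 carry no direction),
pre-tagged literature sentences (64 relation-word stems, 36 increase / 28
decrease, matched by longest prefix between entity mentions, with
passive-voice role switching and a typed pair whitelist), and flat rule
tables. A synthetic module generates all three input kinds with planted
conflict structure, so the whole pipeline is testable without downloads.

## Worked example

```python
from pathconflict import (CorpusSpec, generate_rule_corpus, build_groups,
                          context_resolution_analysis, balance_records,
                          balance_summary, is_conflicting)

rules, truth = generate_rule_corpus(CorpusSpec(n_interactions=2000, seed=11))
groups = build_groups(rules)
print(sum(is_conflicting(g) for g in groups), "conflicting of", len(groups))

for s in context_resolution_analysis(groups):
    print(s.combination.label, s.n_conflicting_subgroups, s.n_rules_in_conflicting)

s = balance_summary(balance_records(groups))
print(f"balanced {100*s.balanced_fraction:.1f}%  dominating {100*s.dominating_fraction:.1f}%")
```

prints (abridged; see `examples/03_conflict_resolution.py` and
`examples/04_balance_analysis.py` for the full scripts):

```
389 conflicting of 2000
none 389 3532
CT 295 2665
...
CT+OG+DS+DR 43 419
balanced 95.9%  dominating 4.1%
```

389 of 2000 interactions (19.4%) hold both increase and decrease evidence;
conditioning on all four context types shrinks the conflicting-subgroup
count from 389 to 43 (the planted non-separable contradictions), and the
trapped rule mass from 3,532 to 419, monotonically along the subset
lattice. Of the context-free conflicts, 95.9% are balanced — the two sides
compete closely — so wholesale elimination of one side is rarely
defensible.

The `examples/` directory holds one narrative script per capability (KGML
ingestion, literature extraction with context expansion, conflict
resolution, balance analysis). The same operations are exposed on the
command line:

```bash
pathconflict simulate --n 2000 --seed 11 --out sim/
pathconflict report --rules sim/rules.tsv --out report/
```

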