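"""Rule grouping, conflict judgment, subgrouping, and lattice monotonicity."""

import itertools

import numpy as np
import pytest

from pathconflict import (
    ALL_COMBINATIONS,
    ContextAssignment,
    ContextCombination,
    CorpusSpec,
    EntityType,
    MetaRelation,
    Rule,
    build_groups,
    conflict_count,
    context_resolution_analysis,
    generate_rule_corpus,
    is_conflicting,
    normalize_entity,
    subgroup,
)
from pathconflict.model import RuleGroup, ValidationError


def rule(left, right, meta, **ctx):
    return Rule(
        left=normalize_entity(left, EntityType.GENE_PROTEIN),
        right=normalize_entity(right, EntityType.GENE_PROTEIN),
        meta=meta,
        context=ContextAssignment(**ctx),
    )


INC, DEC = MetaRelation.INCREASE, MetaRelation.DECREASE


def brute_force_conflict_scan(rules):
    """Independent O(n^2) oracle: an interaction conflicts iff some pair of
    its rules carries opposite polarities."""
    conflicted = set()
    for a, b in itertools.combinations(rules, 2):
        if a.interaction == b.interaction and a.meta is not b.meta:
            conflicted.add(a.interaction)
    return conflicted


def test_build_groups_directed():
    rules = [rule("a", "b", INC), rule("a", "b", INC), rule("a", "b", DEC), rule("b", "a", INC)]
    groups = build_groups(rules)
    assert sorted(g.n_total for g in groups) == [1, 3]
    assert sum(g.n_total for g in groups) == len(rules)


def test_build_groups_empty():
    assert build_groups([]) == []


def test_build_groups_distinct_pair_count():
    spec = CorpusSpec(n_interactions=500, seed=3)
    rules, _ = generate_rule_corpus(spec)
    assert len(build_groups(rules)) == 500


@pytest.mark.parametrize(
    "n_inc, n_dec, expected",
    [(2, 1, True), (5, 0, False), (0, 3, False), (1, 1, True)],
)
def test_is_conflicting(n_inc, n_dec, expected):
    rules = [rule("a", "b", INC)] * n_inc + [rule("a", "b", DEC)] * n_dec
    g = RuleGroup(interaction=rules[0].interaction, rules=rules)
    assert is_conflicting(g) is expected


@pytest.mark.parametrize("n_inc, n_dec", [(2, 1), (1, 1), (10, 7)])
def test_conflict_count_is_group_size(n_inc, n_dec):
    rules = [rule("a", "b", INC)] * n_inc + [rule("a", "b", DEC)] * n_dec
    g = RuleGroup(interaction=rules[0].interaction, rules=rules)
    assert conflict_count(g) == n_inc + n_dec


def test_conflict_count_undefined_for_consistent_group():
    rules = [rule("a", "b", INC)] * 3
    g = RuleGroup(interaction=rules[0].interaction, rules=rules)
    with pytest.raises(ValidationError):
        conflict_count(g)


def test_conflict_judgment_matches_brute_force_oracle():
    for seed in range(20):
        spec = CorpusSpec(n_interactions=30, seed=seed)
        rules, _ = generate_rule_corpus(spec)
        oracle = brute_force_conflict_scan(rules)
        for g in build_groups(rules):
            assert is_conflicting(g) == (g.interaction in oracle)


def test_combination_lattice_is_complete():
    assert len(ALL_COMBINATIONS) == 16
    assert len(set(ALL_COMBINATIONS)) == 16
    assert ContextCombination.empty() in ALL_COMBINATIONS
    assert ContextCombination.full() in ALL_COMBINATIONS
    sizes = sorted(len(c) for c in ALL_COMBINATIONS)
    assert sizes == sorted([0] + [1] * 4 + [2] * 6 + [3] * 4 + [4])


def test_subgroup_partition_by_single_type():
    rules = [
        rule("a", "b", INC, og="liver"),
        rule("a", "b", DEC, og="liver"),
        rule("a", "b", INC, og="lung"),
        rule("a", "b", INC),
    ]
    g = build_groups(rules)[0]
    subs = subgroup(g, ContextCombination.of("OG"))
    assert sorted(s.n_total for s in subs) == [1, 1, 2]
    assert sum(s.n_total for s in subs) == g.n_total


def test_empty_combination_returns_whole_group():
    rules = [rule("a", "b", INC, og="liver"), rule("a", "b", DEC, og="lung")]
    g = build_groups(rules)[0]
    [only] = subgroup(g, ContextCombination.empty())
    assert only.rules == g.rules
    assert only.context_key == ()


def test_subgroup_tuple_keys_with_null_as_ordinary_value():
    rules = [
        rule("a", "b", INC, og="liver", dr="aspirin"),
        rule("a", "b", DEC, og="liver"),
        rule("a", "b", INC, og="liver", dr="aspirin"),
    ]
    g = build_groups(rules)[0]
    subs = subgroup(g, ContextCombination.of("OG", "DR"))
    assert sorted(s.n_total for s in subs) == [1, 2]
    # the null-context rule sits in its own subgroup, not in every subgroup
    keys = {s.context_key for s in subs}
    assert ("liver", None) in keys and ("liver", "aspirin") in keys


def test_resolution_analysis_empty_combo_equals_context_free():
    spec = CorpusSpec(n_interactions=200, seed=5)
    rules, _ = generate_rule_corpus(spec)
    groups = build_groups(rules)
    [summary] = context_resolution_analysis(groups, [ContextCombination.empty()])
    n_conf = sum(1 for g in groups if is_conflicting(g))
    assert summary.n_conflicting_subgroups == n_conf
    assert summary.n_subgroups == len(groups)
    assert summary.n_rules_in_conflicting == sum(
        g.n_total for g in groups if is_conflicting(g)
    )


def test_fully_separable_corpus_resolves_completely():
    spec = CorpusSpec(n_interactions=150, context_resolvable_fraction=1.0, seed=9)
    rules, truths = generate_rule_corpus(spec)
    groups = build_groups(rules)
    [summary] = context_resolution_analysis(groups, [ContextCombination.full()])
    assert summary.n_conflicting_subgroups == 0
    assert any(t.conflicting for t in truths)  # the corpus did contain conflicts


def test_rule_mass_in_conflicts_is_monotone_on_the_lattice():
    spec = CorpusSpec(n_interactions=300, seed=17)
    rules, _ = generate_rule_corpus(spec)
    groups = build_groups(rules)
    summaries = {s.combination: s for s in context_resolution_analysis(groups)}
    for c1, c2 in itertools.product(ALL_COMBINATIONS, repeat=2):
        if c1.members <= c2.members:
            assert (
                summaries[c2].n_rules_in_conflicting <= summaries[c1].n_rules_in_conflicting
            ), f"monotonicity violated between {c1.label} and {c2.label}"


def test_subgroup_conflict_implies_parent_conflict():
    spec = CorpusSpec(n_interactions=100, seed=23)
    rules, _ = generate_rule_corpus(spec)
    for g in build_groups(rules):
        for combo in ALL_COMBINATIONS:
            if any(is_conflicting(s) for s in subgroup(g, combo)):
                assert is_conflicting(g)
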