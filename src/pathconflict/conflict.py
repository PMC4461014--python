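"""Conflict judgment and context-dependent resolution.

An interaction carries *conflicting information* when its rule group holds
both increase and decrease rules.  Conflicts are then re-judged under each
of the 16 subsets of the four context types: projecting the rules of a
group onto a context combination partitions them into subgroups of
identical projected context, and a subgroup conflicts only if both
polarities survive within it.  Two contradictory rules whose contexts
differ on a projected field land in different subgroups — their conflict is
*resolved* by that combination.

Null context fields are ordinary key values: a context-free rule does not
join every context-specific subgroup.  The alternative (null as wildcard)
would make subgroups overlap and break the partition the counting relies
on.

Resolution is monotone along the subset lattice: refining the combination
can only split subgroups, so the rule mass sitting in conflicting subgroups
never grows as contexts are added.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations as _combinations
from typing import Iterable, Sequence

from .model import Interaction, MetaRelation, Rule, RuleGroup, ValidationError

__all__ = [
    "ContextCombination",
    "ALL_COMBINATIONS",
    "RuleSubgroup",
    "CombinationSummary",
    "build_groups",
    "is_conflicting",
    "conflict_count",
    "subgroup",
    "context_resolution_analysis",
]

_TYPES = ("CT", "OG", "DS", "DR")


@dataclass(frozen=True)
class ContextCombination:
    """A subset of {CT, OG, DS, DR}; 16 values including the empty set."""

    members: frozenset[str]

    def __post_init__(self) -> None:
        bad = self.members - set(_TYPES)
        if bad:
            raise ValidationError(f"unknown context types {sorted(bad)}")

    @classmethod
    def of(cls, *types: str) -> "ContextCombination":
        return cls(frozenset(t.upper() for t in types))

    @classmethod
    def full(cls) -> "ContextCombination":
        return cls(frozenset(_TYPES))

    @classmethod
    def empty(cls) -> "ContextCombination":
        return cls(frozenset())

    @classmethod
    def all_combinations(cls) -> list["ContextCombination"]:
        """All 16 combinations, ordered by size then canonical type order."""
        out = []
        for k in range(5):
            for subset in _combinations(_TYPES, k):
                out.append(cls(frozenset(subset)))
        return out

    @property
    def ordered(self) -> tuple[str, ...]:
        return tuple(t for t in _TYPES if t in self.members)

    @property
    def label(self) -> str:
        return "+".join(self.ordered) if self.members else "none"

    def project(self, rule: Rule) -> tuple[str | None, ...]:
        return tuple(rule.context.get(t) for t in self.ordered)

    def __le__(self, other: "ContextCombination") -> bool:
        return self.members <= other.members

    def __len__(self) -> int:
        return len(self.members)


ALL_COMBINATIONS = ContextCombination.all_combinations()


@dataclass
class RuleSubgroup:
    """Rules of one group agreeing on every projected context field."""

    interaction: Interaction
    combination: ContextCombination
    context_key: tuple[str | None, ...]
    rules: list[Rule]

    @property
    def n_increase(self) -> int:
        return sum(1 for r in self.rules if r.meta is MetaRelation.INCREASE)

    @property
    def n_decrease(self) -> int:
        return sum(1 for r in self.rules if r.meta is MetaRelation.DECREASE)

    @property
    def n_total(self) -> int:
        return len(self.rules)


def build_groups(rules: Iterable[Rule]) -> list[RuleGroup]:
    """One group per distinct directed interaction, in deterministic order."""
    by_key: dict[Interaction, list[Rule]] = {}
    for r in rules:
        by_key.setdefault(r.interaction, []).append(r)
    keys = sorted(
        by_key,
        key=lambda i: (i.left_name, i.left_etype.value, i.right_name, i.right_etype.value),
    )
    return [RuleGroup(interaction=k, rules=by_key[k]) for k in keys]


def is_conflicting(group: RuleGroup | RuleSubgroup) -> bool:
    """True iff both the increase and the decrease side are non-empty."""
    return group.n_increase > 0 and group.n_decrease > 0


def conflict_count(group: RuleGroup | RuleSubgroup) -> int:
    """Number of conflicts of a conflicting (sub)group: N+ + N-."""
    if not is_conflicting(group):
        raise ValidationError("conflict_count is defined only for conflicting groups")
    return group.n_increase + group.n_decrease


def subgroup(group: RuleGroup, combo: ContextCombination) -> list[RuleSubgroup]:
    """Partition a group's rules by exact equality of the projected context.

    Null is an ordinary key value.  The empty combination projects every
    rule to the same (empty) key, returning the whole group as one subgroup.
    Subgroup sizes always sum to the group size.
    """
    buckets: dict[tuple[str | None, ...], list[Rule]] = {}
    for r in group.rules:
        buckets.setdefault(combo.project(r), []).append(r)
    keys = sorted(buckets, key=lambda k: tuple(v if v is not None else "" for v in k))
    return [
        RuleSubgroup(interaction=group.interaction, combination=combo, context_key=k, rules=buckets[k])
        for k in keys
    ]


@dataclass(frozen=True)
class CombinationSummary:
    """Conflict tallies for one context combination over a set of groups.

    Both a subgroup-weighted and a rule-weighted resolution metric are
    reported because either may be the quantity of interest; the rule
    weighting counts the evidence mass still trapped in conflicts.
    """

    combination: ContextCombination
    n_groups: int
    n_groups_with_conflict: int
    n_subgroups: int
    n_conflicting_subgroups: int
    n_rules: int
    n_rules_in_conflicting: int

    @property
    def frac_subgroups_conflicting(self) -> float | None:
        return self.n_conflicting_subgroups / self.n_subgroups if self.n_subgroups else None

    @property
    def frac_rules_in_conflicting(self) -> float | None:
        return self.n_rules_in_conflicting / self.n_rules if self.n_rules else None

    @property
    def frac_groups_with_conflict(self) -> float | None:
        return self.n_groups_with_conflict / self.n_groups if self.n_groups else None


def context_resolution_analysis(
    groups: Sequence[RuleGroup],
    combos: Sequence[ContextCombination] | None = None,
) -> list[CombinationSummary]:
    """Re-judge conflicts under each context combination.

    For the empty combination the summary reproduces the context-free
    judgment exactly.  Adding context types never increases the number of
    rules lying in conflicting subgroups (subset-lattice monotonicity).
    """
    if combos is None:
        combos = ALL_COMBINATIONS
    n_rules = sum(g.n_total for g in groups)
    out: list[CombinationSummary] = []
    for combo in combos:
        n_sub = 0
        n_conf_sub = 0
        n_rules_conf = 0
        n_groups_conf = 0
        for g in groups:
            subs = subgroup(g, combo)
            n_sub += len(subs)
            conflicted = False
            for s in subs:
                if is_conflicting(s):
                    conflicted = True
                    n_conf_sub += 1
                    n_rules_conf += s.n_total
            if conflicted:
                n_groups_conf += 1
        out.append(
            CombinationSummary(
                combination=combo,
                n_groups=len(groups),
                n_groups_with_conflict=n_groups_conf,
                n_subgroups=n_sub,
                n_conflicting_subgroups=n_conf_sub,
                n_rules=n_rules,
                n_rules_in_conflicting=n_rules_conf,
            )
        )
    return out
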