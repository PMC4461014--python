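"""Balance analysis of conflicting rule (sub)groups.

A conflict is a competition between an increase side and a decrease side.
The minor rule frequency

    MRF = min(N+, N-) / (N+ + N-)

measures how closely the two sides compete: values near 0.5 mean evenly
matched evidence (candidate dual-function biology), very small values mean
one side dominates (candidate extraction or curation error).  A conflict is
*dominating* when MRF < 0.25 — strictly below — and *balanced* otherwise,
so the boundary value 0.25 itself is balanced.  MRF is only defined for
competitive groups (both sides non-empty) and always lies in (0, 0.5].
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable, Sequence

import numpy as np

from .conflict import ContextCombination, RuleSubgroup, is_conflicting, subgroup
from .model import Interaction, RuleGroup, ValidationError

__all__ = [
    "DOMINATING",
    "BALANCED",
    "BalanceRecord",
    "BalanceSummary",
    "mrf",
    "classify",
    "balance_record",
    "balance_records",
    "balance_summary",
]

DOMINATING = "dominating"
BALANCED = "balanced"

DEFAULT_THRESHOLD = 0.25


def mrf(n_increase: int, n_decrease: int) -> float:
    """min(N+, N-) / (N+ + N-), computed in exact rational arithmetic."""
    if n_increase < 1 or n_decrease < 1:
        raise ValidationError(
            f"MRF requires both sides non-empty; got ({n_increase}, {n_decrease})"
        )
    return float(Fraction(min(n_increase, n_decrease), n_increase + n_decrease))


def classify(mrf_value: float, threshold: float = DEFAULT_THRESHOLD) -> str:
    """``dominating`` iff strictly below the threshold; ``balanced`` otherwise."""
    if not (0.0 < mrf_value <= 0.5):
        raise ValidationError(f"MRF must lie in (0, 0.5]; got {mrf_value}")
    return DOMINATING if mrf_value < threshold else BALANCED


@dataclass(frozen=True)
class BalanceRecord:
    interaction: Interaction
    combination: ContextCombination
    context_key: tuple[str | None, ...]
    n_increase: int
    n_decrease: int
    mrf: float
    dominance: str


def balance_record(
    group: RuleGroup | RuleSubgroup,
    combination: ContextCombination | None = None,
    context_key: tuple[str | None, ...] = (),
    threshold: float = DEFAULT_THRESHOLD,
) -> BalanceRecord:
    """Score one conflicting (sub)group."""
    if not is_conflicting(group):
        raise ValidationError("balance is defined only for conflicting groups")
    if isinstance(group, RuleSubgroup):
        combination = group.combination
        context_key = group.context_key
    elif combination is None:
        combination = ContextCombination.empty()
    value = mrf(group.n_increase, group.n_decrease)
    return BalanceRecord(
        interaction=group.interaction,
        combination=combination,
        context_key=context_key,
        n_increase=group.n_increase,
        n_decrease=group.n_decrease,
        mrf=value,
        dominance=classify(value, threshold),
    )


def balance_records(
    groups: Sequence[RuleGroup],
    combination: ContextCombination | None = None,
    threshold: float = DEFAULT_THRESHOLD,
) -> list[BalanceRecord]:
    """Score every conflicting (sub)group in a corpus.

    With ``combination=None`` (or the empty combination) scoring is
    context-free, one record per conflicting group.  Otherwise each group
    is partitioned under the combination and every conflicting subgroup is
    scored — the fully-contextualized variant uses the full combination.
    """
    out: list[BalanceRecord] = []
    if combination is None or not combination.members:
        for g in groups:
            if is_conflicting(g):
                out.append(balance_record(g, threshold=threshold))
        return out
    for g in groups:
        for s in subgroup(g, combination):
            if is_conflicting(s):
                out.append(balance_record(s, threshold=threshold))
    return out


@dataclass(frozen=True)
class BalanceSummary:
    n_records: int
    bin_edges: tuple[float, ...]
    histogram: tuple[int, ...]
    dominating_fraction: float | None
    balanced_fraction: float | None


def balance_summary(
    records: Iterable[BalanceRecord],
    bins: int = 10,
    threshold: float = DEFAULT_THRESHOLD,
) -> BalanceSummary:
    """Histogram of MRF over (0, 0.5] plus dominance class fractions.

    Empty input yields an empty histogram and null fractions.
    """
    values = np.asarray([r.mrf for r in records], dtype=float)
    edges = np.linspace(0.0, 0.5, bins + 1)
    if values.size == 0:
        return BalanceSummary(
            n_records=0,
            bin_edges=tuple(edges.tolist()),
            histogram=(0,) * bins,
            dominating_fraction=None,
            balanced_fraction=None,
        )
    counts, _ = np.histogram(values, bins=edges)
    dom = float(np.mean(values < threshold))
    return BalanceSummary(
        n_records=int(values.size),
        bin_edges=tuple(edges.tolist()),
        histogram=tuple(int(c) for c in counts),
        dominating_fraction=dom,
        balanced_fraction=1.0 - dom,
    )
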