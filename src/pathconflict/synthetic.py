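"""Synthetic corpora with planted conflict structure.

Every pipeline stage can be exercised without any external download: this
module generates (a) flat rule corpora with known per-interaction ground
truth, (b) tagged documents whose expected extraction output is carried
along, and (c) well-formed KGML files with known mapped/unmapped subtype
counts.

The rule-corpus generator plants three population parameters and records
the per-interaction outcome of each draw:

* ``conflict_fraction`` — probability that an interaction's rule group
  contains both polarities;
* ``context_resolvable_fraction`` — among conflicts, the probability that
  the two sides carry different context tuples, so that conditioning on the
  full context combination separates them;
* ``dominating_fraction`` — among conflicts, the probability that the minor
  side is small enough that MRF < 0.25.

Evidence counts per interaction follow a shifted geometric distribution by
default; literature evidence counts are heavy-tailed and the geometric is
the simplest one-parameter family with the right shape.  Entity names are
synthetic tokens (``gene00001``) chosen so they can never collide with
relation stems or context lexicon terms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Iterable

import numpy as np
import yaml
from lxml import etree

from .context import CONTEXT_TYPES, ContextLexicon
from .extraction import EntitySpan, TaggedDocument, TaggedSentence
from .model import (
    ContextAssignment,
    EntityRef,
    EntityType,
    Interaction,
    MetaRelation,
    Rule,
    ValidationError,
    normalize_entity,
)

__all__ = [
    "CorpusSpec",
    "InteractionTruth",
    "generate_rule_corpus",
    "generate_tagged_documents",
    "generate_kgml",
]


@dataclass(frozen=True)
class CorpusSpec:
    """Parameters of a planted rule corpus.

    Defaults reproduce the measured regime of a large literature+database
    corpus: ~19.4% conflicting interactions, 86% of conflicts separable by
    the four contexts, 5.7% of conflicts dominating, and a mean of ~3.2
    rules per interaction.
    """

    n_interactions: int = 2000
    rules_per_interaction: tuple[str, float] = ("geometric", 0.31)
    conflict_fraction: float = 0.194
    context_resolvable_fraction: float = 0.86
    dominating_fraction: float = 0.057
    context_vocab_sizes: dict[str, int] = field(
        default_factory=lambda: {"CT": 6, "OG": 6, "DS": 6, "DR": 6}
    )
    context_null_prob: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_interactions < 0:
            raise ValidationError("n_interactions must be non-negative")
        for name in ("conflict_fraction", "context_resolvable_fraction", "dominating_fraction", "context_null_prob"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValidationError(f"{name} must lie in [0, 1]; got {v}")
        dist, param = self.rules_per_interaction
        if dist == "geometric":
            if not (0.0 < param <= 1.0):
                raise ValidationError(f"geometric p must lie in (0, 1]; got {param}")
        elif dist == "constant":
            if param < 1:
                raise ValidationError("constant rules_per_interaction must be >= 1")
            if param < 2 and self.conflict_fraction > 0:
                raise ValidationError(
                    "conflict_fraction > 0 is infeasible with fewer than 2 rules per interaction"
                )
        else:
            raise ValidationError(f"unknown rules_per_interaction distribution {dist!r}")
        for t in CONTEXT_TYPES:
            size = self.context_vocab_sizes.get(t, 0)
            if size < 2 and self.conflict_fraction * self.context_resolvable_fraction > 0:
                raise ValidationError(
                    f"context vocabulary for {t} needs >= 2 terms to plant separable conflicts"
                )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CorpusSpec":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        if "rules_per_interaction" in raw and isinstance(raw["rules_per_interaction"], (list, tuple)):
            raw["rules_per_interaction"] = tuple(raw["rules_per_interaction"])
        return cls(**raw)


@dataclass(frozen=True)
class InteractionTruth:
    """Planted ground truth for one interaction."""

    interaction: Interaction
    conflicting: bool
    separable: bool | None  # None for non-conflicting interactions
    n_increase: int
    n_decrease: int
    mrf: float | None
    dominating: bool | None


def _draw_size(rng: np.random.Generator, spec: CorpusSpec) -> int:
    dist, param = spec.rules_per_interaction
    if dist == "geometric":
        return int(rng.geometric(param))
    return int(param)


def _vocab(spec: CorpusSpec) -> dict[str, list[str]]:
    return {
        t: [f"{t.lower()}term{j:03d}" for j in range(spec.context_vocab_sizes.get(t, 0))]
        for t in CONTEXT_TYPES
    }


def _draw_context(rng: np.random.Generator, spec: CorpusSpec, vocab: dict[str, list[str]]) -> dict[str, str | None]:
    out: dict[str, str | None] = {}
    for t in CONTEXT_TYPES:
        if vocab[t] and rng.random() >= spec.context_null_prob:
            out[t] = vocab[t][int(rng.integers(0, len(vocab[t])))]
        else:
            out[t] = None
    return out


def _assignment(fields: dict[str, str | None]) -> ContextAssignment:
    return ContextAssignment(ct=fields["CT"], og=fields["OG"], ds=fields["DS"], dr=fields["DR"])


def _conflict_sizes(rng: np.random.Generator, dominating: bool) -> tuple[int, int]:
    """Draw (n_increase, n_decrease), both >= 1, with MRF strictly below
    0.25 when dominating and in [0.25, 0.5] otherwise."""
    if dominating:
        minor = int(rng.integers(1, 4))
        total = int(4 * minor + 1 + rng.integers(0, 3 * minor + 1))  # minor/total < 1/4
    else:
        minor = int(rng.integers(1, 6))
        total = int(rng.integers(2 * minor, 4 * minor + 1))  # 1/4 <= minor/total <= 1/2
    major = total - minor
    if rng.random() < 0.5:
        return minor, major
    return major, minor


def generate_rule_corpus(spec: CorpusSpec) -> tuple[list[Rule], list[InteractionTruth]]:
    """Generate a rule corpus with per-interaction planted ground truth.

    Deterministic under a fixed seed.  Conflicting interactions draw both
    polarities with the planted MRF class; separable conflicts give the two
    sides context tuples differing in exactly one (randomly chosen) type,
    non-separable conflicts share a single tuple, so conditioning on the
    full context combination resolves exactly the separable ones.
    """
    rng = np.random.default_rng(spec.seed)
    vocab = _vocab(spec)
    rules: list[Rule] = []
    truths: list[InteractionTruth] = []
    for k in range(spec.n_interactions):
        left = EntityRef(name=f"gene{2 * k:05d}", etype=EntityType.GENE_PROTEIN)
        right = EntityRef(name=f"gene{2 * k + 1:05d}", etype=EntityType.GENE_PROTEIN)
        interaction = Interaction(left.name, left.etype, right.name, right.etype)
        doc = f"sim{k:05d}"
        conflicting = bool(rng.random() < spec.conflict_fraction)
        if not conflicting:
            n = _draw_size(rng, spec)
            meta = MetaRelation.INCREASE if rng.random() < 0.5 else MetaRelation.DECREASE
            ctx = _assignment(_draw_context(rng, spec, vocab))
            for j in range(n):
                rules.append(
                    Rule(left=left, right=right, meta=meta, context=ctx,
                         source="table", doc_id=doc, sentence_id=f"r{j}")
                )
            truths.append(
                InteractionTruth(
                    interaction=interaction, conflicting=False, separable=None,
                    n_increase=n if meta is MetaRelation.INCREASE else 0,
                    n_decrease=n if meta is MetaRelation.DECREASE else 0,
                    mrf=None, dominating=None,
                )
            )
            continue

        dominating = bool(rng.random() < spec.dominating_fraction)
        separable = bool(rng.random() < spec.context_resolvable_fraction)
        n_inc, n_dec = _conflict_sizes(rng, dominating)
        base = _draw_context(rng, spec, vocab)
        if separable:
            diff_type = CONTEXT_TYPES[int(rng.integers(0, 4))]
            terms = vocab[diff_type]
            a, b = rng.choice(len(terms), size=2, replace=False)
            ctx_inc = dict(base, **{diff_type: terms[int(a)]})
            ctx_dec = dict(base, **{diff_type: terms[int(b)]})
        else:
            ctx_inc = ctx_dec = base
        j = 0
        for _ in range(n_inc):
            rules.append(
                Rule(left=left, right=right, meta=MetaRelation.INCREASE,
                     context=_assignment(ctx_inc), source="table",
                     doc_id=doc, sentence_id=f"r{j}")
            )
            j += 1
        for _ in range(n_dec):
            rules.append(
                Rule(left=left, right=right, meta=MetaRelation.DECREASE,
                     context=_assignment(ctx_dec), source="table",
                     doc_id=doc, sentence_id=f"r{j}")
            )
            j += 1
        value = float(Fraction(min(n_inc, n_dec), n_inc + n_dec))
        truths.append(
            InteractionTruth(
                interaction=interaction, conflicting=True, separable=separable,
                n_increase=n_inc, n_decrease=n_dec, mrf=value, dominating=dominating,
            )
        )
    return rules, truths


# ---------------------------------------------------------------------------
# Templated tagged documents
# ---------------------------------------------------------------------------

# stem, active form, passive participle, polarity — polarity is template
# knowledge, recorded independently of any stem table
_VERBS: list[tuple[str, str, str, MetaRelation]] = [
    ("activat", "activates", "activated", MetaRelation.INCREASE),
    ("stimulat", "stimulates", "stimulated", MetaRelation.INCREASE),
    ("increas", "increases", "increased", MetaRelation.INCREASE),
    ("induc", "induces", "induced", MetaRelation.INCREASE),
    ("up-regulat", "up-regulates", "up-regulated", MetaRelation.INCREASE),
    ("inhibit", "inhibits", "inhibited", MetaRelation.DECREASE),
    ("suppress", "suppresses", "suppressed", MetaRelation.DECREASE),
    ("reduc", "reduces", "reduced", MetaRelation.DECREASE),
]

# typed entity name prefixes; tokens never collide with stems or lexicon terms
_NAME_PREFIX = {
    EntityType.GENE_PROTEIN: "px",
    EntityType.DRUG: "dx",
    EntityType.DISEASE: "dz",
    EntityType.BIOLOGICAL_PROCESS: "bpx",
    EntityType.METABOLITE: "mx",
}

# (acting type, target type) pairs valid for both polarities
_TYPE_PAIRS: list[tuple[EntityType, EntityType]] = [
    (EntityType.GENE_PROTEIN, EntityType.GENE_PROTEIN),
    (EntityType.GENE_PROTEIN, EntityType.BIOLOGICAL_PROCESS),
    (EntityType.GENE_PROTEIN, EntityType.METABOLITE),
    (EntityType.GENE_PROTEIN, EntityType.DISEASE),
    (EntityType.DRUG, EntityType.GENE_PROTEIN),
    (EntityType.DRUG, EntityType.DISEASE),
    (EntityType.DISEASE, EntityType.GENE_PROTEIN),
    (EntityType.BIOLOGICAL_PROCESS, EntityType.DISEASE),
]

# context phrase options over the bundled synthetic lexicon
_CONTEXT_PHRASES: list[tuple[str, dict[str, set[str]]]] = [
    ("", {}),
    (" in liver", {"OG": {"liver"}}),
    (" in liver or lung", {"OG": {"liver", "lung"}}),
    (" in neutrophil", {"CT": {"neutrophil"}}),
    (" in asthma", {"DS": {"asthma"}}),
    (" under aspirin", {"DR": {"aspirin"}}),
    (" in liver under aspirin", {"OG": {"liver"}, "DR": {"aspirin"}}),
]


def _expected_expansion(base: Rule, contexts: dict[str, set[str]]) -> list[Rule]:
    per_type = []
    for t in CONTEXT_TYPES:
        terms = sorted(contexts.get(t, set()))
        per_type.append(terms if terms else [None])
    out = []
    for ct in per_type[0]:
        for og in per_type[1]:
            for ds in per_type[2]:
                for dr in per_type[3]:
                    out.append(base.with_context(ContextAssignment(ct=ct, og=og, ds=ds, dr=dr)))
    return out


def generate_tagged_documents(
    n_docs: int = 50,
    seed: int = 0,
    passive_fraction: float = 0.4,
    distractor_fraction: float = 0.1,
) -> tuple[list[TaggedDocument], list[Rule]]:
    """Templated one-sentence documents with exact expected rules.

    Templates are "<E1> <verb> <E2><context phrase>." in active voice and
    "<E1> is <participle> by <E2><context phrase>." in passive voice (the
    expected rule switches roles accordingly); a small fraction of
    distractor documents contain no relation word between the entities and
    expect no rule.  Context phrases draw on the bundled synthetic lexicon
    and the expected rules carry the full OR-expansion.
    """
    rng = np.random.default_rng(seed)
    docs: list[TaggedDocument] = []
    expected: list[Rule] = []
    for k in range(n_docs):
        doc_id = f"doc{k:04d}"
        acting_t, target_t = _TYPE_PAIRS[int(rng.integers(0, len(_TYPE_PAIRS)))]
        acting_name = f"{_NAME_PREFIX[acting_t]}{2 * k:04d}"
        target_name = f"{_NAME_PREFIX[target_t]}{2 * k + 1:04d}"
        phrase, contexts = _CONTEXT_PHRASES[int(rng.integers(0, len(_CONTEXT_PHRASES)))]
        roll = rng.random()
        if roll < distractor_fraction:
            text = f"{acting_name} binds {target_name}{phrase}."
            e1 = EntitySpan(0, len(acting_name), acting_t)
            s2 = len(acting_name) + len(" binds ")
            e2 = EntitySpan(s2, s2 + len(target_name), target_t)
            docs.append(
                TaggedDocument(doc_id, (TaggedSentence("s0", text, (e1, e2)),))
            )
            continue
        stem, active, participle, meta = _VERBS[int(rng.integers(0, len(_VERBS)))]
        passive = roll < distractor_fraction + passive_fraction * (1 - distractor_fraction)
        if passive:
            # target appears first in text; roles are switched back by voice
            text = f"{target_name} is {participle} by {acting_name}{phrase}."
            e1 = EntitySpan(0, len(target_name), target_t)
            s2 = len(target_name) + len(f" is {participle} by ")
            e2 = EntitySpan(s2, s2 + len(acting_name), acting_t)
        else:
            text = f"{acting_name} {active} {target_name}{phrase}."
            e1 = EntitySpan(0, len(acting_name), acting_t)
            s2 = len(acting_name) + 1 + len(active) + 1
            e2 = EntitySpan(s2, s2 + len(target_name), target_t)
        docs.append(TaggedDocument(doc_id, (TaggedSentence("s0", text, (e1, e2)),)))
        base = Rule(
            left=normalize_entity(acting_name, acting_t),
            right=normalize_entity(target_name, target_t),
            meta=meta,
            source="literature",
            doc_id=doc_id,
            sentence_id="s0",
        )
        expected.extend(_expected_expansion(base, contexts))
    return docs, expected


# ---------------------------------------------------------------------------
# KGML fixtures
# ---------------------------------------------------------------------------

# template knowledge of which KEGG subtypes carry a direction, independent
# of the bundled mapping table
_KGML_SUBTYPES: dict[str, MetaRelation | None] = {
    "activation": MetaRelation.INCREASE,
    "phosphorylation": MetaRelation.INCREASE,
    "glycosylation": MetaRelation.INCREASE,
    "methylation": MetaRelation.INCREASE,
    "expression": MetaRelation.INCREASE,
    "inhibition": MetaRelation.DECREASE,
    "dephosphorylation": MetaRelation.DECREASE,
    "repression": MetaRelation.DECREASE,
    "indirect effect": None,
    "missing interaction": None,
    "binding/association": None,
    "dissociation": None,
    "reaction": None,
    "ubiquitination": None,
}


def generate_kgml(
    n_entries: int = 20,
    n_relations: int = 30,
    subtype_mix: dict[str, float] | None = None,
    seed: int = 0,
    path: str | Path | None = None,
) -> tuple[str, list[Rule], int]:
    """Write a minimal valid KGML pathway with known expected output.

    Returns ``(xml_text, expected_rules, expected_skips)`` where the
    expected rules are those whose subtype carries a direction; the rest
    are skips.  ``subtype_mix`` weights the 14 subtype names (uniform by
    default).
    """
    if n_entries < 2 and n_relations > 0:
        raise ValidationError("need at least 2 entries to draw relations")
    rng = np.random.default_rng(seed)
    names = list(_KGML_SUBTYPES)
    if subtype_mix is None:
        weights = np.ones(len(names))
    else:
        unknown = set(subtype_mix) - set(names)
        if unknown:
            raise ValidationError(f"unknown subtypes in mix: {sorted(unknown)}")
        weights = np.array([subtype_mix.get(n, 0.0) for n in names], dtype=float)
    weights = weights / weights.sum()

    root = etree.Element(
        "pathway",
        name="path:syn00001",
        org="syn",
        number="00001",
        title="synthetic pathway",
    )
    kegg_ids = [f"syn:{1000 + i}" for i in range(n_entries)]
    for i in range(n_entries):
        etree.SubElement(root, "entry", id=str(i + 1), name=kegg_ids[i], type="gene")
    expected: list[Rule] = []
    skips = 0
    for _ in range(n_relations):
        i, j = rng.choice(n_entries, size=2, replace=False)
        subtype = names[int(rng.choice(len(names), p=weights))]
        rel = etree.SubElement(
            root, "relation", entry1=str(int(i) + 1), entry2=str(int(j) + 1), type="PPrel"
        )
        etree.SubElement(rel, "subtype", name=subtype, value="-->")
        meta = _KGML_SUBTYPES[subtype]
        if meta is None:
            skips += 1
        else:
            left = normalize_entity(kegg_ids[int(i)], EntityType.GENE_PROTEIN)
            right = normalize_entity(kegg_ids[int(j)], EntityType.GENE_PROTEIN)
            expected.append(
                Rule(
                    left=EntityRef(left.name, left.etype, native_id=kegg_ids[int(i)]),
                    right=EntityRef(right.name, right.etype, native_id=kegg_ids[int(j)]),
                    meta=meta,
                    source="kgml",
                )
            )
    xml = etree.tostring(root, pretty_print=True, xml_declaration=True, encoding="UTF-8").decode()
    if path is not None:
        Path(path).write_text(xml, encoding="utf-8")
    return xml, expected, skips
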