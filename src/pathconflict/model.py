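"""Domain types shared by every pipeline stage.

The evidence model is deliberately small.  A *rule* is one unit of evidence:
a directed, typed entity pair, a meta-relation (``increase`` or ``decrease``)
and up to four optional context terms (cell type, organ, disease, drug).
An *interaction* is the directed entity pair alone; all rules sharing an
interaction form a *rule group*, the unit at which conflicts are judged.

Entity matching across sources is case-insensitive exact string match on
normalized names — no synonym or ontology resolution.  Gene and protein are
collapsed into a single entity class because every pairing and mapping rule
in the meta-relation scheme treats them as one.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "MetaRelation",
    "EntityType",
    "EntityRef",
    "ContextAssignment",
    "NULL_CONTEXT",
    "Rule",
    "Interaction",
    "RuleGroup",
    "ValidationError",
    "normalize_entity",
    "read_rule_table",
    "write_rule_table",
    "RULE_TABLE_COLUMNS",
]


class ValidationError(ValueError):
    """Raised when a domain object violates its invariants."""


class MetaRelation(str, enum.Enum):
    """Coarse relation polarity subsuming quantity change, functional
    activation/inhibition and phenotype induction/suppression.

    Exactly two members; an unmappable relation never becomes a rule, so
    there is no "unknown" value.
    """

    INCREASE = "increase"
    DECREASE = "decrease"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class EntityType(str, enum.Enum):
    """The seven biomedical entity classes (gene and protein merged)."""

    GENE_PROTEIN = "gene/protein"
    CELL_TYPE = "cell type"
    DISEASE = "disease"
    ORGAN = "organ"
    METABOLITE = "metabolite"
    DRUG = "drug"
    BIOLOGICAL_PROCESS = "biological process"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


_WS = re.compile(r"\s+")

#: admissible provenance tags for a rule
RULE_SOURCES = ("kgml", "literature", "table")


def _normalize_name(raw: str) -> str:
    name = _WS.sub(" ", raw).strip().lower()
    if not name:
        raise ValidationError(f"entity name is empty after normalization: {raw!r}")
    return name


@dataclass(frozen=True)
class EntityRef:
    """A normalized, typed entity reference.

    ``name`` is lower-cased with collapsed whitespace; ``native_id`` keeps an
    optional source identifier (e.g. a KEGG id string) for provenance.
    """

    name: str
    etype: EntityType
    native_id: str | None = None

    def __post_init__(self) -> None:
        if not self.name or not self.name.strip():
            raise ValidationError("EntityRef.name must be non-empty")
        if not isinstance(self.etype, EntityType):
            object.__setattr__(self, "etype", EntityType(self.etype))

    @property
    def key(self) -> tuple[str, str]:
        return (self.name, self.etype.value)


def normalize_entity(raw_name: str, etype: EntityType | str) -> EntityRef:
    """Build an :class:`EntityRef` from a raw string.

    Lower-cases, strips, and collapses internal whitespace; the string is
    otherwise preserved byte-for-byte (unicode-transparent).  Raises
    :class:`ValidationError` on an empty or whitespace-only name.
    """
    if raw_name is None or not str(raw_name).strip():
        raise ValidationError(f"cannot normalize empty entity name: {raw_name!r}")
    return EntityRef(name=_normalize_name(str(raw_name)), etype=EntityType(etype))


@dataclass(frozen=True)
class ContextAssignment:
    """At most one term per context type; all-``None`` means context-free."""

    ct: str | None = None
    og: str | None = None
    ds: str | None = None
    dr: str | None = None

    @property
    def is_null(self) -> bool:
        return self.ct is None and self.og is None and self.ds is None and self.dr is None

    def get(self, context_type: str) -> str | None:
        return getattr(self, context_type.lower())


NULL_CONTEXT = ContextAssignment()


@dataclass(frozen=True)
class Interaction:
    """The directed (left entity, right entity) key identifying one edge.

    Directed: (A, B) != (B, A).  Keys are built from normalized refs, so two
    interactions are equal iff both normalized names and entity types agree.
    """

    left_name: str
    left_etype: EntityType
    right_name: str
    right_etype: EntityType

    @property
    def is_self_loop(self) -> bool:
        return (self.left_name, self.left_etype) == (self.right_name, self.right_etype)

    def __str__(self) -> str:
        return f"{self.left_name}[{self.left_etype.value}] -> {self.right_name}[{self.right_etype.value}]"


@dataclass(frozen=True)
class Rule:
    """One unit of evidence.

    Rules are evidence *instances*: two otherwise identical rules from
    different sentences are distinct records (dataclass equality still holds,
    but collections of rules are lists, never sets).
    """

    left: EntityRef
    right: EntityRef
    meta: MetaRelation
    context: ContextAssignment = NULL_CONTEXT
    source: str = "table"
    doc_id: str | None = None
    sentence_id: str | None = None

    def __post_init__(self) -> None:
        if not isinstance(self.meta, MetaRelation):
            object.__setattr__(self, "meta", MetaRelation(self.meta))
        if self.source not in RULE_SOURCES:
            raise ValidationError(f"unknown rule source {self.source!r}; expected one of {RULE_SOURCES}")

    @property
    def interaction(self) -> Interaction:
        return Interaction(
            left_name=self.left.name,
            left_etype=self.left.etype,
            right_name=self.right.name,
            right_etype=self.right.etype,
        )

    def with_context(self, context: ContextAssignment) -> "Rule":
        return replace(self, context=context)


@dataclass
class RuleGroup:
    """All rules sharing one directed interaction, split by polarity."""

    interaction: Interaction
    rules: list[Rule] = field(default_factory=list)

    def __post_init__(self) -> None:
        for r in self.rules:
            if r.interaction != self.interaction:
                raise ValidationError(
                    f"rule {r.interaction} does not belong to group {self.interaction}"
                )

    @property
    def n_increase(self) -> int:
        return sum(1 for r in self.rules if r.meta is MetaRelation.INCREASE)

    @property
    def n_decrease(self) -> int:
        return sum(1 for r in self.rules if r.meta is MetaRelation.DECREASE)

    @property
    def n_total(self) -> int:
        return len(self.rules)


# ---------------------------------------------------------------------------
# Flat rule table I/O
# ---------------------------------------------------------------------------

RULE_TABLE_COLUMNS = [
    "left_name",
    "left_type",
    "right_name",
    "right_type",
    "meta_relation",
    "ct",
    "og",
    "ds",
    "dr",
    "source",
    "doc_id",
    "sentence_id",
]


def write_rule_table(rules: Iterable[Rule], path: str | Path) -> None:
    """Write rules to the flat TSV interchange format.

    Empty string encodes a null context field or missing provenance.
    """
    records = [
        {
            "left_name": r.left.name,
            "left_type": r.left.etype.value,
            "right_name": r.right.name,
            "right_type": r.right.etype.value,
            "meta_relation": r.meta.value,
            "ct": r.context.ct or "",
            "og": r.context.og or "",
            "ds": r.context.ds or "",
            "dr": r.context.dr or "",
            "source": r.source,
            "doc_id": r.doc_id or "",
            "sentence_id": r.sentence_id or "",
        }
        for r in rules
    ]
    df = pd.DataFrame.from_records(records, columns=RULE_TABLE_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


def read_rule_table(path: str | Path) -> list[Rule]:
    """Read rules from the flat TSV interchange format."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = set(RULE_TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"rule table {path} missing columns: {sorted(missing)}")
    rules: list[Rule] = []
    for row in df.itertuples(index=False):
        rules.append(
            Rule(
                left=normalize_entity(row.left_name, row.left_type),
                right=normalize_entity(row.right_name, row.right_type),
                meta=MetaRelation(row.meta_relation),
                context=ContextAssignment(
                    ct=row.ct or None,
                    og=row.og or None,
                    ds=row.ds or None,
                    dr=row.dr or None,
                ),
                source=row.source or "table",
                doc_id=row.doc_id or None,
                sentence_id=row.sentence_id or None,
            )
        )
    return rules
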