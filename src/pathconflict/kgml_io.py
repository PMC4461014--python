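"""KGML (KEGG Markup Language) ingestion.

Only the subset of KGML needed for signed-relation extraction is parsed:
``entry`` id/name/type and ``relation`` entry1/entry2/type with ``subtype``
children.  Graphics, components and group expansion are ignored; relations
touching a group entry are skipped with a warning because no member
expansion rule is defined.  Directionality comes from the format itself:
entry1 acts on entry2.

KGML relations carry no context, so every emitted rule is context-free.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

from lxml import etree

from .mapping import SubtypeTable, UNMAPPED
from .model import EntityRef, EntityType, Rule, normalize_entity

__all__ = ["KgmlEntry", "KgmlRelation", "read_kgml", "kgml_to_rules"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class KgmlEntry:
    entry_id: str
    name: str  # full space-separated id list as written in the file
    etype: str  # KGML entry type: gene, compound, group, map, ...

    @property
    def native_id(self) -> str:
        """First id of the (possibly multi-id) name string."""
        return self.name.split()[0] if self.name.split() else self.name


@dataclass(frozen=True)
class KgmlRelation:
    """One typed relation record; entry1 acts on entry2.

    ``read_kgml`` emits one record per ``subtype`` child, so ``subtypes`` is
    a singleton tuple for annotated relations and empty when the relation
    element had no subtype (such records can never map and count as skips).
    """

    entry1: KgmlEntry
    entry2: KgmlEntry
    rel_type: str
    subtypes: tuple[str, ...]


def read_kgml(path: str | Path) -> list[KgmlRelation]:
    """Parse a KGML file into relation records.

    Malformed XML raises an ``lxml.etree.XMLSyntaxError`` carrying file and
    line; relations referencing undefined or group entries are skipped with
    a warning.
    """
    tree = etree.parse(str(path))
    root = tree.getroot()
    entries: dict[str, KgmlEntry] = {}
    for el in root.findall("entry"):
        entry = KgmlEntry(
            entry_id=el.get("id", ""),
            name=el.get("name", ""),
            etype=el.get("type", ""),
        )
        entries[entry.entry_id] = entry

    relations: list[KgmlRelation] = []
    for rel in root.findall("relation"):
        id1, id2 = rel.get("entry1"), rel.get("entry2")
        e1, e2 = entries.get(id1), entries.get(id2)
        if e1 is None or e2 is None:
            logger.warning("%s: relation %s->%s references undefined entry; skipped", path, id1, id2)
            continue
        if e1.etype == "group" or e2.etype == "group":
            logger.warning("%s: relation %s->%s touches a group entry; skipped", path, id1, id2)
            continue
        rel_type = rel.get("type", "")
        subtype_names = [st.get("name", "") for st in rel.findall("subtype")]
        if not subtype_names:
            relations.append(KgmlRelation(entry1=e1, entry2=e2, rel_type=rel_type, subtypes=()))
        else:
            for name in subtype_names:
                relations.append(
                    KgmlRelation(entry1=e1, entry2=e2, rel_type=rel_type, subtypes=(name,))
                )
    return relations


def kgml_to_rules(
    rels: list[KgmlRelation],
    table: SubtypeTable | None = None,
) -> tuple[list[Rule], int]:
    """Map relation records to rules; returns ``(rules, n_skipped)``.

    A record whose subtype maps to increase/decrease becomes one rule with
    all-null context; unmapped (or absent) subtypes are counted, not
    emitted.  Conservation holds: ``len(rules) + n_skipped == len(rels)``.
    """
    if table is None:
        table = SubtypeTable.default()
    rules: list[Rule] = []
    skipped = 0
    for rel in rels:
        if not rel.subtypes:
            skipped += 1
            continue
        meta = table.lookup(rel.subtypes[0])
        if meta is UNMAPPED:
            skipped += 1
            continue
        # identity is the first id of the entry name; the whole id list is
        # kept on native_id for provenance
        left = normalize_entity(rel.entry1.native_id, EntityType.GENE_PROTEIN)
        right = normalize_entity(rel.entry2.native_id, EntityType.GENE_PROTEIN)
        rules.append(
            Rule(
                left=EntityRef(name=left.name, etype=left.etype, native_id=rel.entry1.name),
                right=EntityRef(name=right.name, etype=right.etype, native_id=rel.entry2.name),
                meta=meta,
                source="kgml",
            )
        )
    return rules, skipped
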