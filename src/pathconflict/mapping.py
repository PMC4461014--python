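"""Meta-relation mapping tables.

Two vocabularies feed the pipeline and both collapse onto the same pair of
meta-relations:

* a 64-entry table of literature relation-word *stems* (36 increase,
  28 decrease), matched by longest-prefix against sentence tokens;
* the 14 KEGG relation subtype names, of which 5 map to increase, 3 to
  decrease, and 6 (e.g. ``binding/association``, ``reaction``) stay unmapped
  because they carry no functional direction.

Both ship as TSV data files so the vocabulary can be extended without code
changes; the bundled defaults are the reference vocabulary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd

from .model import MetaRelation, ValidationError

__all__ = [
    "StemTable",
    "SubtypeTable",
    "UNMAPPED",
    "match_relation_token",
    "map_kegg_subtype",
]

logger = logging.getLogger(__name__)


class _Unmapped:
    """Sentinel for KEGG subtypes without a functional direction."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:
        return "UNMAPPED"


UNMAPPED = _Unmapped()


def _data_path(name: str) -> Path:
    return Path(str(resources.files("pathconflict.data") / name))


@dataclass(frozen=True)
class StemTable:
    """Ordered stem → meta-relation entries for literature relation words.

    Matching is prefix-based: a stem matches a token when the stem is a
    prefix of the (lower-cased) token, and among multiple matching stems the
    longest wins.  Prefix semantics reproduce both the full verbs
    (``phosphorylate``) and the truncated stems (``activat``) in the
    vocabulary; longest-match keeps ``dephosphorylat`` from ever being
    shadowed by a shorter competitor.
    """

    entries: tuple[tuple[str, MetaRelation], ...]

    def __post_init__(self) -> None:
        stems = [s for s, _ in self.entries]
        if len(set(stems)) != len(stems):
            dupes = sorted({s for s in stems if stems.count(s) > 1})
            raise ValidationError(f"duplicate stems in table: {dupes}")
        for s, _ in self.entries:
            if s != s.lower():
                raise ValidationError(f"stem {s!r} is not lower-case")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "StemTable":
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
        return cls(tuple((row.stem, MetaRelation(row.meta_relation)) for row in df.itertuples(index=False)))

    @classmethod
    def default(cls) -> "StemTable":
        """The bundled 64-stem vocabulary (36 increase, 28 decrease)."""
        return cls.from_tsv(_data_path("relation_stems.tsv"))

    def count(self, meta: MetaRelation) -> int:
        return sum(1 for _, m in self.entries if m is meta)

    def __len__(self) -> int:
        return len(self.entries)

    def match(self, token: str) -> MetaRelation | None:
        token = token.lower()
        best: tuple[str, MetaRelation] | None = None
        for stem, meta in self.entries:
            if token.startswith(stem):
                if best is None or len(stem) > len(best[0]):
                    best = (stem, meta)
        return best[1] if best else None


def match_relation_token(token: str, table: StemTable) -> MetaRelation | None:
    """Longest-prefix stem lookup; ``None`` means no relation word.

    Deterministic and independent of table entry order: stems are unique, so
    the longest matching stem is unambiguous.
    """
    if not token or not token.strip():
        raise ValidationError("cannot match an empty token")
    return table.match(token)


@dataclass(frozen=True)
class SubtypeTable:
    """Exact-name map from KEGG relation subtypes to meta-relations."""

    entries: tuple[tuple[str, MetaRelation | _Unmapped], ...]

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SubtypeTable":
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
        out = []
        for row in df.itertuples(index=False):
            meta = UNMAPPED if row.meta_relation == "unmapped" else MetaRelation(row.meta_relation)
            out.append((row.subtype.lower(), meta))
        return cls(tuple(out))

    @classmethod
    def default(cls) -> "SubtypeTable":
        """The bundled 14-subtype table (5 increase, 3 decrease, 6 unmapped)."""
        return cls.from_tsv(_data_path("kegg_subtypes.tsv"))

    def __len__(self) -> int:
        return len(self.entries)

    def count_mapped(self, meta: MetaRelation) -> int:
        return sum(1 for _, m in self.entries if m is meta)

    @property
    def n_unmapped(self) -> int:
        return sum(1 for _, m in self.entries if m is UNMAPPED)

    def lookup(self, subtype: str) -> MetaRelation | _Unmapped:
        key = subtype.strip().lower()
        for name, meta in self.entries:
            if name == key:
                return meta
        logger.warning("unknown KEGG subtype %r treated as unmapped", subtype)
        return UNMAPPED


def map_kegg_subtype(subtype: str, table: SubtypeTable) -> MetaRelation | _Unmapped:
    """Case-insensitive exact lookup; unknown names return ``UNMAPPED`` and
    are logged so corpus-scale loss stays auditable."""
    return table.lookup(subtype)
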