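"""Rule extraction from pre-tagged sentences.

A sentence carries a relation when a relation word (a stem-table match) lies
strictly *between* two tagged entity mentions.  Roles are assigned by voice:
in the active form ("A increases B") the first entity acts on the second; in
the passive form ("A is increased by B") the roles are switched.  Candidate
(acting-type, target-type, meta-relation) triples must appear in the pair
whitelist or the candidate is dropped.

Named entity recognition itself is out of scope — documents arrive with
entity spans already annotated (a trivial dictionary tagger is provided for
building fixtures).  The extractor is intentionally shallow: no parsing, no
negation or speculation handling.  That shallowness is faithful to the
extraction behaviour being modelled, including its documented false
positives (see the regression tests).
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd

from .mapping import StemTable
from .model import (
    EntityType,
    MetaRelation,
    Rule,
    ValidationError,
    normalize_entity,
)

__all__ = [
    "EntitySpan",
    "TaggedSentence",
    "TaggedDocument",
    "PairWhitelist",
    "tokenize",
    "detect_voice",
    "extract_candidates",
    "dictionary_tag",
    "read_tagged_documents",
    "write_tagged_documents",
]

# words split on non-alphanumeric characters, but internal hyphens are kept
# so hyphenated stems like "up-regulat" survive tokenization
_TOKEN = re.compile(r"\w+(?:-\w+)*", re.UNICODE)

_BE_FORMS = frozenset({"is", "are", "was", "were", "be", "been", "being"})


def tokenize(text: str) -> list[tuple[str, int]]:
    """Lower-cased word tokens with their start offsets."""
    return [(m.group(0).lower(), m.start()) for m in _TOKEN.finditer(text)]


@dataclass(frozen=True)
class EntitySpan:
    """A tagged mention: 0-based half-open character offsets into the sentence."""

    start: int
    end: int
    etype: EntityType

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValidationError(f"invalid span offsets [{self.start}, {self.end})")
        if not isinstance(self.etype, EntityType):
            object.__setattr__(self, "etype", EntityType(self.etype))

    def surface(self, text: str) -> str:
        return text[self.start : self.end]


@dataclass(frozen=True)
class TaggedSentence:
    sentence_id: str
    text: str
    entities: tuple[EntitySpan, ...]

    def __post_init__(self) -> None:
        spans = sorted(self.entities, key=lambda s: s.start)
        for s in spans:
            if s.end > len(self.text):
                raise ValidationError(
                    f"span [{s.start},{s.end}) exceeds sentence of length {len(self.text)}"
                )
        for a, b in zip(spans, spans[1:]):
            if b.start < a.end:
                raise ValidationError(f"overlapping spans at {a.start} and {b.start}")
        object.__setattr__(self, "entities", tuple(spans))


@dataclass(frozen=True)
class TaggedDocument:
    doc_id: str
    sentences: tuple[TaggedSentence, ...]

    @property
    def text(self) -> str:
        return " ".join(s.text for s in self.sentences)


@dataclass(frozen=True)
class PairWhitelist:
    """Admissible (acting-type, target-type, meta-relation) triples.

    The bundled default lists 16 increase and 17 decrease pairs over
    gene/protein, drug, disease, biological process and metabolite.  The
    table is asymmetric on purpose: e.g. a biological process may *decrease*
    a drug but never increase one, and drugs never act on metabolites.
    """

    allowed: frozenset[tuple[EntityType, EntityType, MetaRelation]]

    @classmethod
    def from_tsv(cls, path: str | Path) -> "PairWhitelist":
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
        return cls(
            frozenset(
                (EntityType(r.acting_type), EntityType(r.target_type), MetaRelation(r.meta_relation))
                for r in df.itertuples(index=False)
            )
        )

    @classmethod
    def default(cls) -> "PairWhitelist":
        return cls.from_tsv(Path(str(resources.files("pathconflict.data") / "meta_relation_pairs.tsv")))

    def permits(self, acting: EntityType, target: EntityType, meta: MetaRelation) -> bool:
        return (acting, target, meta) in self.allowed

    def count(self, meta: MetaRelation) -> int:
        return sum(1 for (_, _, m) in self.allowed if m is meta)

    def __len__(self) -> int:
        return len(self.allowed)


def detect_voice(between_tokens: list[str], match_index: int) -> str:
    """Classify the matched relation token as ``"active"`` or ``"passive"``.

    Passive iff a be-form (is/are/was/were/be/been/being) occurs within the
    two tokens before the match AND "by" occurs within the two tokens after
    it.  Anything else — including reduced relatives and perfect tenses like
    "has been shown to reduce" — is treated as active.
    """
    before = between_tokens[max(0, match_index - 2) : match_index]
    after = between_tokens[match_index + 1 : match_index + 3]
    return "passive" if (_BE_FORMS & set(before)) and "by" in after else "active"


def extract_candidates(
    doc: TaggedDocument,
    stems: StemTable,
    pairs: PairWhitelist,
) -> list[Rule]:
    """Extract context-free literature rules from one tagged document.

    For every ordered pair of entity spans (first span textually before the
    second) within a sentence, the text strictly between them is tokenized
    and the *first* stem-table match becomes the relation word.  Voice
    resolves acting/target roles; candidates whose typed pair is not
    whitelisted are dropped.  Sentences are independent — no cross-sentence
    relations.
    """
    rules: list[Rule] = []
    for sent in doc.sentences:
        spans = sent.entities  # already sorted by start
        for i in range(len(spans)):
            for j in range(i + 1, len(spans)):
                e1, e2 = spans[i], spans[j]
                between = sent.text[e1.end : e2.start]
                tokens = tokenize(between)
                token_strings = [t for t, _ in tokens]
                match = None
                for idx, tok in enumerate(token_strings):
                    meta = stems.match(tok)
                    if meta is not None:
                        match = (idx, meta)
                        break
                if match is None:
                    continue
                idx, meta = match
                voice = detect_voice(token_strings, idx)
                if voice == "passive":
                    acting, target = e2, e1
                else:
                    acting, target = e1, e2
                if not pairs.permits(acting.etype, target.etype, meta):
                    continue
                rules.append(
                    Rule(
                        left=normalize_entity(acting.surface(sent.text), acting.etype),
                        right=normalize_entity(target.surface(sent.text), target.etype),
                        meta=meta,
                        source="literature",
                        doc_id=doc.doc_id,
                        sentence_id=sent.sentence_id,
                    )
                )
    return rules


# ---------------------------------------------------------------------------
# Fixture helpers: trivial dictionary tagger and JSONL I/O
# ---------------------------------------------------------------------------


def dictionary_tag(
    doc_id: str,
    sentences: Iterable[str],
    lexicon: dict[str, EntityType],
) -> TaggedDocument:
    """Tag sentences by exact (case-insensitive) lexicon match.

    Fixture-grade only: longest lexicon entries are matched first and
    overlaps with already-placed spans are skipped.  Real NER is out of scope.
    """
    entries = sorted(lexicon.items(), key=lambda kv: -len(kv[0]))
    tagged = []
    for n, text in enumerate(sentences):
        spans: list[EntitySpan] = []
        taken: list[tuple[int, int]] = []
        low = text.lower()
        for term, etype in entries:
            pattern = re.compile(
                r"(?<!\w)" + re.escape(term.lower()).replace(r"\ ", r"\s+") + r"(?!\w)"
            )
            for m in pattern.finditer(low):
                if any(m.start() < e and s < m.end() for s, e in taken):
                    continue
                taken.append((m.start(), m.end()))
                spans.append(EntitySpan(start=m.start(), end=m.end(), etype=etype))
        tagged.append(TaggedSentence(sentence_id=f"s{n}", text=text, entities=tuple(spans)))
    return TaggedDocument(doc_id=doc_id, sentences=tuple(tagged))


def write_tagged_documents(docs: Iterable[TaggedDocument], path: str | Path) -> None:
    """One JSON object per line: {doc_id, sentences:[{sentence_id, text, entities}]}"""
    with open(path, "w", encoding="utf-8") as fh:
        for doc in docs:
            obj = {
                "doc_id": doc.doc_id,
                "sentences": [
                    {
                        "sentence_id": s.sentence_id,
                        "text": s.text,
                        "entities": [
                            {"start": e.start, "end": e.end, "etype": e.etype.value}
                            for e in s.entities
                        ],
                    }
                    for s in doc.sentences
                ],
            }
            fh.write(json.dumps(obj, ensure_ascii=False) + "\n")


def read_tagged_documents(path: str | Path) -> Iterator[TaggedDocument]:
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            obj = json.loads(line)
            yield TaggedDocument(
                doc_id=obj["doc_id"],
                sentences=tuple(
                    TaggedSentence(
                        sentence_id=s["sentence_id"],
                        text=s["text"],
                        entities=tuple(
                            EntitySpan(start=e["start"], end=e["end"], etype=EntityType(e["etype"]))
                            for e in s["entities"]
                        ),
                    )
                    for s in obj["sentences"]
                ),
            )
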