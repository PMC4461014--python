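"""Document-level context annotation and OR-expansion.

Context terms (organ OG, cell type CT, disease DS, drug DR) constrain the
effect range of a rule.  A term found anywhere in a document annotates every
rule extracted from that document — document scope, not sentence scope,
which is lossy but matches how the evidence was built.

Terms of *different* types combine AND-like into one assignment ("A
increases B in liver under aspirin"); multiple terms of the *same* type are
OR-like alternatives and spawn separate rules ("A decreases B in liver or
lung" becomes two rules).  Expansion is therefore a Cartesian product across
types with one-of semantics within a type: one input rule yields
``prod_type max(1, |terms_type|)`` output rules.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd

from .extraction import TaggedDocument
from .model import ContextAssignment, Rule, ValidationError

__all__ = [
    "CONTEXT_TYPES",
    "ContextLexicon",
    "find_document_contexts",
    "expand_rules",
]

#: canonical order of the four context types
CONTEXT_TYPES = ("CT", "OG", "DS", "DR")


@dataclass(frozen=True)
class ContextLexicon:
    """term → context-type entries; a term may (rarely) carry two types."""

    entries: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        seen = set()
        for term, ctype in self.entries:
            if ctype not in CONTEXT_TYPES:
                raise ValidationError(f"unknown context type {ctype!r} for term {term!r}")
            if (term, ctype) in seen:
                raise ValidationError(f"duplicate lexicon entry ({term!r}, {ctype})")
            seen.add((term, ctype))

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ContextLexicon":
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
        return cls(tuple((row.term.lower(), row.context_type) for row in df.itertuples(index=False)))

    @classmethod
    def synthetic_fixture(cls) -> "ContextLexicon":
        """A small synthetic lexicon (40 terms, 10 per type) bundled for
        tests and examples; it is constructed, not derived from MeSH or
        DrugBank."""
        return cls.from_tsv(Path(str(resources.files("pathconflict.data") / "context_lexicon_synthetic.tsv")))

    def __len__(self) -> int:
        return len(self.entries)


def _term_pattern(term: str) -> re.Pattern:
    # whole-term match with word boundaries on both sides: "liver" must not
    # hit inside "deliver"; multi-word terms match across flexible whitespace
    parts = [re.escape(p) for p in term.split()]
    return re.compile(r"(?<!\w)" + r"\s+".join(parts) + r"(?!\w)", re.IGNORECASE)


def find_document_contexts(
    doc: TaggedDocument | str,
    lexicon: ContextLexicon,
) -> dict[str, set[str]]:
    """Scan the full document text for lexicon terms, per context type."""
    text = doc if isinstance(doc, str) else doc.text
    found: dict[str, set[str]] = {t: set() for t in CONTEXT_TYPES}
    for term, ctype in lexicon.entries:
        if _term_pattern(term).search(text):
            found[ctype].add(term)
    return found


def expand_rules(
    rules: list[Rule],
    contexts: dict[str, set[str]],
) -> list[Rule]:
    """Attach document contexts to context-free rules, expanding same-type
    alternatives into separate rules.

    Each output rule carries exactly one term per non-empty type; an empty
    type stays null.  Expansion conserves interactions and, projected back
    to null context, recovers the input multiset.
    """
    per_type: list[list[str | None]] = []
    for t in CONTEXT_TYPES:
        terms = sorted(contexts.get(t, set()))
        per_type.append(terms if terms else [None])
    out: list[Rule] = []
    for rule in rules:
        if not rule.context.is_null:
            raise ValidationError("expand_rules expects context-free input rules")
        for ct, og, ds, dr in itertools.product(*per_type):
            out.append(rule.with_context(ContextAssignment(ct=ct, og=og, ds=ds, dr=dr)))
    return out
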