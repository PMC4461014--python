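"""End-to-end orchestration: ingest → map → annotate → group → judge → score.

`run_pipeline` composes the stage modules over any mix of input sources
(flat rule table, KGML files, tagged-document stream) and writes the
per-combination conflict summary, the balance tables, and a run manifest.
Reports are reproducible byte-for-byte given identical inputs, tables and
seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import __version__
from .balance import BalanceRecord, BalanceSummary, balance_records, balance_summary
from .conflict import (
    ALL_COMBINATIONS,
    CombinationSummary,
    ContextCombination,
    build_groups,
    is_conflicting,
    context_resolution_analysis,
)
from .context import ContextLexicon, expand_rules, find_document_contexts
from .extraction import PairWhitelist, extract_candidates, read_tagged_documents
from .kgml_io import kgml_to_rules, read_kgml
from .mapping import StemTable, SubtypeTable
from .model import Rule, RuleGroup, ValidationError, read_rule_table, write_rule_table

__all__ = ["RunConfig", "ConflictReport", "parse_combos", "run_pipeline", "extract_documents"]

logger = logging.getLogger(__name__)


def parse_combos(spec: str) -> list[ContextCombination]:
    """Parse a combination selection: ``ALL`` or a comma list of labels
    like ``none,CT,CT+OG``."""
    if spec.strip().upper() == "ALL":
        return list(ALL_COMBINATIONS)
    out = []
    for part in spec.split(","):
        part = part.strip()
        if not part or part.lower() == "none":
            out.append(ContextCombination.empty())
        else:
            out.append(ContextCombination.of(*part.split("+")))
    return out


@dataclass
class RunConfig:
    """Inputs, tables and knobs for one pipeline run."""

    rules: Path | None = None
    kgml: tuple[Path, ...] = ()
    docs: Path | None = None
    lexicon: Path | None = None
    stems: Path | None = None
    subtypes: Path | None = None
    whitelist: Path | None = None
    combos: str = "ALL"
    mrf_threshold: float = 0.25
    out_dir: Path = Path("pathconflict_report")
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.rules is None and not self.kgml and self.docs is None:
            raise ValidationError("at least one input source (rules, kgml, docs) is required")
        if not (0.0 < self.mrf_threshold <= 0.5):
            raise ValidationError(f"mrf_threshold must lie in (0, 0.5]; got {self.mrf_threshold}")


@dataclass
class ConflictReport:
    """In-memory result of one pipeline run."""

    n_rules: int
    n_groups: int
    n_conflicting_groups: int
    dropped: dict[str, int]
    summaries: list[CombinationSummary]
    balance_context_free: list[BalanceRecord]
    balance_full_context: list[BalanceRecord]
    summary_context_free: BalanceSummary
    summary_full_context: BalanceSummary
    groups: list[RuleGroup] = field(repr=False, default_factory=list)


def extract_documents(
    docs_path: Path,
    stems: StemTable,
    pairs: PairWhitelist,
    lexicon: ContextLexicon | None,
    dropped: dict[str, int] | None = None,
) -> list[Rule]:
    """Extract and (when a lexicon is given) context-annotate a JSONL
    tagged-document stream."""
    rules: list[Rule] = []
    for doc in read_tagged_documents(docs_path):
        candidates = extract_candidates(doc, stems, pairs)
        if lexicon is not None:
            contexts = find_document_contexts(doc, lexicon)
            candidates = expand_rules(candidates, contexts)
        rules.extend(candidates)
    return rules


def _table_fingerprint(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(cfg: RunConfig) -> ConflictReport:
    """Run the full conflict pipeline and write TSV/JSON reports."""
    logging.basicConfig(level=cfg.log_level)
    stems = StemTable.from_tsv(cfg.stems) if cfg.stems else StemTable.default()
    subtypes = SubtypeTable.from_tsv(cfg.subtypes) if cfg.subtypes else SubtypeTable.default()
    pairs = PairWhitelist.from_tsv(cfg.whitelist) if cfg.whitelist else PairWhitelist.default()
    lexicon = ContextLexicon.from_tsv(cfg.lexicon) if cfg.lexicon else None

    dropped = {"unmapped_subtype": 0, "no_relation_word_or_pair": 0}
    rules: list[Rule] = []
    if cfg.rules is not None:
        rules.extend(read_rule_table(cfg.rules))
    for kgml_path in cfg.kgml:
        rels = read_kgml(kgml_path)
        mapped, skipped = kgml_to_rules(rels, subtypes)
        dropped["unmapped_subtype"] += skipped
        rules.extend(mapped)
    if cfg.docs is not None:
        rules.extend(extract_documents(cfg.docs, stems, pairs, lexicon, dropped))

    if not rules:
        logger.warning("empty rule set: reports will be empty")

    combos = parse_combos(cfg.combos)
    groups = build_groups(rules)
    summaries = context_resolution_analysis(groups, combos)
    rec_free = balance_records(groups, None, cfg.mrf_threshold)
    rec_full = balance_records(groups, ContextCombination.full(), cfg.mrf_threshold)
    report = ConflictReport(
        n_rules=len(rules),
        n_groups=len(groups),
        n_conflicting_groups=sum(1 for g in groups if is_conflicting(g)),
        dropped=dropped,
        summaries=summaries,
        balance_context_free=rec_free,
        balance_full_context=rec_full,
        summary_context_free=balance_summary(rec_free, threshold=cfg.mrf_threshold),
        summary_full_context=balance_summary(rec_full, threshold=cfg.mrf_threshold),
        groups=groups,
    )
    _write_report(cfg, report, rules)
    return report


def _balance_frame(records: Sequence[BalanceRecord]) -> pd.DataFrame:
    return pd.DataFrame.from_records(
        [
            {
                "interaction": str(r.interaction),
                "combination": r.combination.label,
                "context_key": "|".join(v if v is not None else "" for v in r.context_key),
                "n_increase": r.n_increase,
                "n_decrease": r.n_decrease,
                "mrf": r.mrf,
                "dominance": r.dominance,
            }
            for r in records
        ],
        columns=["interaction", "combination", "context_key", "n_increase", "n_decrease", "mrf", "dominance"],
    )


def _summary_json(s: BalanceSummary) -> dict:
    return {
        "n_records": s.n_records,
        "bin_edges": list(s.bin_edges),
        "histogram": list(s.histogram),
        "dominating_fraction": s.dominating_fraction,
        "balanced_fraction": s.balanced_fraction,
    }


def _write_report(cfg: RunConfig, report: ConflictReport, rules: Sequence[Rule]) -> None:
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_rule_table(rules, out / "rules.tsv")

    combo_df = pd.DataFrame.from_records(
        [
            {
                "combination": s.combination.label,
                "n_groups": s.n_groups,
                "n_groups_with_conflict": s.n_groups_with_conflict,
                "n_subgroups": s.n_subgroups,
                "n_conflicting_subgroups": s.n_conflicting_subgroups,
                "n_rules": s.n_rules,
                "n_rules_in_conflicting": s.n_rules_in_conflicting,
                "frac_subgroups_conflicting": s.frac_subgroups_conflicting,
                "frac_rules_in_conflicting": s.frac_rules_in_conflicting,
                "frac_groups_with_conflict": s.frac_groups_with_conflict,
            }
            for s in report.summaries
        ]
    )
    combo_df.to_csv(out / "combination_summary.tsv", sep="\t", index=False)
    _balance_frame(report.balance_context_free).to_csv(out / "balance_context_free.tsv", sep="\t", index=False)
    _balance_frame(report.balance_full_context).to_csv(out / "balance_full_context.tsv", sep="\t", index=False)

    n_self_loops = sum(1 for g in report.groups if g.interaction.is_self_loop)
    summary = {
        "n_rules": report.n_rules,
        "n_groups": report.n_groups,
        "n_conflicting_groups": report.n_conflicting_groups,
        "conflicting_group_fraction": (report.n_conflicting_groups / report.n_groups if report.n_groups else None),
        "n_self_loop_interactions": n_self_loops,
        "dropped": report.dropped,
        "balance_context_free": _summary_json(report.summary_context_free),
        "balance_full_context": _summary_json(report.summary_full_context),
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2) + "\n", encoding="utf-8")

    data_dir = resources.files("pathconflict.data")
    manifest = {
        "version": __version__,
        "seed": cfg.seed,
        "mrf_threshold": cfg.mrf_threshold,
        "combos": cfg.combos,
        "inputs": {
            "rules": str(cfg.rules) if cfg.rules else None,
            "kgml": [str(p) for p in cfg.kgml],
            "docs": str(cfg.docs) if cfg.docs else None,
        },
        "tables": {
            "stems": str(cfg.stems) if cfg.stems else "bundled:relation_stems.tsv",
            "subtypes": str(cfg.subtypes) if cfg.subtypes else "bundled:kegg_subtypes.tsv",
            "whitelist": str(cfg.whitelist) if cfg.whitelist else "bundled:meta_relation_pairs.tsv",
            "lexicon": str(cfg.lexicon) if cfg.lexicon else None,
        },
        "table_fingerprints": {
            name: _table_fingerprint(Path(str(data_dir / name)))
            for name in ("relation_stems.tsv", "kegg_subtypes.tsv", "meta_relation_pairs.tsv")
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n", encoding="utf-8")
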