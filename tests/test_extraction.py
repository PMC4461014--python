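"""Between-entity relation extraction, voice resolution, and pair filtering."""

import pytest

from pathconflict import (
    EntitySpan,
    EntityType,
    MetaRelation,
    PairWhitelist,
    TaggedDocument,
    TaggedSentence,
    detect_voice,
    dictionary_tag,
    extract_candidates,
    read_tagged_documents,
    write_tagged_documents,
)
from pathconflict.model import ValidationError


def make_doc(text, spans, doc_id="d0"):
    return TaggedDocument(doc_id, (TaggedSentence("s0", text, tuple(spans)),))


def span_of(text, surface, etype):
    start = text.index(surface)
    return EntitySpan(start, start + len(surface), etype)


def test_whitelist_composition(whitelist):
    assert len(whitelist) == 33
    assert whitelist.count(MetaRelation.INCREASE) == 16
    assert whitelist.count(MetaRelation.DECREASE) == 17
    # the asymmetric rows
    bp, dr, gp = EntityType.BIOLOGICAL_PROCESS, EntityType.DRUG, EntityType.GENE_PROTEIN
    assert whitelist.permits(bp, dr, MetaRelation.DECREASE)
    assert not whitelist.permits(bp, dr, MetaRelation.INCREASE)
    assert not whitelist.permits(dr, EntityType.METABOLITE, MetaRelation.INCREASE)
    assert not whitelist.permits(dr, EntityType.METABOLITE, MetaRelation.DECREASE)
    assert whitelist.permits(gp, dr, MetaRelation.INCREASE)
    assert whitelist.permits(gp, dr, MetaRelation.DECREASE)


def test_active_extraction_cyp1a_sentence(stem_table, whitelist):
    text = ("In contrast, CYP1A isoforms can also activate some compounds, "
            "such as benzo[a]pyrene to their carcinogenic metabolite.")
    doc = make_doc(text, [
        span_of(text, "CYP1A", EntityType.GENE_PROTEIN),
        span_of(text, "benzo[a]pyrene", EntityType.METABOLITE),
    ])
    [rule] = extract_candidates(doc, stem_table, whitelist)
    assert rule.left.name == "cyp1a"
    assert rule.right.name == "benzo[a]pyrene"
    assert rule.meta is MetaRelation.INCREASE
    assert rule.source == "literature"
    assert rule.context.is_null


def test_passive_switches_roles(stem_table, whitelist):
    text = "px001 is increased by px002 under stress."
    doc = make_doc(text, [
        span_of(text, "px001", EntityType.GENE_PROTEIN),
        span_of(text, "px002", EntityType.GENE_PROTEIN),
    ])
    [rule] = extract_candidates(doc, stem_table, whitelist)
    assert (rule.left.name, rule.right.name) == ("px002", "px001")
    assert rule.meta is MetaRelation.INCREASE


def test_no_relation_word_no_rule(stem_table, whitelist):
    text = "px001 binds px002."
    doc = make_doc(text, [
        span_of(text, "px001", EntityType.GENE_PROTEIN),
        span_of(text, "px002", EntityType.GENE_PROTEIN),
    ])
    assert extract_candidates(doc, stem_table, whitelist) == []


def test_non_whitelisted_pair_is_dropped(stem_table, whitelist):
    # no (cell type, *) pair is admissible in either polarity
    text = "fibroblast activates px002."
    doc = make_doc(text, [
        span_of(text, "fibroblast", EntityType.CELL_TYPE),
        span_of(text, "px002", EntityType.GENE_PROTEIN),
    ])
    assert extract_candidates(doc, stem_table, whitelist) == []


@pytest.mark.parametrize(
    "tokens, idx, expected",
    [
        (["is", "increased", "by"], 1, "passive"),
        (["increases"], 0, "active"),
        (["has", "been", "shown", "to", "reduce"], 4, "active"),  # no trailing "by"
        (["was", "strongly", "inhibited", "by"], 2, "passive"),  # be-form 2 back
        (["inhibited", "by"], 0, "active"),  # "by" alone is not passive
        (["is", "activated"], 1, "active"),  # be-form alone is not passive
    ],
)
def test_detect_voice(tokens, idx, expected):
    assert detect_voice(tokens, idx) == expected


def test_only_first_stem_between_a_pair_counts(stem_table, whitelist):
    # "stimulates" comes first and wins over the later "inhibits"
    text = "px001 stimulates and never inhibits px002."
    doc = make_doc(text, [
        span_of(text, "px001", EntityType.GENE_PROTEIN),
        span_of(text, "px002", EntityType.GENE_PROTEIN),
    ])
    [rule] = extract_candidates(doc, stem_table, whitelist)
    assert rule.meta is MetaRelation.INCREASE


def test_extraction_is_invariant_to_sentence_order(stem_table, whitelist):
    t1 = "px001 activates px002."
    t2 = "px003 suppresses px004."
    sents = [
        TaggedSentence("s0", t1, (span_of(t1, "px001", EntityType.GENE_PROTEIN),
                                  span_of(t1, "px002", EntityType.GENE_PROTEIN))),
        TaggedSentence("s1", t2, (span_of(t2, "px003", EntityType.GENE_PROTEIN),
                                  span_of(t2, "px004", EntityType.GENE_PROTEIN))),
    ]
    fwd = extract_candidates(TaggedDocument("d", tuple(sents)), stem_table, whitelist)
    rev = extract_candidates(TaggedDocument("d", tuple(reversed(sents))), stem_table, whitelist)
    key = lambda r: (r.left.name, r.right.name, r.meta.value)
    assert sorted(map(key, fwd)) == sorted(map(key, rev))


def test_no_cross_sentence_relations(stem_table, whitelist):
    t1 = "px001 is interesting."
    t2 = "something activates px002."
    sents = (
        TaggedSentence("s0", t1, (span_of(t1, "px001", EntityType.GENE_PROTEIN),)),
        TaggedSentence("s1", t2, (span_of(t2, "px002", EntityType.GENE_PROTEIN),)),
    )
    assert extract_candidates(TaggedDocument("d", sents), stem_table, whitelist) == []


def test_overlapping_spans_rejected():
    with pytest.raises(ValidationError):
        TaggedSentence("s0", "growth hormone receptor", (
            EntitySpan(0, 14, EntityType.GENE_PROTEIN),
            EntitySpan(7, 23, EntityType.GENE_PROTEIN),
        ))


def test_documented_false_positive_growth_hormone(stem_table, whitelist):
    """A known text-mining error case: 'reduce' between 'growth hormone' and
    'pituitary adenoma' yields a spurious decrease rule even though the
    sentence asserts no such relation."""
    text = ("Effective control of growth hormone should, with long-term use, reduce "
            "morbidity and mortality from acromegaly and has been shown to result in "
            "partial involution of the pituitary adenoma in the majority of treated patients.")
    doc = make_doc(text, [
        span_of(text, "growth hormone", EntityType.GENE_PROTEIN),
        span_of(text, "pituitary adenoma", EntityType.DISEASE),
    ], doc_id="pmid15799207")
    [rule] = extract_candidates(doc, stem_table, whitelist)
    assert (rule.left.name, rule.right.name) == ("growth hormone", "pituitary adenoma")
    assert rule.meta is MetaRelation.DECREASE


def test_documented_false_positive_neuronal_death(stem_table, whitelist):
    """Second known error case: a spurious rule linking 'neuronal death' to
    'cerebral ischemia'.  With the first-matching-stem policy the relation
    word picked is the participle 'induced' that precedes 'decreases' in the
    between-text, so the spurious edge surfaces with increase polarity."""
    text = ("a specific form of neuronal death induced by NMDAR overstimulation, "
            "dramatically decreases Kidins220/ARMS levels in cortical neurons and "
            "in a model of cerebral ischemia.")
    doc = make_doc(text, [
        span_of(text, "neuronal death", EntityType.BIOLOGICAL_PROCESS),
        span_of(text, "cerebral ischemia", EntityType.DISEASE),
    ], doc_id="pmid19759287")
    [rule] = extract_candidates(doc, stem_table, whitelist)
    assert (rule.left.name, rule.right.name) == ("neuronal death", "cerebral ischemia")
    assert rule.meta is MetaRelation.INCREASE


def test_dictionary_tagger_and_jsonl_round_trip(tmp_path, stem_table, whitelist):
    lexicon = {"tak1": EntityType.GENE_PROTEIN, "nf-κb": EntityType.GENE_PROTEIN}
    doc = dictionary_tag("d0", ["TAK1 activates NF-κB in neutrophils."], lexicon)
    [rule] = extract_candidates(doc, stem_table, whitelist)
    assert (rule.left.name, rule.right.name) == ("tak1", "nf-κb")

    path = tmp_path / "docs.jsonl"
    write_tagged_documents([doc], path)
    [back] = list(read_tagged_documents(path))
    assert back == doc
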