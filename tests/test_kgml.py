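"""KGML parsing and conversion to context-free rules."""

import pytest
from lxml import etree

from pathconflict import generate_kgml, kgml_to_rules, read_kgml
from pathconflict.model import MetaRelation

MINIMAL = """<?xml version="1.0"?>
<pathway name="path:hsa04668" org="hsa" number="04668" title="TNF signaling pathway">
  <entry id="1" name="hsa:7124" type="gene"/>
  <entry id="2" name="hsa:4790 hsa:5970" type="gene"/>
  <entry id="3" name="hsa:6885" type="gene"/>
  <relation entry1="1" entry2="2" type="PPrel">
    <subtype name="activation" value="--&gt;"/>
  </relation>
  <relation entry1="3" entry2="2" type="PPrel">
    <subtype name="binding/association" value="---"/>
  </relation>
</pathway>
"""


@pytest.fixture
def minimal_kgml(tmp_path):
    path = tmp_path / "hsa04668.xml"
    path.write_text(MINIMAL)
    return path


def test_read_kgml_counts_relations(minimal_kgml):
    rels = read_kgml(minimal_kgml)
    assert len(rels) == 2
    assert rels[0].entry1.native_id == "hsa:7124"
    assert rels[0].subtypes == ("activation",)


def test_multi_id_entry_uses_first_id(minimal_kgml):
    rels = read_kgml(minimal_kgml)
    assert rels[0].entry2.native_id == "hsa:4790"
    assert rels[0].entry2.name == "hsa:4790 hsa:5970"


def test_relation_with_two_subtypes_yields_two_records(tmp_path):
    xml = MINIMAL.replace(
        '<subtype name="activation" value="--&gt;"/>',
        '<subtype name="phosphorylation" value="+p"/><subtype name="activation" value="--&gt;"/>',
    )
    path = tmp_path / "two.xml"
    path.write_text(xml)
    rels = read_kgml(path)
    assert len(rels) == 3  # 2 from the first relation element + 1 from the second
    assert {r.subtypes[0] for r in rels[:2]} == {"phosphorylation", "activation"}
    assert rels[0].entry1 == rels[1].entry1


def test_empty_pathway_gives_empty_list(tmp_path):
    path = tmp_path / "empty.xml"
    path.write_text('<?xml version="1.0"?><pathway name="path:hsa00000" org="hsa" number="0"/>')
    assert read_kgml(path) == []


def test_malformed_xml_raises_with_location(tmp_path):
    path = tmp_path / "bad.xml"
    path.write_text("<pathway><entry id='1'")
    with pytest.raises(etree.XMLSyntaxError):
        read_kgml(path)


def test_undefined_entry_reference_is_skipped(tmp_path, caplog):
    xml = MINIMAL.replace('entry1="3"', 'entry1="99"')
    path = tmp_path / "dangling.xml"
    path.write_text(xml)
    rels = read_kgml(path)
    assert len(rels) == 1


def test_group_relations_are_skipped(tmp_path):
    xml = MINIMAL.replace('<entry id="3" name="hsa:6885" type="gene"/>',
                          '<entry id="3" name="undefined" type="group"/>')
    path = tmp_path / "group.xml"
    path.write_text(xml)
    assert len(read_kgml(path)) == 1


def test_kgml_to_rules_maps_and_skips(minimal_kgml, subtype_table):
    rules, skipped = kgml_to_rules(read_kgml(minimal_kgml), subtype_table)
    assert len(rules) == 1 and skipped == 1
    rule = rules[0]
    assert rule.meta is MetaRelation.INCREASE
    assert rule.source == "kgml"
    assert rule.context.is_null
    assert rule.left.name == "hsa:7124"


def test_kgml_to_rules_empty():
    assert kgml_to_rules([], None) == ([], 0)


def test_all_14_subtypes_once(tmp_path, subtype_table):
    # one relation per subtype over the same entity pair: 5 increase +
    # 3 decrease rules, 6 skips
    entries = "".join(
        f'<relation entry1="1" entry2="2" type="PPrel"><subtype name="{name}" value="x"/></relation>'
        for name, _ in subtype_table.entries
    )
    xml = (
        '<?xml version="1.0"?><pathway name="p" org="hsa" number="1">'
        '<entry id="1" name="hsa:1" type="gene"/><entry id="2" name="hsa:2" type="gene"/>'
        + entries + "</pathway>"
    )
    path = tmp_path / "all14.xml"
    path.write_text(xml)
    rels = read_kgml(path)
    rules, skipped = kgml_to_rules(rels, subtype_table)
    assert len(rels) == 14
    assert len(rules) == 8 and skipped == 6
    assert sum(r.meta is MetaRelation.INCREASE for r in rules) == 5
    assert sum(r.meta is MetaRelation.DECREASE for r in rules) == 3


def test_conservation_on_generated_fixture(tmp_path, subtype_table):
    path = tmp_path / "syn.xml"
    _, expected, expected_skips = generate_kgml(n_entries=15, n_relations=60, seed=11, path=path)
    rels = read_kgml(path)
    rules, skipped = kgml_to_rules(rels, subtype_table)
    assert len(rules) + skipped == len(rels) == 60
    assert skipped == expected_skips
    assert rules == expected
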