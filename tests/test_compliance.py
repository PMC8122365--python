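"""MIAPPE concept coverage and FAIR checklist completion."""

import pytest

from tdaudit.compliance import (
    FAIR_PRINCIPLES,
    FairEntry,
    MappingEntry,
    SchemaMapping,
    assess_miappe,
    fair_checklist,
    load_cropstoredb_fixture,
    miappe_concepts,
)
from tdaudit.model import ValidationError


def complete_mapping():
    """One schema field per attribute of every concept."""
    entries = []
    for concept in miappe_concepts().values():
        for attr in concept.attributes:
            entries.append(
                MappingEntry(
                    schema_field=f"tbl.{concept.name.replace(' ', '_')}.{attr.replace(' ', '_')}",
                    concept=concept.name,
                    attribute=attr,
                )
            )
    return SchemaMapping(entries=entries)


def test_reference_model_has_eleven_concepts():
    assert len(miappe_concepts()) == 11
    assert "observed variable" in miappe_concepts()


def test_empty_mapping_scores_every_concept_absent():
    report = assess_miappe(SchemaMapping(entries=[]))
    assert set(report.per_concept_status.values()) == {"absent"}
    assert len(report.per_concept_status) == 11
    assert sorted(report.unrepresented_concepts) == sorted(miappe_concepts())


def test_complete_mapping_scores_every_concept_full():
    report = assess_miappe(complete_mapping())
    assert set(report.per_concept_status.values()) == {"full"}
    assert report.unrepresented_concepts == []


def test_cropstoredb_fixture_misses_the_four_known_concepts():
    report = assess_miappe(load_cropstoredb_fixture())
    assert {"data file", "environment", "experimental factor", "event"} <= set(
        report.unrepresented_concepts
    )
    assert report.per_concept_status["study"] == "full"
    assert report.per_concept_status["observed variable"] == "full"
    assert report.per_concept_status["experimental factor"] == "partial"
    assert report.per_concept_status["environment"] == "absent"
    assert "scoring_data.raw_value" in report.unmapped_schema_fields


def test_statuses_partition_concepts_and_are_monotone():
    full = complete_mapping()
    rank = {"absent": 0, "partial": 1, "full": 2}
    previous = assess_miappe(SchemaMapping(entries=[])).per_concept_status
    for cut in range(1, len(full.entries) + 1, 7):
        current = assess_miappe(SchemaMapping(entries=full.entries[:cut])).per_concept_status
        assert len(current) == 11
        for concept in current:
            assert rank[current[concept]] >= rank[previous[concept]]
        previous = current


def test_mapping_validation_errors():
    with pytest.raises(ValidationError, match="unknown MIAPPE concept"):
        SchemaMapping(entries=[MappingEntry("f", concept="experiment")])
    with pytest.raises(ValidationError, match="duplicate schema fields"):
        SchemaMapping(entries=[MappingEntry("f"), MappingEntry("f")])
    with pytest.raises(ValidationError, match="not an attribute"):
        SchemaMapping(entries=[MappingEntry("f", concept="study", attribute="nope")])


def test_fair_checklist_empty_draft_is_all_unmet():
    checklist, counts = fair_checklist(None)
    assert len(checklist.entries) == 15
    assert counts["unmet"] == 15


def test_fair_checklist_fills_missing_principles():
    draft = [FairEntry("F1", "met", "globally unique CO identifier")]
    checklist, counts = fair_checklist(draft)
    assert len(checklist.entries) == 15
    assert counts == {"met": 1, "partial": 0, "unmet": 14, "n/a": 0}
    assert checklist.entries[0].evidence == "globally unique CO identifier"


def test_fair_checklist_fully_answered_has_zero_unmet():
    draft = [FairEntry(pid, "met", "evidence") for pid in FAIR_PRINCIPLES]
    _, counts = fair_checklist(draft)
    assert counts["unmet"] == 0 and counts["met"] == 15


def test_fair_checklist_rejects_duplicates_and_unknown_ids():
    with pytest.raises(ValidationError, match="duplicate"):
        fair_checklist([FairEntry("F1", "met"), FairEntry("F1", "unmet")])
    with pytest.raises(ValidationError, match="unknown FAIR principle"):
        FairEntry("F9", "met")
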