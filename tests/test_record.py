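"""Record model: total parsing, canonical serialization, shared-metadata
attachment."""

import json

import pytest

from mms3d import (
    FunderEntry,
    GeneratorConfig,
    MetadataRecord,
    attach_common_metadata,
    generate_valid_record,
    parse_record,
    serialize_record,
)
from mms3d.record import parse_color


class TestParsing:
    def test_direct_field_copy(self):
        rec, issues = parse_record({"Specimen": {"Sex": "Female"}})
        assert rec.specimen.sex == "Female"
        assert issues == []

    def test_unknown_field_is_reported_not_dropped_silently(self):
        rec, issues = parse_record({"Specimen": {"Sex": "Female", "weight": "20g"}})
        assert rec.specimen.sex == "Female"
        assert [(i.code, i.path) for i in issues] == [
            ("UNKNOWN_FIELD", "Specimen.weight")]

    def test_unknown_category_is_reported(self):
        _, issues = parse_record({"Acquisition": {}})
        assert issues[0].code == "UNKNOWN_FIELD"

    def test_scalar_where_list_expected(self):
        rec, issues = parse_record({"Contributors": {"contributorName": "Doe, J"}})
        assert len(rec.contributors) == 1  # coerced, but reported
        assert any(i.code == "MULTIPLICITY" for i in issues)

    def test_unparseable_number_is_kept_verbatim(self):
        rec, issues = parse_record({"Image": {"stepSizeX": "about one micron"}})
        assert rec.image.step_size_x == "about one micron"
        assert any(i.code == "UNPARSEABLE" for i in issues)

    def test_age_unknown_sentinel_case_insensitive(self):
        rec, issues = parse_record({"Specimen": {"Age": "Unknown"}})
        assert rec.specimen.age == "unknown" and not issues

    def test_non_mapping_document_raises(self):
        with pytest.raises(TypeError):
            parse_record(["not", "a", "record"])


@pytest.mark.parametrize(
    "text", ["255,0,0", "(255, 0, 0)", "[255,0,0]", " 255 , 0 , 0 "]
)
def test_display_color_dialects(text):
    assert parse_color(text) == (255, 0, 0)


def test_display_color_canonical_output():
    doc = serialize_record(
        parse_record({"Image": {"Channels": [{"Number": "0",
                                              "displayColor": "(255, 0, 0)"}]}})[0]
    )
    assert doc["Image"]["Channels"][0]["displayColor"] == "255,0,0"


class TestRoundTrip:
    def test_parse_serialize_identity_over_corpus(self, config):
        for i in range(50):
            rec = generate_valid_record(config, index=i)
            doc = serialize_record(rec)
            # through an actual JSON byte round-trip
            rec2, issues = parse_record(json.loads(json.dumps(doc)))
            assert issues == []
            assert rec2 == rec

    def test_serialization_is_deterministic(self, record):
        a = json.dumps(serialize_record(record), indent=2)
        b = json.dumps(serialize_record(record.copy()), indent=2)
        assert a == b

    def test_serialize_parse_is_canonicalizing_idempotent(self):
        messy = {"Specimen": {"Age": "UNKNOWN"},
                 "Image": {"Channels": [{"Number": 1, "displayColor": "[0,255,0]"}]}}
        once = serialize_record(parse_record(messy)[0])
        twice = serialize_record(parse_record(once)[0])
        assert once == twice
        assert once["Image"]["Channels"][0]["displayColor"] == "0,255,0"

    def test_creator_flag_serializes_as_yes_no(self, record):
        doc = serialize_record(record)
        assert doc["Contributors"][0]["Creator"] == "Yes"


class TestAttachCommonMetadata:
    def shared_funder(self):
        shared = MetadataRecord(funding_declared=True)
        shared.funders.append(FunderEntry(
            funder_name="National Institutes of Health",
            funding_reference_identifier="01cwqze88",
            funding_reference_identifier_type="ROR",
            award_number="R01MH123456",
            award_title="Whole-brain connectivity atlas"))
        return shared

    def test_appends_to_every_record(self, config):
        records = [generate_valid_record(config, index=i) for i in range(3)]
        before = [len(r.funders) for r in records]
        out = attach_common_metadata(records, self.shared_funder())
        assert [len(r.funders) for r in out] == [b + 1 for b in before]
        # originals untouched
        assert [len(r.funders) for r in records] == before

    def test_idempotent_and_deduplicating(self, config):
        records = [generate_valid_record(config, index=0)]
        once = attach_common_metadata(records, self.shared_funder())
        twice = attach_common_metadata(once, self.shared_funder())
        assert once == twice

    def test_empty_record_list(self):
        assert attach_common_metadata([], self.shared_funder()) == []

    def test_rejects_non_shared_content(self, record):
        shared = MetadataRecord()
        shared.dataset.title = "not shareable"
        with pytest.raises(ValueError):
            attach_common_metadata([record], shared)
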