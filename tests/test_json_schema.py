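"""JSON-Schema emission and cross-engine agreement with the validator."""

import json

import jsonschema
import pytest

from mms3d import (
    emit_json_schema,
    generate_valid_record,
    inject_errors,
    serialize_record,
    validate_record,
    write_schema_files,
)


@pytest.fixture(scope="module")
def combined_validator(registry):
    schema = emit_json_schema(registry, "all")["record_schema.json"]
    jsonschema.Draft202012Validator.check_schema(schema)
    return jsonschema.Draft202012Validator(schema)


def test_all_scope_emits_eight_documents(registry):
    docs = emit_json_schema(registry, "all")
    assert set(docs) == {
        "record_schema.json", "contributors_schema.json", "funders_schema.json",
        "dataset_schema.json", "image_schema.json", "instrument_schema.json",
        "publication_schema.json", "specimen_schema.json"}


def test_specimen_sex_enumerates_three_values(registry):
    doc = emit_json_schema(registry, "Specimen")
    assert doc["properties"]["Sex"]["enum"] == ["Male", "Female", "Unknown"]


def test_vocabulary_fields_become_enums(registry):
    image = emit_json_schema(registry, "Image")
    assert len(image["properties"]["xAxis"]["enum"]) == 7
    contribs = emit_json_schema(registry, "Contributors")
    items = contribs["items"]
    assert items["properties"]["contributorType"]["enum"][0] == "ContactPerson"


def test_emission_is_deterministic_and_file_layout(registry, tmp_path):
    a = json.dumps(emit_json_schema(registry, "all"), indent=2)
    b = json.dumps(emit_json_schema(registry, "all"), indent=2)
    assert a == b
    paths = write_schema_files(registry, tmp_path)
    assert sorted(p.name for p in paths) == sorted([
        "record_schema.json", "contributors_schema.json", "funders_schema.json",
        "dataset_schema.json", "image_schema.json", "instrument_schema.json",
        "publication_schema.json", "specimen_schema.json"])


def test_unknown_scope_rejected(registry):
    with pytest.raises(ValueError):
        emit_json_schema(registry, "Acquisition")


class TestCrossEngineAgreement:
    def test_clean_records_pass_combined_schema(self, registry, config,
                                                combined_validator):
        for i in range(30):
            rec = generate_valid_record(config, index=i)
            assert validate_record(rec, registry).valid
            errs = list(combined_validator.iter_errors(serialize_record(rec)))
            assert errs == []

    @pytest.mark.parametrize("path", [
        "Dataset.Title", "Dataset.Abstract", "Image.xAxis",
        "Instrument.MicroscopeType", "Specimen.Species"])
    def test_required_missing_fails_combined_schema(self, registry, config,
                                                    combined_validator, path):
        rec = generate_valid_record(config, index=0)
        bad, _ = inject_errors(rec, [f"REQUIRED_MISSING@{path}"], seed=1)
        assert not validate_record(bad, registry).valid
        assert not combined_validator.is_valid(serialize_record(bad))

    def test_personal_identifier_conditional_encoded_in_schema(
            self, registry, config, combined_validator):
        rec = generate_valid_record(config, index=1)
        bad, _ = inject_errors(rec, ["COND_PERSONAL_ID"], seed=1)
        assert not combined_validator.is_valid(serialize_record(bad))

    def test_missing_creator_encoded_in_schema(self, registry, config,
                                               combined_validator):
        rec = generate_valid_record(config, index=2)
        bad, _ = inject_errors(rec, ["NO_CREATOR"], seed=1)
        assert not combined_validator.is_valid(serialize_record(bad))
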