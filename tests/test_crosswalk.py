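"""DataCite/OME crosswalk tables and the DataCite export."""

import pytest

from mms3d import (
    DataCiteExportError,
    crosswalk_table,
    datacite_xml,
    export_datacite,
    inject_errors,
    mapping_counts,
)


@pytest.mark.parametrize("category, n", [
    ("Contributors", 9), ("Funders", 5), ("Dataset", 8), ("Publication", 3),
    ("Image", 0), ("Instrument", 0), ("Specimen", 0)])
def test_datacite_pinned_counts(registry, category, n):
    assert mapping_counts(registry, "DataCite", category) == n


@pytest.mark.parametrize("category, n", [
    ("Instrument", 12), ("Image", 15), ("Contributors", 0), ("Dataset", 0)])
def test_ome_pinned_counts(registry, category, n):
    assert mapping_counts(registry, "OME", category) == n


def test_totals_are_pinned_sums_only(registry):
    assert mapping_counts(registry, "DataCite") == 25
    assert mapping_counts(registry, "OME") == 27


def test_unique_field_target_pairs(registry):
    rows = crosswalk_table(registry)
    keys = [(r.mms_field, r.category, r.target) for r in rows]
    assert len(keys) == len(set(keys)) == 25 + 27


def test_datacite_required_overlap_equals_doi_flags(registry):
    # the 19 DOI-supporting required fields are exactly the required fields
    # with a DataCite mapping
    mapped = {(r.category, r.mms_field) for r in crosswalk_table(registry)
              if r.target == "DataCite"}
    required_mapped = [
        f for f in registry.iter_fields()
        if f.bil_required and (f.category, f.name) in mapped]
    assert len(required_mapped) == 19
    assert all(f.doi_support for f in required_mapped)


class TestExport:
    def test_creator_flag_partition(self, registry, record):
        doc = export_datacite(record, registry)
        n_creators = sum(
            1 for e in record.contributors
            if e.creator is True or str(e.creator).lower() == "yes")
        assert len(doc["creators"]) == n_creators
        # every contributor (creators included) appears with a role
        assert len(doc["contributors"]) == len(record.contributors)
        assert all("contributorType" in c for c in doc["contributors"])

    def test_abstract_becomes_typed_description(self, registry, record):
        doc = export_datacite(record, registry)
        assert doc["descriptions"][0]["descriptionType"] == "Abstract"
        assert doc["descriptions"][0]["description"] == record.dataset.abstract

    def test_refusal_without_creator(self, registry, record):
        bad, _ = inject_errors(record, ["NO_CREATOR"], seed=0)
        with pytest.raises(DataCiteExportError) as exc_info:
            export_datacite(bad, registry)
        assert "NO_CREATOR" in str(exc_info.value)
        assert exc_info.value.report.by_code("NO_CREATOR")

    def test_doi_field_value_inventory_is_lossless(self, registry, config):
        from mms3d import generate_valid_record, serialize_record
        import json

        for i in range(20):
            rec = generate_valid_record(config, index=i)
            doc = export_datacite(rec, registry)
            blob = json.dumps(doc)
            src = serialize_record(rec)
            # every populated DOI-supporting value must surface in the export
            doi_fields = {f.name for f in registry.iter_fields() if f.doi_support}
            for cat in ("Contributors", "Funders", "Publication"):
                for entry in src[cat]:
                    for key, value in entry.items():
                        if key in doi_fields and key != "Creator":
                            assert str(value) in blob, (cat, key, value)
            for key, value in src["Dataset"].items():
                if key not in doi_fields:
                    continue
                if key == "Keywords":  # split into one subject per token
                    for token in value.split(";"):
                        assert token.strip() in blob, (key, token)
                else:
                    assert str(value) in blob, (key, value)

    def test_xml_rendering_carries_kernel_namespace(self, registry, record):
        xml = datacite_xml(export_datacite(record, registry))
        assert b"http://datacite.org/schema/kernel-4" in xml
        assert b"<creators>" in xml
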