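"""Structural fidelity of the compiled 3D-MMS registry."""

import pytest

from mms3d import (
    FieldLookupError,
    FieldSpec,
    RegistryError,
    build_default_registry,
    count_fields,
    get_field,
    registry_to_dict,
)


class TestCounts:
    def test_total_and_version(self, registry):
        assert count_fields(registry) == 91
        assert registry.version == "1.0.0"
        assert len(registry.categories) == 7

    @pytest.mark.parametrize(
        "category, total",
        [("Contributors", 9), ("Funders", 5), ("Dataset", 15), ("Image", 33),
         ("Instrument", 12), ("Publication", 5), ("Specimen", 12)],
    )
    def test_per_category_totals(self, registry, category, total):
        assert count_fields(registry, category=category) == total

    @pytest.mark.parametrize(
        "category, n_required",
        [("Contributors", 9), ("Dataset", 5), ("Funders", 5), ("Instrument", 2),
         ("Image", 8), ("Specimen", 5), ("Publication", 0)],
    )
    def test_submission_required_sets(self, registry, category, n_required):
        assert count_fields(registry, category=category,
                            requirement="bil_required") == n_required

    def test_doi_supporting_required_fields(self, registry):
        assert count_fields(registry, requirement="bil_required",
                            doi_support=True) == 19

    def test_doi_flags_by_category(self, registry):
        # all Contributors and Funders fields support DOI assignment; the
        # five required Dataset fields do; no Instrument/Image/Specimen
        # required field does
        for cname in ("Contributors", "Funders"):
            assert all(f.doi_support for f in registry.category(cname))
        dataset_req = [f for f in registry.category("Dataset") if f.bil_required]
        assert len(dataset_req) == 5 and all(f.doi_support for f in dataset_req)
        for cname in ("Instrument", "Image", "Specimen"):
            assert not any(f.doi_support for f in registry.category(cname)
                           if f.bil_required)

    def test_publication_all_optional(self, registry):
        assert count_fields(registry, category="Publication",
                            requirement="required") == 0
        assert count_fields(registry, category="Publication",
                            requirement="optional") == 5

    def test_unknown_filters_are_usage_errors(self, registry):
        with pytest.raises(ValueError):
            count_fields(registry, category="Acquisition")
        with pytest.raises(ValueError):
            count_fields(registry, requirement="mandatory")


class TestVocabularies:
    def test_sex_vocabulary(self, registry):
        assert get_field(registry, "Sex").vocabulary == ("Male", "Female", "Unknown")

    def test_axis_vocabulary_has_seven_directions(self, registry):
        for name in ("xAxis", "yAxis", "zAxis"):
            assert len(get_field(registry, name).vocabulary) == 7
            assert "Oblique" in get_field(registry, name).vocabulary

    def test_identifier_scheme_vocabulary(self, registry):
        f = get_field(registry, "nameIdentifierScheme")
        assert f.vocabulary == ("GRID", "ISNI", "ORCID", "ROR", "RRID")

    def test_suggested_values_never_close_the_field(self, registry):
        for f in registry.iter_fields():
            if f.suggested_values:
                assert f.value_kind == "free_text"


class TestLookup:
    def test_exact_lookup(self, registry):
        f = get_field(registry, "displayColor")
        assert f.category == "Image" and f.requirement_level == "required"

    def test_case_insensitive_fallback_warns(self, registry):
        with pytest.warns(UserWarning, match="case-insensitively"):
            f = get_field(registry, "DISPLAYCOLOR")
        assert f.name == "displayColor"

    def test_near_miss_suggestion(self, registry):
        with pytest.raises(FieldLookupError, match="displayColor"):
            get_field(registry, "displayColour")

    def test_category_scoping(self, registry):
        assert get_field(registry, "Title", category="Dataset").doi_support
        with pytest.raises(FieldLookupError):
            get_field(registry, "Title", category="Image")


class TestInvariantEnforcement:
    def test_vocabulary_kind_consistency(self):
        with pytest.raises(RegistryError):
            FieldSpec(name="x", category="Dataset", definition="d",
                      value_kind="vocabulary", vocabulary=())

    def test_conditional_needs_condition(self):
        with pytest.raises(RegistryError):
            FieldSpec(name="x", category="Dataset", definition="d",
                      requirement_level="conditional")

    def test_doi_needs_datacite_property(self):
        with pytest.raises(RegistryError):
            FieldSpec(name="x", category="Dataset", definition="d",
                      doi_support=True)

    def test_conditions_are_trilevel(self, registry):
        for f in registry.iter_fields():
            if f.requirement_level == "conditional":
                assert f.condition != "none" and f.condition_text
            else:
                assert f.condition == "none"


def test_registry_dump_covers_every_field(registry):
    dump = registry_to_dict(registry)
    assert sum(len(c["fields"]) for c in dump["categories"]) == 91
    assert [c["name"] for c in dump["categories"]] == [
        "Contributors", "Funders", "Dataset", "Image", "Instrument",
        "Publication", "Specimen"]
    provs = {f["provenance"] for c in dump["categories"] for f in c["fields"]}
    assert provs == {"required-table", "synthesized-from-prose"}
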