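"""Rule-catalog enforcement and report semantics."""

import pytest

from mms3d import (
    GeneratorConfig,
    generate_valid_record,
    inject_errors,
    summarize_report,
    validate_record,
)


def errors(report):
    return {(i.path, i.code) for i in report.issues if i.severity == "error"}


class TestPresence:
    def test_clean_record_is_valid(self, record, registry):
        report = validate_record(record, registry)
        assert report.valid and report.n_errors == 0

    def test_missing_abstract_single_required_missing(self, record, registry):
        record = record.copy()
        record.dataset.abstract = None
        report = validate_record(record, registry)
        missing = report.by_code("REQUIRED_MISSING")
        assert [i.path for i in missing] == ["Dataset.Abstract"]
        assert not report.valid

    def test_personal_contributor_without_identifier(self, record, registry):
        record = record.copy()
        record.contributors[0].name_type = "Personal"
        record.contributors[0].name_identifier = None
        record.contributors[0].name_identifier_scheme = None
        report = validate_record(record, registry)
        assert ("Contributors[0].nameIdentifier", "COND_PERSONAL_ID") in errors(report)

    def test_no_creator(self, record, registry):
        record = record.copy()
        for e in record.contributors:
            e.creator = False
        report = validate_record(record, registry)
        assert ("Contributors", "NO_CREATOR") in errors(report)

    def test_government_funding_requires_funders(self, record, registry):
        record = record.copy()
        record.funders = []
        record.funding_declared = True
        assert ("Funders", "COND_FUNDERS") in errors(validate_record(record, registry))
        record.funding_declared = False
        assert ("Funders", "COND_FUNDERS") not in errors(
            validate_record(record, registry))


class TestValueRules:
    def test_vocabulary_violation_vs_case_drift(self, record, registry):
        rec = record.copy()
        rec.specimen.sex = "female"  # casing drift only: advice
        report = validate_record(rec, registry)
        assert report.valid
        assert [i.code for i in report.issues if i.path == "Specimen.Sex"] == [
            "VOCAB_CASE"]
        rec.specimen.sex = "Hermaphrodite"
        report = validate_record(rec, registry)
        assert ("Specimen.Sex", "VOCAB_VIOLATION") in errors(report)

    def test_color_range_and_format(self, record, registry):
        rec = record.copy()
        rec.image.channels[0].display_color = (300, 0, 0)
        assert ("Image.Channels[0].displayColor", "COLOR_FORMAT") in errors(
            validate_record(rec, registry))
        rec.image.channels[0].display_color = "reddish"
        assert ("Image.Channels[0].displayColor", "COLOR_FORMAT") in errors(
            validate_record(rec, registry))

    def test_nonpositive_step_and_negative_age(self, record, registry):
        rec = record.copy()
        rec.image.step_size_z = 0
        rec.specimen.age = -1
        errs = errors(validate_record(rec, registry))
        assert ("Image.stepSizeZ", "STEP_NONPOSITIVE") in errs
        assert ("Specimen.Age", "AGE_NEGATIVE") in errs

    def test_taxonomy_must_be_digits(self, record, registry):
        rec = record.copy()
        rec.specimen.ncbi_taxonomy = "mouse"
        assert ("Specimen.NCBITaxonomy", "TAXON_SYNTAX") in errors(
            validate_record(rec, registry))

    def test_spdx_hint_is_warning_only(self, record, registry):
        rec = record.copy()
        rec.dataset.rights_identifier = "my own license!!"
        report = validate_record(rec, registry)
        assert report.valid  # warning, not error
        assert [i.severity for i in report.by_code("SPDX_HINT")] == ["warning"]

    def test_suggested_value_miss_is_advice_never_error(self, record, registry):
        rec = record.copy()
        rec.dataset.general_modality = "something entirely new"
        report = validate_record(rec, registry)
        assert report.valid
        assert [i.severity for i in report.by_code("SUGGESTED_VALUE_MISS")] == [
            "advice"]


class TestProfiles:
    def test_lenient_errors_subset_of_bil(self, record, registry):
        rec, _ = inject_errors(
            record, ["COND_FUNDERS", "COND_PERSONAL_ID", "AGE_NEGATIVE"], seed=3)
        bil = errors(validate_record(rec, registry, profile="bil"))
        lenient = errors(validate_record(rec, registry, profile="lenient"))
        assert lenient <= bil
        # the conditional rules specifically got downgraded
        assert ("Funders[0].awardTitle", "COND_FUNDERS") in bil - lenient

    def test_doi_only_ignores_image_and_specimen_rules(self, record, registry):
        rec, _ = inject_errors(
            record, ["AGE_NEGATIVE", "STEP_NONPOSITIVE",
                     "REQUIRED_MISSING@Dataset.Title"], seed=3)
        report = validate_record(rec, registry, profile="doi_only")
        errs = errors(report)
        assert ("Dataset.Title", "REQUIRED_MISSING") in errs
        assert not any(path.startswith(("Image", "Specimen")) for path, _ in errs)

    def test_unknown_profile_is_usage_error(self, record, registry):
        with pytest.raises(ValueError):
            validate_record(record, registry, profile="strict")


class TestReport:
    def test_summarize_counts_sum_to_total(self, record, registry):
        rec, _ = inject_errors(
            record, ["NO_CREATOR", "VOCAB_VIOLATION", "TAXON_SYNTAX"], seed=5)
        report = validate_record(rec, registry)
        summary = summarize_report(report)
        assert sum(summary.values()) == len(report.issues)
        assert summary["NO_CREATOR"] == 1

    def test_empty_report_empty_summary(self, record, registry):
        assert summarize_report(validate_record(record, registry)) == {}

    def test_monotonicity_under_additional_faults(self, registry, config):
        # injecting one more fault never decreases the issue count
        codes = ["NO_CREATOR", "AGE_NEGATIVE", "TAXON_SYNTAX", "SPDX_HINT",
                 "STEP_NONPOSITIVE"]
        for i in range(10):
            rec = generate_valid_record(config, index=i)
            prev = len(validate_record(rec, registry).issues)
            for k in range(1, len(codes) + 1):
                corrupted, _ = inject_errors(rec, codes[:k], seed=i)
                n = len(validate_record(corrupted, registry).issues)
                assert n >= prev
                prev = n

    def test_verdict_is_pure_function_of_issues(self, record, registry):
        report = validate_record(record, registry)
        assert report.valid == (report.n_errors == 0)
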