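"""Synthetic-record generation and labeled fault injection."""

import json

import pytest

from mms3d import (
    GeneratorConfig,
    VALIDATION_CODES,
    generate_corpus,
    generate_valid_record,
    inject_errors,
    serialize_record,
    validate_record,
)


class TestGenerator:
    def test_every_seed_validates_clean(self, registry):
        for seed in range(40):
            rec = generate_valid_record(GeneratorConfig(seed=seed))
            report = validate_record(rec, registry)
            assert report.valid, [
                (i.code, i.path) for i in report.issues if i.severity == "error"]

    def test_same_seed_identical_bytes(self):
        cfg = GeneratorConfig(seed=7)
        a = json.dumps(serialize_record(generate_valid_record(cfg)), indent=2)
        b = json.dumps(serialize_record(generate_valid_record(cfg)), indent=2)
        assert a == b

    def test_different_seeds_differ(self):
        a = serialize_record(generate_valid_record(GeneratorConfig(seed=1)))
        b = serialize_record(generate_valid_record(GeneratorConfig(seed=2)))
        assert a != b

    def test_forced_channel_count(self):
        rec = generate_valid_record(GeneratorConfig(seed=5, n_channels=(3, 3)))
        assert len(rec.image.channels) == 3

    def test_abstract_word_floor(self):
        rec = generate_valid_record(GeneratorConfig(seed=5, abstract_min_words=100))
        assert len(rec.dataset.abstract.split()) >= 100

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            GeneratorConfig(seed=0, n_channels=(3, 1))
        with pytest.raises(ValueError):
            GeneratorConfig(seed=0, optional_fill_probability=1.5)


class TestInjection:
    def test_empty_code_list_is_identity(self, record):
        out, labels = inject_errors(record, [], seed=0)
        assert out == record and labels == []
        assert out is not record

    def test_original_record_untouched(self, record, registry):
        snapshot = record.copy()
        inject_errors(record, ["NO_CREATOR", "AGE_NEGATIVE"], seed=0)
        assert record == snapshot

    def test_every_catalog_code_has_a_detected_recipe(self, record, registry):
        # full catalog coverage: each recipe's fault is found at its path
        for code in VALIDATION_CODES:
            corrupted, labels = inject_errors(record, [code], seed=3)
            assert len(labels) == 1 and labels[0].code == code
            report = validate_record(corrupted, registry)
            found = {(i.code, i.path) for i in report.issues}
            assert (labels[0].code, labels[0].path) in found, code

    def test_unknown_code_is_usage_error(self, record):
        with pytest.raises(ValueError):
            inject_errors(record, ["TOTALLY_BOGUS"], seed=0)

    def test_cardinality_conflicts_rejected(self, record):
        with pytest.raises(ValueError):
            inject_errors(record, ["CARDINALITY", "COLOR_FORMAT"], seed=0)

    def test_targeted_required_missing(self, record, registry):
        corrupted, labels = inject_errors(
            record, ["REQUIRED_MISSING@Dataset.Title", "AGE_NEGATIVE"], seed=0)
        assert [l.path for l in labels] == ["Dataset.Title", "Specimen.Age"]
        codes = {i.code for i in validate_record(corrupted, registry).issues}
        assert {"REQUIRED_MISSING", "AGE_NEGATIVE"} <= codes


class TestCorpus:
    def test_zero_fault_rate_all_clean(self, registry):
        corpus = generate_corpus(30, GeneratorConfig(seed=9), fault_rate=0.0)
        assert all(not labels for _, labels in corpus)
        assert all(validate_record(r, registry).valid for r, _ in corpus)

    def test_full_fault_rate_all_labeled(self):
        corpus = generate_corpus(30, GeneratorConfig(seed=9), fault_rate=1.0)
        assert all(labels for _, labels in corpus)

    def test_corpus_reproducible_and_order_insensitive(self):
        a = generate_corpus(10, GeneratorConfig(seed=13), fault_rate=0.5)
        b = generate_corpus(10, GeneratorConfig(seed=13), fault_rate=0.5)
        assert a == b
        # per-record streams: a shorter corpus is a prefix of a longer one
        short = generate_corpus(5, GeneratorConfig(seed=13), fault_rate=0.5)
        assert a[:5] == short

    def test_bad_arguments(self):
        with pytest.raises(ValueError):
            generate_corpus(0, GeneratorConfig(seed=1))
        with pytest.raises(ValueError):
            generate_corpus(5, GeneratorConfig(seed=1), fault_rate=2.0)
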