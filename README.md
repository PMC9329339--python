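# mms3d

An executable implementation of the **3D Microscopy Metadata Standards
(3D-MMS)** — the 91-field metadata standard for three-dimensional light
microscopy datasets (whole cleared brains, light-sheet and confocal volumes)
used by brain-imaging archives such as the Brain Image Library.

Sharing a 3D microscopy volume is only useful if a stranger can open it,
orient it, and cite it: that takes consistent metadata about who made the
dataset (and their ORCID/ROR identifiers), who funded it, what the specimen
was, how the instrument was configured, and how the voxel grid maps onto
anatomy (axis orientations, microns per pixel, microns between slices,
channel colors). 3D-MMS fixes that vocabulary as 91 fields in seven ordered
categories — **Contributors, Funders, Dataset, Image, Instrument,
Publication, Specimen** — of which 34 are required (or conditionally
required) for repository submission and 19 of the required fields carry the
DataCite properties needed to mint a DOI.

`mms3d` compiles the standard into a queryable registry and builds the full
toolchain around it:

- **schema registry** — every field with definition, requirement level,
  controlled vocabulary, repeatability, DOI-support flag and crosswalk links
  (`build_default_registry`, `count_fields`, `get_field`);
- **record model** — one dataset's metadata as a JSON tree or an in-memory
  `MetadataRecord`; parsing is total (anomalies become issues, never crashes);
- **validator** — a fixed 15-rule catalog (missing required fields,
  conditional requirements, vocabulary and cardinality violations, RGB color
  format, step-size positivity, NCBI taxonomy syntax, ORCID/ISNI ISO 7064
  mod 11-2 check digits, SPDX hints, suggested-value advice) with `bil`,
  `doi_only` and `lenient` profiles;
- **JSON-Schema emission** — seven per-category schemas plus a combined
  `record_schema.json` (draft 2020-12, conditionals as `if`/`then`);
- **tabular interchange** — the multi-table spreadsheet layout (per-category
  CSV files or a multi-sheet `.xlsx` workbook) converted losslessly to and
  from the JSON form;
- **crosswalks** — the pinned DataCite (25 fields) and OME Data Model
  (27 fields) mappings, plus a DataCite kernel-4 exporter (JSON and XML) for
  DOI minting;
- **synthesis** — a seed-reproducible generator of valid records and
  labeled fault injection, so every component is testable offline.

## Worked example

Generate a synthetic record, validate it, break it, and validate again:

```sh
$ mms3d generate --n 1 --seed 7 --out demo
wrote 1 records to demo

$ mms3d validate --input demo/record_0000.json
VALID: 0 error(s), 0 warning(s), 0 advice note(s)
```

`demo/record_0000.json` is a complete submission: a creator with a
checksum-valid ORCID (`Franklin, June`, `3933-7862-8896-6169`), an NIH-style
funder with a ROR identifier, a one-channel image block
(`displayColor 255,0,0`, `Fluorophore GFP`, excitation 488 nm) and a
zebrafish specimen (NCBI taxonomy `7955`). Deleting its Abstract and setting
`Sex` to `"F"` produces:

```sh
$ mms3d validate --input demo/broken.json
ERROR   REQUIRED_MISSING     Dataset.Abstract: required field Abstract is missing
ERROR   VOCAB_VIOLATION      Specimen.Sex: 'F' is not an allowable value for Sex (Male; Female; Unknown)
INVALID: 2 error(s), 0 warning(s), 0 advice note(s)
```

The exit code is the pipeline contract: `0` valid, `1` validation errors,
`2` usage or I/O error. Registry queries come from the same compiled
standard:

```sh
$ mms3d stats --category Image
33 fields
$ mms3d stats --requirement bil_required --doi-support
19 fields
$ mms3d stats --crosswalk ome --category Instrument
12 OME mappings in Instrument
```

Other subcommands: `mms3d schema --out DIR` (writes the 7+1 JSON-Schema
files), `mms3d convert --from json --to tabular …` (and back),
`mms3d export-datacite --input record.json --output datacite.json [--xml]`.

The same operations are available as library calls:

```python
from mms3d import (build_default_registry, GeneratorConfig,
                   generate_valid_record, validate_record)

registry = build_default_registry()
record = generate_valid_record(GeneratorConfig(seed=7))
report = validate_record(record, registry, profile="bil")
assert report.valid
```

## Layout

```
src/mms3d/
  _fields.py     field-by-field definition of the standard (data, not code)
  registry.py    FieldSpec / SchemaRegistry, counting and lookup
  record.py      MetadataRecord, JSON parse/serialize, shared-metadata attach
  validation.py  rule catalog, profiles, identifier checksums
  schema_json.py JSON-Schema emission (7 + 1 documents)
  tabular.py     CSV-directory and .xlsx carriers for the multi-table layout
  crosswalk.py   DataCite/OME mapping tables and the DataCite exporter
  synthesis.py   seeded record generator and labeled fault injection
  cli.py         the `mms3d` command
```

See `docs/methods.md` for the modeling decisions, rule semantics, and known
limitations.
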