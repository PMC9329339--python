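# Methods

## The standard as data

3D-MMS is compiled into `mms3d/_fields.py` as a literal table: 91 fields in
the seven fixed-order categories (Contributors 9, Funders 5, Dataset 15,
Image 33, Instrument 12, Publication 5, Specimen 12). The registry builder
re-derives and enforces every structural invariant at construction time —
category order, per-category totals, the required sets (Contributors 9,
Dataset 5, Funders 5, Instrument 2, Image 8, Specimen 5, Publication 0),
universal DOI support across Contributors and Funders, and the count of 19
DOI-supporting required fields — and fails loudly rather than returning a
partial registry. The registry ships as version 1.0.0 under
major.minor.patch semantic versioning; the patch digit is this package's
own.

The standard publishes exact names, definitions, allowable values and DOI
flags only for the 34 required and conditionally required fields; the
optional fields are described in category prose. Optional field names here
(`generalModality`, `sizeX`, `landmarkName`, `objectiveNA`,
`relatedIdentifier`, `Organ`, …) are synthesized in camelCase from those
descriptions, chosen to satisfy the per-category totals. Each field carries
a `provenance` tag — `required-table` or `synthesized-from-prose` — so the
synthesized names are auditable and individually replaceable without
touching any logic. The same applies to four closed vocabularies the prose
implies but does not enumerate (`relatedIdentifierType`, `relationType`)
or types as free text with suggestions (immersion, illumination, detector):
these use DataCite- and OME-conventional value sets.

## Requirement semantics

Three requirement levels, with a derived notion of "submission-required":

- `required` — unconditionally required; absence is `REQUIRED_MISSING`.
- `conditional` — required only when its trigger holds. Three triggers
  exist: `personal_name_type` (nameIdentifier and nameIdentifierScheme when
  a contributor's nameType is Personal → `COND_PERSONAL_ID`),
  `government_funded` (all five Funders fields → `COND_FUNDERS`), and
  `common_license` (rightsURI/rightsIdentifier).
- `optional` — everything else; all five Publication fields are optional.

`bil_required` (= not optional) counts the 34-field submission set.

The government-funding trigger has no field of its own in the standard, so
records carry an explicit `funding_declared` flag (default **true**, the
conservative choice for a repository whose depositors are mostly
agency-funded). It serializes as a top-level `fundingDeclared` JSON key and
as a single extra column on the Funders table. The common-license trigger
is not machine-decidable at all, so absence of rightsURI/rightsIdentifier
is never an error; a populated rightsIdentifier that does not look like an
SPDX token earns a `SPDX_HINT` warning. A funder entry that exists but is
incomplete is flagged regardless of the flag: an entry, once present, must
be whole (this also keeps the validator and the emitted JSON Schema in
exact agreement).

## Validation

The rule catalog is fixed and closed (15 codes; see `mms3d/issues.py`).
Severities are `error` (invalidates), `warning` (suspicious but legal) and
`advice` (style/curation guidance). Design points:

- **Vocabulary matching** is case-insensitive with the printed casing
  canonical: an exact match is silent, a casing-only mismatch is
  `VOCAB_CASE` advice, anything else is a `VOCAB_VIOLATION` error.
  Rationale: spreadsheet-sourced submissions drift in case long before they
  drift in substance.
- **Suggested values** for modality/technique/immersion/illumination/
  detector are advisory lists; misses are `SUGGESTED_VALUE_MISS` advice,
  never errors, because the standard types those fields as free text.
- **Identifier syntax** is checked per scheme: ORCID (4 hyphenated
  quartets) and ISNI (16 digits, hyphens optional) share the ISO 7064
  mod 11-2 check character (X = 10); ROR is `0` + 8 alphanumerics; RRID
  requires the `RRID:` prefix; GRID requires the `grid.` prefix. A leading
  resolver URL is stripped for every scheme. Only syntax is checked — no
  registry lookups, and species↔taxonomy-code pairings are not verified
  semantically (`TAXON_SYNTAX` is an all-digits check).
- **Profiles**: `bil` applies everything; `doi_only` keeps only issues on
  DOI-supporting fields plus the creator and funder presence rules (it
  gates the DataCite export); `lenient` downgrades the two conditional
  codes to warnings. Error sets are monotone: lenient ⊆ bil.
- **Ordering** is deterministic — categories in standard order, entries by
  index, rules in the order the walker applies them — and every issue on a
  field is reported (no short-circuiting).

All problems are reported, never raised; parsing is likewise total, with
its own issue codes (`UNKNOWN_FIELD`, `MULTIPLICITY`, `UNPARSEABLE`).
Unparseable numbers and colors are kept verbatim in the record so reports
can point at the offending text and serialization can echo it back.

## Carriers

The JSON form is a tree keyed by category, then field name; Contributors,
Funders and Publication are arrays of entry objects; the Image block nests
`Channels` (one object per channel: Number, displayColor, Fluorophore,
excitation/emission wavelengths) and `Landmarks` arrays. Display colors
accept the `"255,0,0"`, `"(255, 0, 0)"` and `"[255,0,0]"` dialects on input
and always serialize as `"R,G,B"`. The donor-age sentinel `unknown` is
accepted case-insensitively and canonicalized to lowercase. Key order is
canonical (category order, then registry field order), so serialization is
byte-deterministic and `serialize ∘ parse` is an idempotent
canonicalization.

The tabular layout is declared normative for this package (the standard
describes a multi-tab spreadsheet but prints no cell-level layout): one
table per category with full registry headers in registry order; one row
per entry for the repeatable categories; exactly one data row for Dataset,
Instrument and Specimen; and an Image table with one row per channel, one
row per landmark (independently, in the landmark columns), and the scalar
Image fields on the first row. The canonical carrier is a directory of
per-category UTF-8 CSV files written with the standard library's `csv`
module for byte-exact control; the `.xlsx` adapter (openpyxl) maps the same
grid onto one sheet per category. Floats are written with `repr`, which
round-trips exactly.

## JSON-Schema emission

Schemas use the 2020-12 dialect: seven category documents
(`<category>_schema.json`) plus a combined `record_schema.json` that
composes them by `$ref`. Vocabulary fields become `enum`s, numeric fields
`number` (step sizes with `exclusiveMinimum: 0`), displayColor and
NCBITaxonomy become patterns, and Age is `anyOf` non-negative number /
`unknown`. Conditionals expressible in the dialect are encoded:
Personal-nameType identifier requirements as an `if`/`then` on contributor
items, the at-least-one-creator rule as an array `contains`, and the
funding trigger as a record-level `if`/`then` on `fundingDeclared`.
`additionalProperties` is false throughout, matching the parser's
unknown-field reporting. Emission is a pure function of the registry, so
identical registries yield byte-identical documents; agreement between the
validator and an independent schema engine on the emitted combined schema
is part of the test suite.

## Crosswalks and DataCite export

The crosswalk tabulates only the mappings the standard pins per category —
DataCite: Contributors 9, Funders 5, Dataset 8, Publication 3 (25 rows);
OME Data Model: Instrument 12, Image 15 (27 rows) — and invents none
beyond them, so `mapping_counts` totals are 25 and 27 by construction. The
19 DOI-supporting required fields are exactly the required fields with a
DataCite mapping. The exporter renders kernel-4 property names from one
internal tree (JSON canonical, XML derived via lxml); contributors flagged
as creators appear in `creators` and, with their role, in `contributors`.
Export refuses records that fail the `doi_only` profile and attaches the
report. The OME direction is a term-level mapping report only — no OME-XML
instance document is produced, since the standard's Instrument/Image values
lack the pixel-data context OME-XML requires.

## Synthetic records and fault injection

The generator emulates a plausible repository submission: 1–4 contributors
(the first always a creator; Personal contributors get checksum-valid
ORCIDs, Organizational ones ROR codes), 1–3 government funders, micron-scale
step sizes drawn log-uniformly (0.1–10 µm/px in X/Y), 1–4 channels with
standard fluorophores and laser lines, 0–3 publications, and mouse /
human / rat / zebrafish specimens with correct taxonomy codes. Optional
scalars fill with probability 0.35. Abstracts are seeded word salad — an
`abstract_min_words` option reproduces the ≥100-word guidance, which is
advisory, matching the standard's own phrasing. One RNG stream is derived
per record from (master seed, record index), so corpora are reproducible,
order-insensitive, and prefix-stable.

What the generator does **not** emulate: natural-language coherence,
real-world name/affiliation correlations, genuinely messy spreadsheet
input (stray units, merged cells), or semantically wrong but syntactically
legal values. Passing tests therefore demonstrate rule enforcement and
carrier fidelity, not robustness to every artifact of human data entry.

Fault injection gives each rule code a deterministic corruption recipe
(delete a required scalar, clear all creator flags, flip an ORCID check
digit, out-of-range color component, negative age, empty the channel
list, …) and returns ground-truth labels `(path, code)`. Recipes target
disjoint parts of the record so combinations compose; the one exception —
`CARDINALITY` empties the channel list that the channel-content recipes
need — is rejected explicitly and never sampled into the same record by
`generate_corpus`. `VOCAB_CASE` shares its target field with
`VOCAB_VIOLATION`, so random corpora sample only the error-level code.
Over labeled corpora the validator's recall is exactly 1 by test.

## Problem sizes and tolerances

Corpus-based properties (clean-pass, recall, round-trips, cross-engine
agreement) run on 200-record seeded corpora, and checksum agreement on
1,000 generated identifiers (half valid, half with a deliberately flipped
check character) — sizes at which every per-record property is exercised
across all generator branches many times over while the full suite stays
interactive. All structural counts are exact integers; all agreement
properties are asserted at 100%, with no tolerance: every quantity here is
deterministic given the seed.

## Known limitations

- Optional-field names beyond the required table are this package's
  synthesis; a submission authored against a different rendering of the
  optional fields will see `UNKNOWN_FIELD` issues rather than silent
  acceptance (by design, but worth knowing).
- Suggested-value lists are small snapshots of the community inventories
  they model, not live copies.
- Two further DataCite equivalences and fourteen further OME
  correspondences are sometimes attributed to the standard in aggregate;
  they are not identified per field anywhere, so the crosswalk deliberately
  omits them rather than guessing.
- No network lookups of any kind: ORCID/ROR/RRID existence, taxonomy
  validity and license texts are out of scope; checks are purely syntactic.
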