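"""Rule enforcement for 3D-MMS records.

The validator applies a fixed, documented rule catalog (see
``issues.VALIDATION_CODES``) covering presence, conditional requirements,
controlled vocabularies, cross-field consistency and identifier syntax.
All problems are reported in a :class:`ValidationReport`; nothing is
raised on bad metadata.

Identifier checks implement the ISO 7064 mod 11-2 check digit shared by
ORCID and ISNI, plus the structural rules for ROR, RRID and GRID codes.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
import re

from . import _fields
from .issues import SEVERITIES, VALIDATION_CODES, ValidationIssue
from .record import FUNDER_KEYS, MetadataRecord
from .registry import SchemaRegistry

__all__ = [
    "ValidationReport",
    "validate_record",
    "check_identifier",
    "summarize_report",
    "iso7064_mod11_2_check_character",
]

PROFILES = ("bil", "doi_only", "lenient")


@dataclass(frozen=True)
class ValidationReport:
    issues: tuple[ValidationIssue, ...]

    @property
    def counts(self) -> dict[str, int]:
        c = Counter(i.severity for i in self.issues)
        return {s: c.get(s, 0) for s in SEVERITIES}

    @property
    def n_errors(self) -> int:
        return self.counts["error"]

    @property
    def valid(self) -> bool:
        """A record is valid iff it has zero error-severity issues."""
        return self.n_errors == 0

    def by_code(self, code: str) -> list[ValidationIssue]:
        return [i for i in self.issues if i.code == code]

    def to_dict(self) -> dict:
        return {
            "valid": self.valid,
            "counts": self.counts,
            "issues": [
                {"path": i.path, "code": i.code, "severity": i.severity,
                 "message": i.message}
                for i in self.issues
            ],
        }


def summarize_report(report: ValidationReport) -> dict[str, int]:
    """Count issues per rule code; counts sum to the total issue count."""
    return dict(Counter(i.code for i in report.issues))


# ---------------------------------------------------------------------------
# identifier syntax
# ---------------------------------------------------------------------------

_RESOLVER_RE = re.compile(r"^https?://[^/\s]+/", re.IGNORECASE)


def _strip_resolver(value: str) -> str:
    return _RESOLVER_RE.sub("", value.strip())


def iso7064_mod11_2_check_character(digits: str) -> str:
    """Check character (0-9 or X) for a digit string under ISO 7064 mod 11-2."""
    total = 0
    for ch in digits:
        total = (total + int(ch)) * 2
    remainder = total % 11
    result = (12 - remainder) % 11
    return "X" if result == 10 else str(result)


def _check_mod11_2(body: str) -> bool:
    """True if the final character of ``body`` is the correct check digit."""
    return iso7064_mod11_2_check_character(body[:-1]) == body[-1].upper()


_ORCID_RE = re.compile(r"^\d{4}-\d{4}-\d{4}-\d{3}[\dX]$", re.IGNORECASE)
_ISNI_RE = re.compile(r"^\d{15}[\dX]$", re.IGNORECASE)
_ROR_RE = re.compile(r"^0[0-9a-z]{8}$")


def _identifier_problems(scheme: str, value: str) -> list[str]:
    bare = _strip_resolver(value)
    if scheme == "ORCID":
        if not _ORCID_RE.match(bare):
            return ["ORCID must be 16 characters in 4 hyphenated quartets "
                    f"(got {bare!r})"]
        if not _check_mod11_2(bare.replace("-", "")):
            return [f"ORCID {bare!r} fails its ISO 7064 mod 11-2 check digit"]
        return []
    if scheme == "ISNI":
        compact = bare.replace("-", "").replace(" ", "")
        if not _ISNI_RE.match(compact):
            return [f"ISNI must be 16 digits (got {bare!r})"]
        if not _check_mod11_2(compact):
            return [f"ISNI {bare!r} fails its ISO 7064 mod 11-2 check digit"]
        return []
    if scheme == "ROR":
        if not _ROR_RE.match(bare):
            return ["ROR identifiers start with '0' followed by 8 "
                    f"alphanumerics (got {bare!r})"]
        return []
    if scheme == "RRID":
        if not value.strip().startswith("RRID:"):
            return [f"RRID values carry the 'RRID:' prefix (got {value!r})"]
        return []
    if scheme == "GRID":
        if not bare.startswith("grid."):
            return [f"GRID identifiers carry the 'grid.' prefix (got {value!r})"]
        return []
    raise ValueError(
        f"unknown identifier scheme {scheme!r}; expected one of "
        f"{', '.join(_fields.IDENTIFIER_SCHEMES)}"
    )


def check_identifier(scheme: str, value: str, path: str = "") -> list[ValidationIssue]:
    """Syntax-check an identifier against its scheme's rules.

    A leading resolver URL (``https://orcid.org/…``) is tolerated for every
    scheme.  Unknown schemes raise ``ValueError``; syntactic problems come
    back as ``ID_SYNTAX`` issues.
    """
    return [
        ValidationIssue(path, "ID_SYNTAX", "error", msg)
        for msg in _identifier_problems(scheme, value)
    ]


# ---------------------------------------------------------------------------
# record validation
# ---------------------------------------------------------------------------

_SPDX_RE = re.compile(r"^[A-Za-z0-9][A-Za-z0-9.+-]*$")

# Per-category (json key, attr) of unconditionally required scalar fields.
_REQUIRED_SCALARS = {
    "Dataset": [("Title", "title"), ("Rights", "rights"), ("Abstract", "abstract")],
    "Image": [("xAxis", "x_axis"), ("yAxis", "y_axis"), ("zAxis", "z_axis"),
              ("stepSizeX", "step_size_x"), ("stepSizeY", "step_size_y"),
              ("stepSizeZ", "step_size_z")],
    "Instrument": [("MicroscopeType", "microscope_type"),
                   ("MicroscopeManufacturerAndModel",
                    "microscope_manufacturer_and_model")],
    "Specimen": [("Species", "species"), ("NCBITaxonomy", "ncbi_taxonomy"),
                 ("Age", "age"), ("Ageunit", "ageunit"), ("Sex", "sex")],
}

_REQUIRED_CONTRIBUTOR = [
    ("contributorName", "contributor_name"),
    ("Creator", "creator"),
    ("contributorType", "contributor_type"),
    ("nameType", "name_type"),
    ("affiliation", "affiliation"),
    ("affiliationIdentifier", "affiliation_identifier"),
    ("affiliationIdentifierScheme", "affiliation_identifier_scheme"),
]

_FUNDER_FIELDS = FUNDER_KEYS  # all five are conditionally required


class _Collector:
    def __init__(self) -> None:
        self.issues: list[ValidationIssue] = []

    def add(self, path: str, code: str, severity: str, message: str) -> None:
        self.issues.append(ValidationIssue(path, code, severity, message))


def _check_vocab(col, path, value, vocabulary, field_name):
    """Case-insensitive vocabulary check; casing drift is advice-level."""
    if value is None or not isinstance(value, str):
        if value is not None:
            col.add(path, "VOCAB_VIOLATION", "error",
                    f"{field_name} must be one of: {'; '.join(vocabulary)}")
        return
    if value in vocabulary:
        return
    lowered = {v.lower(): v for v in vocabulary}
    if value.lower() in lowered:
        col.add(path, "VOCAB_CASE", "advice",
                f"{value!r} matches {lowered[value.lower()]!r} except for "
                "casing; the printed casing is canonical")
        return
    col.add(path, "VOCAB_VIOLATION", "error",
            f"{value!r} is not an allowable value for {field_name} "
            f"({'; '.join(vocabulary)})")


def _is_number(v) -> bool:
    return isinstance(v, (int, float)) and not isinstance(v, bool)


def _check_suggested(col, path, value, suggested, field_name):
    if value is None or not suggested:
        return
    if str(value).strip().lower() not in {s.lower() for s in suggested}:
        col.add(path, "SUGGESTED_VALUE_MISS", "advice",
                f"{value!r} is not among the suggested values for "
                f"{field_name}; free text is accepted but suggested values "
                "aid archive-side categorization")


def validate_record(
    record: MetadataRecord,
    registry: SchemaRegistry,
    profile: str = "bil",
) -> ValidationReport:
    """Apply the full 3D-MMS rule catalog to one record.

    Profiles: ``bil`` enforces everything a repository submission needs;
    ``doi_only`` restricts checks to DOI-supporting fields (plus the
    at-least-one-creator rule); ``lenient`` downgrades conditional-rule
    errors (COND_FUNDERS, COND_PERSONAL_ID) to warnings.
    """
    if profile not in PROFILES:
        raise ValueError(f"unknown profile {profile!r}; expected one of {PROFILES}")
    col = _Collector()
    vocab = {
        "contributorType": _fields.CONTRIBUTOR_TYPES,
        "nameType": _fields.NAME_TYPES,
        "scheme": _fields.IDENTIFIER_SCHEMES,
        "axis": _fields.AXIS_DIRECTIONS,
        "ageunit": _fields.AGE_UNITS,
        "sex": _fields.SEXES,
        "relatedIdentifierType": _fields.RELATED_IDENTIFIER_TYPES,
        "relationType": _fields.RELATION_TYPES,
    }
    cond_severity = "warning" if profile == "lenient" else "error"

    # --- Contributors -----------------------------------------------------
    if not record.contributors:
        col.add("Contributors", "CARDINALITY", "error",
                "at least one contributor entry is required")
    creators = [
        e for e in record.contributors
        if e.creator is True or (isinstance(e.creator, str) and e.creator.lower() == "yes")
    ]
    if record.contributors and not creators:
        col.add("Contributors", "NO_CREATOR", "error",
                "there must be at least one creator")
    for i, e in enumerate(record.contributors):
        p = f"Contributors[{i}]"
        for key, attr in _REQUIRED_CONTRIBUTOR:
            if getattr(e, attr) is None:
                col.add(f"{p}.{key}", "REQUIRED_MISSING", "error",
                        f"required field {key} is missing")
        if isinstance(e.creator, str):
            _check_vocab(col, f"{p}.Creator", e.creator, _fields.YES_NO, "Creator")
        if e.contributor_type is not None:
            _check_vocab(col, f"{p}.contributorType", e.contributor_type,
                         vocab["contributorType"], "contributorType")
        if e.name_type is not None:
            _check_vocab(col, f"{p}.nameType", e.name_type, vocab["nameType"],
                         "nameType")
        if isinstance(e.name_type, str) and e.name_type.lower() == "personal":
            missing = [k for k, a in (("nameIdentifier", "name_identifier"),
                                      ("nameIdentifierScheme", "name_identifier_scheme"))
                       if getattr(e, a) is None]
            for k in missing:
                col.add(f"{p}.{k}", "COND_PERSONAL_ID", cond_severity,
                        f"{k} is required for Personal nameType")
        if e.name_identifier_scheme is not None:
            _check_vocab(col, f"{p}.nameIdentifierScheme", e.name_identifier_scheme,
                         vocab["scheme"], "nameIdentifierScheme")
        if (e.name_identifier is not None
                and e.name_identifier_scheme in _fields.IDENTIFIER_SCHEMES):
            col.issues.extend(check_identifier(
                e.name_identifier_scheme, e.name_identifier,
                f"{p}.nameIdentifier"))
        if e.affiliation_identifier_scheme is not None:
            _check_vocab(col, f"{p}.affiliationIdentifierScheme",
                         e.affiliation_identifier_scheme, vocab["scheme"],
                         "affiliationIdentifierScheme")
        if (e.affiliation_identifier is not None
                and e.affiliation_identifier_scheme in _fields.IDENTIFIER_SCHEMES):
            col.issues.extend(check_identifier(
                e.affiliation_identifier_scheme, e.affiliation_identifier,
                f"{p}.affiliationIdentifier"))

    # --- Funders ----------------------------------------------------------
    if record.funding_declared and not record.funders:
        col.add("Funders", "COND_FUNDERS", cond_severity,
                "Funders metadata is required for government-funded projects")
    for i, e in enumerate(record.funders):
        # a funder entry, once present, must be complete
        p = f"Funders[{i}]"
        for key, attr, _ in _FUNDER_FIELDS:
            if getattr(e, attr) is None:
                col.add(f"{p}.{key}", "COND_FUNDERS", cond_severity,
                        f"{key} is required for government-funded projects")
    for i, e in enumerate(record.funders):
        p = f"Funders[{i}]"
        if e.funding_reference_identifier_type is not None:
            _check_vocab(col, f"{p}.fundingReferenceIdentifierType",
                         e.funding_reference_identifier_type, vocab["scheme"],
                         "fundingReferenceIdentifierType")
        if (e.funding_reference_identifier is not None
                and e.funding_reference_identifier_type in _fields.IDENTIFIER_SCHEMES):
            col.issues.extend(check_identifier(
                e.funding_reference_identifier_type,
                e.funding_reference_identifier,
                f"{p}.fundingReferenceIdentifier"))

    # --- Dataset ----------------------------------------------------------
    d = record.dataset
    for key, attr in _REQUIRED_SCALARS["Dataset"]:
        if getattr(d, attr) is None:
            col.add(f"Dataset.{key}", "REQUIRED_MISSING", "error",
                    f"required field {key} is missing")
    if d.rights_identifier is not None and not _SPDX_RE.match(d.rights_identifier):
        col.add("Dataset.rightsIdentifier", "SPDX_HINT", "warning",
                f"{d.rights_identifier!r} does not look like an SPDX license "
                "identifier (see https://spdx.org/licenses)")
    _check_suggested(col, "Dataset.generalModality", d.general_modality,
                     _fields.SUGGESTED_MODALITIES, "generalModality")
    _check_suggested(col, "Dataset.Technique", d.technique,
                     _fields.SUGGESTED_TECHNIQUES, "Technique")

    # --- Image ------------------------------------------------------------
    img = record.image
    for key, attr in _REQUIRED_SCALARS["Image"]:
        if getattr(img, attr) is None:
            col.add(f"Image.{key}", "REQUIRED_MISSING", "error",
                    f"required field {key} is missing")
    for key, attr in (("xAxis", "x_axis"), ("yAxis", "y_axis"), ("zAxis", "z_axis")):
        if getattr(img, attr) is not None:
            _check_vocab(col, f"Image.{key}", getattr(img, attr), vocab["axis"], key)
    for key, attr in (("stepSizeX", "step_size_x"), ("stepSizeY", "step_size_y"),
                      ("stepSizeZ", "step_size_z")):
        v = getattr(img, attr)
        if _is_number(v) and v <= 0:
            col.add(f"Image.{key}", "STEP_NONPOSITIVE", "error",
                    f"{key} must be strictly positive, got {v}")
    if not img.channels:
        col.add("Image.Channels", "CARDINALITY", "error",
                "at least one channel entry is required")
    for i, ch in enumerate(img.channels):
        p = f"Image.Channels[{i}]"
        if ch.number is None:
            col.add(f"{p}.Number", "CHANNEL_MISMATCH", "error",
                    "channel entry is missing its channel Number")
        if ch.display_color is None:
            col.add(f"{p}.displayColor", "CHANNEL_MISMATCH", "error",
                    "channel entry is missing its displayColor")
        elif isinstance(ch.display_color, str):
            col.add(f"{p}.displayColor", "COLOR_FORMAT", "error",
                    f"{ch.display_color!r} is not an R,G,B integer triplet")
        elif not all(0 <= c <= 255 for c in ch.display_color):
            col.add(f"{p}.displayColor", "COLOR_FORMAT", "error",
                    f"displayColor components must be in [0, 255], got "
                    f"{ch.display_color}")

    # --- Instrument -------------------------------------------------------
    ins = record.instrument
    for key, attr in _REQUIRED_SCALARS["Instrument"]:
        if getattr(ins, attr) is None:
            col.add(f"Instrument.{key}", "REQUIRED_MISSING", "error",
                    f"required field {key} is missing")
    _check_suggested(col, "Instrument.objectiveImmersion", ins.objective_immersion,
                     _fields.SUGGESTED_IMMERSIONS, "objectiveImmersion")
    _check_suggested(col, "Instrument.detectorType", ins.detector_type,
                     _fields.SUGGESTED_DETECTORS, "detectorType")
    _check_suggested(col, "Instrument.illuminationType", ins.illumination_type,
                     _fields.SUGGESTED_ILLUMINATIONS, "illuminationType")

    # --- Publication ------------------------------------------------------
    for i, e in enumerate(record.publications):
        p = f"Publication[{i}]"
        if e.related_identifier_type is not None:
            _check_vocab(col, f"{p}.relatedIdentifierType",
                         e.related_identifier_type,
                         vocab["relatedIdentifierType"], "relatedIdentifierType")
        if e.relation_type is not None:
            _check_vocab(col, f"{p}.relationType", e.relation_type,
                         vocab["relationType"], "relationType")

    # --- Specimen ---------------------------------------------------------
    s = record.specimen
    for key, attr in _REQUIRED_SCALARS["Specimen"]:
        if getattr(s, attr) is None:
            col.add(f"Specimen.{key}", "REQUIRED_MISSING", "error",
                    f"required field {key} is missing")
    if s.ncbi_taxonomy is not None and not s.ncbi_taxonomy.isdigit():
        col.add("Specimen.NCBITaxonomy", "TAXON_SYNTAX", "error",
                f"{s.ncbi_taxonomy!r} is not an all-digit NCBI taxonomy code")
    if _is_number(s.age) and s.age < 0:
        col.add("Specimen.Age", "AGE_NEGATIVE", "error",
                f"age must be non-negative or 'unknown', got {s.age}")
    if isinstance(s.age, str) and s.age.lower() != "unknown":
        col.add("Specimen.Age", "AGE_NEGATIVE", "error",
                f"age must be a number or 'unknown', got {s.age!r}")
    if s.ageunit is not None:
        _check_vocab(col, "Specimen.Ageunit", s.ageunit, vocab["ageunit"], "Ageunit")
    if s.sex is not None:
        _check_vocab(col, "Specimen.Sex", s.sex, vocab["sex"], "Sex")

    issues = col.issues
    if profile == "doi_only":
        issues = [i for i in issues if _doi_relevant(i, registry)]
    return ValidationReport(issues=tuple(issues))


# field names, per category, that support DOI assignment (computed lazily
# from a default registry would re-enter build; the catalog is static)
def _doi_relevant(issue: ValidationIssue, registry: SchemaRegistry) -> bool:
    if issue.code in ("NO_CREATOR", "COND_FUNDERS", "CARDINALITY"):
        return not issue.path.startswith("Image")
    head = issue.path.split(".")[0].split("[")[0]
    leaf = issue.path.rsplit(".", 1)[-1].split("[")[0]
    if head not in ("Contributors", "Funders", "Dataset", "Publication"):
        return False
    try:
        return registry.field(head, leaf).doi_support
    except KeyError:
        return False
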