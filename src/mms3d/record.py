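"""In-memory model of one dataset's 3D-MMS metadata instance.

A :class:`MetadataRecord` holds the seven category blocks independent of
the on-disk carrier (JSON tree or per-category tables).  Parsing is
total: it always returns a record plus a list of issues — unknown keys,
wrong multiplicity and unparseable scalars are reported, never silently
dropped and never raised.
"""

from __future__ import annotations

import copy
import re
from dataclasses import dataclass, field as dc_field, fields as dc_fields

from .issues import ValidationIssue

__all__ = [
    "ContributorEntry",
    "FunderEntry",
    "ChannelEntry",
    "LandmarkEntry",
    "PublicationEntry",
    "DatasetBlock",
    "ImageBlock",
    "InstrumentBlock",
    "SpecimenBlock",
    "MetadataRecord",
    "parse_record",
    "serialize_record",
    "attach_common_metadata",
]


@dataclass
class ContributorEntry:
    contributor_name: str | None = None
    creator: bool | str | None = None  # "Yes"/"No" flag; raw text kept if unrecognized
    contributor_type: str | None = None
    name_type: str | None = None
    name_identifier: str | None = None
    name_identifier_scheme: str | None = None
    affiliation: str | None = None
    affiliation_identifier: str | None = None
    affiliation_identifier_scheme: str | None = None


@dataclass
class FunderEntry:
    funder_name: str | None = None
    funding_reference_identifier: str | None = None
    funding_reference_identifier_type: str | None = None
    award_number: str | None = None
    award_title: str | None = None


@dataclass
class ChannelEntry:
    number: str | None = None
    # canonical form is an (r, g, b) int tuple; unparseable input is kept
    # verbatim as text so the validator can report COLOR_FORMAT at its path
    display_color: tuple[int, int, int] | str | None = None
    fluorophore: str | None = None
    excitation_wavelength: float | int | str | None = None
    emission_wavelength: float | int | str | None = None


@dataclass
class LandmarkEntry:
    landmark_name: str | None = None
    landmark_x: float | int | str | None = None
    landmark_y: float | int | str | None = None
    landmark_z: float | int | str | None = None


@dataclass
class PublicationEntry:
    related_identifier: str | None = None
    related_identifier_type: str | None = None
    relation_type: str | None = None
    pmcid: str | None = None
    citation: str | None = None


@dataclass
class DatasetBlock:
    title: str | None = None
    rights: str | None = None
    rights_uri: str | None = None
    rights_identifier: str | None = None
    abstract: str | None = None
    general_modality: str | None = None
    technique: str | None = None
    methods: str | None = None
    technical_info: str | None = None
    keywords: str | None = None
    dataset_date: str | None = None
    dataset_doi: str | None = None
    acknowledgement: str | None = None
    embargo_until: str | None = None
    related_project_name: str | None = None


@dataclass
class ImageBlock:
    x_axis: str | None = None
    y_axis: str | None = None
    z_axis: str | None = None
    step_size_x: float | int | str | None = None
    step_size_y: float | int | str | None = None
    step_size_z: float | int | str | None = None
    channels: list[ChannelEntry] = dc_field(default_factory=list)
    landmarks: list[LandmarkEntry] = dc_field(default_factory=list)
    size_x: float | int | str | None = None
    size_y: float | int | str | None = None
    size_z: float | int | str | None = None
    number_of_files: float | int | str | None = None
    number_of_timepoints: float | int | str | None = None
    number_of_channels: float | int | str | None = None
    number_of_slices: float | int | str | None = None
    step_size_t: float | int | str | None = None
    oblique_x_dim1: str | None = None
    oblique_x_dim2: str | None = None
    oblique_x_dim3: str | None = None
    oblique_y_dim1: str | None = None
    oblique_y_dim2: str | None = None
    oblique_y_dim3: str | None = None
    oblique_z_dim1: str | None = None
    oblique_z_dim2: str | None = None
    oblique_z_dim3: str | None = None
    comments: str | None = None


@dataclass
class InstrumentBlock:
    microscope_type: str | None = None
    microscope_manufacturer_and_model: str | None = None
    objective_manufacturer: str | None = None
    objective_model: str | None = None
    objective_magnification: float | int | str | None = None
    objective_na: float | int | str | None = None
    objective_immersion: str | None = None
    detector_type: str | None = None
    detector_model: str | None = None
    illumination_type: str | None = None
    illumination_wavelength: float | int | str | None = None
    sample_temperature: float | int | str | None = None


@dataclass
class SpecimenBlock:
    species: str | None = None
    ncbi_taxonomy: str | None = None
    age: float | int | str | None = None  # number, or the sentinel "unknown"
    ageunit: str | None = None
    sex: str | None = None
    genotype: str | None = None
    strain: str | None = None
    organ: str | None = None
    organ_substructure: str | None = None
    locations: str | None = None
    atlas: str | None = None
    sample_preparation: str | None = None


@dataclass
class MetadataRecord:
    """One dataset's metadata instance across the seven categories."""

    dataset: DatasetBlock = dc_field(default_factory=DatasetBlock)
    contributors: list[ContributorEntry] = dc_field(default_factory=list)
    funders: list[FunderEntry] = dc_field(default_factory=list)
    image: ImageBlock = dc_field(default_factory=ImageBlock)
    instrument: InstrumentBlock = dc_field(default_factory=InstrumentBlock)
    publications: list[PublicationEntry] = dc_field(default_factory=list)
    specimen: SpecimenBlock = dc_field(default_factory=SpecimenBlock)
    # Declares that the government-funded profile applies, which makes the
    # Funders category required.  There is no 3D-MMS field carrying this, so
    # it travels as a top-level "fundingDeclared" key.
    funding_declared: bool = True

    def copy(self) -> "MetadataRecord":
        return copy.deepcopy(self)


# ---------------------------------------------------------------------------
# field maps: (JSON key, attribute, scalar kind) in registry field order
# ---------------------------------------------------------------------------

CONTRIBUTOR_KEYS = [
    ("contributorName", "contributor_name", "text"),
    ("Creator", "creator", "yesno"),
    ("contributorType", "contributor_type", "text"),
    ("nameType", "name_type", "text"),
    ("nameIdentifier", "name_identifier", "text"),
    ("nameIdentifierScheme", "name_identifier_scheme", "text"),
    ("affiliation", "affiliation", "text"),
    ("affiliationIdentifier", "affiliation_identifier", "text"),
    ("affiliationIdentifierScheme", "affiliation_identifier_scheme", "text"),
]

FUNDER_KEYS = [
    ("funderName", "funder_name", "text"),
    ("fundingReferenceIdentifier", "funding_reference_identifier", "text"),
    ("fundingReferenceIdentifierType", "funding_reference_identifier_type", "text"),
    ("awardNumber", "award_number", "text"),
    ("awardTitle", "award_title", "text"),
]

DATASET_KEYS = [
    ("Title", "title", "text"),
    ("Rights", "rights", "text"),
    ("rightsURI", "rights_uri", "text"),
    ("rightsIdentifier", "rights_identifier", "text"),
    ("Abstract", "abstract", "text"),
    ("generalModality", "general_modality", "text"),
    ("Technique", "technique", "text"),
    ("Methods", "methods", "text"),
    ("technicalInfo", "technical_info", "text"),
    ("Keywords", "keywords", "text"),
    ("datasetDate", "dataset_date", "text"),
    ("datasetDOI", "dataset_doi", "text"),
    ("Acknowledgement", "acknowledgement", "text"),
    ("embargoUntil", "embargo_until", "text"),
    ("relatedProjectName", "related_project_name", "text"),
]

CHANNEL_KEYS = [
    ("Number", "number", "text"),
    ("displayColor", "display_color", "color"),
    ("Fluorophore", "fluorophore", "text"),
    ("excitationWavelength", "excitation_wavelength", "number"),
    ("emissionWavelength", "emission_wavelength", "number"),
]

LANDMARK_KEYS = [
    ("landmarkName", "landmark_name", "text"),
    ("landmarkX", "landmark_x", "number"),
    ("landmarkY", "landmark_y", "number"),
    ("landmarkZ", "landmark_z", "number"),
]

# Image scalars, in registry order; Channels and Landmarks lists are emitted
# at the position of their first member field.
IMAGE_SCALAR_KEYS = [
    ("xAxis", "x_axis", "text"),
    ("yAxis", "y_axis", "text"),
    ("zAxis", "z_axis", "text"),
    ("stepSizeX", "step_size_x", "number"),
    ("stepSizeY", "step_size_y", "number"),
    ("stepSizeZ", "step_size_z", "number"),
    ("sizeX", "size_x", "number"),
    ("sizeY", "size_y", "number"),
    ("sizeZ", "size_z", "number"),
    ("numberOfFiles", "number_of_files", "number"),
    ("numberOfTimepoints", "number_of_timepoints", "number"),
    ("numberOfChannels", "number_of_channels", "number"),
    ("numberOfSlices", "number_of_slices", "number"),
    ("stepSizeT", "step_size_t", "number"),
    ("obliqueXDim1", "oblique_x_dim1", "text"),
    ("obliqueXDim2", "oblique_x_dim2", "text"),
    ("obliqueXDim3", "oblique_x_dim3", "text"),
    ("obliqueYDim1", "oblique_y_dim1", "text"),
    ("obliqueYDim2", "oblique_y_dim2", "text"),
    ("obliqueYDim3", "oblique_y_dim3", "text"),
    ("obliqueZDim1", "oblique_z_dim1", "text"),
    ("obliqueZDim2", "oblique_z_dim2", "text"),
    ("obliqueZDim3", "oblique_z_dim3", "text"),
    ("Comments", "comments", "text"),
]

INSTRUMENT_KEYS = [
    ("MicroscopeType", "microscope_type", "text"),
    ("MicroscopeManufacturerAndModel", "microscope_manufacturer_and_model", "text"),
    ("objectiveManufacturer", "objective_manufacturer", "text"),
    ("objectiveModel", "objective_model", "text"),
    ("objectiveMagnification", "objective_magnification", "number"),
    ("objectiveNA", "objective_na", "number"),
    ("objectiveImmersion", "objective_immersion", "text"),
    ("detectorType", "detector_type", "text"),
    ("detectorModel", "detector_model", "text"),
    ("illuminationType", "illumination_type", "text"),
    ("illuminationWavelength", "illumination_wavelength", "number"),
    ("sampleTemperature", "sample_temperature", "number"),
]

PUBLICATION_KEYS = [
    ("relatedIdentifier", "related_identifier", "text"),
    ("relatedIdentifierType", "related_identifier_type", "text"),
    ("relationType", "relation_type", "text"),
    ("PMCID", "pmcid", "text"),
    ("Citation", "citation", "text"),
]

SPECIMEN_KEYS = [
    ("Species", "species", "text"),
    ("NCBITaxonomy", "ncbi_taxonomy", "text"),
    ("Age", "age", "age"),
    ("Ageunit", "ageunit", "text"),
    ("Sex", "sex", "text"),
    ("Genotype", "genotype", "text"),
    ("Strain", "strain", "text"),
    ("Organ", "organ", "text"),
    ("OrganSubstructure", "organ_substructure", "text"),
    ("Locations", "locations", "text"),
    ("Atlas", "atlas", "text"),
    ("samplePreparation", "sample_preparation", "text"),
]


_COLOR_RE = re.compile(r"^\s*[\(\[]?\s*(\d+)\s*,\s*(\d+)\s*,\s*(\d+)\s*[\)\]]?\s*$")


def parse_color(value) -> tuple[int, int, int] | str | None:
    """Parse a display color from any accepted dialect.

    Accepts ``"255,0,0"``, ``"(255, 0, 0)"``, ``"[255,0,0]"`` and a
    three-integer sequence.  Unparseable input is returned verbatim so the
    validator can point at it.
    """
    if value is None:
        return None
    if isinstance(value, (list, tuple)):
        if len(value) == 3 and all(isinstance(v, int) and not isinstance(v, bool) for v in value):
            return (value[0], value[1], value[2])
        return str(value)
    m = _COLOR_RE.match(str(value))
    if m:
        return tuple(int(g) for g in m.groups())  # type: ignore[return-value]
    return str(value)


def format_color(value) -> str:
    if isinstance(value, tuple):
        return "%d,%d,%d" % value
    return str(value)


def _parse_scalar(kind: str, value, path: str, issues: list[ValidationIssue]):
    """Parse one cell/leaf into canonical form.  Returns None for blanks."""
    if value is None:
        return None
    if isinstance(value, str) and value.strip() == "":
        return None
    if isinstance(value, (dict, list)) and kind != "color":
        issues.append(
            ValidationIssue(path, "MULTIPLICITY", "warning",
                            f"expected a scalar value, got {type(value).__name__}")
        )
        return None
    if kind == "text":
        return str(value).strip() if isinstance(value, str) else str(value)
    if kind == "yesno":
        if isinstance(value, bool):
            return value
        token = str(value).strip()
        if token.lower() == "yes":
            return True
        if token.lower() == "no":
            return False
        return token  # validator reports VOCAB_VIOLATION
    if kind == "color":
        return parse_color(value)
    if kind in ("number", "age"):
        if isinstance(value, bool):
            issues.append(
                ValidationIssue(path, "UNPARSEABLE", "warning",
                                "expected a number, got a boolean")
            )
            return str(value)
        if isinstance(value, (int, float)):
            return value
        token = str(value).strip()
        if kind == "age" and token.lower() == "unknown":
            return "unknown"
        try:
            return int(token)
        except ValueError:
            pass
        try:
            return float(token)
        except ValueError:
            issues.append(
                ValidationIssue(path, "UNPARSEABLE", "warning",
                                f"could not parse {token!r} as a number")
            )
            return token
    raise AssertionError(f"unknown scalar kind {kind!r}")


def _parse_object(obj, keymap, target, path, issues):
    """Copy recognized keys of a mapping onto a dataclass instance."""
    if not isinstance(obj, dict):
        issues.append(
            ValidationIssue(path, "MULTIPLICITY", "warning",
                            f"expected an object, got {type(obj).__name__}")
        )
        return target
    known = {k for k, _, _ in keymap}
    for key in obj:
        if key not in known:
            issues.append(
                ValidationIssue(f"{path}.{key}" if path else key,
                                "UNKNOWN_FIELD", "warning",
                                f"{key!r} is not a 3D-MMS field")
            )
    for key, attr, kind in keymap:
        if key in obj:
            setattr(target, attr,
                    _parse_scalar(kind, obj[key], f"{path}.{key}" if path else key, issues))
    return target


def _parse_entries(value, keymap, cls, path, issues):
    if value is None:
        return []
    if isinstance(value, dict):
        issues.append(
            ValidationIssue(path, "MULTIPLICITY", "warning",
                            "expected a list of entries, got a single object")
        )
        value = [value]
    if not isinstance(value, list):
        issues.append(
            ValidationIssue(path, "MULTIPLICITY", "warning",
                            f"expected a list of entries, got {type(value).__name__}")
        )
        return []
    return [
        _parse_object(item, keymap, cls(), f"{path}[{i}]", issues)
        for i, item in enumerate(value)
    ]


def parse_record(document: dict) -> tuple[MetadataRecord, list[ValidationIssue]]:
    """Parse a category-keyed JSON tree into a :class:`MetadataRecord`.

    Parsing is total: every anomaly becomes an issue and the best-effort
    record is still returned.  Raises ``TypeError`` only if ``document``
    is not a mapping at all.
    """
    if not isinstance(document, dict):
        raise TypeError(f"record document must be a mapping, got {type(document).__name__}")
    issues: list[ValidationIssue] = []
    rec = MetadataRecord()

    known_top = {"Contributors", "Funders", "Dataset", "Image", "Instrument",
                 "Publication", "Specimen", "fundingDeclared"}
    for key in document:
        if key not in known_top:
            issues.append(
                ValidationIssue(key, "UNKNOWN_FIELD", "warning",
                                f"{key!r} is not a 3D-MMS category")
            )

    rec.contributors = _parse_entries(
        document.get("Contributors"), CONTRIBUTOR_KEYS, ContributorEntry,
        "Contributors", issues)
    rec.funders = _parse_entries(
        document.get("Funders"), FUNDER_KEYS, FunderEntry, "Funders", issues)
    if "Dataset" in document:
        _parse_object(document["Dataset"], DATASET_KEYS, rec.dataset, "Dataset", issues)
    if "Image" in document:
        img = document["Image"]
        if isinstance(img, dict):
            scalars = {k: v for k, v in img.items() if k not in ("Channels", "Landmarks")}
            _parse_object(scalars, IMAGE_SCALAR_KEYS, rec.image, "Image", issues)
            rec.image.channels = _parse_entries(
                img.get("Channels"), CHANNEL_KEYS, ChannelEntry,
                "Image.Channels", issues)
            rec.image.landmarks = _parse_entries(
                img.get("Landmarks"), LANDMARK_KEYS, LandmarkEntry,
                "Image.Landmarks", issues)
        else:
            issues.append(
                ValidationIssue("Image", "MULTIPLICITY", "warning",
                                f"expected an object, got {type(img).__name__}"))
    if "Instrument" in document:
        _parse_object(document["Instrument"], INSTRUMENT_KEYS, rec.instrument,
                      "Instrument", issues)
    rec.publications = _parse_entries(
        document.get("Publication"), PUBLICATION_KEYS, PublicationEntry,
        "Publication", issues)
    if "Specimen" in document:
        _parse_object(document["Specimen"], SPECIMEN_KEYS, rec.specimen,
                      "Specimen", issues)

    fd = document.get("fundingDeclared", True)
    if isinstance(fd, bool):
        rec.funding_declared = fd
    elif isinstance(fd, str) and fd.strip().lower() in ("yes", "no", "true", "false"):
        rec.funding_declared = fd.strip().lower() in ("yes", "true")
    else:
        issues.append(
            ValidationIssue("fundingDeclared", "UNPARSEABLE", "warning",
                            f"could not parse {fd!r} as a flag"))
    return rec, issues


def _serialize_scalar(kind: str, value):
    if value is None:
        return None
    if kind == "yesno":
        if isinstance(value, bool):
            return "Yes" if value else "No"
        return value
    if kind == "color":
        return format_color(value)
    return value


def _serialize_object(obj, keymap) -> dict:
    out = {}
    for key, attr, kind in keymap:
        v = _serialize_scalar(kind, getattr(obj, attr))
        if v is not None:
            out[key] = v
    return out


def serialize_record(record: MetadataRecord) -> dict:
    """Serialize to the canonical category-keyed JSON tree.

    Key order is deterministic (category order, registry field order);
    absent values are omitted; repeated entries are ordered lists; display
    colors come out as ``"R,G,B"`` text.  ``serialize ∘ parse`` is a
    canonicalization and ``parse ∘ serialize`` is the identity.
    """
    doc: dict = {}
    doc["Contributors"] = [_serialize_object(e, CONTRIBUTOR_KEYS) for e in record.contributors]
    doc["Funders"] = [_serialize_object(e, FUNDER_KEYS) for e in record.funders]
    doc["Dataset"] = _serialize_object(record.dataset, DATASET_KEYS)

    img: dict = {}
    for key, attr, kind in IMAGE_SCALAR_KEYS:
        v = _serialize_scalar(kind, getattr(record.image, attr))
        if v is not None:
            img[key] = v
        if key == "stepSizeZ":
            img["Channels"] = [_serialize_object(c, CHANNEL_KEYS) for c in record.image.channels]
            if record.image.landmarks:
                img["Landmarks"] = [
                    _serialize_object(l, LANDMARK_KEYS) for l in record.image.landmarks
                ]
    doc["Image"] = img
    doc["Instrument"] = _serialize_object(record.instrument, INSTRUMENT_KEYS)
    doc["Publication"] = [_serialize_object(e, PUBLICATION_KEYS) for e in record.publications]
    doc["Specimen"] = _serialize_object(record.specimen, SPECIMEN_KEYS)
    doc["fundingDeclared"] = record.funding_declared
    return doc


def _is_blank_block(block) -> bool:
    return all(
        getattr(block, f.name) in (None, [], ()) for f in dc_fields(block)
    )


def attach_common_metadata(
    records: list[MetadataRecord], shared: MetadataRecord
) -> list[MetadataRecord]:
    """Append shared Contributors/Funders entries to every record.

    ``shared`` must contain only Contributors and/or Funders content
    (submission portals collect these once for a series of datasets).
    Entries already present in a record (all fields equal) are not
    appended twice, so the operation is idempotent.
    """
    if not (
        _is_blank_block(shared.dataset)
        and _is_blank_block(shared.image)
        and _is_blank_block(shared.instrument)
        and _is_blank_block(shared.specimen)
        and not shared.publications
    ):
        raise ValueError(
            "shared metadata may contain only Contributors and Funders entries"
        )
    out = []
    for rec in records:
        new = rec.copy()
        for entry in shared.contributors:
            if entry not in new.contributors:
                new.contributors.append(copy.deepcopy(entry))
        for entry in shared.funders:
            if entry not in new.funders:
                new.funders.append(copy.deepcopy(entry))
        out.append(new)
    return out
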