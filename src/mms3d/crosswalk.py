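"""Crosswalks from 3D-MMS to the DataCite metadata kernel and the OME
Data Model, plus the DataCite export used for DOI minting.

The crosswalk tables contain exactly the mappings the standard pins per
category — DataCite: all 9 Contributors fields, all 5 Funders fields, 8
Dataset fields and 3 Publication fields (25 rows); OME: all 12
Instrument fields and 15 Image fields (27 rows).  No further mappings
are invented.

The DataCite export renders kernel-4 property names from one internal
tree; the JSON rendering is canonical and an XML rendering is derived
from it.
"""

from __future__ import annotations

from dataclasses import dataclass

from .record import MetadataRecord
from .registry import SchemaRegistry
from .validation import ValidationReport, validate_record

__all__ = [
    "CrosswalkRow",
    "crosswalk_table",
    "mapping_counts",
    "export_datacite",
    "datacite_xml",
    "DataCiteExportError",
]

TARGETS = ("DataCite", "OME")


@dataclass(frozen=True)
class CrosswalkRow:
    mms_field: str
    category: str
    target: str
    target_term: str
    mapping_kind: str  # "equivalent" or "mappable"


def crosswalk_table(registry: SchemaRegistry) -> tuple[CrosswalkRow, ...]:
    """All pinned crosswalk rows, derived from the registry's link columns."""
    rows = []
    for f in registry.iter_fields():
        if f.datacite_property:
            rows.append(CrosswalkRow(f.name, f.category, "DataCite",
                                     f.datacite_property, "equivalent"))
        if f.ome_term:
            rows.append(CrosswalkRow(f.name, f.category, "OME",
                                     f.ome_term, "equivalent"))
    seen = set()
    for r in rows:
        key = (r.mms_field, r.category, r.target)
        if key in seen:
            raise ValueError(f"duplicate crosswalk row {key}")
        seen.add(key)
    return tuple(rows)


def mapping_counts(
    registry: SchemaRegistry, target: str, category: str | None = None
) -> int:
    """Count pinned crosswalk rows for one target, optionally per category."""
    if target not in TARGETS:
        raise ValueError(f"unknown crosswalk target {target!r}; expected {TARGETS}")
    return sum(
        1
        for r in crosswalk_table(registry)
        if r.target == target and (category is None or r.category == category)
    )


class DataCiteExportError(ValueError):
    """The record fails the DOI profile; the report explains why."""

    def __init__(self, report: ValidationReport):
        self.report = report
        codes = sorted({i.code for i in report.issues if i.severity == "error"})
        super().__init__(
            "record fails DOI-profile validation "
            f"({report.n_errors} error(s): {', '.join(codes)})"
        )


def _is_creator(entry) -> bool:
    return entry.creator is True or (
        isinstance(entry.creator, str) and entry.creator.lower() == "yes"
    )


def _name_block(e) -> dict:
    out: dict = {"name": e.contributor_name}
    if e.name_type:
        out["nameType"] = e.name_type
    if e.name_identifier:
        ni = {"nameIdentifier": e.name_identifier}
        if e.name_identifier_scheme:
            ni["nameIdentifierScheme"] = e.name_identifier_scheme
        out["nameIdentifiers"] = [ni]
    if e.affiliation:
        aff: dict = {"name": e.affiliation}
        if e.affiliation_identifier:
            aff["affiliationIdentifier"] = e.affiliation_identifier
        if e.affiliation_identifier_scheme:
            aff["affiliationIdentifierScheme"] = e.affiliation_identifier_scheme
        out["affiliation"] = [aff]
    return out


def export_datacite(record: MetadataRecord, registry: SchemaRegistry) -> dict:
    """Render the DOI-supporting content of a record as a DataCite
    kernel-4 document.

    The record must pass the ``doi_only`` validation profile with zero
    errors; otherwise :class:`DataCiteExportError` is raised with the
    validation report attached.  Creators (contributors flagged as
    creators) are also listed as contributors with their role, matching
    the kernel's creators/contributors split.
    """
    report = validate_record(record, registry, profile="doi_only")
    if not report.valid:
        raise DataCiteExportError(report)

    doc: dict = {"schemaVersion": "http://datacite.org/schema/kernel-4"}
    d = record.dataset
    if d.dataset_doi:
        doc["identifiers"] = [{"identifier": d.dataset_doi, "identifierType": "DOI"}]

    doc["creators"] = [_name_block(e) for e in record.contributors if _is_creator(e)]
    contributors = []
    for e in record.contributors:
        block = _name_block(e)
        if e.contributor_type:
            block["contributorType"] = e.contributor_type
        contributors.append(block)
    doc["contributors"] = contributors

    if d.title is not None:
        doc["titles"] = [{"title": d.title}]
    if d.abstract is not None:
        doc["descriptions"] = [
            {"description": d.abstract, "descriptionType": "Abstract"}
        ]
    rights: dict = {}
    if d.rights is not None:
        rights["rights"] = d.rights
    if d.rights_uri is not None:
        rights["rightsUri"] = d.rights_uri
    if d.rights_identifier is not None:
        rights["rightsIdentifier"] = d.rights_identifier
    if rights:
        doc["rightsList"] = [rights]
    if d.keywords is not None:
        doc["subjects"] = [
            {"subject": s.strip()} for s in d.keywords.split(";") if s.strip()
        ]
    if d.dataset_date is not None:
        doc["dates"] = [{"date": d.dataset_date, "dateType": "Collected"}]

    if record.funders:
        doc["fundingReferences"] = []
        for e in record.funders:
            ref: dict = {}
            if e.funder_name is not None:
                ref["funderName"] = e.funder_name
            if e.funding_reference_identifier is not None:
                ref["funderIdentifier"] = e.funding_reference_identifier
            if e.funding_reference_identifier_type is not None:
                ref["funderIdentifierType"] = e.funding_reference_identifier_type
            if e.award_number is not None:
                ref["awardNumber"] = e.award_number
            if e.award_title is not None:
                ref["awardTitle"] = e.award_title
            doc["fundingReferences"].append(ref)

    related = []
    for e in record.publications:
        if e.related_identifier is None:
            continue
        rel: dict = {"relatedIdentifier": e.related_identifier}
        if e.related_identifier_type is not None:
            rel["relatedIdentifierType"] = e.related_identifier_type
        if e.relation_type is not None:
            rel["relationType"] = e.relation_type
        related.append(rel)
    if related:
        doc["relatedIdentifiers"] = related
    return doc


def datacite_xml(doc: dict) -> bytes:
    """Render the JSON export as a DataCite kernel-4 XML resource."""
    from lxml import etree

    NS = "http://datacite.org/schema/kernel-4"
    root = etree.Element(f"{{{NS}}}resource", nsmap={None: NS})

    def sub(parent, tag, text=None, **attrs):
        el = etree.SubElement(parent, f"{{{NS}}}{tag}")
        if text is not None:
            el.text = str(text)
        for k, v in attrs.items():
            el.set(k, str(v))
        return el

    def name_entry(parent, tag, block, name_tag):
        el = sub(parent, tag)
        sub(el, name_tag, block["name"],
            **({"nameType": block["nameType"]} if "nameType" in block else {}))
        if tag == "contributor" and "contributorType" in block:
            el.set("contributorType", block["contributorType"])
        for ni in block.get("nameIdentifiers", []):
            sub(el, "nameIdentifier", ni["nameIdentifier"],
                nameIdentifierScheme=ni.get("nameIdentifierScheme", ""))
        for aff in block.get("affiliation", []):
            attrs = {}
            if "affiliationIdentifier" in aff:
                attrs["affiliationIdentifier"] = aff["affiliationIdentifier"]
            if "affiliationIdentifierScheme" in aff:
                attrs["affiliationIdentifierScheme"] = aff["affiliationIdentifierScheme"]
            sub(el, "affiliation", aff["name"], **attrs)

    for ident in doc.get("identifiers", []):
        sub(root, "identifier", ident["identifier"],
            identifierType=ident["identifierType"])
    creators = sub(root, "creators")
    for c in doc.get("creators", []):
        name_entry(creators, "creator", c, "creatorName")
    contributors = sub(root, "contributors")
    for c in doc.get("contributors", []):
        name_entry(contributors, "contributor", c, "contributorName")
    if "titles" in doc:
        titles = sub(root, "titles")
        for t in doc["titles"]:
            sub(titles, "title", t["title"])
    if "descriptions" in doc:
        descs = sub(root, "descriptions")
        for t in doc["descriptions"]:
            sub(descs, "description", t["description"],
                descriptionType=t["descriptionType"])
    if "rightsList" in doc:
        rl = sub(root, "rightsList")
        for r in doc["rightsList"]:
            attrs = {}
            if "rightsUri" in r:
                attrs["rightsURI"] = r["rightsUri"]
            if "rightsIdentifier" in r:
                attrs["rightsIdentifier"] = r["rightsIdentifier"]
            sub(rl, "rights", r.get("rights"), **attrs)
    if "subjects" in doc:
        subjects = sub(root, "subjects")
        for s in doc["subjects"]:
            sub(subjects, "subject", s["subject"])
    if "dates" in doc:
        dates = sub(root, "dates")
        for t in doc["dates"]:
            sub(dates, "date", t["date"], dateType=t["dateType"])
    if "fundingReferences" in doc:
        frs = sub(root, "fundingReferences")
        for r in doc["fundingReferences"]:
            fr = sub(frs, "fundingReference")
            if "funderName" in r:
                sub(fr, "funderName", r["funderName"])
            if "funderIdentifier" in r:
                sub(fr, "funderIdentifier", r["funderIdentifier"],
                    funderIdentifierType=r.get("funderIdentifierType", "Other"))
            if "awardNumber" in r:
                sub(fr, "awardNumber", r["awardNumber"])
            if "awardTitle" in r:
                sub(fr, "awardTitle", r["awardTitle"])
    if "relatedIdentifiers" in doc:
        ris = sub(root, "relatedIdentifiers")
        for r in doc["relatedIdentifiers"]:
            sub(ris, "relatedIdentifier", r["relatedIdentifier"],
                relatedIdentifierType=r.get("relatedIdentifierType", ""),
                relationType=r.get("relationType", ""))
    return etree.tostring(root, pretty_print=True, xml_declaration=True,
                          encoding="UTF-8")
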