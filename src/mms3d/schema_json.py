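"""JSON-Schema emission from the registry.

One schema document per category plus a combined ``record_schema.json``
that composes the seven by reference, in the 2020-12 dialect.
Conditional requirements that the dialect can express are encoded with
``if``/``then`` (Personal-nameType identifiers, the government-funding
trigger); advisory rules (suggested values, the common-license SPDX
hint) stay in the validator.
"""

from __future__ import annotations

import json
from pathlib import Path

from . import _fields
from .registry import SchemaRegistry, FieldSpec

__all__ = ["emit_json_schema", "schema_filename", "write_schema_files"]

DIALECT = "https://json-schema.org/draft/2020-12/schema"

_NUMBER_OR_NUMERIC_TEXT = {"type": "number"}


def _scalar_schema(f: FieldSpec) -> dict:
    if f.name == "displayColor":
        return {
            "type": "string",
            "pattern": r"^\d{1,3},\d{1,3},\d{1,3}$",
            "description": f.definition,
        }
    if f.category == "Specimen" and f.name == "Age":
        return {
            "description": f.definition,
            "anyOf": [
                {"type": "number", "minimum": 0},
                {"type": "string", "pattern": "^[Uu]nknown$"},
            ],
        }
    if f.category == "Specimen" and f.name == "NCBITaxonomy":
        return {"type": "string", "pattern": "^[0-9]+$", "description": f.definition}
    if f.value_kind == "vocabulary":
        return {"type": "string", "enum": list(f.vocabulary), "description": f.definition}
    if f.value_kind == "number":
        sch = {"type": "number", "description": f.definition}
        if f.name.startswith("stepSize"):
            sch["exclusiveMinimum"] = 0
        return sch
    return {"type": "string", "description": f.definition}


def _entry_schema(fields: list[FieldSpec], required: list[str]) -> dict:
    sch: dict = {
        "type": "object",
        "properties": {f.name: _scalar_schema(f) for f in fields},
        "additionalProperties": False,
    }
    if required:
        sch["required"] = required
    return sch


def _category_schema(registry: SchemaRegistry, name: str) -> dict:
    cat = registry.category(name)
    fields = list(cat.ordered_fields)

    if name in ("Contributors", "Funders", "Publication"):
        required = [
            f.name for f in fields
            if f.requirement_level == "required"
            or (name == "Funders" and f.requirement_level == "conditional")
        ]
        items = _entry_schema(fields, required)
        if name == "Contributors":
            # nameIdentifier/-Scheme are required only for Personal nameType
            items["if"] = {"properties": {"nameType": {"const": "Personal"}},
                          "required": ["nameType"]}
            items["then"] = {"required": ["nameIdentifier", "nameIdentifierScheme"]}
        body: dict = {"type": "array", "items": items}
        if name == "Contributors":
            body["minItems"] = 1
            # at least one entry must be flagged as a creator
            body["contains"] = {"properties": {"Creator": {"const": "Yes"}},
                                "required": ["Creator"]}
        return body

    if name == "Image":
        scalars = [f for f in fields if f.entry_group is None]
        channels = [f for f in fields if f.entry_group == "Channels"]
        landmarks = [f for f in fields if f.entry_group == "Landmarks"]
        props = {f.name: _scalar_schema(f) for f in scalars}
        props["Channels"] = {
            "type": "array",
            "minItems": 1,
            "items": _entry_schema(
                channels, [f.name for f in channels if f.requirement_level == "required"]
            ),
        }
        props["Landmarks"] = {
            "type": "array",
            "items": _entry_schema(landmarks, []),
        }
        return {
            "type": "object",
            "properties": props,
            "required": [f.name for f in scalars if f.requirement_level == "required"]
            + ["Channels"],
            "additionalProperties": False,
        }

    required = [f.name for f in fields if f.requirement_level == "required"]
    return _entry_schema(fields, required)


def schema_filename(scope: str) -> str:
    return "record_schema.json" if scope == "all" else f"{scope.lower()}_schema.json"


def emit_json_schema(registry: SchemaRegistry, scope: str = "all") -> dict:
    """Emit JSON-Schema documents from the registry.

    ``scope`` is one category name (returns that category's schema) or
    ``"all"`` (returns a mapping of all eight file names to documents:
    seven category schemas plus the combined record schema).  Emission is
    deterministic: identical registries produce byte-identical documents.
    """
    if scope != "all" and scope not in _fields.CATEGORIES:
        raise ValueError(
            f"unknown scope {scope!r}; expected 'all' or one of "
            f"{', '.join(_fields.CATEGORIES)}"
        )
    if scope != "all":
        body = _category_schema(registry, scope)
        return {
            "$schema": DIALECT,
            "$id": schema_filename(scope),
            "title": f"3D-MMS {scope} category (v{registry.version})",
            **body,
        }

    combined: dict = {
        "$schema": DIALECT,
        "$id": schema_filename("all"),
        "title": f"3D-MMS metadata record (v{registry.version})",
        "type": "object",
        "$defs": {
            cat.name: _category_schema(registry, cat.name)
            for cat in registry.categories
        },
        "properties": {
            **{cat.name: {"$ref": f"#/$defs/{cat.name}"} for cat in registry.categories},
            "fundingDeclared": {
                "type": "boolean",
                "description": "True if the project is funded by government "
                "agencies, which makes the Funders category required.",
            },
        },
        "required": ["Contributors", "Dataset", "Image", "Instrument", "Specimen"],
        "additionalProperties": False,
        # government funding makes Funders mandatory with fully populated rows
        "if": {
            "anyOf": [
                {"properties": {"fundingDeclared": {"const": True}},
                 "required": ["fundingDeclared"]},
                {"not": {"required": ["fundingDeclared"]}},
            ]
        },
        "then": {
            "properties": {"Funders": {"minItems": 1}},
            "required": ["Funders"],
        },
    }
    out = {schema_filename("all"): combined}
    for cat in registry.categories:
        out[schema_filename(cat.name)] = emit_json_schema(registry, cat.name)
    return out


def write_schema_files(registry: SchemaRegistry, out_dir: str | Path) -> list[Path]:
    """Write the 7+1 schema files to ``out_dir``; returns the paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    docs = emit_json_schema(registry, "all")
    paths = []
    for fname, doc in docs.items():
        p = out_dir / fname
        p.write_text(json.dumps(doc, indent=2) + "\n", encoding="utf-8")
        paths.append(p)
    return paths
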