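"""The 3D-MMS schema registry.

The registry is the single source of truth for the standard: 91 metadata
fields in seven fixed-order categories (Contributors, Funders, Dataset,
Image, Instrument, Publication, Specimen), each field carrying its
definition, requirement level, controlled vocabulary, repeatability,
DOI-support flag and crosswalk links.  Everything else in the package —
parsing, validation, tabular headers, JSON-Schema emission, the DataCite
export — is driven by this data.
"""

from __future__ import annotations

import difflib
import warnings
from dataclasses import dataclass, field as dc_field

from . import _fields

__all__ = [
    "FieldSpec",
    "CategorySpec",
    "SchemaRegistry",
    "RegistryError",
    "FieldLookupError",
    "build_default_registry",
    "count_fields",
    "get_field",
    "registry_to_dict",
]

CATEGORY_ORDER = _fields.CATEGORIES

REQUIREMENT_LEVELS = ("required", "conditional", "optional")
CONDITIONS = ("none", "personal_name_type", "government_funded", "common_license")
VALUE_KINDS = ("free_text", "vocabulary", "number")


class RegistryError(RuntimeError):
    """An internal invariant of the standard's registry is violated."""


class FieldLookupError(KeyError):
    """A field name could not be resolved against the registry."""


@dataclass(frozen=True)
class FieldSpec:
    """Complete definition of one 3D-MMS metadata field."""

    name: str
    category: str
    definition: str
    value_kind: str = "free_text"
    vocabulary: tuple[str, ...] = ()
    suggested_values: tuple[str, ...] = ()
    requirement_level: str = "optional"
    condition: str = "none"
    condition_text: str = ""
    repeatable: bool = False
    max_occurrences: int | None = 1  # None = unbounded
    doi_support: bool = False
    datacite_property: str | None = None
    ome_term: str | None = None
    units: str | None = None
    entry_group: str | None = None  # "Channels" / "Landmarks" for Image
    provenance: str = "required-table"

    def __post_init__(self) -> None:
        if self.category not in CATEGORY_ORDER:
            raise RegistryError(f"unknown category {self.category!r}")
        if self.value_kind not in VALUE_KINDS:
            raise RegistryError(f"{self.name}: unknown value_kind {self.value_kind!r}")
        if self.requirement_level not in REQUIREMENT_LEVELS:
            raise RegistryError(
                f"{self.name}: unknown requirement_level {self.requirement_level!r}"
            )
        if self.condition not in CONDITIONS:
            raise RegistryError(f"{self.name}: unknown condition {self.condition!r}")
        if bool(self.vocabulary) != (self.value_kind == "vocabulary"):
            raise RegistryError(
                f"{self.name}: vocabulary must be non-empty iff value_kind=vocabulary"
            )
        if self.requirement_level == "conditional" and self.condition == "none":
            raise RegistryError(f"{self.name}: conditional field needs a condition")
        if self.requirement_level != "conditional" and self.condition != "none":
            raise RegistryError(
                f"{self.name}: condition given for non-conditional field"
            )
        if self.doi_support and not self.datacite_property:
            raise RegistryError(
                f"{self.name}: doi_support=True requires a datacite_property"
            )
        if self.max_occurrences is not None and self.max_occurrences < 1:
            raise RegistryError(f"{self.name}: max_occurrences must be positive")

    @property
    def bil_required(self) -> bool:
        """True if the field is required or conditionally required for
        repository submission (i.e., not optional)."""
        return self.requirement_level != "optional"


@dataclass(frozen=True)
class CategorySpec:
    name: str
    ordered_fields: tuple[FieldSpec, ...]

    def __post_init__(self) -> None:
        names = [f.name for f in self.ordered_fields]
        if len(set(names)) != len(names):
            raise RegistryError(f"duplicate field names in category {self.name}")

    def field_names(self) -> tuple[str, ...]:
        return tuple(f.name for f in self.ordered_fields)

    def __iter__(self):
        return iter(self.ordered_fields)


@dataclass(frozen=True)
class SchemaRegistry:
    """The versioned collection of all FieldSpecs, in category order."""

    version: str
    categories: tuple[CategorySpec, ...]
    _by_category: dict = dc_field(repr=False, compare=False, default_factory=dict)

    def __post_init__(self) -> None:
        self._by_category.update({c.name: c for c in self.categories})

    def category(self, name: str) -> CategorySpec:
        try:
            return self._by_category[name]
        except KeyError:
            raise FieldLookupError(
                f"unknown category {name!r}; expected one of {', '.join(CATEGORY_ORDER)}"
            ) from None

    def iter_fields(self):
        for cat in self.categories:
            yield from cat.ordered_fields

    def field(self, category: str, name: str) -> FieldSpec:
        for f in self.category(category).ordered_fields:
            if f.name == name:
                return f
        raise FieldLookupError(f"no field {name!r} in category {category}")


# Per-category totals and required (non-optional) totals the registry must
# reproduce; the standard prints both sets.
_EXPECTED_TOTALS = {
    "Contributors": 9,
    "Funders": 5,
    "Dataset": 15,
    "Image": 33,
    "Instrument": 12,
    "Publication": 5,
    "Specimen": 12,
}
_EXPECTED_REQUIRED = {
    "Contributors": 9,
    "Funders": 5,
    "Dataset": 5,
    "Image": 8,
    "Instrument": 2,
    "Publication": 0,
    "Specimen": 5,
}


def _check_invariants(reg: SchemaRegistry) -> None:
    if tuple(c.name for c in reg.categories) != CATEGORY_ORDER:
        raise RegistryError("categories out of order")
    total = sum(len(c.ordered_fields) for c in reg.categories)
    if total != 91:
        raise RegistryError(f"expected 91 fields, registry has {total}")
    for cat in reg.categories:
        n = len(cat.ordered_fields)
        if n != _EXPECTED_TOTALS[cat.name]:
            raise RegistryError(
                f"{cat.name}: expected {_EXPECTED_TOTALS[cat.name]} fields, got {n}"
            )
        n_req = sum(1 for f in cat if f.bil_required)
        if n_req != _EXPECTED_REQUIRED[cat.name]:
            raise RegistryError(
                f"{cat.name}: expected {_EXPECTED_REQUIRED[cat.name]} "
                f"required fields, got {n_req}"
            )
    if any(f.requirement_level != "optional" for f in reg.category("Publication")):
        raise RegistryError("all Publication fields must be optional")
    for cname in ("Contributors", "Funders"):
        if not all(f.doi_support for f in reg.category(cname)):
            raise RegistryError(f"all {cname} fields must support DOI assignment")
    n_doi_req = sum(1 for f in reg.iter_fields() if f.doi_support and f.bil_required)
    if n_doi_req != 19:
        raise RegistryError(f"expected 19 DOI-supporting required fields, got {n_doi_req}")


def build_default_registry() -> SchemaRegistry:
    """Build the built-in 3D-MMS v1.0.0 registry.

    Raises :class:`RegistryError` (never returns a partial registry) if the
    compiled field table violates any structural invariant of the standard.
    """
    categories = tuple(
        CategorySpec(
            name=cname,
            ordered_fields=tuple(
                FieldSpec(category=cname, **row) for row in _fields.FIELD_TABLE[cname]
            ),
        )
        for cname in CATEGORY_ORDER
    )
    reg = SchemaRegistry(version="1.0.0", categories=categories)
    _check_invariants(reg)
    return reg


def count_fields(
    registry: SchemaRegistry,
    category: str | None = None,
    requirement: str | None = None,
    doi_support: bool | None = None,
) -> int:
    """Count fields matching the conjunction of the supplied filters.

    ``requirement`` accepts the three requirement levels plus
    ``"bil_required"``, shorthand for "not optional" (the set a repository
    submission must carry).
    """
    if category is not None and category not in CATEGORY_ORDER:
        raise ValueError(
            f"unknown category {category!r}; expected one of {', '.join(CATEGORY_ORDER)}"
        )
    if requirement is not None and requirement not in (*REQUIREMENT_LEVELS, "bil_required"):
        raise ValueError(f"unknown requirement filter {requirement!r}")
    n = 0
    for f in registry.iter_fields():
        if category is not None and f.category != category:
            continue
        if requirement == "bil_required":
            if not f.bil_required:
                continue
        elif requirement is not None and f.requirement_level != requirement:
            continue
        if doi_support is not None and f.doi_support != doi_support:
            continue
        n += 1
    return n


def get_field(
    registry: SchemaRegistry, name: str, category: str | None = None
) -> FieldSpec:
    """Look up a field by its printed name.

    Lookup is case-sensitive; a case-insensitive fallback succeeds with a
    warning.  Unknown names raise :class:`FieldLookupError` with near-miss
    suggestions; a name present in more than one category must be
    disambiguated with ``category``.
    """
    cats = [registry.category(category)] if category else registry.categories
    exact = [f for c in cats for f in c if f.name == name]
    if len(exact) == 1:
        return exact[0]
    if len(exact) > 1:
        raise FieldLookupError(
            f"field name {name!r} occurs in categories "
            f"{[f.category for f in exact]}; pass category= to disambiguate"
        )
    ci = [f for c in cats for f in c if f.name.lower() == name.lower()]
    if len(ci) == 1:
        warnings.warn(
            f"field name {name!r} matched {ci[0].name!r} case-insensitively; "
            "the standard's printed spelling is preferred",
            UserWarning,
            stacklevel=2,
        )
        return ci[0]
    if len(ci) > 1:
        raise FieldLookupError(
            f"field name {name!r} is ambiguous across categories "
            f"{[f.category for f in ci]}; pass category= to disambiguate"
        )
    all_names = sorted({f.name for c in cats for f in c})
    near = difflib.get_close_matches(name, all_names, n=3, cutoff=0.6)
    hint = f"; did you mean {', '.join(repr(n) for n in near)}?" if near else ""
    raise FieldLookupError(f"no field named {name!r}{hint}")


def registry_to_dict(registry: SchemaRegistry) -> dict:
    """Machine-readable dump of every FieldSpec (used by docs generation)."""
    return {
        "standard": "3D-MMS",
        "version": registry.version,
        "categories": [
            {
                "name": cat.name,
                "fields": [
                    {
                        "name": f.name,
                        "definition": f.definition,
                        "value_kind": f.value_kind,
                        "vocabulary": list(f.vocabulary),
                        "suggested_values": list(f.suggested_values),
                        "requirement_level": f.requirement_level,
                        "condition": f.condition,
                        "condition_text": f.condition_text,
                        "repeatable": f.repeatable,
                        "max_occurrences": f.max_occurrences,
                        "doi_support": f.doi_support,
                        "datacite_property": f.datacite_property,
                        "ome_term": f.ome_term,
                        "units": f.units,
                        "entry_group": f.entry_group,
                        "provenance": f.provenance,
                    }
                    for f in cat.ordered_fields
                ],
            }
            for cat in registry.categories
        ],
    }
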