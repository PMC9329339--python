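"""Multi-table (spreadsheet-style) carrier for 3D-MMS records.

One rectangular table per category, header row of field names in
registry order.  Contributors, Funders and Publication hold one row per
entry; Dataset, Instrument and Specimen hold exactly one data row; the
Image table holds one row per channel (and, independently in the
landmark columns, one row per landmark) with the scalar Image fields on
the first row.

The canonical physical carrier is a directory of per-category CSV files
(UTF-8, comma, minimal quoting); a multi-sheet ``.xlsx`` workbook
adapter is provided on top of the same grid.  An extra trailing
``fundingDeclared`` column on the Funders table carries the
government-funding flag, which has no field of its own.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field as dc_field
from pathlib import Path

from .issues import ValidationIssue
from .record import (
    CHANNEL_KEYS,
    CONTRIBUTOR_KEYS,
    DATASET_KEYS,
    FUNDER_KEYS,
    IMAGE_SCALAR_KEYS,
    INSTRUMENT_KEYS,
    LANDMARK_KEYS,
    PUBLICATION_KEYS,
    SPECIMEN_KEYS,
    ChannelEntry,
    ContributorEntry,
    FunderEntry,
    LandmarkEntry,
    MetadataRecord,
    PublicationEntry,
    _parse_scalar,
    _serialize_scalar,
)
from .registry import SchemaRegistry

__all__ = [
    "TabularBundle",
    "read_tabular",
    "write_tabular",
    "read_csv_dir",
    "write_csv_dir",
    "read_workbook",
    "write_workbook",
]

_FUNDING_FLAG = "fundingDeclared"

_ENTRY_TABLES = {
    "Contributors": (CONTRIBUTOR_KEYS, ContributorEntry, "contributors"),
    "Funders": (FUNDER_KEYS, FunderEntry, "funders"),
    "Publication": (PUBLICATION_KEYS, PublicationEntry, "publications"),
}
_SCALAR_TABLES = {
    "Dataset": (DATASET_KEYS, "dataset"),
    "Instrument": (INSTRUMENT_KEYS, "instrument"),
    "Specimen": (SPECIMEN_KEYS, "specimen"),
}

# Image table columns: scalars, then channel columns, then landmark columns,
# matching registry field order.
_IMAGE_COLUMNS = (
    IMAGE_SCALAR_KEYS[:6] + CHANNEL_KEYS + IMAGE_SCALAR_KEYS[6:-1]
    + LANDMARK_KEYS + IMAGE_SCALAR_KEYS[-1:]
)


@dataclass
class TabularBundle:
    """Seven category tables, each a list of rows (row 0 = header)."""

    tables: dict[str, list[list[str]]] = dc_field(default_factory=dict)


def _cell(kind: str, value) -> str:
    v = _serialize_scalar(kind, value)
    if v is None:
        return ""
    if isinstance(v, bool):
        return "Yes" if v else "No"
    if isinstance(v, float):
        return repr(v)
    return str(v)


def write_tabular(record: MetadataRecord, registry: SchemaRegistry) -> TabularBundle:
    """Emit all seven tables with full registry headers in registry order.

    Empty optional columns are kept (template behavior: an empty record
    yields seven header-only templates, except Funders which carries the
    funding flag row).  Output is deterministic.
    """
    tables: dict[str, list[list[str]]] = {}

    for cname, (keymap, _, attr) in _ENTRY_TABLES.items():
        header = [k for k, _, _ in keymap]
        extra = [_FUNDING_FLAG] if cname == "Funders" else []
        rows = [header + extra]
        entries = getattr(record, attr)
        for i, entry in enumerate(entries):
            row = [_cell(kind, getattr(entry, a)) for _, a, kind in keymap]
            if cname == "Funders":
                row.append(_cell("yesno", record.funding_declared) if i == 0 else "")
            rows.append(row)
        if cname == "Funders" and not entries:
            rows.append([""] * len(header) + [_cell("yesno", record.funding_declared)])
        tables[cname] = rows

    for cname, (keymap, attr) in _SCALAR_TABLES.items():
        block = getattr(record, attr)
        header = [k for k, _, _ in keymap]
        row = [_cell(kind, getattr(block, a)) for _, a, kind in keymap]
        tables[cname] = [header, row]

    img = record.image
    header = [k for k, _, _ in _IMAGE_COLUMNS]
    n_rows = max(len(img.channels), len(img.landmarks), 1)
    rows = [header]
    for i in range(n_rows):
        row = []
        for key, attr, kind in _IMAGE_COLUMNS:
            if (key, attr, kind) in CHANNEL_KEYS:
                v = getattr(img.channels[i], attr) if i < len(img.channels) else None
            elif (key, attr, kind) in LANDMARK_KEYS:
                v = getattr(img.landmarks[i], attr) if i < len(img.landmarks) else None
            else:
                v = getattr(img, attr) if i == 0 else None
            row.append(_cell(kind, v))
        rows.append(row)
    tables["Image"] = rows

    ordered = {}
    for cname in ("Contributors", "Funders", "Dataset", "Image", "Instrument",
                  "Publication", "Specimen"):
        ordered[cname] = tables[cname]
    return TabularBundle(tables=ordered)


def _resolve_columns(header, keymap, category, issues, extra=()):
    """Map header names to (column index -> column spec); unknowns reported."""
    known = {k: (k, a, kind) for k, a, kind in keymap}
    cols = {}
    for j, name in enumerate(header):
        name = name.strip()
        if not name:
            continue
        if name in extra:
            cols[j] = (name, None, "flag")
        elif name in known:
            cols[j] = known[name]
        else:
            issues.append(ValidationIssue(
                f"{category}.{name}", "UNKNOWN_FIELD", "warning",
                f"{name!r} is not a 3D-MMS field in {category}; column ignored"))
    return cols


def read_tabular(
    bundle: TabularBundle, registry: SchemaRegistry
) -> tuple[MetadataRecord, list[ValidationIssue]]:
    """Convert a tabular bundle to a record.  All anomalies become issues."""
    issues: list[ValidationIssue] = []
    rec = MetadataRecord()

    for cname, (keymap, cls, attr) in _ENTRY_TABLES.items():
        rows = bundle.tables.get(cname)
        if not rows:
            continue
        extra = (_FUNDING_FLAG,) if cname == "Funders" else ()
        cols = _resolve_columns(rows[0], keymap, cname, issues, extra)
        entries = []
        for i, row in enumerate(rows[1:]):
            entry = cls()
            blank = True
            for j, (key, a, kind) in cols.items():
                raw = row[j] if j < len(row) else ""
                if kind == "flag":
                    if raw.strip():
                        rec.funding_declared = raw.strip().lower() in ("yes", "true")
                    continue
                v = _parse_scalar(kind, raw, f"{cname}[{i}].{key}", issues)
                if v is not None:
                    blank = False
                    setattr(entry, a, v)
            if not blank:
                entries.append(entry)
        setattr(rec, attr, entries)

    for cname, (keymap, attr) in _SCALAR_TABLES.items():
        rows = bundle.tables.get(cname)
        if not rows:
            continue
        cols = _resolve_columns(rows[0], keymap, cname, issues)
        block = getattr(rec, attr)
        for i, row in enumerate(rows[1:]):
            for j, (key, a, kind) in cols.items():
                raw = row[j] if j < len(row) else ""
                if raw.strip() == "":
                    continue
                if i > 0:
                    issues.append(ValidationIssue(
                        f"{cname}.{key}", "MULTIPLICITY", "warning",
                        f"{key} is single-occurrence; value on data row "
                        f"{i + 1} ignored"))
                    continue
                setattr(block, a, _parse_scalar(kind, raw, f"{cname}.{key}", issues))

    rows = bundle.tables.get("Image")
    if rows:
        channel_specs = {k for k, _, _ in CHANNEL_KEYS}
        landmark_specs = {k for k, _, _ in LANDMARK_KEYS}
        cols = _resolve_columns(rows[0], _IMAGE_COLUMNS, "Image", issues)
        channels: list[ChannelEntry] = []
        landmarks: list[LandmarkEntry] = []
        for i, row in enumerate(rows[1:]):
            ch, lm = ChannelEntry(), LandmarkEntry()
            ch_blank = lm_blank = True
            for j, (key, a, kind) in cols.items():
                raw = row[j] if j < len(row) else ""
                if raw.strip() == "":
                    continue
                if key in channel_specs:
                    setattr(ch, a, _parse_scalar(
                        kind, raw, f"Image.Channels[{i}].{key}", issues))
                    ch_blank = False
                elif key in landmark_specs:
                    setattr(lm, a, _parse_scalar(
                        kind, raw, f"Image.Landmarks[{i}].{key}", issues))
                    lm_blank = False
                elif i == 0:
                    setattr(rec.image, a, _parse_scalar(
                        kind, raw, f"Image.{key}", issues))
                else:
                    issues.append(ValidationIssue(
                        f"Image.{key}", "MULTIPLICITY", "warning",
                        f"{key} is single-occurrence; value on data row "
                        f"{i + 1} ignored"))
            if not ch_blank:
                channels.append(ch)
            if not lm_blank:
                landmarks.append(lm)
        rec.image.channels = channels
        rec.image.landmarks = landmarks

    return rec, issues


# ---------------------------------------------------------------------------
# physical carriers
# ---------------------------------------------------------------------------

_CSV_NAMES = {
    "Contributors": "contributors.csv",
    "Funders": "funders.csv",
    "Dataset": "dataset.csv",
    "Image": "image.csv",
    "Instrument": "instrument.csv",
    "Publication": "publication.csv",
    "Specimen": "specimen.csv",
}


def write_csv_dir(bundle: TabularBundle, out_dir: str | Path) -> list[Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for cname, rows in bundle.tables.items():
        p = out_dir / _CSV_NAMES[cname]
        with open(p, "w", newline="", encoding="utf-8") as fh:
            csv.writer(fh, lineterminator="\n").writerows(rows)
        paths.append(p)
    return paths


def read_csv_dir(in_dir: str | Path) -> TabularBundle:
    in_dir = Path(in_dir)
    tables = {}
    for cname, fname in _CSV_NAMES.items():
        p = in_dir / fname
        if not p.exists():
            continue
        with open(p, newline="", encoding="utf-8") as fh:
            tables[cname] = [list(row) for row in csv.reader(fh)]
    return TabularBundle(tables=tables)


def write_workbook(bundle: TabularBundle, path: str | Path) -> Path:
    """Write the bundle as a multi-sheet workbook (one sheet per category)."""
    from openpyxl import Workbook

    wb = Workbook()
    wb.remove(wb.active)
    for cname, rows in bundle.tables.items():
        ws = wb.create_sheet(title=cname)
        for row in rows:
            ws.append(row)
    path = Path(path)
    wb.save(path)
    return path


def read_workbook(path: str | Path) -> TabularBundle:
    from openpyxl import load_workbook

    wb = load_workbook(path, read_only=True, data_only=True)
    tables = {}
    for ws in wb.worksheets:
        if ws.title not in _CSV_NAMES:
            continue
        rows = [["" if c is None else str(c) for c in row]
                for row in ws.iter_rows(values_only=True)]
        tables[ws.title] = rows
    return TabularBundle(tables=tables)
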