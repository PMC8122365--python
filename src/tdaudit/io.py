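"""Readers and writers for trait-dictionary tables and name lists.

Three dialects are supported:

``td_template_v5``
    The Crop Ontology TD template: a delimited table with (at least)
    variable name, trait name and trait class columns.  Header names vary
    across published TDs, so headers are matched case-insensitively after
    trimming and can be overridden with a user column map.
``two_column``
    A minimal table with just ``trait name`` and ``trait class`` columns.
``namelist``
    Plain text, one trait name per line, no header.

Cells are trimmed but otherwise left untouched at read time; every
normalization (case folding, orthography, synonyms) is an explicit later
pass in :mod:`tdaudit.harmonize`.  Files must be UTF-8 (a byte-order mark
is tolerated); anything else is a hard error.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .model import (
    FormatError,
    MultiSpeciesTD,
    NameList,
    TDAuditError,
    TraitDescriptor,
    TraitDictionary,
    ValidationError,
)

__all__ = [
    "read_td",
    "read_multispecies",
    "write_td",
    "parse_xref",
    "DIALECTS",
    "DEFAULT_COLUMN_MAP",
]

DIALECTS = ("td_template_v5", "two_column", "namelist")

#: canonical field -> accepted header spellings (compared lowercased/trimmed)
DEFAULT_COLUMN_MAP: dict[str, tuple[str, ...]] = {
    "variable_id": ("variable id",),
    "variable_name": ("variable name",),
    "variable_synonyms": ("variable synonyms",),
    "trait_id": ("trait id",),
    "trait_name": ("trait name", "trait", "name"),
    "trait_class": ("trait class", "class"),
    "trait_description": ("trait description",),
    "method_name": ("method name",),
    "method_class": ("method class",),
    "scale_name": ("scale name",),
    "scale_class": ("scale class",),
    # several real TDs carry xrefs on the variable, others on the trait;
    # all such columns are pooled into TraitDescriptor.xrefs
    "xrefs": ("variable xref", "trait xref", "xref", "xrefs"),
}

_MANDATORY = {
    "td_template_v5": ("variable_name", "trait_name", "trait_class"),
    "two_column": ("trait_name",),
}

_V5_WRITE_ORDER = (
    ("Variable ID", "variable_id"),
    ("Variable name", "variable_name"),
    ("Variable synonyms", "variable_synonyms"),
    ("Trait ID", "trait_id"),
    ("Trait name", "trait_name"),
    ("Trait class", "trait_class"),
    ("Trait description", "trait_description"),
    ("Method name", "method_name"),
    ("Method class", "method_class"),
    ("Scale name", "scale_name"),
    ("Scale class", "scale_class"),
    ("Variable Xref", "xrefs"),
)


def parse_xref(cell: str) -> tuple[list[tuple[str, str]], list[str]]:
    """Parse an xref cell into ``(prefix, local_id)`` pairs.

    The cell is split on commas, semicolons and whitespace; each token is
    split at its first colon.  Tokens without a colon, or with an empty or
    non-alphanumeric prefix, are dropped and recorded as warnings rather
    than raised, so arbitrary cell content never aborts a read.

    Returns
    -------
    (xrefs, warnings)
        Parsed pairs in input order and one human-readable message per
        rejected token.  Together they partition the input tokens.
    """
    xrefs: list[tuple[str, str]] = []
    warnings: list[str] = []
    if cell is None:
        return xrefs, warnings
    tokens = [t for t in cell.replace(";", " ").replace(",", " ").split() if t]
    for tok in tokens:
        if ":" not in tok:
            warnings.append(f"xref token {tok!r} has no colon")
            continue
        prefix, local = tok.split(":", 1)
        prefix = prefix.strip().upper()
        local = local.strip()
        if not prefix or not prefix.isalnum() or not local:
            warnings.append(f"xref token {tok!r} is malformed")
            continue
        xrefs.append((prefix, local))
    return xrefs, warnings


def _delimiter_for(path: Path, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    return "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","


def _check_raw_header(path: Path, delimiter: str) -> None:
    # pandas mangles duplicate headers ("x", "x.1"), so duplicates must be
    # caught on the raw first line
    try:
        with open(path, newline="", encoding="utf-8-sig") as fh:
            first = next(csv.reader(fh, delimiter=delimiter), None)
    except UnicodeDecodeError as exc:
        raise FormatError(f"{path}: not valid UTF-8: {exc}") from exc
    if first is None:
        raise FormatError(f"{path}: file is empty")
    keys = [c.strip().lower() for c in first]
    dupes = sorted({k for k in keys if keys.count(k) > 1 and k})
    if dupes:
        raise FormatError(f"{path}: duplicate header {dupes[0]!r}")


def _read_table(path: Path, delimiter: str) -> pd.DataFrame:
    _check_raw_header(path, delimiter)
    try:
        frame = pd.read_csv(
            path,
            sep=delimiter,
            dtype=str,
            keep_default_na=False,
            encoding="utf-8-sig",
            skip_blank_lines=True,
            engine="python",
        )
    except UnicodeDecodeError as exc:
        raise FormatError(f"{path}: not valid UTF-8: {exc}") from exc
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: file is empty") from exc
    return frame


def _resolve_columns(
    headers: Sequence[str],
    column_map: Mapping[str, tuple[str, ...]],
    path: Path,
) -> dict[str, list[int]]:
    """Map canonical field names to column indices; unmatched headers are extras."""
    alias_to_field = {}
    for fieldname, aliases in column_map.items():
        for alias in aliases:
            alias_to_field[alias.strip().lower()] = fieldname
    seen_raw: dict[str, int] = {}
    resolved: dict[str, list[int]] = {}
    for idx, raw in enumerate(headers):
        key = str(raw).strip().lower()
        if key in seen_raw:
            raise FormatError(f"{path}: duplicate header {raw!r}")
        seen_raw[key] = idx
        fieldname = alias_to_field.get(key)
        if fieldname is None:
            continue
        if fieldname != "xrefs" and fieldname in resolved:
            raise FormatError(
                f"{path}: headers {raw!r} and column {resolved[fieldname][0]} "
                f"both map to {fieldname}"
            )
        resolved.setdefault(fieldname, []).append(idx)
    return resolved


def _split_list_cell(cell: str) -> list[str]:
    parts = [p.strip() for p in cell.replace(";", ",").split(",")]
    return [p for p in parts if p]


def read_td(
    path: str | Path,
    dialect: str = "td_template_v5",
    *,
    label: str | None = None,
    column_map: Mapping[str, tuple[str, ...]] | None = None,
    delimiter: str | None = None,
    warning_sink: list[str] | None = None,
) -> TraitDictionary | NameList:
    """Read one file as a :class:`TraitDictionary` or :class:`NameList`.

    Parameters
    ----------
    path
        Input file.  Delimiter defaults to tab for ``.tsv``, comma otherwise.
    dialect
        One of :data:`DIALECTS`.  ``namelist`` returns a :class:`NameList`;
        the table dialects return a :class:`TraitDictionary`.
    label
        Crop / source label; defaults to the file stem.
    column_map
        Overrides entries of :data:`DEFAULT_COLUMN_MAP` (canonical field
        name -> accepted header spellings).
    warning_sink
        If given, non-fatal parse warnings (malformed xref tokens) are
        appended to this list instead of being discarded.
    """
    path = Path(path)
    if dialect not in DIALECTS:
        raise ValidationError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")
    label = label if label is not None else path.stem

    if dialect == "namelist":
        try:
            text = path.read_text(encoding="utf-8-sig")
        except UnicodeDecodeError as exc:
            raise FormatError(f"{path}: not valid UTF-8: {exc}") from exc
        names = [line.strip() for line in text.splitlines()]
        names = [n for n in names if n]
        if not names:
            raise FormatError(f"{path}: name list is empty")
        return NameList(source_label=label, names=names)

    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update({k: tuple(v) for k, v in column_map.items()})
    frame = _read_table(path, _delimiter_for(path, delimiter))
    columns = _resolve_columns(list(frame.columns), cmap, path)
    for required in _MANDATORY[dialect]:
        if required not in columns:
            raise FormatError(f"{path}: missing mandatory column for {required!r}")

    known_idx = {i for idxs in columns.values() for i in idxs}
    extra_headers = [
        (i, str(h).strip()) for i, h in enumerate(frame.columns) if i not in known_idx
    ]

    descriptors: list[TraitDescriptor] = []
    for row_no, row in enumerate(frame.itertuples(index=False, name=None), start=2):
        cells = [str(c).strip() for c in row]
        if all(not c for c in cells):
            continue  # blank data row

        def cell(fieldname: str) -> str:
            idxs = columns.get(fieldname)
            return cells[idxs[0]] if idxs else ""

        name = cell("trait_name")
        if not name:
            if warning_sink is not None:
                warning_sink.append(f"{path}: row {row_no}: empty trait name, row skipped")
            continue
        xrefs: list[tuple[str, str]] = []
        for idx in columns.get("xrefs", []):
            parsed, warns = parse_xref(cells[idx])
            xrefs.extend(parsed)
            if warning_sink is not None:
                warning_sink.extend(f"{path}: row {row_no}: {w}" for w in warns)
        descriptors.append(
            TraitDescriptor(
                trait_name=name,
                variable_id=cell("variable_id") or None,
                variable_name=cell("variable_name"),
                variable_synonyms=_split_list_cell(cell("variable_synonyms")),
                trait_id=cell("trait_id") or None,
                trait_class=cell("trait_class"),
                trait_description=cell("trait_description"),
                method_name=cell("method_name"),
                method_class=cell("method_class"),
                scale_name=cell("scale_name"),
                scale_class=cell("scale_class"),
                xrefs=xrefs,
                extras={h: cells[i] for i, h in extra_headers},
            )
        )
    return TraitDictionary(crop_label=label, descriptors=descriptors)


def read_multispecies(
    paths: Iterable[tuple[str, str | Path]],
    dialect: str = "td_template_v5",
    **kwargs,
) -> MultiSpeciesTD:
    """Read several ``(crop_label, path)`` pairs into one multi-species TD.

    Dictionaries appear in input order; duplicate crop labels raise a
    :class:`ValidationError` naming the offending label.
    """
    pairs = list(paths)
    if not pairs:
        raise ValidationError("read_multispecies requires at least one path")
    dictionaries = []
    for crop_label, path in pairs:
        td = read_td(path, dialect, label=crop_label, **kwargs)
        if isinstance(td, NameList):
            raise ValidationError(
                f"{path}: dialect {dialect!r} yields a NameList, not a TraitDictionary"
            )
        dictionaries.append(td)
    return MultiSpeciesTD(dictionaries=dictionaries)


def _format_xrefs(xrefs: list[tuple[str, str]]) -> str:
    return "; ".join(f"{p}:{l}" for p, l in xrefs)


def write_td(
    td: TraitDictionary | NameList,
    path: str | Path,
    dialect: str = "td_template_v5",
    *,
    delimiter: str | None = None,
) -> Path:
    """Write a dictionary or name list; inverse of :func:`read_td`.

    Round-trip property: ``read_td(write_td(td), dialect)`` reproduces
    every descriptor field verbatim (xrefs serialize as ``PFX:localid``).
    """
    path = Path(path)
    if dialect not in DIALECTS:
        raise ValidationError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")

    if dialect == "namelist":
        if isinstance(td, TraitDictionary):
            lines = td.trait_names()
        else:
            lines = list(td.names)
        path.write_text("\n".join(lines) + ("\n" if lines else ""), encoding="utf-8")
        return path

    if isinstance(td, NameList):
        raise ValidationError(f"cannot write a NameList with dialect {dialect!r}")
    sep = _delimiter_for(path, delimiter)
    if dialect == "two_column":
        header = ["Trait name", "Trait class"]
        rows = [[d.trait_name, d.trait_class] for d in td.descriptors]
    else:
        extra_keys = sorted({k for d in td.descriptors for k in d.extras})
        header = [h for h, _ in _V5_WRITE_ORDER] + extra_keys
        rows = []
        for d in td.descriptors:
            row = [
                d.variable_id or "",
                d.variable_name,
                "; ".join(d.variable_synonyms),
                d.trait_id or "",
                d.trait_name,
                d.trait_class,
                d.trait_description,
                d.method_name,
                d.method_class,
                d.scale_name,
                d.scale_class,
                _format_xrefs(d.xrefs),
            ]
            row.extend(d.extras.get(k, "") for k in extra_keys)
            rows.append(row)
    try:
        with open(path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh, delimiter=sep, quoting=csv.QUOTE_MINIMAL)
            writer.writerow(header)
            writer.writerows(rows)
    except OSError as exc:
        raise TDAuditError(f"cannot write {path}: {exc}") from exc
    return path
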