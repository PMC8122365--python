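"""Core data model for Crop Ontology trait dictionaries.

A Trait Dictionary (TD) is a crop-specific controlled vocabulary: one row
per *variable*, where a variable binds a *trait* to a measurement *method*
and *scale*.  Rows may carry cross-references (xrefs) to external
ontologies such as the Plant Ontology (PO), the Plant Trait Ontology (TO)
or PATO.  A collection of per-crop dictionaries forms a multi-species TD,
the unit of all cross-crop consistency analyses in this package.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterator

__all__ = [
    "TDAuditError",
    "FormatError",
    "ValidationError",
    "UndefinedValueError",
    "TraitDescriptor",
    "TraitDictionary",
    "MultiSpeciesTD",
    "NameList",
    "CO_VARIABLE_ID_RE",
]


class TDAuditError(Exception):
    """Base class for all errors raised by tdaudit."""


class FormatError(TDAuditError):
    """A file does not conform to its declared dialect."""


class ValidationError(TDAuditError):
    """An in-memory object violates a model invariant."""


class UndefinedValueError(ValidationError):
    """A statistic is mathematically undefined for the given input."""


#: Crop Ontology term identifiers look like ``CO_366:0000181`` — a crop
#: root code followed by a seven-digit local id.
CO_VARIABLE_ID_RE = re.compile(r"^CO_\d+:\d{7}$")

_XREF_PREFIX_RE = re.compile(r"^[A-Z0-9]+$")


@dataclass
class TraitDescriptor:
    """One TD row: a variable with its trait, method and scale fields.

    Only ``trait_name`` is required; draft dictionaries frequently lack
    formal CO identifiers.  ``extras`` holds any columns of the source
    file that the reader did not recognise, so that writing a dictionary
    back out is lossless.
    """

    trait_name: str
    variable_id: str | None = None
    variable_name: str = ""
    variable_synonyms: list[str] = field(default_factory=list)
    trait_id: str | None = None
    trait_class: str = ""
    trait_description: str = ""
    method_name: str = ""
    method_class: str = ""
    scale_name: str = ""
    scale_class: str = ""
    xrefs: list[tuple[str, str]] = field(default_factory=list)
    extras: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.trait_name or not self.trait_name.strip():
            raise ValidationError("trait_name must be non-empty after trimming")
        self.trait_name = self.trait_name.strip()
        if self.variable_id is not None and not CO_VARIABLE_ID_RE.match(self.variable_id):
            raise ValidationError(
                f"variable_id {self.variable_id!r} does not match CO_<digits>:<7 digits>"
            )
        for prefix, _ in self.xrefs:
            if not _XREF_PREFIX_RE.match(prefix):
                raise ValidationError(
                    f"xref prefix {prefix!r} is not an uppercase alphanumeric token"
                )


@dataclass
class TraitDictionary:
    """A single crop's TD: an ordered list of descriptors.

    Row order is preserved exactly as read from file; deduplication is an
    explicit, separate operation (see :mod:`tdaudit.harmonize`).
    """

    crop_label: str
    descriptors: list[TraitDescriptor] = field(default_factory=list)
    co_root_code: str | None = None

    def __post_init__(self) -> None:
        if not self.crop_label or not self.crop_label.strip():
            raise ValidationError("crop_label must be non-empty")

    def __len__(self) -> int:
        return len(self.descriptors)

    def __iter__(self) -> Iterator[TraitDescriptor]:
        return iter(self.descriptors)

    def trait_names(self) -> list[str]:
        """All trait names in row order (duplicates retained)."""
        return [d.trait_name for d in self.descriptors]


@dataclass
class MultiSpeciesTD:
    """A named collection of per-crop trait dictionaries."""

    dictionaries: list[TraitDictionary] = field(default_factory=list)

    def __post_init__(self) -> None:
        labels = [td.crop_label for td in self.dictionaries]
        dupes = sorted({lab for lab in labels if labels.count(lab) > 1})
        if dupes:
            raise ValidationError(f"duplicate crop labels: {', '.join(dupes)}")

    @property
    def labels(self) -> list[str]:
        return [td.crop_label for td in self.dictionaries]

    def __len__(self) -> int:
        return len(self.dictionaries)

    def __iter__(self) -> Iterator[TraitDictionary]:
        return iter(self.dictionaries)

    def __getitem__(self, crop_label: str) -> TraitDictionary:
        for td in self.dictionaries:
            if td.crop_label == crop_label:
                return td
        raise KeyError(crop_label)


@dataclass
class NameList:
    """A plain list of trait names from one source (one name per line)."""

    source_label: str
    names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.source_label or not self.source_label.strip():
            raise ValidationError("source_label must be non-empty")
        for n in self.names:
            if not n or not n.strip():
                raise ValidationError("names must be non-empty strings")

    def __len__(self) -> int:
        return len(self.names)

    def __iter__(self) -> Iterator[str]:
        return iter(self.names)
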