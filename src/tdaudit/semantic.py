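"""Semantic-cohesion audits: xref coverage, class-label variants, conflicts.

Trait dictionaries gain semantic interoperability by cross-referencing
external ontologies (PO anatomy, TO traits, PATO qualities) and by
assigning each trait to one of eight de-facto standard trait classes.
This module measures how consistently a multi-crop collection does both:

* what fraction of distinct trait names carries at least one xref;
* which trait-class labels are mere spelling variants of one another
  (``quality`` vs ``quality trait`` vs ``quality traits``);
* which trait names are filed under genuinely different classes in
  different crops (e.g. a protein-content trait under ``biochemical``
  for one crop and ``quality`` for another).
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path

from .harmonize import DEFAULT_CONFIG, NormalizationConfig, name_key
from .model import MultiSpeciesTD, ValidationError

__all__ = [
    "STANDARD_TRAIT_CLASSES",
    "XrefReport",
    "ClassVariantGroup",
    "ClassConflict",
    "xref_coverage",
    "canonicalize_class_label",
    "class_variants",
    "class_conflicts",
    "write_conflicts_csv",
]

#: The eight top-level trait classes used, with minor label variation,
#: across published crop TDs.
STANDARD_TRAIT_CLASSES = (
    "abiotic stress",
    "biotic stress",
    "agronomical",
    "biochemical",
    "morphological",
    "phenological",
    "physiological",
    "quality",
)


def canonicalize_class_label(label: str) -> str:
    """Canonical form of a trait-class label.

    Lowercases, collapses whitespace and strips trailing ``trait`` /
    ``traits`` tokens (repeatedly, so the result is a fixed point), but
    never empties a label whose only content is such a token.

    >>> canonicalize_class_label("Quality Traits")
    'quality'
    """
    if label is None or not label.strip():
        raise ValidationError("cannot canonicalize an empty class label")
    tokens = label.casefold().split()
    while len(tokens) > 1 and tokens[-1] in ("trait", "traits"):
        tokens.pop()
    return " ".join(tokens)


@dataclass
class XrefReport:
    """Cross-reference coverage of a multi-crop collection.

    Distinct-name level: ``n_names`` distinct name keys across all crops,
    of which ``n_with_xref`` have at least one parsed xref on any of
    their rows in any TD.  Occurrence level: ``n_occurrences`` sums the
    per-crop unique-name counts (the same universe as the frequency
    analysis before cross-crop collapsing), so per-crop entries add up
    to the occurrence totals.
    """

    n_names: int
    n_with_xref: int
    n_occurrences: int
    n_occurrences_with_xref: int
    per_prefix_counts: dict[str, int] = field(default_factory=dict)
    per_crop: dict[str, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0 <= self.n_with_xref <= self.n_names:
            raise ValidationError("n_with_xref outside [0, n_names]")

    @property
    def percent(self) -> float:
        return 100.0 * self.n_with_xref / self.n_names if self.n_names else 0.0

    def to_json_dict(self) -> dict:
        return {
            "n_names": self.n_names,
            "n_with_xref": self.n_with_xref,
            "percent": self.percent,
            "percent_rounded": round(self.percent, 1),
            "n_occurrences": self.n_occurrences,
            "n_occurrences_with_xref": self.n_occurrences_with_xref,
            "per_prefix_counts": dict(sorted(self.per_prefix_counts.items())),
            "per_crop": {k: list(v) for k, v in self.per_crop.items()},
        }

    def write_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.to_json_dict(), indent=2) + "\n")
        return path


def xref_coverage(
    mstd: MultiSpeciesTD,
    mode: str = "raw_exact",
    config: NormalizationConfig = DEFAULT_CONFIG,
) -> XrefReport:
    """Measure how many trait names reference an external ontology.

    A name counts as referenced when any of its rows, in any crop, has at
    least one parsed xref.  Totals are over distinct name keys (the same
    universe as :func:`tdaudit.metrics.shared_name_frequencies`).
    """
    referenced: set[str] = set()
    universe: set[str] = set()
    per_prefix_names: dict[str, set[str]] = {}
    per_crop: dict[str, tuple[int, int]] = {}
    n_occ = 0
    n_occ_ref = 0
    for td in mstd:
        crop_names: set[str] = set()
        crop_ref: set[str] = set()
        for d in td.descriptors:
            k = name_key(d.trait_name, mode, config)
            crop_names.add(k)
            if d.xrefs:
                crop_ref.add(k)
                for prefix, _ in d.xrefs:
                    per_prefix_names.setdefault(prefix, set()).add(k)
        universe |= crop_names
        referenced |= crop_ref
        per_crop[td.crop_label] = (len(crop_names), len(crop_ref))
        n_occ += len(crop_names)
        n_occ_ref += len(crop_ref)
    return XrefReport(
        n_names=len(universe),
        n_with_xref=len(referenced),
        n_occurrences=n_occ,
        n_occurrences_with_xref=n_occ_ref,
        per_prefix_counts={p: len(s) for p, s in per_prefix_names.items()},
        per_crop=per_crop,
    )


@dataclass
class ClassVariantGroup:
    """Observed trait-class labels sharing one canonical form."""

    canonical_label: str
    variants: set[str]
    crops_using: dict[str, list[str]]

    @property
    def flagged(self) -> bool:
        """True when the same canonical class is spelt in ≥2 ways."""
        return len(self.variants) >= 2

    @property
    def is_standard(self) -> bool:
        return self.canonical_label in STANDARD_TRAIT_CLASSES


def class_variants(mstd: MultiSpeciesTD) -> list[ClassVariantGroup]:
    """Group observed class labels by canonical form; flag inconsistencies.

    Labels canonicalizing outside the eight standard classes are reported
    with ``is_standard=False`` rather than treated as errors.
    """
    groups: dict[str, dict[str, list[str]]] = {}
    for td in mstd:
        for d in td.descriptors:
            if not d.trait_class.strip():
                continue
            canon = canonicalize_class_label(d.trait_class)
            crops = groups.setdefault(canon, {}).setdefault(d.trait_class.strip(), [])
            if td.crop_label not in crops:
                crops.append(td.crop_label)
    return [
        ClassVariantGroup(
            canonical_label=canon,
            variants=set(variants.keys()),
            crops_using=variants,
        )
        for canon, variants in sorted(groups.items())
    ]


@dataclass
class ClassConflict:
    """One trait name filed under different canonical classes by crop."""

    trait_name: str
    assignments: dict[str, str]
    raw_assignments: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.assignments.values())) < 2:
            raise ValidationError(
                f"ClassConflict for {self.trait_name!r} needs ≥2 distinct classes"
            )


def class_conflicts(
    mstd: MultiSpeciesTD,
    mode: str = "raw_exact",
    config: NormalizationConfig = DEFAULT_CONFIG,
) -> list[ClassConflict]:
    """Find trait names whose canonical class differs across crops.

    Names are compared under the chosen matcher mode; class labels are
    compared after canonicalization, so pure spelling variants of a class
    never count as conflicts.  Per crop, the first row of a name defines
    its class (consistent with first-occurrence deduplication).  Results
    are sorted by name.
    """
    by_name: dict[str, dict[str, str]] = {}
    raw_by_name: dict[str, dict[str, str]] = {}
    display: dict[str, str] = {}
    for td in mstd:
        seen: set[str] = set()
        for d in td.descriptors:
            k = name_key(d.trait_name, mode, config)
            if k in seen:
                continue
            seen.add(k)
            if not d.trait_class.strip():
                continue
            display.setdefault(k, d.trait_name.strip())
            by_name.setdefault(k, {})[td.crop_label] = canonicalize_class_label(d.trait_class)
            raw_by_name.setdefault(k, {})[td.crop_label] = d.trait_class.strip()
    conflicts = []
    for k in sorted(by_name):
        assignments = by_name[k]
        if len(set(assignments.values())) >= 2:
            conflicts.append(
                ClassConflict(
                    trait_name=display[k],
                    assignments=assignments,
                    raw_assignments=raw_by_name[k],
                )
            )
    return conflicts


def write_conflicts_csv(conflicts: list[ClassConflict], path: str | Path) -> Path:
    """Long-form CSV: one row per (trait name, crop) assignment."""
    path = Path(path)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["trait_name", "crop", "raw_class", "canonical_class"])
        for c in conflicts:
            for crop, canon in c.assignments.items():
                writer.writerow([c.trait_name, crop, c.raw_assignments.get(crop, ""), canon])
    return path
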