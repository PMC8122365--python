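"""MIAPPE concept-coverage and FAIR-checklist reporting.

MIAPPE (Minimal Information About a Plant Phenotyping Experiment) v1.1
defines eleven concepts — investigation, study, person, data file,
biological material, environment, experimental factor, event,
observation unit, sample, observed variable — each with attributes of
stated obligation.  Given a mapping from the fields of some database
schema onto those attributes, :func:`assess_miappe` scores every concept
as *full* (all mandatory attributes mapped), *partial* or *absent*.

The FAIR side is a structured qualitative checklist over the fifteen
GO FAIR sub-principles (F1–F4, A1, A1.1, A1.2, A2, I1–I3, R1,
R1.1–R1.3): :func:`fair_checklist` completes a draft assessment,
filling unanswered principles as *unmet* and tallying statuses.

The v1.1 attribute reference data is bundled with the package
(``reference_data/miappe_v1_1.json``) under an explicit version tag.
Where the checklist leaves an attribute's obligation conditional it is
marked optional, so coverage scoring is conservative.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

from .model import ValidationError

__all__ = [
    "MiappeConcept",
    "SchemaMapping",
    "MappingEntry",
    "ComplianceReport",
    "FairEntry",
    "FairChecklist",
    "miappe_concepts",
    "assess_miappe",
    "fair_checklist",
    "load_mapping_csv",
    "load_cropstoredb_fixture",
    "FAIR_PRINCIPLES",
    "FAIR_STATUSES",
]

FAIR_PRINCIPLES: tuple[str, ...] = (
    "F1", "F2", "F3", "F4",
    "A1", "A1.1", "A1.2", "A2",
    "I1", "I2", "I3",
    "R1", "R1.1", "R1.2", "R1.3",
)

#: One-line reminders of what each GO FAIR sub-principle asks for.
FAIR_PRINCIPLE_TEXT = {
    "F1": "(Meta)data are assigned a globally unique and persistent identifier",
    "F2": "Data are described with rich metadata",
    "F3": "Metadata clearly and explicitly include the identifier of the data they describe",
    "F4": "(Meta)data are registered or indexed in a searchable resource",
    "A1": "(Meta)data are retrievable by their identifier using a standardized protocol",
    "A1.1": "The protocol is open, free and universally implementable",
    "A1.2": "The protocol allows for authentication and authorization where necessary",
    "A2": "Metadata are accessible even when the data are no longer available",
    "I1": "(Meta)data use a formal, accessible, shared and broadly applicable language",
    "I2": "(Meta)data use vocabularies that follow FAIR principles",
    "I3": "(Meta)data include qualified references to other (meta)data",
    "R1": "(Meta)data are richly described with a plurality of accurate attributes",
    "R1.1": "(Meta)data are released with a clear and accessible data usage license",
    "R1.2": "(Meta)data are associated with detailed provenance",
    "R1.3": "(Meta)data meet domain-relevant community standards",
}

FAIR_STATUSES = ("met", "partial", "unmet", "n/a")


@dataclass(frozen=True)
class MiappeConcept:
    """One MIAPPE concept with its attributes and their obligation."""

    name: str
    attributes: tuple[str, ...]
    mandatory: tuple[str, ...]


def _load_reference() -> tuple[str, dict[str, MiappeConcept]]:
    raw = json.loads(
        resources.files("tdaudit.reference_data").joinpath("miappe_v1_1.json").read_text()
    )
    concepts = {}
    for name, body in raw["concepts"].items():
        attrs = body["attributes"]
        concepts[name] = MiappeConcept(
            name=name,
            attributes=tuple(attrs.keys()),
            mandatory=tuple(a for a, m in attrs.items() if m),
        )
    return raw["version"], concepts


MIAPPE_VERSION, _MIAPPE_CONCEPTS = _load_reference()


def miappe_concepts() -> dict[str, MiappeConcept]:
    """The bundled MIAPPE v1.1 concept model, keyed by concept name."""
    return dict(_MIAPPE_CONCEPTS)


@dataclass(frozen=True)
class MappingEntry:
    """One schema field mapped onto a MIAPPE attribute (or left unmapped)."""

    schema_field: str
    concept: str = "unmapped"
    attribute: str = ""
    note: str = ""


@dataclass
class SchemaMapping:
    """A full mapping of a database schema's fields onto MIAPPE."""

    entries: list[MappingEntry]

    def __post_init__(self) -> None:
        fields = [e.schema_field for e in self.entries]
        dupes = sorted({f for f in fields if fields.count(f) > 1})
        if dupes:
            raise ValidationError(f"duplicate schema fields: {', '.join(dupes)}")
        for e in self.entries:
            if e.concept != "unmapped" and e.concept not in _MIAPPE_CONCEPTS:
                raise ValidationError(
                    f"entry {e.schema_field!r}: unknown MIAPPE concept {e.concept!r}"
                )
            if e.concept != "unmapped" and e.attribute:
                if e.attribute not in _MIAPPE_CONCEPTS[e.concept].attributes:
                    raise ValidationError(
                        f"entry {e.schema_field!r}: {e.attribute!r} is not an "
                        f"attribute of concept {e.concept!r}"
                    )


@dataclass
class ComplianceReport:
    """Per-concept MIAPPE coverage of one schema mapping."""

    miappe_version: str
    per_concept_status: dict[str, str]
    unmapped_schema_fields: list[str]
    unrepresented_concepts: list[str]
    missing_mandatory: dict[str, list[str]]

    def to_json_dict(self) -> dict:
        return {
            "miappe_version": self.miappe_version,
            "per_concept_status": self.per_concept_status,
            "unmapped_schema_fields": self.unmapped_schema_fields,
            "unrepresented_concepts": self.unrepresented_concepts,
            "missing_mandatory": self.missing_mandatory,
        }

    def write_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.to_json_dict(), indent=2) + "\n")
        return path

    def to_text(self) -> str:
        width = max(len(c) for c in self.per_concept_status)
        lines = [f"MIAPPE v{self.miappe_version} concept coverage", ""]
        for concept, status in self.per_concept_status.items():
            lines.append(f"  {concept:<{width}}  {status}")
            if status == "partial":
                missing = ", ".join(self.missing_mandatory[concept])
                lines.append(f"  {'':<{width}}    missing mandatory: {missing}")
        if self.unmapped_schema_fields:
            lines += ["", "unmapped schema fields: " + ", ".join(self.unmapped_schema_fields)]
        return "\n".join(lines)


def assess_miappe(mapping: SchemaMapping) -> ComplianceReport:
    """Score each MIAPPE concept against a schema mapping.

    *full* — every mandatory attribute of the concept is mapped by some
    schema field; *partial* — the concept is referenced but one or more
    mandatory attributes are missing; *absent* — no schema field maps to
    the concept.  ``unrepresented_concepts`` lists everything not full.
    Adding mapping entries can only promote statuses (monotone).
    """
    mapped_attrs: dict[str, set[str]] = {c: set() for c in _MIAPPE_CONCEPTS}
    touched: set[str] = set()
    unmapped_fields = []
    for e in mapping.entries:
        if e.concept == "unmapped":
            unmapped_fields.append(e.schema_field)
            continue
        touched.add(e.concept)
        if e.attribute:
            mapped_attrs[e.concept].add(e.attribute)
    statuses: dict[str, str] = {}
    missing: dict[str, list[str]] = {}
    for name, concept in _MIAPPE_CONCEPTS.items():
        absent_mandatory = [a for a in concept.mandatory if a not in mapped_attrs[name]]
        if name in touched and not absent_mandatory:
            statuses[name] = "full"
        elif name in touched:
            statuses[name] = "partial"
            missing[name] = absent_mandatory
        else:
            statuses[name] = "absent"
    return ComplianceReport(
        miappe_version=MIAPPE_VERSION,
        per_concept_status=statuses,
        unmapped_schema_fields=unmapped_fields,
        unrepresented_concepts=[c for c, s in statuses.items() if s != "full"],
        missing_mandatory=missing,
    )


@dataclass(frozen=True)
class FairEntry:
    principle_id: str
    status: str
    evidence: str = ""

    def __post_init__(self) -> None:
        if self.principle_id not in FAIR_PRINCIPLES:
            raise ValidationError(f"unknown FAIR principle {self.principle_id!r}")
        if self.status not in FAIR_STATUSES:
            raise ValidationError(
                f"status {self.status!r} not in {FAIR_STATUSES} for {self.principle_id}"
            )


@dataclass
class FairChecklist:
    """A complete 15-entry FAIR assessment."""

    entries: list[FairEntry]

    def __post_init__(self) -> None:
        ids = [e.principle_id for e in self.entries]
        if ids != list(FAIR_PRINCIPLES):
            raise ValidationError(
                "FairChecklist must contain exactly the 15 principles in order; "
                f"got {ids}"
            )

    def status_counts(self) -> dict[str, int]:
        counts = {s: 0 for s in FAIR_STATUSES}
        for e in self.entries:
            counts[e.status] += 1
        return counts

    def to_json_dict(self) -> dict:
        return {
            "entries": [
                {
                    "principle_id": e.principle_id,
                    "principle": FAIR_PRINCIPLE_TEXT[e.principle_id],
                    "status": e.status,
                    "evidence": e.evidence,
                }
                for e in self.entries
            ],
            "status_counts": self.status_counts(),
        }

    def write_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.to_json_dict(), indent=2) + "\n")
        return path

    def to_text(self) -> str:
        lines = ["FAIR checklist", ""]
        for e in self.entries:
            lines.append(f"  {e.principle_id:<5} {e.status:<8} {e.evidence}")
        counts = self.status_counts()
        lines += ["", "  " + "  ".join(f"{s}: {n}" for s, n in counts.items())]
        return "\n".join(lines)


def fair_checklist(
    draft: list[FairEntry] | None,
) -> tuple[FairChecklist, dict[str, int]]:
    """Complete a draft FAIR assessment.

    Principles absent from the draft become ``unmet`` with empty
    evidence; duplicates are an error.  Returns the completed checklist
    and its status tally.
    """
    draft = draft or []
    seen: dict[str, FairEntry] = {}
    for e in draft:
        if e.principle_id in seen:
            raise ValidationError(f"duplicate FAIR principle entry {e.principle_id!r}")
        seen[e.principle_id] = e
    entries = [
        seen.get(pid, FairEntry(principle_id=pid, status="unmet")) for pid in FAIR_PRINCIPLES
    ]
    checklist = FairChecklist(entries=entries)
    return checklist, checklist.status_counts()


def load_mapping_csv(path: str | Path) -> SchemaMapping:
    """Read a schema mapping CSV (schema_field, concept, attribute, note)."""
    entries = []
    with open(path, newline="", encoding="utf-8-sig") as fh:
        reader = csv.DictReader(fh)
        required = {"schema_field", "concept"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise ValidationError(f"{path}: mapping CSV needs columns {sorted(required)}")
        for row in reader:
            if not row["schema_field"].strip():
                continue
            entries.append(
                MappingEntry(
                    schema_field=row["schema_field"].strip(),
                    concept=(row.get("concept") or "unmapped").strip() or "unmapped",
                    attribute=(row.get("attribute") or "").strip(),
                    note=(row.get("note") or "").strip(),
                )
            )
    return SchemaMapping(entries=entries)


def load_cropstoredb_fixture() -> SchemaMapping:
    """The bundled CropStoreDB-style example mapping.

    A synthetic reconstruction of how a crop curation relational schema
    maps onto MIAPPE v1.1: trial metadata covers the study section while
    the concepts data file, environment, experimental factor and event
    are not fully represented.
    """
    with resources.as_file(
        resources.files("tdaudit.reference_data").joinpath("cropstoredb_miappe_mapping.csv")
    ) as p:
        return load_mapping_csv(p)
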