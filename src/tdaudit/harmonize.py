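"""Trait-name normalization, exact matching and deduplication.

Trait vocabularies assembled by different institutions diverge in
orthography (``colour``/``color``), case, word order and pluralization
even when names are semantically equivalent.  This module implements the
explicit pre-processing pipeline used before exact string matching, and
the two deduplication passes applied to a multi-crop collection:

1. *within-crop*: the same trait name may appear on several rows of one
   TD because different methods/scales attach to it; duplicates are
   removed keeping the first occurrence;
2. *across-crop*: the per-crop unique name sets are collapsed into one
   distinct-name universe, counting how many duplicate occurrences were
   removed in the process.

Two matcher modes exist everywhere: ``raw_exact`` compares trimmed
strings byte-wise (case-sensitive) and is the default for cross-TD
statistics, because published corpus counts treat ``Leaf color`` and
``Leaf colour`` as distinct; ``normalized_exact`` compares
:func:`normalize_name` outputs and is the mode for curation workflows
that deliberately merge such variants.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from types import MappingProxyType
from typing import Iterable, Mapping

import yaml

from .model import MultiSpeciesTD, TraitDictionary, ValidationError

__all__ = [
    "BRITISH_TO_AMERICAN",
    "NormalizationConfig",
    "DEFAULT_CONFIG",
    "MatchReport",
    "normalize_name",
    "match_names",
    "dedup_within_crop",
    "collapse_across_crops",
    "name_key",
    "load_normalization_config",
    "MATCH_MODES",
]

MATCH_MODES = ("raw_exact", "normalized_exact")

#: Shipped British -> American orthography table (token-wise, lowercase).
BRITISH_TO_AMERICAN: Mapping[str, str] = MappingProxyType({
    "colour": "color",
    "coloured": "colored",
    "colouration": "coloration",
    "fibre": "fiber",
    "fibres": "fibers",
    "vigour": "vigor",
    "flavour": "flavor",
    "flavours": "flavors",
    "odour": "odor",
    "odours": "odors",
    "behaviour": "behavior",
    "mould": "mold",
    "grey": "gray",
    "centre": "center",
    "metre": "meter",
    "litre": "liter",
    "tuberisation": "tuberization",
    "utilisation": "utilization",
})


def _map_token_core(token: str, mapping: Mapping[str, str]) -> str:
    """Apply a word map to the alphanumeric core of a token.

    Leading/trailing punctuation is preserved, so the orthography pass
    commutes with optional punctuation stripping and the pipeline stays
    idempotent regardless of flag combinations.
    """
    start = 0
    end = len(token)
    while start < end and not token[start].isalnum():
        start += 1
    while end > start and not token[end - 1].isalnum():
        end -= 1
    core = token[start:end]
    replacement = mapping.get(core)
    if replacement is None:
        return token
    return token[:start] + replacement + token[end:]


@dataclass(frozen=True)
class NormalizationConfig:
    """Configuration for the fixed normalization pipeline.

    Pipeline order (fixed): trim -> case fold -> collapse whitespace ->
    token-wise orthography map -> whole-string synonym map -> optional
    punctuation strip -> optional token sort.

    ``synonym_map`` applies to whole names only, never substrings, to
    avoid cascading rewrites; its values must themselves be fixed points
    of the pipeline, which is validated at construction.
    """

    case_fold: bool = True
    collapse_whitespace: bool = True
    orthography_map: Mapping[str, str] = field(
        default_factory=lambda: BRITISH_TO_AMERICAN
    )
    synonym_map: Mapping[str, str] = field(default_factory=dict)
    strip_punctuation: bool = False
    sort_tokens: bool = False

    def __post_init__(self) -> None:
        for source, target in self.orthography_map.items():
            if not source or not target:
                raise ValidationError("orthography_map entries must be non-empty")

        def fixed_point(target: str) -> str:
            # pipeline sans synonym pass, so synonym targets may be any
            # orthographically-canonical form
            return _run_pipeline(
                target,
                self.case_fold,
                self.collapse_whitespace,
                self.orthography_map,
                {},
                self.strip_punctuation,
                self.sort_tokens,
            )

        for which, mapping in (("orthography_map", self.orthography_map),
                               ("synonym_map", self.synonym_map)):
            for target in mapping.values():
                fixed = fixed_point(target)
                if fixed != target:
                    raise ValidationError(
                        f"{which} target {target!r} is not a fixed point of the "
                        f"pipeline (normalizes to {fixed!r})"
                    )


def _run_pipeline(
    name: str,
    case_fold: bool,
    collapse_whitespace: bool,
    orthography_map: Mapping[str, str],
    synonym_map: Mapping[str, str],
    strip_punctuation: bool,
    sort_tokens: bool,
) -> str:
    out = name.strip()
    if case_fold:
        out = out.casefold()
    tokens = out.split() if collapse_whitespace else [out]
    tokens = [_map_token_core(t, orthography_map) for t in tokens]
    out = " ".join(tokens)
    out = synonym_map.get(out, out)
    if strip_punctuation:
        out = "".join(c if (c.isalnum() or c.isspace()) else " " for c in out)
        out = " ".join(out.split())
    if sort_tokens:
        out = " ".join(sorted(out.split()))
    return out


def normalize_name(name: str, config: "NormalizationConfig | None" = None) -> str:
    """Normalize one trait name; deterministic and idempotent.

    >>> normalize_name("Leaf colour")
    'leaf color'
    """
    if config is None:
        config = DEFAULT_CONFIG
    if name is None or not name.strip():
        raise ValidationError("cannot normalize an empty name")
    return _run_pipeline(
        name,
        config.case_fold,
        config.collapse_whitespace,
        config.orthography_map,
        config.synonym_map,
        config.strip_punctuation,
        config.sort_tokens,
    )


DEFAULT_CONFIG = NormalizationConfig()


def name_key(name: str, mode: str, config: NormalizationConfig = DEFAULT_CONFIG) -> str:
    """Comparison key for a name under the chosen matcher mode."""
    if mode == "raw_exact":
        return name.strip()
    if mode == "normalized_exact":
        return normalize_name(name, config)
    raise ValidationError(f"unknown matcher mode {mode!r}; expected one of {MATCH_MODES}")


@dataclass
class MatchReport:
    """Outcome of exact matching between two name lists (set semantics)."""

    matched_pairs: list[tuple[str, str]]
    unmatched_a: list[str]
    unmatched_b: list[str]
    matcher_mode: str

    @property
    def n_matched(self) -> int:
        return len(self.matched_pairs)

    def to_rows(self) -> list[tuple[str, str, str, str]]:
        """Long-form rows (side, name, status, counterpart) for CSV export."""
        rows = []
        for a, b in self.matched_pairs:
            rows.append(("a", a, "matched", b))
            rows.append(("b", b, "matched", a))
        rows.extend(("a", n, "unmatched", "") for n in self.unmatched_a)
        rows.extend(("b", n, "unmatched", "") for n in self.unmatched_b)
        return rows

    def write_csv(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow(["side", "name", "status", "counterpart"])
            writer.writerows(self.to_rows())
        return path


def _unique_by_key(
    names: Iterable[str], mode: str, config: NormalizationConfig
) -> dict[str, str]:
    """key -> first original spelling, insertion-ordered."""
    out: dict[str, str] = {}
    for n in names:
        k = name_key(n, mode, config)
        out.setdefault(k, n.strip())
    return out


def match_names(
    a: Iterable[str],
    b: Iterable[str],
    mode: str = "raw_exact",
    config: NormalizationConfig = DEFAULT_CONFIG,
) -> MatchReport:
    """Exact string matching between two name lists.

    Multiplicity is ignored (set semantics); each side is represented by
    the first original spelling of every distinct key.  Matched pairs are
    sorted by key so reports are deterministic.
    """
    a = list(a)
    b = list(b)
    if not a or not b:
        raise ValidationError("match_names requires two non-empty name lists")
    ua = _unique_by_key(a, mode, config)
    ub = _unique_by_key(b, mode, config)
    shared = sorted(ua.keys() & ub.keys())
    return MatchReport(
        matched_pairs=[(ua[k], ub[k]) for k in shared],
        unmatched_a=[v for k, v in ua.items() if k not in ub],
        unmatched_b=[v for k, v in ub.items() if k not in ua],
        matcher_mode=mode,
    )


def dedup_within_crop(
    td: TraitDictionary,
    mode: str = "raw_exact",
    config: NormalizationConfig = DEFAULT_CONFIG,
) -> tuple[TraitDictionary, int]:
    """Remove trait-name duplicates inside one TD, keeping first occurrences.

    The same trait name legitimately appears on several rows of a TD when
    different methods or scales attach to it; for name-level statistics
    those rows are redundant.  Returns the deduplicated dictionary (row
    order preserved) and the number of rows removed.  Idempotent.
    """
    seen: set[str] = set()
    kept = []
    for d in td.descriptors:
        k = name_key(d.trait_name, mode, config)
        if k in seen:
            continue
        seen.add(k)
        kept.append(d)
    return (
        TraitDictionary(crop_label=td.crop_label, descriptors=kept, co_root_code=td.co_root_code),
        len(td.descriptors) - len(kept),
    )


def collapse_across_crops(
    mstd: MultiSpeciesTD,
    mode: str = "raw_exact",
    config: NormalizationConfig = DEFAULT_CONFIG,
) -> tuple[set[str], int]:
    """Collapse per-crop unique name sets into one distinct-name universe.

    Precondition: every TD is already deduplicated within crop under the
    same mode (violations raise).  Returns the union of per-crop name
    keys and the number of duplicate occurrences removed, satisfying the
    conservation identity::

        sum(per-crop unique counts) == len(union) + removed
    """
    union: set[str] = set()
    total = 0
    for td in mstd:
        keys = [name_key(d.trait_name, mode, config) for d in td.descriptors]
        if len(keys) != len(set(keys)):
            raise ValidationError(
                f"TD {td.crop_label!r} still contains within-crop duplicates "
                f"under mode {mode!r}; run dedup_within_crop first"
            )
        total += len(keys)
        union.update(keys)
    return union, total - len(union)


def load_normalization_config(path: str | Path) -> NormalizationConfig:
    """Load a :class:`NormalizationConfig` from YAML.

    Recognised keys mirror the dataclass fields; ``orthography_map`` and
    ``synonym_map`` may alternatively point at two-column CSV files.
    """
    raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
    if not isinstance(raw, dict):
        raise ValidationError(f"{path}: normalization config must be a mapping")

    def resolve_map(value, default):
        if value is None:
            return default
        if isinstance(value, str):
            table = {}
            with open(Path(path).parent / value, newline="", encoding="utf-8") as fh:
                for row in csv.reader(fh):
                    if len(row) >= 2 and row[0].strip():
                        table[row[0].strip()] = row[1].strip()
            return table
        if isinstance(value, dict):
            return {str(k): str(v) for k, v in value.items()}
        raise ValidationError(f"{path}: cannot interpret map specification {value!r}")

    return NormalizationConfig(
        case_fold=bool(raw.get("case_fold", True)),
        collapse_whitespace=bool(raw.get("collapse_whitespace", True)),
        orthography_map=resolve_map(raw.get("orthography_map"), BRITISH_TO_AMERICAN),
        synonym_map=resolve_map(raw.get("synonym_map"), {}),
        strip_punctuation=bool(raw.get("strip_punctuation", False)),
        sort_tokens=bool(raw.get("sort_tokens", False)),
    )
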