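"""Synthetic multi-crop trait-dictionary corpora with known ground truth.

Every audit metric in this package can be exercised without downloading
anything: the generator emits a multi-crop TD collection whose sharing
structure, within-crop duplicates, orthographic variants, xref coverage
and class labelling are all planned in advance and recorded in a
:class:`GroundTruth` ledger, so recovery tests can compare measured
statistics with exact expected values.

Two sharing designs are supported:

* :class:`PairwiseSharing` — an explicit target number of shared names
  per crop pair.  Each pair's shared names occur in exactly those two
  crops, so the planned counts *are* the true pairwise overlaps.
* :class:`OccupancyDesign` — how many dictionaries each name occurs in,
  given either as exact per-k name counts or as a probability
  distribution over k.  This is the natural way to emulate a large
  corpus dominated by crop-specific vocabulary.

A single seeded random stream drives generation in a fixed order
(crops -> names -> noise), so output is byte-reproducible for a given
spec and adding a later noise stage never perturbs earlier draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import json
from pathlib import Path

import numpy as np
import yaml

from ._words import METHODS, ORGANS, PROPERTIES, QUALIFIERS, SCALES
from .harmonize import BRITISH_TO_AMERICAN
from .model import MultiSpeciesTD, TraitDescriptor, TraitDictionary, ValidationError

__all__ = [
    "PairwiseSharing",
    "OccupancyDesign",
    "SyntheticSpec",
    "GroundTruth",
    "generate_multispecies_td",
    "emulate_co_corpus",
    "write_corpus",
    "load_spec_yaml",
    "ORTHOGRAPHIC_TRANSFORMS",
]

ORTHOGRAPHIC_TRANSFORMS = ("british", "reorder", "pluralize", "titlecase")

_AMERICAN_TO_BRITISH = {v: k for k, v in BRITISH_TO_AMERICAN.items()}


@dataclass(frozen=True)
class PairwiseSharing:
    """Target shared-name counts per crop pair (0-based index pairs)."""

    shared: dict[tuple[int, int], int] = field(default_factory=dict)


@dataclass(frozen=True)
class OccupancyDesign:
    """Distribution of name occupancy (number of crops containing a name).

    Provide either ``exact_counts`` (occupancy k -> number of names, used
    verbatim) or ``probabilities`` (occupancy k -> probability, sampled
    for ``vocab_size`` names).
    """

    exact_counts: dict[int, int] | None = None
    probabilities: dict[int, float] | None = None

    def __post_init__(self) -> None:
        if (self.exact_counts is None) == (self.probabilities is None):
            raise ValidationError(
                "OccupancyDesign needs exactly one of exact_counts/probabilities"
            )


@dataclass(frozen=True)
class SyntheticSpec:
    """Full specification of one synthetic corpus.

    Rates are fractions in [0, 1].  ``within_crop_duplicate_rate`` is the
    number of injected duplicate rows per unique row (so 0.25 adds one
    duplicate for every four unique names, rounded per crop).
    ``xref_rate`` applies at the name level: exactly
    ``round(rate * n_names)`` names receive a synthetic xref on every one
    of their rows.  ``orthographic_noise_rate`` applies per occurrence;
    each noised occurrence receives one applicable transformation from
    ``orthographic_transforms``.
    """

    n_crops: int
    sharing_design: PairwiseSharing | OccupancyDesign
    names_per_crop: int | None = None
    vocab_size: int | None = None
    within_crop_duplicate_rate: float = 0.0
    orthographic_noise_rate: float = 0.0
    orthographic_transforms: tuple[str, ...] = ORTHOGRAPHIC_TRANSFORMS
    xref_rate: float = 0.0
    xref_prefixes: tuple[str, ...] = ("TO", "PO", "PATO")
    class_labels: tuple[str, ...] = (
        "abiotic stress", "biotic stress", "agronomical", "biochemical",
        "morphological", "phenological", "physiological", "quality",
    )
    class_variant_rate: float = 0.0
    class_conflict_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_crops < 1:
            raise ValidationError("n_crops must be >= 1")
        for rate_name in (
            "within_crop_duplicate_rate",
            "orthographic_noise_rate",
            "xref_rate",
            "class_variant_rate",
            "class_conflict_rate",
        ):
            rate = getattr(self, rate_name)
            if not 0.0 <= rate <= 1.0:
                raise ValidationError(f"{rate_name}={rate} outside [0, 1]")
        unknown = set(self.orthographic_transforms) - set(ORTHOGRAPHIC_TRANSFORMS)
        if unknown:
            raise ValidationError(f"unknown orthographic transforms: {sorted(unknown)}")
        if isinstance(self.sharing_design, PairwiseSharing):
            if self.names_per_crop is None:
                raise ValidationError("PairwiseSharing requires names_per_crop")
            per_crop: dict[int, int] = {}
            for (i, j), s in self.sharing_design.shared.items():
                if not (0 <= i < self.n_crops and 0 <= j < self.n_crops and i != j):
                    raise ValidationError(f"invalid crop pair ({i}, {j})")
                if s < 0:
                    raise ValidationError(f"negative shared count for pair ({i}, {j})")
                per_crop[i] = per_crop.get(i, 0) + s
                per_crop[j] = per_crop.get(j, 0) + s
            for crop, total in per_crop.items():
                if total > self.names_per_crop:
                    raise ValidationError(
                        f"sharing design infeasible: crop {crop} needs {total} shared "
                        f"names but names_per_crop={self.names_per_crop}"
                    )
        else:
            counts = self.sharing_design.exact_counts
            if counts is not None:
                for k in counts:
                    if not 1 <= k <= self.n_crops:
                        raise ValidationError(f"occupancy {k} outside [1, {self.n_crops}]")
            else:
                probs = self.sharing_design.probabilities
                for k in probs:
                    if not 1 <= k <= self.n_crops:
                        raise ValidationError(f"occupancy {k} outside [1, {self.n_crops}]")
                if self.vocab_size is None:
                    raise ValidationError("probability occupancy design needs vocab_size")


@dataclass
class GroundTruth:
    """Ledger of everything the generator planned.

    ``canonical_name_of`` maps every emitted trait-name spelling back to
    its canonical (lowercase, American-spelled) form; identity entries
    are included for unnoised names.  ``true_pair_overlaps`` counts
    canonical names co-occurring per crop pair.
    """

    canonical_name_of: dict[str, str]
    true_pair_overlaps: dict[tuple[str, str], int]
    per_crop_names: dict[str, list[str]]
    injected_duplicates: dict[str, int]
    injected_conflicts: list[dict]
    xref_names: set[str]
    class_of: dict[str, str]

    def overlap(self, crop_a: str, crop_b: str) -> int:
        key = (crop_a, crop_b) if (crop_a, crop_b) in self.true_pair_overlaps else (crop_b, crop_a)
        return self.true_pair_overlaps.get(key, 0)

    def analytic_smc(self, crop_a: str, crop_b: str) -> float:
        """SMC implied by the ledger (shared / (total_a + total_b) * 100)."""
        ta = len(self.per_crop_names[crop_a])
        tb = len(self.per_crop_names[crop_b])
        if ta + tb == 0:
            raise ValidationError("analytic SMC undefined: both crops empty")
        return self.overlap(crop_a, crop_b) / (ta + tb) * 100.0

    def occupancy(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for names in self.per_crop_names.values():
            for n in names:
                counts[n] = counts.get(n, 0) + 1
        return counts

    def to_json_dict(self) -> dict:
        return {
            "canonical_name_of": self.canonical_name_of,
            "true_pair_overlaps": {
                f"{a}|{b}": v for (a, b), v in self.true_pair_overlaps.items()
            },
            "per_crop_names": self.per_crop_names,
            "injected_duplicates": self.injected_duplicates,
            "injected_conflicts": self.injected_conflicts,
            "xref_names": sorted(self.xref_names),
            "class_of": self.class_of,
        }

    def write_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.to_json_dict(), indent=2, sort_keys=True) + "\n")
        return path


def _make_vocabulary(n_names: int, rng: np.random.Generator) -> list[str]:
    """Draw n distinct canonical names (organ + property [+ qualifier])."""
    combos = [
        (o, p, q) for o in ORGANS for p in PROPERTIES for q in QUALIFIERS
    ]
    names: list[str] = []
    seen: set[str] = set()
    order = rng.permutation(len(combos))
    for idx in order:
        o, p, q = combos[idx]
        name = f"{o} {p}" + (f" {q}" if q else "")
        if name not in seen:
            seen.add(name)
            names.append(name)
        if len(names) == n_names:
            return names
    raise ValidationError(
        f"vocabulary pool exhausted: need {n_names} names, have {len(names)}"
    )


def _applicable_transforms(name: str, allowed: tuple[str, ...]) -> list[str]:
    out = []
    tokens = name.split()
    for t in allowed:
        if t == "british" and any(tok in _AMERICAN_TO_BRITISH for tok in tokens):
            out.append(t)
        elif t == "reorder" and len(tokens) >= 2:
            out.append(t)
        elif t in ("pluralize", "titlecase"):
            out.append(t)
    return out


def _apply_transform(name: str, transform: str, rng: np.random.Generator) -> str:
    tokens = name.split()
    if transform == "british":
        idx = [i for i, tok in enumerate(tokens) if tok in _AMERICAN_TO_BRITISH]
        i = idx[int(rng.integers(len(idx)))]
        tokens[i] = _AMERICAN_TO_BRITISH[tokens[i]]
        return " ".join(tokens)
    if transform == "reorder":
        i = int(rng.integers(len(tokens) - 1))
        tokens[i], tokens[i + 1] = tokens[i + 1], tokens[i]
        return " ".join(tokens)
    if transform == "pluralize":
        return name + "s" if not name.endswith("s") else name
    if transform == "titlecase":
        return name.title()
    raise ValidationError(f"unknown transform {transform!r}")


def _assign_names(
    spec: SyntheticSpec, rng: np.random.Generator
) -> tuple[list[str], dict[str, list[str]]]:
    """Plan which canonical names occur in which crops (pre-noise)."""
    crops = [f"crop{c + 1:02d}" for c in range(spec.n_crops)]
    per_crop: dict[str, list[str]] = {c: [] for c in crops}

    if isinstance(spec.sharing_design, PairwiseSharing):
        n_shared_total = sum(spec.sharing_design.shared.values())
        fill = {c: spec.names_per_crop for c in range(spec.n_crops)}
        for (i, j), s in spec.sharing_design.shared.items():
            fill[i] -= s
            fill[j] -= s
        n_needed = n_shared_total + sum(fill.values())
        vocab = _make_vocabulary(n_needed, rng)
        cursor = 0
        for (i, j), s in sorted(spec.sharing_design.shared.items()):
            for _ in range(s):
                name = vocab[cursor]
                cursor += 1
                per_crop[crops[i]].append(name)
                per_crop[crops[j]].append(name)
        for c in range(spec.n_crops):
            for _ in range(fill[c]):
                per_crop[crops[c]].append(vocab[cursor])
                cursor += 1
    else:
        design = spec.sharing_design
        if design.exact_counts is not None:
            occupancies: list[int] = []
            for k, n_k in sorted(design.exact_counts.items()):
                occupancies.extend([k] * n_k)
        else:
            ks = sorted(design.probabilities)
            p = np.array([design.probabilities[k] for k in ks], dtype=float)
            p = p / p.sum()
            occupancies = [int(k) for k in rng.choice(ks, size=spec.vocab_size, p=p)]
        vocab = _make_vocabulary(len(occupancies), rng)
        for name, k in zip(vocab, occupancies):
            chosen = rng.choice(spec.n_crops, size=k, replace=False)
            for c in sorted(int(x) for x in chosen):
                per_crop[crops[c]].append(name)

    # shuffle row order within each crop so position carries no signal
    for c in crops:
        order = rng.permutation(len(per_crop[c]))
        per_crop[c] = [per_crop[c][i] for i in order]
    return crops, per_crop


def generate_multispecies_td(spec: SyntheticSpec) -> tuple[MultiSpeciesTD, GroundTruth]:
    """Generate a corpus and its ground-truth ledger.

    With all noise rates zero, every emitted name equals its canonical
    form and the ledger's pair overlaps equal the corpus's exact-match
    overlaps; recovery tests rely on this identity.
    """
    rng = np.random.default_rng(spec.seed)

    # ---- stage 1: crops and canonical name assignment -------------------
    crops, per_crop = _assign_names(spec, rng)
    all_names = sorted({n for names in per_crop.values() for n in names})

    overlaps: dict[tuple[str, str], int] = {}
    for ia in range(len(crops)):
        for ib in range(ia + 1, len(crops)):
            a, b = crops[ia], crops[ib]
            overlaps[(a, b)] = len(set(per_crop[a]) & set(per_crop[b]))

    # ---- stage 2: name-level annotations (classes, conflicts, xrefs) ----
    class_of = {
        name: spec.class_labels[int(rng.integers(len(spec.class_labels)))]
        for name in all_names
    }
    shared_names = sorted(n for n, k in _occupancy_of(per_crop).items() if k >= 2)
    n_conflicts = int(round(spec.class_conflict_rate * len(shared_names)))
    conflict_names = (
        [shared_names[i] for i in rng.choice(len(shared_names), size=n_conflicts, replace=False)]
        if n_conflicts
        else []
    )
    injected_conflicts = []
    conflict_override: dict[tuple[str, str], str] = {}
    for name in sorted(conflict_names):
        holders = sorted(c for c in crops if name in per_crop[c])
        flip_crop = holders[int(rng.integers(len(holders)))]
        others = [c for c in spec.class_labels if c != class_of[name]]
        new_class = others[int(rng.integers(len(others)))]
        conflict_override[(flip_crop, name)] = new_class
        assignment = {c: class_of[name] for c in holders}
        assignment[flip_crop] = new_class
        injected_conflicts.append(
            {"name": name, "crops": holders, "classes": assignment}
        )

    n_xref = int(round(spec.xref_rate * len(all_names)))
    xref_names = (
        {all_names[i] for i in rng.choice(len(all_names), size=n_xref, replace=False)}
        if n_xref
        else set()
    )
    xref_of = {
        name: (
            spec.xref_prefixes[int(rng.integers(len(spec.xref_prefixes)))],
            f"{int(rng.integers(10 ** 7)):07d}",
        )
        for name in sorted(xref_names)
    }

    # ---- stage 3: rows (duplicates appended, then per-row noise) ---------
    canonical_name_of: dict[str, str] = {}
    injected_duplicates: dict[str, int] = {}
    dictionaries = []
    class_variant_forms = ("{c}", "{c} trait", "{c} traits")
    for crop in crops:
        uniques = per_crop[crop]
        n_dup = int(round(spec.within_crop_duplicate_rate * len(uniques)))
        injected_duplicates[crop] = n_dup
        dup_idx = rng.integers(len(uniques), size=n_dup) if n_dup else []
        row_names = list(uniques) + [uniques[int(i)] for i in dup_idx]
        order = rng.permutation(len(row_names))
        row_names = [row_names[i] for i in order]

        descriptors = []
        for name in row_names:
            emitted = name
            if spec.orthographic_noise_rate > 0 and rng.random() < spec.orthographic_noise_rate:
                applicable = _applicable_transforms(name, spec.orthographic_transforms)
                if applicable:
                    transform = applicable[int(rng.integers(len(applicable)))]
                    emitted = _apply_transform(name, transform, rng)
            canonical_name_of[emitted] = name

            canon_class = conflict_override.get((crop, name), class_of[name])
            label_form = class_variant_forms[0]
            if spec.class_variant_rate > 0 and rng.random() < spec.class_variant_rate:
                label_form = class_variant_forms[int(rng.integers(1, len(class_variant_forms)))]
            trait_class = label_form.format(c=canon_class)

            xrefs = [xref_of[name]] if name in xref_names else []
            descriptors.append(
                TraitDescriptor(
                    trait_name=emitted,
                    variable_name=f"{emitted} - measurement",
                    trait_class=trait_class,
                    method_name=METHODS[int(rng.integers(len(METHODS)))],
                    scale_name=SCALES[int(rng.integers(len(SCALES)))],
                    xrefs=xrefs,
                )
            )
        dictionaries.append(TraitDictionary(crop_label=crop, descriptors=descriptors))

    mstd = MultiSpeciesTD(dictionaries=dictionaries)
    truth = GroundTruth(
        canonical_name_of=canonical_name_of,
        true_pair_overlaps=overlaps,
        per_crop_names={c: sorted(set(per_crop[c])) for c in crops},
        injected_duplicates=injected_duplicates,
        injected_conflicts=injected_conflicts,
        xref_names=xref_names,
        class_of=class_of,
    )
    return mstd, truth


def _occupancy_of(per_crop: dict[str, list[str]]) -> dict[str, int]:
    counts: dict[str, int] = {}
    for names in per_crop.values():
        for n in set(names):
            counts[n] = counts.get(n, 0) + 1
    return counts


#: Exact occupancy profile used by :func:`emulate_co_corpus`:
#: 3113 distinct names, 3627 per-crop occurrences, 90% singletons, a
#: single name present in 20 of 28 dictionaries, one in 10 and two in 9.
_CORPUS_OCCUPANCY = {
    1: 2802, 2: 220, 3: 48, 4: 20, 5: 10, 6: 5, 7: 3, 9: 2, 10: 1, 12: 1, 20: 1,
}


def emulate_co_corpus(seed: int = 0) -> SyntheticSpec:
    """A 28-crop spec shaped like the published multi-species TD corpus.

    The occupancy profile is fixed so the headline corpus statistics hold
    by construction: 3113 distinct names of which 90% occur in a single
    dictionary, 3627 within-crop-unique occurrences (so collapsing
    across crops removes 514 duplicate occurrences), and a maximum
    occupancy of 20.  The within-crop duplicate rate is set so the
    expected total row count is about 4739, and 12.6% of names (392)
    carry an xref.
    """
    n_names = sum(_CORPUS_OCCUPANCY.values())
    return SyntheticSpec(
        n_crops=28,
        sharing_design=OccupancyDesign(exact_counts=dict(_CORPUS_OCCUPANCY)),
        within_crop_duplicate_rate=1112 / 3627,
        xref_rate=392 / n_names,
        class_variant_rate=0.15,
        class_conflict_rate=0.02,
        seed=seed,
    )


def write_corpus(
    mstd: MultiSpeciesTD,
    truth: GroundTruth,
    outdir: str | Path,
    dialect: str = "td_template_v5",
) -> Path:
    """Write one TD file per crop plus the ground-truth JSON ledger."""
    from .io import write_td

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for td in mstd:
        write_td(td, outdir / f"{td.crop_label}.csv", dialect)
    truth.write_json(outdir / "ground_truth.json")
    return outdir


def load_spec_yaml(path: str | Path) -> SyntheticSpec:
    """Load a :class:`SyntheticSpec` from YAML.

    The ``sharing_design`` block carries either ``pairwise`` (keys like
    ``"0-1": 5``) or ``occupancy`` with ``exact_counts``/``probabilities``.
    """
    raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
    design_raw = raw.pop("sharing_design", None)
    if design_raw is None:
        raise ValidationError(f"{path}: spec requires a sharing_design block")
    if "pairwise" in design_raw:
        shared = {}
        for key, v in design_raw["pairwise"].items():
            i, j = (int(x) for x in str(key).replace(",", "-").split("-"))
            shared[(i, j)] = int(v)
        design = PairwiseSharing(shared=shared)
    elif "occupancy" in design_raw:
        occ = design_raw["occupancy"]
        exact = occ.get("exact_counts")
        probs = occ.get("probabilities")
        design = OccupancyDesign(
            exact_counts={int(k): int(v) for k, v in exact.items()} if exact else None,
            probabilities={int(k): float(v) for k, v in probs.items()} if probs else None,
        )
    else:
        raise ValidationError(f"{path}: sharing_design must be 'pairwise' or 'occupancy'")
    for tuple_field in ("orthographic_transforms", "xref_prefixes", "class_labels"):
        if tuple_field in raw:
            raw[tuple_field] = tuple(raw[tuple_field])
    return SyntheticSpec(sharing_design=design, **raw)
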