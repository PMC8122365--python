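"""Cross-dictionary cohesion statistics.

Three views of vocabulary sharing across a multi-crop TD collection:

* **occupancy frequencies** — for each distinct trait name, the number of
  dictionaries containing it, summarised as a histogram;
* **pairwise similarity** — a simple matching coefficient computed, for
  crops 1 and 2 with unique-name totals ``N_total1``/``N_total2`` and
  ``N_shared`` names in common, as::

      SMC = N_shared / (N_total1 + N_total2) * 100

  Note this differs from the classical simple matching coefficient: the
  denominator is the *sum* of the two totals, so two identical
  vocabularies score 50, not 100, and every value lies in [0, 50].  The
  formula is implemented exactly as published for comparability with the
  reported crop-pair percentages; treat 50 as "identical".
* **k-set overlap regions** — Venn-style counts of names falling in
  exactly each subset of up to six sources.

All statistics operate on unique name *keys* under a matcher mode (see
:func:`tdaudit.harmonize.name_key`); within-crop deduplication is applied
internally.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .harmonize import DEFAULT_CONFIG, NormalizationConfig, name_key
from .model import MultiSpeciesTD, UndefinedValueError, ValidationError

__all__ = [
    "PairOverlap",
    "SimilarityMatrix",
    "NameFrequency",
    "OverlapReport",
    "compute_smc",
    "smc_matrix",
    "shared_name_frequencies",
    "frequency_histogram",
    "unshared_percent",
    "overlap_regions",
]


@dataclass(frozen=True)
class PairOverlap:
    """Shared-name count between two crops plus their unique-name totals."""

    crop_a: str
    crop_b: str
    n_shared: int
    n_total_a: int
    n_total_b: int

    def __post_init__(self) -> None:
        if not (0 <= self.n_shared <= min(self.n_total_a, self.n_total_b)):
            raise ValidationError(
                f"n_shared={self.n_shared} outside [0, min({self.n_total_a}, "
                f"{self.n_total_b})] for pair ({self.crop_a}, {self.crop_b})"
            )


def compute_smc(overlap: PairOverlap) -> float:
    """Similarity of one crop pair on the 0–50 percent scale.

    Full floating precision; round only at the reporting layer.
    """
    denom = overlap.n_total_a + overlap.n_total_b
    if denom == 0:
        raise UndefinedValueError(
            f"SMC undefined for ({overlap.crop_a}, {overlap.crop_b}): both totals zero"
        )
    return overlap.n_shared / denom * 100.0


@dataclass
class SimilarityMatrix:
    """Symmetric matrix of pairwise SMC percentages.

    ``values[i, j]`` is the SMC of crops ``labels[i]`` and ``labels[j]``;
    the diagonal is 50 for non-empty crops.  Crops with empty vocabularies
    are listed in ``flagged`` and score 0 everywhere.
    """

    labels: list[str]
    values: np.ndarray
    n_shared: np.ndarray
    n_totals: list[int]
    flagged: list[str] = field(default_factory=list)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def pair(self, crop_a: str, crop_b: str) -> float:
        i, j = self.labels.index(crop_a), self.labels.index(crop_b)
        return float(self.values[i, j])

    def to_long_dataframe(self) -> pd.DataFrame:
        """One row per unordered crop pair with counts and the SMC value."""
        rows = []
        for i, j in combinations(range(len(self.labels)), 2):
            rows.append(
                {
                    "crop_a": self.labels[i],
                    "crop_b": self.labels[j],
                    "n_shared": int(self.n_shared[i, j]),
                    "n_total_a": self.n_totals[i],
                    "n_total_b": self.n_totals[j],
                    "smc": float(self.values[i, j]),
                    "smc_rounded": round(float(self.values[i, j]), 1),
                }
            )
        return pd.DataFrame(rows)

    def write_csv(self, path: str | Path) -> Path:
        path = Path(path)
        self.to_dataframe().to_csv(path, index_label="crop")
        return path

    def write_long_csv(self, path: str | Path) -> Path:
        path = Path(path)
        self.to_long_dataframe().to_csv(path, index=False)
        return path


def _unique_key_sets(
    mstd: MultiSpeciesTD, mode: str, config: NormalizationConfig
) -> list[set[str]]:
    return [
        {name_key(d.trait_name, mode, config) for d in td.descriptors} for td in mstd
    ]


def smc_matrix(
    mstd: MultiSpeciesTD,
    mode: str = "raw_exact",
    config: NormalizationConfig = DEFAULT_CONFIG,
) -> SimilarityMatrix:
    """Pairwise SMC matrix over the unique name sets of every crop.

    Within-crop deduplication happens internally (sets of name keys).
    Empty dictionaries are flagged rather than fatal: their rows and
    columns are 0, including the diagonal.
    """
    if len(mstd) < 2:
        raise ValidationError("smc_matrix requires at least two crops")
    sets = _unique_key_sets(mstd, mode, config)
    labels = mstd.labels
    totals = [len(s) for s in sets]
    flagged = [lab for lab, t in zip(labels, totals) if t == 0]
    n = len(labels)
    shared = np.zeros((n, n), dtype=int)
    values = np.zeros((n, n), dtype=float)
    for i in range(n):
        shared[i, i] = totals[i]
        if totals[i] > 0:
            values[i, i] = 50.0
        for j in range(i + 1, n):
            s = len(sets[i] & sets[j])
            shared[i, j] = shared[j, i] = s
            if totals[i] + totals[j] > 0:
                smc = compute_smc(PairOverlap(labels[i], labels[j], s, totals[i], totals[j]))
            else:
                smc = 0.0
            values[i, j] = values[j, i] = smc
    return SimilarityMatrix(
        labels=list(labels), values=values, n_shared=shared, n_totals=totals, flagged=flagged
    )


@dataclass
class NameFrequency:
    """Occupancy of each distinct trait name: in how many TDs it occurs."""

    counts: dict[str, int]
    n_crops: int

    def __post_init__(self) -> None:
        bad = {k: v for k, v in self.counts.items() if not 1 <= v <= self.n_crops}
        if bad:
            raise ValidationError(f"occupancy outside [1, {self.n_crops}]: {bad}")

    def __len__(self) -> int:
        return len(self.counts)

    def max_occupancy(self) -> int:
        return max(self.counts.values()) if self.counts else 0

    def most_frequent(self) -> list[str]:
        """All names attaining the maximum occupancy, lexicographic order."""
        if not self.counts:
            return []
        top = self.max_occupancy()
        return sorted(k for k, v in self.counts.items() if v == top)

    def write_csv(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow(["trait_name", "n_dictionaries"])
            for name in sorted(self.counts):
                writer.writerow([name, self.counts[name]])
        return path


def shared_name_frequencies(
    mstd: MultiSpeciesTD,
    mode: str = "raw_exact",
    config: NormalizationConfig = DEFAULT_CONFIG,
) -> NameFrequency:
    """Count, per distinct name key, the number of TDs containing it."""
    if len(mstd) < 1:
        raise ValidationError("shared_name_frequencies requires at least one crop")
    counts: dict[str, int] = {}
    for key_set in _unique_key_sets(mstd, mode, config):
        for k in key_set:
            counts[k] = counts.get(k, 0) + 1
    return NameFrequency(counts=counts, n_crops=len(mstd))


def frequency_histogram(freq: NameFrequency) -> dict[int, int]:
    """Histogram occupancy -> number of names.

    Identities: the values sum to the number of distinct names, and
    ``sum(k * n_k)`` equals the total of per-crop unique occurrences.
    """
    hist: dict[int, int] = {}
    for occ in freq.counts.values():
        hist[occ] = hist.get(occ, 0) + 1
    return dict(sorted(hist.items()))


def unshared_percent(freq: NameFrequency) -> float:
    """Percentage of distinct names occurring in exactly one TD.

    Returned at full precision; report layers round to the nearest
    integer.
    """
    if not freq.counts:
        raise ValidationError("unshared_percent of an empty frequency table")
    singletons = sum(1 for v in freq.counts.values() if v == 1)
    return 100.0 * singletons / len(freq.counts)


@dataclass
class OverlapReport:
    """Venn-style region counts for up to six name sets.

    ``region_counts`` maps every non-empty subset of ``set_labels``
    (as a tuple in input-label order) to the number of names contained in
    exactly that subset of sets; regions are disjoint and sum to the size
    of the union.  ``region_members`` retains the names themselves.
    """

    set_labels: list[str]
    region_counts: dict[tuple[str, ...], int]
    region_members: dict[tuple[str, ...], list[str]]

    def union_size(self) -> int:
        return sum(self.region_counts.values())

    def count(self, *labels: str) -> int:
        """Count for the region covering exactly the given labels."""
        key = tuple(lab for lab in self.set_labels if lab in set(labels))
        if len(key) != len(set(labels)):
            raise KeyError(f"unknown labels in {labels!r}")
        return self.region_counts[key]

    def set_size(self, label: str) -> int:
        """Reconstruct one input set's cardinality from the regions."""
        return sum(c for region, c in self.region_counts.items() if label in region)

    def to_json_dict(self) -> dict:
        return {
            "set_labels": self.set_labels,
            "regions": {
                "&".join(region): {"count": c, "names": self.region_members[region]}
                for region, c in self.region_counts.items()
            },
        }

    def write_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.to_json_dict(), indent=2, sort_keys=True) + "\n")
        return path


def overlap_regions(sets: Sequence[tuple[str, Iterable[str]]]) -> OverlapReport:
    """Assign every name of the union to its exact region of membership.

    Accepts between two and six labelled sets (the practical ceiling for
    a readable Venn diagram).  Every one of the ``2**k - 1`` regions is
    reported, including empty ones.
    """
    if not 2 <= len(sets) <= 6:
        raise ValidationError("overlap_regions requires between 2 and 6 sets")
    labels = [lab for lab, _ in sets]
    if len(set(labels)) != len(labels):
        raise ValidationError("set labels must be distinct")
    as_sets = {lab: set(members) for lab, members in sets}

    region_members: dict[tuple[str, ...], list[str]] = {}
    for r in range(1, len(labels) + 1):
        for combo in combinations(labels, r):
            region_members[combo] = []
    union = set().union(*as_sets.values())
    for name in sorted(union):
        region = tuple(lab for lab in labels if name in as_sets[lab])
        region_members[region].append(name)
    return OverlapReport(
        set_labels=labels,
        region_counts={k: len(v) for k, v in region_members.items()},
        region_members=region_members,
    )
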