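"""Bundled example datasets.

The bambara groundnut (*Vigna subterranea*) curation exercise compared
trait-name lists from four institutions — the IPGRI crop descriptor
list (73 names), a University of Nottingham dataset (27), the IITA
accession descriptors (54) and the Integrated Breeding Platform TD
draft (76) — 230 names in all, of which exactly 11 string-match across
all four sources.

The full source lists are not redistributable, so
:func:`reconstruct_bambara_sources` builds a synthetic reconstruction
with the published structure: the 11 genuinely shared names appear in
every list and the remaining names are unique to their source.  Any
overlap statistic that depends only on list sizes and the all-four
region is therefore exact; pairwise sub-overlaps of the real lists are
not modelled.
"""

from __future__ import annotations

import numpy as np

from ._words import ORGANS, PROPERTIES, QUALIFIERS
from .model import NameList

__all__ = ["BAMBARA_SHARED_TRAITS", "BAMBARA_SOURCE_SIZES", "reconstruct_bambara_sources"]

#: The eleven trait names shared by all four bambara sources.
BAMBARA_SHARED_TRAITS = (
    "Terminal leaflet length",
    "Terminal leaflet width",
    "Internode length",
    "Petiole length",
    "Peduncle length",
    "Plant height",
    "Pod length",
    "Pod width",
    "Seed width",
    "Seed length",
    "Shell thickness",
)

#: Published list sizes per source (they sum to 230).
BAMBARA_SOURCE_SIZES = {"IPGRI": 73, "UoN": 27, "IITA": 54, "IBP": 76}


def reconstruct_bambara_sources(seed: int = 0) -> list[NameList]:
    """Four synthetic source lists with the published overlap structure.

    Every list contains the 11 shared trait names; filler names are
    drawn from the synthetic vocabulary pool, distinct across sources
    and disjoint from the shared names (case-insensitively), so the
    all-four overlap region is exactly 11 of a 230-name total.
    """
    rng = np.random.default_rng(seed)
    shared_lower = {n.casefold() for n in BAMBARA_SHARED_TRAITS}
    pool = [
        f"{o} {p}" + (f" {q}" if q else "")
        for o in ORGANS
        for p in PROPERTIES
        for q in QUALIFIERS
    ]
    pool = sorted({name for name in pool if name.casefold() not in shared_lower})
    order = rng.permutation(len(pool))
    cursor = 0
    lists = []
    for label, size in BAMBARA_SOURCE_SIZES.items():
        n_fill = size - len(BAMBARA_SHARED_TRAITS)
        fillers = [pool[order[cursor + i]] for i in range(n_fill)]
        cursor += n_fill
        lists.append(NameList(source_label=label, names=list(BAMBARA_SHARED_TRAITS) + fillers))
    return lists
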