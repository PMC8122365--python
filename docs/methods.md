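# Methods

## The audit model

A Trait Dictionary (TD) is treated as an ordered table of descriptors; the
unit of every cross-crop statistic is the **unique trait-name set** of each
crop under a *matcher mode*. Two modes exist throughout:

- `raw_exact`: trimmed, byte-wise, case-sensitive comparison. This is the
  default for corpus-level statistics because published multi-crop counts
  treat orthographic variants ("Leaf color" vs "Leaf colour") as distinct
  names — the inconsistency is precisely what is being measured.
- `normalized_exact`: comparison after the normalization pipeline. This is
  the mode for curation workflows that deliberately merge variants.

The normalization pipeline has a fixed stage order — trim → case fold →
whitespace collapse → token-wise orthography map → whole-name synonym map →
optional punctuation strip → optional token sort — and is idempotent by
construction: orthography is applied to the alphanumeric core of each token
(so it commutes with punctuation stripping), and map targets are validated
to be fixed points of the pipeline at configuration time. The synonym map
applies to whole names only, never substrings, to prevent cascading
rewrites. Token sorting exists for word-order variants ("Leaf number" vs
"Number of leaves") but defaults off: word-order equivalence is a semantic
judgement best left to an explicit synonym table supplied by a curator.

Deduplication is two-staged and mirrors how multi-crop collections are
assembled. Within a crop, the same trait name legitimately recurs when
different methods/scales attach to it; `dedup_within_crop` keeps the first
occurrence (which duplicate row survives does not affect any name-level
metric). Across crops, `collapse_across_crops` unions the per-crop unique
sets and reports the conservation identity
`Σ per-crop unique = |union| + removed`.

## Similarity statistic

The pairwise similarity of two crops is the simple matching coefficient as
used in this setting:

    SMC = N_shared / (N_total1 + N_total2) × 100

This deliberately differs from the classical simple matching coefficient:
with the summed denominator, two identical vocabularies score 50 rather
than 100, disjoint vocabularies score 0, and all values lie in [0, 50].
The formula is implemented exactly in this form for comparability with
published crop-pair percentages; the matrix stores 50 on the diagonal for
non-empty crops (the report layer may blank it) and values at full floating
precision — rounding (one decimal for matrix cells, nearest integer for
headline percentages) happens only in reports. Crops with empty
vocabularies are flagged and scored 0 rather than raising, so one bad file
does not abort a corpus-wide audit.

Occupancy (the number of dictionaries containing a name) is summarised as a
histogram satisfying `Σ n_k = distinct names` and `Σ k·n_k = total per-crop
unique occurrences`; `unshared_percent` is the share of occupancy-1 names.
Venn-style `overlap_regions` supports 2–6 sets and assigns every union
element to exactly one region (its exact membership subset); all `2^k − 1`
regions are reported, including empty ones, and ties for "most frequent
name" are reported in full, sorted lexicographically.

## Semantic audit

Trait-class labels are canonicalized by lowercasing, whitespace collapse
and repeated removal of trailing "trait"/"traits" tokens (never emptying a
label); the canonicalizer is a fixed point of itself. Labels grouping to
the same canonical form with ≥2 spellings are flagged as variants; a
*class conflict* requires genuinely different canonical classes for the
same name in different crops. The eight de-facto standard classes (abiotic
stress, biotic stress, agronomical, biochemical, morphological,
phenological, physiological, quality) ship built in; labels outside the
list are reported as non-standard, not rejected.

Xref coverage counts a name as referenced when any of its rows in any crop
carries at least one parsed xref. Headline coverage is reported over the
distinct-name universe (the same universe as the frequency analysis), and
the report also carries occurrence-level totals, to which the per-crop
entries sum exactly; both conventions are therefore checkable.

## MIAPPE and FAIR

The MIAPPE v1.1 concept model (eleven concepts with attributes and
obligation levels) is bundled as versioned reference data; attributes whose
obligation the checklist leaves conditional are marked optional, so
coverage scoring is conservative. A concept is *full* when every mandatory
attribute is mapped, *partial* when referenced but incomplete, *absent*
otherwise; the scoring is monotone in mapping entries. The bundled
CropStoreDB-style mapping is a synthetic reconstruction encoding only the
documented relationships (trial metadata covering the study section; data
file, environment, experimental factor and event not fully represented) —
it is an illustrative fixture, not a dump of any real schema. The FAIR
checklist is a structured qualitative instrument over the fifteen GO FAIR
sub-principles; completion fills unanswered principles as *unmet* so gaps
are always explicit.

## Synthetic corpora and what they do (not) show

The generator plans everything before emitting rows: name-to-crop
assignment (pairwise targets or an occupancy distribution), within-crop
duplicate rows, name-level class assignment with optional spelling-variant
and conflict injection, name-level xrefs, and per-occurrence orthographic
noise (British spelling swap, adjacent-token reorder, pluralization,
title-casing — each noised occurrence gets one applicable transform). A
single seeded stream drives generation in fixed order (crops → names →
noise) so output files are byte-reproducible and later noise stages never
perturb earlier draws. Canonical names are organ + property (+ qualifier)
phrases from a bundled word pool, all lowercase American English, so every
transform has material to act on and normalized matching maps noised forms
back to their canonicals without collisions.

The 28-crop preset (`emulate_co_corpus`) fixes the occupancy profile
exactly — 3113 distinct names, 2802 of them singletons (90.0%), a tail
reaching one name at occupancy 20, one at 10 and two at 9, for 3627
within-crop-unique occurrences — rather than sampling it, so the headline
identities hold by construction; the within-crop duplicate rate (1112/3627)
makes the expected total ≈4739 rows, and the xref rate (392/3113) is
applied as an exact name count so coverage is 12.6% deterministically.
Orthographic noise is off in this preset: corpus-level statistics use raw
matching, under which real collections already count spelling variants as
distinct names, so the canonical-level profile is the right emulation
target.

What passing recovery tests shows: the measurement pipeline is exact on
corpora whose generative structure is known, and normalization provably
inverts the specific noise it models. What it does not show: real breeder
vocabularies have richer structure (institution effects that correlate
sharing across crop groups, abbreviations, free-text descriptions, genuine
semantic synonyms like hairs/trichomes) which the generator does not model
and exact matching cannot resolve; fuzzy or embedding-based matching is
deliberately out of scope.

The four bambara-groundnut source lists are likewise a labelled synthetic
reconstruction: list sizes (73/27/54/76) and the eleven all-four shared
names are as documented, filler names are unique per source. Statistics
depending only on those constraints (230 total, 11 shared by all four) are
exact; pairwise sub-overlaps of the real lists are not modelled.

## Numerical and design choices

- Percentages are exact floats internally; machine-readable outputs carry
  both the unrounded value and a display-rounded field.
- SMC of two empty crops is an error (undefined value), not 0.
- File encoding is strictly UTF-8 (BOM tolerated); anything else fails
  hard, for determinism.
- TD header names vary across published files: headers match
  case-insensitively after trimming, with a user-overridable column map.
  Cells are trimmed at read time but otherwise untouched; all
  normalization is an explicit later pass.
- Malformed xref tokens are warnings (dropped, counted), never fatal.
- Problem sizes in the test suite are small by design — recovery runs use
  8-crop, ~60-name corpora over 20 seeds, and the exhaustive similarity
  oracle enumerates all subset pairs of a 6-name universe — which is ample
  to pin down exact combinatorial identities while keeping the whole suite
  in a few seconds.

## Known limitations

- Only exact matching (raw or normalized) is implemented; no edit-distance
  or semantic similarity.
- Xref targets are not validated against live ontology releases, so a
  well-formed but wrong cross-reference is invisible to the audit.
- The MIAPPE reference data is a transcription of the v1.1 checklist at
  the stated version; it will not track later MIAPPE revisions.
- OWL/OBO parsing and reasoning are out of scope.
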