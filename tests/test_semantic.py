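"""Xref coverage, class-label variants and class-assignment conflicts."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tdaudit.model import ValidationError
from tdaudit.semantic import (
    canonicalize_class_label,
    class_conflicts,
    class_variants,
    xref_coverage,
)
from tests.conftest import make_mstd


@pytest.mark.parametrize(
    "label,expected",
    [
        ("quality traits", "quality"),
        ("quality trait", "quality"),
        ("quality", "quality"),
        ("Biochemical Trait", "biochemical"),
        ("  Abiotic   Stress ", "abiotic stress"),
        ("trait", "trait"),  # never emptied
        ("Traits", "traits"),
    ],
)
def test_canonicalize_class_label(label, expected):
    assert canonicalize_class_label(label) == expected


def test_canonicalize_rejects_empty():
    with pytest.raises(ValidationError):
        canonicalize_class_label(" ")


@settings(max_examples=150, deadline=None, derandomize=True)
@given(st.text(st.sampled_from(list("abc QualityTraits")), min_size=1, max_size=30))
def test_canonicalize_is_idempotent(label):
    try:
        once = canonicalize_class_label(label)
    except ValidationError:
        return
    assert canonicalize_class_label(once) == once


def test_class_variants_groups_and_flags():
    mstd = make_mstd(
        soy=[("a", "quality trait")],
        chick=[("b", "quality")],
        mung=[("c", "quality traits"), ("d", "morphological")],
    )
    groups = {g.canonical_label: g for g in class_variants(mstd)}
    quality = groups["quality"]
    assert quality.variants == {"quality trait", "quality", "quality traits"}
    assert quality.flagged and quality.is_standard
    assert not groups["morphological"].flagged


def test_class_variants_identical_labels_not_flagged():
    mstd = make_mstd(a=[("x", "quality")], b=[("y", "quality")])
    assert not any(g.flagged for g in class_variants(mstd))


def test_nonstandard_class_reported_not_rejected():
    mstd = make_mstd(a=[("x", "culinary")])
    (group,) = class_variants(mstd)
    assert group.canonical_label == "culinary" and not group.is_standard


def test_class_conflicts_detects_cross_crop_disagreement():
    mstd = make_mstd(
        soybean=[("seed protein content", "biochemical traits")],
        chickpea=[("seed protein content", "quality traits")],
        mungbean=[("seed protein content", "quality trait")],
    )
    (conflict,) = class_conflicts(mstd)
    assert conflict.trait_name == "seed protein content"
    assert conflict.assignments == {
        "soybean": "biochemical",
        "chickpea": "quality",
        "mungbean": "quality",
    }


def test_class_variant_spelling_is_not_a_conflict():
    mstd = make_mstd(
        a=[("seed weight", "quality trait")],
        b=[("seed weight", "quality traits")],
    )
    assert class_conflicts(mstd) == []


def test_single_crop_has_no_conflicts():
    mstd = make_mstd(a=[("x", "quality"), ("y", "morphological")])
    assert class_conflicts(mstd) == []


def test_conflicts_sorted_by_name_and_respect_matcher_mode():
    mstd = make_mstd(
        a=[("Leaf colour", "morphological"), ("b trait name", "quality")],
        b=[("Leaf color", "physiological"), ("b trait name", "morphological")],
    )
    raw = class_conflicts(mstd, "raw_exact")
    assert [c.trait_name for c in raw] == ["b trait name"]
    norm = class_conflicts(mstd, "normalized_exact")
    assert [c.trait_name for c in norm] == ["b trait name", "Leaf colour"]


def test_xref_coverage_counts_names_with_any_reference():
    mstd = make_mstd(
        a=[("n1", "", [("TO", "1")]), ("n2", "", [])],
        b=[("n1", "", []), ("n3", "", []), ("n4", "", [])],
    )
    report = xref_coverage(mstd)
    assert report.n_names == 4
    assert report.n_with_xref == 1
    assert report.percent == 25.0
    assert report.per_prefix_counts == {"TO": 1}


def test_xref_coverage_empty_corpus_is_zero():
    report = xref_coverage(make_mstd(a=["n1"], b=["n2"]))
    assert report.n_with_xref == 0 and report.percent == 0.0


def test_xref_per_crop_entries_sum_to_occurrence_totals():
    mstd = make_mstd(
        a=[("n1", "", [("TO", "1")]), ("n2", "", [])],
        b=[("n1", "", [("PO", "9")]), ("n3", "", [])],
    )
    report = xref_coverage(mstd)
    assert sum(n for n, _ in report.per_crop.values()) == report.n_occurrences == 4
    assert sum(r for _, r in report.per_crop.values()) == report.n_occurrences_with_xref == 2
    # distinct-name universe is smaller because n1 is shared
    assert report.n_names == 3 and report.n_with_xref == 1
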