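"""Name normalization, exact matching and deduplication."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tdaudit.harmonize import (
    DEFAULT_CONFIG,
    NormalizationConfig,
    collapse_across_crops,
    dedup_within_crop,
    load_normalization_config,
    match_names,
    normalize_name,
)
from tdaudit.model import ValidationError
from tests.conftest import make_mstd, make_td


@pytest.mark.parametrize(
    "raw,expected",
    [
        ("Leaf colour", "leaf color"),
        ("leaf color", "leaf color"),
        ("  Hundred  Seed Dry Weight ", "hundred seed dry weight"),
        ("Fibre content", "fiber content"),
    ],
)
def test_normalize_name_examples(raw, expected):
    assert normalize_name(raw) == expected


def test_normalize_rejects_empty():
    with pytest.raises(ValidationError):
        normalize_name("   ")


def test_synonym_map_applies_to_whole_names_only():
    config = NormalizationConfig(synonym_map={"leaf number": "number of leaves"})
    assert normalize_name("Leaf Number", config) == "number of leaves"
    # substring is untouched
    assert normalize_name("leaf number per plant", config) == "leaf number per plant"


def test_config_rejects_non_fixed_point_synonym_target():
    with pytest.raises(ValidationError, match="fixed point"):
        NormalizationConfig(synonym_map={"leaf number": "Leaf Colour"})


@pytest.mark.parametrize("strip_punctuation", [False, True])
@pytest.mark.parametrize("sort_tokens", [False, True])
@settings(max_examples=150, deadline=None, derandomize=True)
@given(name=st.text(st.characters(codec="utf-8", exclude_categories=("C",)), min_size=1, max_size=40))
def test_normalize_is_idempotent(name, strip_punctuation, sort_tokens):
    config = NormalizationConfig(
        strip_punctuation=strip_punctuation, sort_tokens=sort_tokens
    )
    try:
        once = normalize_name(name, config)
    except ValidationError:
        return  # effectively-empty input
    if not once.strip():
        return
    assert normalize_name(once, config) == once


def test_match_raw_vs_normalized_orthography():
    raw = match_names(["Leaf color"], ["Leaf colour"], "raw_exact")
    assert raw.n_matched == 0
    norm = match_names(["Leaf color"], ["Leaf colour"], "normalized_exact")
    assert norm.n_matched == 1
    assert norm.matched_pairs == [("Leaf color", "Leaf colour")]


def test_match_set_semantics():
    report = match_names(["x", "y", "y"], ["y", "z"])
    assert report.matched_pairs == [("y", "y")]
    assert report.unmatched_a == ["x"]
    assert report.unmatched_b == ["z"]
    rows = report.to_rows()
    # every distinct input name appears exactly once per side
    assert sorted(n for side, n, _, _ in rows if side == "a") == ["x", "y"]
    assert sorted(n for side, n, _, _ in rows if side == "b") == ["y", "z"]


def test_match_requires_non_empty_lists():
    with pytest.raises(ValidationError):
        match_names([], ["x"])


@settings(max_examples=100, deadline=None, derandomize=True)
@given(
    a=st.lists(st.sampled_from("abcdefgh"), min_size=1, max_size=8),
    b=st.lists(st.sampled_from("abcdefgh"), min_size=1, max_size=8),
)
def test_match_cardinality_is_symmetric_and_set_correct(a, b):
    ab = match_names(a, b)
    ba = match_names(b, a)
    assert ab.n_matched == ba.n_matched == len(set(a) & set(b))
    assert len(ab.unmatched_a) == len(set(a) - set(b))


def test_dedup_keeps_first_occurrence_in_order():
    td = make_td("x", ["A", "A", "B"])
    out, removed = dedup_within_crop(td)
    assert [d.trait_name for d in out] == ["A", "B"]
    assert removed == 1
    again, removed2 = dedup_within_crop(out)
    assert removed2 == 0 and [d.trait_name for d in again] == ["A", "B"]


def test_dedup_no_duplicates_is_identity():
    td = make_td("x", ["A", "B", "C"])
    out, removed = dedup_within_crop(td)
    assert removed == 0
    assert len(out) + removed == len(td)


def test_dedup_mode_changes_what_counts_as_duplicate():
    td = make_td("x", ["Leaf color", "Leaf colour"])
    _, removed_raw = dedup_within_crop(td, "raw_exact")
    _, removed_norm = dedup_within_crop(td, "normalized_exact")
    assert removed_raw == 0
    assert removed_norm == 1


def test_collapse_across_crops_counts_and_conservation():
    mstd = make_mstd(c1=["A", "B"], c2=["B", "C"])
    union, removed = collapse_across_crops(mstd)
    assert union == {"A", "B", "C"}
    assert removed == 1
    assert sum(len(td) for td in mstd) == len(union) + removed


def test_collapse_single_crop_removes_nothing():
    mstd = make_mstd(only=["A", "B"])
    union, removed = collapse_across_crops(mstd)
    assert removed == 0 and union == {"A", "B"}


def test_collapse_rejects_undeduplicated_input():
    mstd = make_mstd(c1=["A", "A"])
    with pytest.raises(ValidationError, match="within-crop duplicates"):
        collapse_across_crops(mstd)


def test_load_normalization_config_yaml(tmp_path):
    (tmp_path / "syn.csv").write_text("leaf number,number of leaves\n")
    cfg_path = tmp_path / "norm.yaml"
    cfg_path.write_text(
        "case_fold: true\nsort_tokens: false\nsynonym_map: syn.csv\n"
    )
    config = load_normalization_config(cfg_path)
    assert normalize_name("Leaf Number", config) == "number of leaves"
    assert config.orthography_map == DEFAULT_CONFIG.orthography_map
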