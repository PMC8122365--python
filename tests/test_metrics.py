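"""Cohesion statistics: SMC, frequencies, histogram, overlap regions."""

from itertools import combinations

import numpy as np
import pytest

from tdaudit.metrics import (
    NameFrequency,
    PairOverlap,
    compute_smc,
    frequency_histogram,
    overlap_regions,
    shared_name_frequencies,
    smc_matrix,
    unshared_percent,
)
from tdaudit.model import UndefinedValueError, ValidationError
from tests.conftest import make_mstd


def smc_oracle(set_a, set_b):
    """Brute-force: shared over summed totals, on the 0-50 scale."""
    return len(set_a & set_b) / (len(set_a) + len(set_b)) * 100.0


def test_compute_smc_examples():
    assert compute_smc(PairOverlap("a", "b", 4, 4, 4)) == 50.0
    assert compute_smc(PairOverlap("a", "b", 0, 5, 7)) == 0.0
    assert compute_smc(PairOverlap("a", "b", 2, 3, 3)) == pytest.approx(33.3333, abs=1e-3)


def test_compute_smc_undefined_for_two_empty_crops():
    with pytest.raises(UndefinedValueError):
        compute_smc(PairOverlap("a", "b", 0, 0, 0))


def test_pair_overlap_rejects_impossible_sharing():
    with pytest.raises(ValidationError):
        PairOverlap("a", "b", 5, 3, 9)


def test_smc_matrix_identical_dictionaries_score_50():
    mstd = make_mstd(a=["x", "y", "z"], b=["x", "y", "z"])
    matrix = smc_matrix(mstd)
    assert matrix.pair("a", "b") == 50.0
    assert matrix.values[0, 0] == matrix.values[1, 1] == 50.0


def test_smc_matrix_matches_bruteforce_oracle_on_random_instances():
    rng = np.random.default_rng(42)
    universe = [f"n{i}" for i in range(50)]
    for _ in range(10):
        n_crops = int(rng.integers(2, 11))
        sets = [
            set(rng.choice(universe, size=int(rng.integers(1, 51)), replace=False))
            for _ in range(n_crops)
        ]
        mstd = make_mstd(**{f"c{i}": sorted(s) for i, s in enumerate(sets)})
        matrix = smc_matrix(mstd)
        assert np.allclose(matrix.values, matrix.values.T)
        assert matrix.values.min() >= 0 and matrix.values.max() <= 50
        for i, j in combinations(range(n_crops), 2):
            assert matrix.values[i, j] == pytest.approx(smc_oracle(sets[i], sets[j]))


def test_smc_matrix_dedups_internally_and_flags_empty_crops(tmp_path):
    mstd = make_mstd(a=["x", "x", "y"], b=["y"])
    matrix = smc_matrix(mstd)
    assert matrix.n_totals == [2, 1]
    assert matrix.pair("a", "b") == pytest.approx(1 / 3 * 100)

    from tdaudit.model import MultiSpeciesTD, TraitDictionary

    mstd2 = MultiSpeciesTD(
        dictionaries=[
            TraitDictionary(crop_label="full", descriptors=mstd["a"].descriptors),
            TraitDictionary(crop_label="hollow"),
        ]
    )
    matrix2 = smc_matrix(mstd2)
    assert matrix2.flagged == ["hollow"]
    assert matrix2.pair("full", "hollow") == 0.0
    assert matrix2.values[1, 1] == 0.0


def test_smc_matrix_long_form_counts(tiny_mstd):
    long = smc_matrix(tiny_mstd).to_long_dataframe()
    row = long[(long.crop_a == "alpha") & (long.crop_b == "beta")].iloc[0]
    assert row.n_shared == 1 and row.n_total_a == 3 and row.n_total_b == 2
    assert row.smc == pytest.approx(20.0)


def test_shared_name_frequencies(tiny_mstd):
    freq = shared_name_frequencies(tiny_mstd)
    assert freq.counts["Plant height"] == 3
    assert freq.counts["Leaf color"] == 1  # raw mode: colour is distinct
    norm = shared_name_frequencies(tiny_mstd, "normalized_exact")
    assert norm.counts["leaf color"] == 2


def test_single_td_frequencies_are_all_one():
    freq = shared_name_frequencies(make_mstd(only=["a", "b"]))
    assert set(freq.counts.values()) == {1}


def test_frequency_histogram_identities(tiny_mstd):
    freq = shared_name_frequencies(tiny_mstd)
    hist = frequency_histogram(freq)
    assert sum(hist.values()) == len(freq)
    occurrences = sum(k * v for k, v in hist.items())
    assert occurrences == sum(len({d.trait_name for d in td}) for td in tiny_mstd)


def test_frequency_histogram_hand_tally():
    freq = NameFrequency(counts={"A": 2, "B": 1, "C": 1}, n_crops=2)
    assert frequency_histogram(freq) == {1: 2, 2: 1}


def test_unshared_percent():
    assert unshared_percent(NameFrequency(counts={"a": 2, "b": 3}, n_crops=3)) == 0.0
    nine_singletons = {f"s{i}": 1 for i in range(9)} | {"shared": 2}
    assert unshared_percent(NameFrequency(counts=nine_singletons, n_crops=2)) == 90.0


def test_most_frequent_lists_all_comaximal_names_sorted():
    freq = NameFrequency(counts={"b": 3, "a": 3, "c": 1}, n_crops=3)
    assert freq.most_frequent() == ["a", "b"]


def test_overlap_regions_two_identical_sets():
    report = overlap_regions([("A", {"x", "y"}), ("B", {"x", "y"})])
    assert report.region_counts[("A", "B")] == 2
    assert report.region_counts[("A",)] == report.region_counts[("B",)] == 0


def test_overlap_regions_enumeration():
    report = overlap_regions([("A", {"a", "b"}), ("B", {"b", "c"})])
    assert report.count("A") == 1
    assert report.count("B") == 1
    assert report.count("A", "B") == 1
    assert report.union_size() == 3
    assert report.set_size("A") == 2 and report.set_size("B") == 2


def test_overlap_regions_counts_sum_to_union_and_reconstruct_sets():
    rng = np.random.default_rng(3)
    universe = [f"n{i}" for i in range(30)]
    sets = [
        (f"s{i}", set(rng.choice(universe, size=int(rng.integers(1, 20)), replace=False)))
        for i in range(5)
    ]
    report = overlap_regions(sets)
    assert report.union_size() == len(set().union(*(s for _, s in sets)))
    for label, members in sets:
        assert report.set_size(label) == len(members)
    assert len(report.region_counts) == 2 ** 5 - 1


@pytest.mark.parametrize("k", [1, 7])
def test_overlap_regions_rejects_out_of_range_set_counts(k):
    sets = [(f"s{i}", {"x"}) for i in range(k)]
    with pytest.raises(ValidationError):
        overlap_regions(sets)
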