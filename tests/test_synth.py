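"""Synthetic corpus generation and ground-truth consistency."""

import pytest

from tdaudit.harmonize import dedup_within_crop
from tdaudit.metrics import smc_matrix, shared_name_frequencies, unshared_percent
from tdaudit.model import ValidationError
from tdaudit.semantic import class_conflicts, xref_coverage
from tdaudit.synth import (
    OccupancyDesign,
    PairwiseSharing,
    SyntheticSpec,
    emulate_co_corpus,
    generate_multispecies_td,
    load_spec_yaml,
    write_corpus,
)


def small_occupancy_spec(seed, **overrides):
    params = dict(
        n_crops=6,
        sharing_design=OccupancyDesign(exact_counts={1: 30, 2: 8, 3: 4, 6: 1}),
        seed=seed,
    )
    params.update(overrides)
    return SyntheticSpec(**params)


def test_pairwise_design_yields_planned_smc():
    spec = SyntheticSpec(
        n_crops=2,
        sharing_design=PairwiseSharing(shared={(0, 1): 5}),
        names_per_crop=10,
        seed=0,
    )
    mstd, truth = generate_multispecies_td(spec)
    matrix = smc_matrix(mstd)
    assert matrix.pair("crop01", "crop02") == 25.0
    assert truth.analytic_smc("crop01", "crop02") == 25.0


def test_infeasible_pairwise_design_rejected_before_generation():
    with pytest.raises(ValidationError, match="infeasible"):
        SyntheticSpec(
            n_crops=3,
            sharing_design=PairwiseSharing(shared={(0, 1): 8, (0, 2): 5}),
            names_per_crop=10,
        )


def test_occupancy_exact_counts_are_respected():
    mstd, truth = generate_multispecies_td(small_occupancy_spec(3))
    occ = truth.occupancy()
    freq = shared_name_frequencies(mstd)
    assert freq.counts == occ
    assert sorted(occ.values()).count(1) == 30
    assert max(occ.values()) == 6


def test_zero_noise_corpus_matches_ledger_exactly():
    spec = small_occupancy_spec(
        11, within_crop_duplicate_rate=0.25, xref_rate=0.2, class_conflict_rate=0.3
    )
    mstd, truth = generate_multispecies_td(spec)
    for td in mstd:
        _, removed = dedup_within_crop(td)
        assert removed == truth.injected_duplicates[td.crop_label]
    matrix = smc_matrix(mstd)
    for (a, b), n_shared in truth.true_pair_overlaps.items():
        assert matrix.n_shared[matrix.labels.index(a), matrix.labels.index(b)] == n_shared
        assert matrix.pair(a, b) == pytest.approx(truth.analytic_smc(a, b))
    assert {c.trait_name for c in class_conflicts(mstd)} == {
        c["name"] for c in truth.injected_conflicts
    }
    report = xref_coverage(mstd)
    assert report.n_with_xref == len(truth.xref_names)


def test_seeded_generation_is_reproducible_bytewise(tmp_path):
    spec = small_occupancy_spec(5, within_crop_duplicate_rate=0.2, orthographic_noise_rate=0.3)
    out1, out2 = tmp_path / "a", tmp_path / "b"
    for out in (out1, out2):
        mstd, truth = generate_multispecies_td(spec)
        write_corpus(mstd, truth, out)
    for f1 in sorted(out1.iterdir()):
        assert f1.read_bytes() == (out2 / f1.name).read_bytes()
    mstd_other, _ = generate_multispecies_td(small_occupancy_spec(6))
    assert [d.trait_name for d in mstd_other["crop01"]] != [
        d.trait_name for d in generate_multispecies_td(small_occupancy_spec(5))[0]["crop01"]
    ]


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_british_noise_recovered_by_normalized_matching(seed):
    spec = small_occupancy_spec(
        seed,
        orthographic_noise_rate=0.6,
        orthographic_transforms=("british",),
    )
    mstd, truth = generate_multispecies_td(spec)
    norm = smc_matrix(mstd, "normalized_exact")
    raw = smc_matrix(mstd, "raw_exact")
    for (a, b), n_shared in truth.true_pair_overlaps.items():
        i, j = norm.labels.index(a), norm.labels.index(b)
        assert norm.n_shared[i, j] == n_shared
        assert raw.n_shared[i, j] <= n_shared


def test_emulated_corpus_has_the_published_shape():
    mstd, truth = generate_multispecies_td(emulate_co_corpus(seed=4))
    freq = shared_name_frequencies(mstd)
    assert len(freq) == 3113
    assert 85 <= unshared_percent(freq) <= 95
    assert freq.max_occupancy() == 20
    matrix = smc_matrix(mstd)
    assert matrix.values.max() <= 50.0


def test_spec_yaml_round_trip(tmp_path):
    path = tmp_path / "spec.yaml"
    path.write_text(
        "n_crops: 3\n"
        "names_per_crop: 8\n"
        "within_crop_duplicate_rate: 0.25\n"
        "seed: 9\n"
        "sharing_design:\n"
        "  pairwise:\n"
        "    0-1: 2\n"
        "    1-2: 1\n"
    )
    spec = load_spec_yaml(path)
    assert spec.sharing_design.shared == {(0, 1): 2, (1, 2): 1}
    mstd, truth = generate_multispecies_td(spec)
    assert truth.overlap("crop01", "crop02") == 2
    assert truth.overlap("crop02", "crop03") == 1
    assert truth.overlap("crop01", "crop03") == 0
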