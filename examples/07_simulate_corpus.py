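"""Generate a synthetic corpus with ground truth and verify recovery.

Plans 5 shared names between two 10-name crops, adds British-spelling
noise, and shows that normalized matching recovers the planned overlap
while raw matching can miss it.
"""

from tdaudit import (
    PairwiseSharing,
    SyntheticSpec,
    generate_multispecies_td,
    smc_matrix,
)

spec = SyntheticSpec(
    n_crops=2,
    sharing_design=PairwiseSharing(shared={(0, 1): 5}),
    names_per_crop=10,
    orthographic_noise_rate=0.8,
    orthographic_transforms=("british",),
    seed=4,
)
mstd, truth = generate_multispecies_td(spec)

print("planned overlap:", truth.overlap("crop01", "crop02"),
      "-> analytic SMC", truth.analytic_smc("crop01", "crop02"))
for td in mstd:
    print(f"{td.crop_label}: {sorted(td.trait_names())[:4]} ...")

raw = smc_matrix(mstd, "raw_exact")
norm = smc_matrix(mstd, "normalized_exact")
print(f"measured SMC raw:        {raw.pair('crop01', 'crop02'):.1f}%")
print(f"measured SMC normalized: {norm.pair('crop01', 'crop02'):.1f}%")
# With zero noise both modes equal the analytic 25.0; under
# British-spelling noise only normalization restores the ground truth.
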