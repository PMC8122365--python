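"""Audit trait-class consistency and ontology cross-referencing.

Builds a tiny three-crop collection showing both failure modes: the same
class spelt three ways, and one trait name filed under genuinely
different classes.
"""

from tdaudit import (
    TraitDescriptor,
    TraitDictionary,
    MultiSpeciesTD,
    class_conflicts,
    class_variants,
    xref_coverage,
)


def td(crop, rows):
    return TraitDictionary(
        crop_label=crop,
        descriptors=[
            TraitDescriptor(trait_name=n, trait_class=c, xrefs=x) for n, c, x in rows
        ],
    )


mstd = MultiSpeciesTD(dictionaries=[
    td("soybean", [("seed protein content", "biochemical traits", [("TO", "0000598")])]),
    td("chickpea", [("seed protein content", "quality traits", []),
                    ("days to flowering", "phenological", [])]),
    td("mungbean", [("seed protein content", "quality trait", []),
                    ("plant height", "morphological", [])]),
])

for group in class_variants(mstd):
    flag = "INCONSISTENT" if group.flagged else "ok"
    print(f"class {group.canonical_label!r}: variants {sorted(group.variants)} [{flag}]")

for conflict in class_conflicts(mstd):
    print(f"\nconflict: {conflict.trait_name!r} -> {conflict.assignments}")

report = xref_coverage(mstd)
print(f"\nxref coverage: {report.n_with_xref}/{report.n_names} names "
      f"({report.percent:.1f}%), by ontology: {report.per_prefix_counts}")
# 'quality trait(s)' variants are spelling noise (not conflicts); the
# protein-content trait is a real classification disagreement between
# crops, and only one of three names links out to an external ontology.
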