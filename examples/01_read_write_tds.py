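"""Read and write trait-dictionary tables in the supported dialects.

Builds a two-row TD in memory, writes it as a TD-template CSV, reads it
back and parses an ontology cross-reference cell.
"""

import tempfile
from pathlib import Path

from tdaudit import TraitDescriptor, TraitDictionary, parse_xref, read_td, write_td

td = TraitDictionary(
    crop_label="rice",
    descriptors=[
        TraitDescriptor(
            trait_name="Flag leaf area",
            trait_class="morphological",
            method_name="image analysis",
            scale_name="cm",
            xrefs=[("TO", "0000996")],
        ),
        TraitDescriptor(trait_name="Plant height", trait_class="morphological"),
    ],
)

with tempfile.TemporaryDirectory() as tmp:
    path = Path(tmp) / "rice_td.csv"
    write_td(td, path)
    back = read_td(path, "td_template_v5", label="rice")
    print(f"wrote and re-read {len(back)} descriptors for crop {back.crop_label!r}")
    for d in back:
        print(f"  {d.trait_name:<16} class={d.trait_class}  xrefs={d.xrefs}")

xrefs, warnings = parse_xref("PO:0025131; PATO:0000001, not-an-xref")
print(f"parsed xrefs: {xrefs}  ({len(warnings)} malformed token dropped)")
# The xref pairs link a trait row to terms in external ontologies (PO
# anatomy, PATO qualities); malformed tokens are warnings, never fatal.
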