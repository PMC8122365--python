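"""Word pools for synthetic trait-name generation.

Names are organ + property (+ optional qualifier) phrases, so every
orthographic transform used by the generator has material to act on.
Canonical spellings are American English; the British variants live in
:data:`tdaudit.harmonize.BRITISH_TO_AMERICAN`.
"""

ORGANS = (
    "leaf", "seed", "pod", "stem", "root", "flower", "grain", "shoot",
    "petiole", "peduncle", "internode", "canopy", "tuber", "panicle",
    "spike", "kernel", "shell", "leaflet", "branch", "plant",
)

PROPERTIES = (
    "length", "width", "height", "weight", "color", "number", "area",
    "diameter", "thickness", "density", "content", "yield", "vigor",
    "maturity", "duration", "angle", "shape", "texture", "flavor", "fiber",
)

QUALIFIERS = (
    "", "", "", "",  # most names have no qualifier
    "per plant", "at maturity", "at flowering", "dry", "fresh",
    "primary", "total", "average", "index", "uniformity",
)

METHODS = (
    "visual scoring", "ruler measurement", "caliper measurement",
    "balance weighing", "counting", "spectrophotometry",
    "field estimation", "image analysis",
)

SCALES = ("cm", "mm", "g", "count", "1-9 scale", "percent", "ratio", "score")
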