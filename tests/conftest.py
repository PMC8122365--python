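import pytest

from tdaudit.model import MultiSpeciesTD, TraitDescriptor, TraitDictionary


def make_td(crop, rows):
    """rows: list of names or (name, trait_class) or (name, class, xrefs)."""
    descriptors = []
    for row in rows:
        if isinstance(row, str):
            row = (row, "", [])
        name, trait_class, *rest = row
        xrefs = rest[0] if rest else []
        descriptors.append(
            TraitDescriptor(trait_name=name, trait_class=trait_class, xrefs=xrefs)
        )
    return TraitDictionary(crop_label=crop, descriptors=descriptors)


def make_mstd(**crops):
    return MultiSpeciesTD(dictionaries=[make_td(c, rows) for c, rows in crops.items()])


@pytest.fixture
def tiny_mstd():
    """Three small crops with one fully shared name."""
    return make_mstd(
        alpha=["Plant height", "Leaf color", "Pod length"],
        beta=["Plant height", "Seed weight"],
        gamma=["Plant height", "Leaf colour", "Days to flowering"],
    )
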