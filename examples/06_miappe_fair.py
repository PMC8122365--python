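"""Score a database schema against MIAPPE v1.1 and draft a FAIR checklist."""

from tdaudit import FairEntry, assess_miappe, fair_checklist, load_cropstoredb_fixture

report = assess_miappe(load_cropstoredb_fixture())
print(report.to_text())
# 'full' means every mandatory attribute of the concept is mapped by a
# schema field; the unrepresented concepts are the metadata a curator
# would need to add before a dataset is fully MIAPPE-described.

draft = [
    FairEntry("F1", "met", "each variable has a globally unique ontology identifier"),
    FairEntry("A1", "met", "records retrievable over HTTPS at a stable URL"),
    FairEntry("I2", "partial", "controlled vocabulary adopted, cross-referencing sparse"),
    FairEntry("R1.1", "met", "data released under CC BY 4.0"),
]
checklist, counts = fair_checklist(draft)
print()
print(checklist.to_text())
# Unanswered principles default to 'unmet', making gaps explicit.
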