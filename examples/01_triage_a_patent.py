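"""Triage a single patent: keyword tables + template mentions -> group.

Builds one small patent document by hand, runs both annotation scans and
prints the resulting six-group classification.
"""

from patriage import (
    IDGFamily,
    PatentDocument,
    PatentTable,
    TDL,
    TargetEntry,
    is_life_science_relevant,
    triage_document,
)

dictionary = [
    TargetEntry("T1", "LATS1", "LATS1", TDL.Tbio, IDGFamily.kinase),
    TargetEntry("T2", "G protein-coupled receptor 6", "GPR6", TDL.Tdark, IDGFamily.gpcr),
]

doc = PatentDocument(
    patent_id="US-0000001-A1",
    family_id="FAM-00001",
    classification_codes=("A61K 31/00", "C07D 401/04"),
    title="Heterocyclic inhibitors of LATS1 and uses thereof",
    abstract="Compounds that inhibit a Ser/Thr kinase are disclosed.",
    description="Example 12 showed potent activity. LATS1 binding was confirmed.",
    claims=("A compound of formula (I).", "Use of compounds that interact with GPR6."),
    tables=(PatentTable("tbl-1", ("Compound", "IC50 (nM)", "1", "12.5", "2", "340")),),
)

print(f"life-science relevant: {is_life_science_relevant(doc)}")

triage, hits, mentions = triage_document(doc, dictionary)
print(f"table keyword hits:    {[(h.keyword, h.cell_index) for h in hits]}")
for m in mentions:
    print(f"mention: {m.matched_name!r} via {m.template.pattern!r} in {m.section.value}"
          + (f" (claim {m.claim_index})" if m.claim_index is not None else ""))
print(f"group:                 {triage.group.value}")

# The patent has a bioactivity table (the IC50 column) and a target mention
# in the title, so it lands in G1 — the highest-priority curation group.
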