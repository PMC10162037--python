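"""Curation-yield reporting: per-group positive rates, corpus flag
percentage, and overlap between two family sets.

Reproduces the worked arithmetic for a curation campaign: a top-priority
group with 49 of 291 read families positive, a corpus of 3.7 M patents
with 69,289 flagged, and a 70-family result set sharing 20 families with
an external patent-extraction source.
"""

from patriage import (
    CurationLabel,
    FamilyTriage,
    Group,
    compare_family_sets,
    flag_percentage,
    summarize_groups,
)

families = [
    FamilyTriage(f"F{i:05d}", (f"F{i:05d}-P1",), frozenset({Group.G1}), Group.G1)
    for i in range(291)
]
labels = {
    f.family_id: CurationLabel(read=True, positive=i < 49)
    for i, f in enumerate(families)
}
(g1,) = [s for s in summarize_groups(families, labels) if s.group is Group.G1]
print(f"G1: {g1.families_positive}/{g1.families_read} read families positive "
      f"-> {g1.positive_rate_pct}%")

print(f"corpus flag rate: {flag_percentage(69_289, 3_700_000, headline=True):g}% "
      f"({flag_percentage(69_289, 3_700_000):.4f}% exact)")

ours = {f"FAM{i:04d}" for i in range(70)}
external = {f"FAM{i:04d}" for i in range(20)} | {f"EXT{i:04d}" for i in range(34)}
cmp = compare_family_sets(ours, external)
print(f"family overlap: {cmp.n_shared} shared, {cmp.n_only_a} only ours, "
      f"{cmp.n_only_b} only external")

# 16.8% of read top-group families carry usable bioactivity data; the
# keyword table scan flags ~2% of a life-science patent corpus.
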