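"""Generate a synthetic corpus with planted groups and recover the labels.

The generator plants each patent's group by construction (keyword tables,
template-embedded mentions, near-miss decoys); the classifier must then
recover every label exactly — the pipeline's core correctness property.
"""

from collections import Counter

from patriage import SimulationConfig, generate_corpus, triage_corpus

config = SimulationConfig(n_families=100, patents_per_family=(1, 3),
                          keyword_noise_rate=0.5, seed=42)
syn = generate_corpus(config)
print(f"{len(syn.documents)} patents in {config.n_families} families, "
      f"{len(syn.dictionary)} dictionary targets")

triages, hits, mentions = triage_corpus(syn.documents, list(syn.dictionary))
planted = {r.patent_id: r.planted_group for r in syn.truth}
n_ok = sum(1 for t in triages if t.group is planted[t.patent_id])
print(f"table hits: {len(hits)}, mentions: {len(mentions)}")
print(f"recovered planted groups: {n_ok}/{len(triages)}")
print("group distribution:", dict(sorted(Counter(t.group.value for t in triages).items())))

# Every planted label is recovered despite the 50% near-miss decoy rate:
# tokens like "NIC50" or "Kinase" sit just outside the matching rules.
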