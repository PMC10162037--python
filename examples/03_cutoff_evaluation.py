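"""Evaluate IDG Tchem potency cut-offs and promotion candidates.

Normalizes a handful of measurements to nM and decides, per target family,
whether each meets the Tchem threshold (kinase 30 nM, GPCR/NR 100 nM,
ion channel 10 uM, other 1 uM).
"""

from patriage import (
    ActivityMeasurement,
    IDGFamily,
    TDL,
    TargetEntry,
    evaluate_cutoff,
    promote_targets,
)

targets = [
    TargetEntry("T1", "LATS1", "LATS1", TDL.Tbio, IDGFamily.kinase),
    TargetEntry("T2", "G protein-coupled receptor 6", "GPR6", TDL.Tdark, IDGFamily.gpcr),
    TargetEntry("T3", "sodium channel homolog", "SCNX1", TDL.Tbio, IDGFamily.ion_channel),
]

measurements = [
    ActivityMeasurement("T1", "CMP1", "IC50", "=", 25, "nM"),     # potent kinase hit
    ActivityMeasurement("T1", "CMP2", "pIC50", "=", 7.0, "none"),  # 100 nM: too weak
    ActivityMeasurement("T2", "CMP3", "Ki", "=", 0.08, "uM"),      # 80 nM: within
    ActivityMeasurement("T2", "CMP4", "Ki", ">", 50, "nM"),        # censored away
    ActivityMeasurement("T3", "CMP5", "EC50", "=", 5, "uM"),       # within 10 uM
]

by_id = {t.target_id: t for t in targets}
for m in measurements:
    v = evaluate_cutoff(m, by_id[m.target_id].idg_family)
    print(f"{m.compound_id}: {m.activity_type} {m.relation} {m.value} {m.units}"
          f" -> {v.normalized_nM:g} nM vs {v.threshold_nM:g} nM"
          f" -> {'within' if v.within_cutoff else 'outside'}")

print()
for rec in promote_targets(measurements, targets):
    print(f"{rec.target_id}: {rec.n_within} in-cutoff measurement(s), "
          f"promotable={rec.promotable}")

# A Tdark/Tbio target with at least one in-cutoff measurement is a Tchem
# promotion candidate; censored '>' values never qualify.
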