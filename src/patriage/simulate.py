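"""Seeded synthetic patent corpora with planted ground truth.

The generator builds small corpora that look, to the pipeline, like the
normalized patent dialect: families of publications with title, abstract,
description, claims, IPC/CPC codes and flattened tables.  Each patent is
constructed to satisfy exactly the defining predicate of its planted triage
group — e.g. a G2 patent receives a table carrying one sampled bioactivity
keyword plus a template-embedded target mention only in its description or
claims — so the classifier can be scored against an exact ground truth.

Correct-by-construction guarantees:

* the decoy vocabulary (filler words, near-miss tokens such as "Kinase" and
  "NIC50") is disjoint from every template fixed word and sits just outside
  the keyword token-boundary rules, so no accidental hit or mention can
  arise;
* target names appear in a document only inside a deliberately planted
  template phrase;
* the generator writes raw text only — it never calls the annotator or the
  classifier to label its own output.

A companion generator produces activity measurements with known
within-cut-off truth for exercising the potency evaluator, including exact
boundary values at each family threshold.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from .activity import DEFAULT_THRESHOLDS_NM, ActivityMeasurement
from .annotate import DEFAULT_KEYWORDS, PhraseTemplate, default_templates
from .corpus import (
    IDGFamily,
    PatentDocument,
    PatentTable,
    Section,
    TargetEntry,
    TDL,
    write_corpus,
    write_target_dictionary,
)
from .errors import ValidationError
from .triage import Group

__all__ = [
    "SimulationConfig",
    "TruthRecord",
    "SyntheticCorpus",
    "generate_corpus",
    "generate_activities",
    "write_synthetic_corpus",
    "load_truth_tsv",
    "write_activity_truth",
]

# Filler words for decoy prose.  Deliberately free of every template fixed
# word (no "of", "inhibitors", "targeting", ...) so that no sequence of
# decoys can complete a phrase template around a target name.
DECOY_WORDS: tuple[str, ...] = (
    "granule", "porous", "membrane", "polymer", "solvent", "reactor",
    "coating", "assembly", "vessel", "catalyst", "aqueous", "slurry",
    "excipient", "lattice", "sintered", "pigment", "filtration",
    "substrate", "annealing", "extrusion", "granulation", "copolymer",
    "dispersion", "viscosity", "emulsion", "microsphere", "capsule",
    "tablet", "formulation", "matrix", "crystalline", "hydrate",
    "reagent", "distillate", "effluent", "turbine", "gasket", "flange",
    "conduit", "laminate", "abrasive", "adhesive", "dielectric",
)

# Near-miss tokens that must NOT fire the keyword detector: keywords
# embedded in longer tokens, digit-flanked, or wrong-case short symbols.
NEARMISS_TOKENS: tuple[str, ...] = (
    "Kinase", "NIC50", "IC500", "kinetics", "ki", "kd", "MIC50",
    "XC505", "picric", "logIC50", "Kit",
)

# Vocabulary for synthetic protein names; disjoint from DECOY_WORDS and
# from template fixed words.
_NAME_ADJ = ("orphan", "putative", "uncharacterized", "vestigial")
_NAME_NOUN = (
    "synthase", "oxidase", "demethylase", "esterase", "permease",
    "cyclase", "sulfatase", "reductase",
)

_GROUPS = tuple(Group)


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the synthetic corpus.

    ``group_mix`` is the sampling probability of each triage group per
    patent, in G1..G6 order.  ``keyword_noise_rate`` controls how often
    near-miss decoys (and bioactivity keywords placed in running text,
    where they must not count) are injected.
    """

    n_families: int = 200
    patents_per_family: tuple[int, int] = (1, 3)
    group_mix: tuple[float, ...] = (0.15, 0.15, 0.15, 0.15, 0.15, 0.25)
    n_targets: int = 25
    decoy_text_length: int = 60
    keyword_noise_rate: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_families <= 0 or self.n_targets < 0 or self.decoy_text_length <= 0:
            raise ValidationError("counts must be positive")
        lo, hi = self.patents_per_family
        if not (1 <= lo <= hi):
            raise ValidationError("patents_per_family must satisfy 1 <= min <= max")
        if len(self.group_mix) != 6:
            raise ValidationError("group_mix needs one probability per group")
        if any(not 0.0 <= p <= 1.0 for p in self.group_mix):
            raise ValidationError("group_mix probabilities must lie in [0, 1]")
        if abs(sum(self.group_mix) - 1.0) > 1e-9:
            raise ValidationError("group_mix must sum to 1")
        if not 0.0 <= self.keyword_noise_rate <= 1.0:
            raise ValidationError("keyword_noise_rate must lie in [0, 1]")
        needs_targets = any(p > 0 for p in self.group_mix[:4])
        if needs_targets and self.n_targets == 0:
            raise ValidationError(
                "group_mix plants mentions (G1-G4) but n_targets is 0"
            )


@dataclass(frozen=True)
class TruthRecord:
    """Planted ground truth for one synthetic patent."""

    patent_id: str
    planted_group: Group
    planted_targets: tuple[str, ...]
    planted_sections: tuple[Section, ...]
    planted_keywords: tuple[str, ...]


@dataclass(frozen=True)
class SyntheticCorpus:
    documents: tuple[PatentDocument, ...]
    truth: tuple[TruthRecord, ...]
    dictionary: tuple[TargetEntry, ...]
    config: SimulationConfig


def _make_dictionary(rng: random.Random, n_targets: int) -> list[TargetEntry]:
    entries: list[TargetEntry] = []
    for i in range(1, n_targets + 1):
        name = f"{rng.choice(_NAME_ADJ)} {rng.choice(_NAME_NOUN)} {i}"
        tdl = rng.choice((TDL.Tdark, TDL.Tbio))
        # ~10% studied entries exercise the understudied filter; their
        # names are never planted in any document.
        if rng.random() < 0.1:
            tdl = rng.choice((TDL.Tchem, TDL.Tclin))
        entries.append(
            TargetEntry(
                target_id=f"T{i:04d}",
                preferred_name=name,
                gene_symbol=f"STG{i}",
                tdl=tdl,
                idg_family=rng.choice(tuple(IDGFamily)),
            )
        )
    return entries


def _decoy_words(rng: random.Random, n: int, noise_rate: float) -> list[str]:
    words = []
    for _ in range(n):
        if rng.random() < noise_rate:
            words.append(rng.choice(NEARMISS_TOKENS))
        else:
            words.append(rng.choice(DECOY_WORDS))
    return words


def _plant_phrase(rng: random.Random, words: list[str], phrase: str) -> list[str]:
    pos = rng.randint(0, len(words))
    return words[:pos] + [phrase] + words[pos:]


def _keyword_cell(rng: random.Random, kw: str) -> str:
    forms = (
        f"{kw} (nM)",
        f"{kw}",
        f"Compound {rng.randint(1, 99)}: {kw} = {rng.randint(1, 900)} nM",
        f"{kw}-value",
    )
    return rng.choice(forms)


def _decoy_cells(rng: random.Random, n: int, noise_rate: float) -> list[str]:
    cells = []
    for _ in range(n):
        r = rng.random()
        if r < noise_rate:
            cells.append(rng.choice(NEARMISS_TOKENS))
        elif r < noise_rate + 0.2:
            cells.append(str(rng.randint(1, 5000)))
        else:
            cells.append(" ".join(_decoy_words(rng, rng.randint(1, 3), 0.0)))
    return cells


def _instantiate(tpl: PhraseTemplate, name: str) -> str:
    prefix, suffix = tpl.split()
    return prefix + name + suffix


def generate_corpus(config: SimulationConfig) -> SyntheticCorpus:
    """Build a deterministic corpus whose every patent matches its planted
    group label by construction."""
    rng = random.Random(config.seed)
    dictionary = _make_dictionary(rng, config.n_targets)
    plantable = [e for e in dictionary if e.is_understudied]
    templates = default_templates()
    needs_targets = any(p > 0 for p in config.group_mix[:4])
    if needs_targets and not plantable:
        raise ValidationError(
            "no understudied targets available to plant mentions"
        )

    docs: list[PatentDocument] = []
    truth: list[TruthRecord] = []
    pidx = 0
    noise = config.keyword_noise_rate
    for fidx in range(1, config.n_families + 1):
        family_id = f"FAM-{fidx:05d}"
        n_members = rng.randint(*config.patents_per_family)
        for _ in range(n_members):
            pidx += 1
            patent_id = f"SYN-{pidx:07d}-A1"
            group = rng.choices(_GROUPS, weights=config.group_mix, k=1)[0]

            title_words = _decoy_words(rng, rng.randint(4, 7), 0.0)
            abstract_words = _decoy_words(rng, rng.randint(10, 18), noise)
            desc_words = _decoy_words(rng, config.decoy_text_length, noise)
            claim_lists = [
                _decoy_words(rng, rng.randint(8, 14), noise)
                for _ in range(rng.randint(1, 3))
            ]
            # bioactivity keywords in running text must not flag the patent
            if rng.random() < noise:
                kw = rng.choice(DEFAULT_KEYWORDS)
                desc_words = _plant_phrase(
                    rng, desc_words, f"{kw} = {rng.randint(1, 50)} nM"
                )

            planted_targets: list[str] = []
            planted_sections: list[Section] = []
            if group in (Group.G1, Group.G3):
                sections = [rng.choice((Section.title, Section.abstract))]
                # sometimes add a lower-priority mention to exercise the
                # title/abstract-priority rule
                if rng.random() < 0.3:
                    sections.append(rng.choice((Section.description, Section.claims)))
            elif group in (Group.G2, Group.G4):
                sections = [rng.choice((Section.description, Section.claims))]
                if rng.random() < 0.3:
                    other = (
                        Section.claims
                        if sections[0] is Section.description
                        else Section.description
                    )
                    sections.append(other)
            else:
                sections = []

            for section in sections:
                entry = rng.choice(plantable)
                name = rng.choice(entry.names())
                phrase = _instantiate(rng.choice(templates), name)
                if section is Section.title:
                    title_words = _plant_phrase(rng, title_words, phrase)
                elif section is Section.abstract:
                    abstract_words = _plant_phrase(rng, abstract_words, phrase)
                elif section is Section.description:
                    desc_words = _plant_phrase(rng, desc_words, phrase)
                else:
                    ci = rng.randrange(len(claim_lists))
                    claim_lists[ci] = _plant_phrase(rng, claim_lists[ci], phrase)
                planted_targets.append(entry.target_id)
                planted_sections.append(section)

            tables: list[PatentTable] = []
            planted_keywords: list[str] = []
            if group in (Group.G1, Group.G2, Group.G5):
                kw = rng.choice(DEFAULT_KEYWORDS)
                planted_keywords.append(kw)
                cells = _decoy_cells(rng, rng.randint(2, 6), noise)
                cells.insert(rng.randint(0, len(cells)), _keyword_cell(rng, kw))
                tables.append(PatentTable(table_id="tbl-1", cells=tuple(cells)))
            elif rng.random() < 0.5:
                # keyword-free decoy table
                tables.append(
                    PatentTable(
                        table_id="tbl-1",
                        cells=tuple(_decoy_cells(rng, rng.randint(2, 6), noise)),
                    )
                )

            docs.append(
                PatentDocument(
                    patent_id=patent_id,
                    family_id=family_id,
                    publication_date=f"20{rng.randint(12, 18)}-0{rng.randint(1, 9)}-1{rng.randint(0, 9)}",
                    classification_codes=(
                        rng.choice(("A61K 31/00", "C07D 401/04", "A61P 35/00", "G01N 33/50")),
                    ),
                    title=" ".join(title_words),
                    abstract=" ".join(abstract_words),
                    description=" ".join(desc_words),
                    claims=tuple(" ".join(c) for c in claim_lists),
                    tables=tuple(tables),
                )
            )
            truth.append(
                TruthRecord(
                    patent_id=patent_id,
                    planted_group=group,
                    planted_targets=tuple(dict.fromkeys(planted_targets)),
                    planted_sections=tuple(dict.fromkeys(planted_sections)),
                    planted_keywords=tuple(planted_keywords),
                )
            )
    return SyntheticCorpus(
        documents=tuple(docs),
        truth=tuple(truth),
        dictionary=tuple(dictionary),
        config=config,
    )


# ---------------------------------------------------------------------------
# activity simulation

_CONC_TYPES = ("IC50", "XC50", "EC50", "AC50", "Ki", "Kd")
_P_OF = {"IC50": "pIC50", "XC50": "pXC50", "EC50": "pEC50", "AC50": "pAC50"}
_UNIT_FACTORS = (("pM", 1e-3), ("nM", 1.0), ("uM", 1e3), ("mM", 1e6))


def _log_uniform(rng: random.Random, lo: float, hi: float) -> float:
    import math

    return 10.0 ** rng.uniform(math.log10(lo), math.log10(hi))


def generate_activities(
    targets: Sequence[TargetEntry],
    frac_within: float,
    n_per_target: int = 8,
    seed: int = 0,
) -> tuple[list[ActivityMeasurement], list[bool]]:
    """Simulate potency measurements with known within-cut-off truth.

    Values are sampled log-uniformly on either side of the target family's
    threshold, with a safety margin so unit conversion cannot flip the
    truth; each family additionally gets one exact boundary measurement
    (value == threshold in nM), which is within the cut-off.  Censored
    records (">" concentrations, "<" p-values) are planted as never
    qualifying.  Deterministic given the seed.
    """
    if not 0.0 <= frac_within <= 1.0:
        raise ValidationError("frac_within must lie in [0, 1]")
    rng = random.Random(seed)
    measurements: list[ActivityMeasurement] = []
    flags: list[bool] = []
    cidx = 0
    boundary_done: set[IDGFamily] = set()
    for target in targets:
        threshold = DEFAULT_THRESHOLDS_NM[target.idg_family]
        if target.idg_family not in boundary_done and frac_within > 0:
            boundary_done.add(target.idg_family)
            cidx += 1
            measurements.append(
                ActivityMeasurement(
                    target_id=target.target_id,
                    compound_id=f"CMP{cidx:05d}",
                    activity_type=rng.choice(_CONC_TYPES),
                    relation="=",
                    value=threshold,  # exactly at the boundary, in nM
                    units="nM",
                )
            )
            flags.append(True)
        for _ in range(n_per_target):
            cidx += 1
            within = rng.random() < frac_within
            if within:
                nm = _log_uniform(rng, threshold * 1e-3, threshold * 0.99)
                relation = "=" if rng.random() < 0.8 else "<"
            elif rng.random() < 0.7:
                nm = _log_uniform(rng, threshold * 1.01, threshold * 1e3)
                relation = "="
            else:
                nm = _log_uniform(rng, threshold * 0.5, threshold * 10)
                relation = ">"  # censored away from potency: never qualifies
            conc_type = rng.choice(_CONC_TYPES)
            if conc_type in _P_OF and rng.random() < 0.5:
                import math

                p = 9.0 - math.log10(nm)
                p_rel = {"=": "=", "<": ">", ">": "<"}[relation]
                m = ActivityMeasurement(
                    target_id=target.target_id,
                    compound_id=f"CMP{cidx:05d}",
                    activity_type=_P_OF[conc_type],
                    relation=p_rel,
                    value=p,
                    units="none",
                )
            else:
                unit, factor = rng.choice(_UNIT_FACTORS)
                m = ActivityMeasurement(
                    target_id=target.target_id,
                    compound_id=f"CMP{cidx:05d}",
                    activity_type=conc_type,
                    relation=relation,
                    value=nm / factor,
                    units=unit,
                )
            measurements.append(m)
            flags.append(within)
    return measurements, flags


# ---------------------------------------------------------------------------
# file output

def write_synthetic_corpus(syn: SyntheticCorpus, out_dir: str | Path) -> dict[str, Path]:
    """Write corpus.jsonl, truth.tsv and targets.tsv under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "corpus": out / "corpus.jsonl",
        "truth": out / "truth.tsv",
        "targets": out / "targets.tsv",
    }
    write_corpus(syn.documents, paths["corpus"])
    with open(paths["truth"], "w", encoding="utf-8") as fh:
        fh.write(f"# seed={syn.config.seed}\n")
        fh.write("patent_id\tplanted_group\tplanted_targets\tplanted_sections\tplanted_keywords\n")
        for r in syn.truth:
            fh.write(
                f"{r.patent_id}\t{r.planted_group.value}\t"
                f"{';'.join(r.planted_targets)}\t"
                f"{';'.join(s.value for s in r.planted_sections)}\t"
                f"{';'.join(r.planted_keywords)}\n"
            )
    write_target_dictionary(syn.dictionary, paths["targets"])
    return paths


def load_truth_tsv(path: str | Path) -> list[TruthRecord]:
    records: list[TruthRecord] = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if line.startswith("#") or line.startswith("patent_id\t") or not line.strip():
                continue
            pid, grp, tgts, secs, kws = line.rstrip("\n").split("\t")
            records.append(
                TruthRecord(
                    patent_id=pid,
                    planted_group=Group(grp),
                    planted_targets=tuple(t for t in tgts.split(";") if t),
                    planted_sections=tuple(
                        Section(s) for s in secs.split(";") if s
                    ),
                    planted_keywords=tuple(k for k in kws.split(";") if k),
                )
            )
    return records


def write_activity_truth(
    measurements: Sequence[ActivityMeasurement],
    flags: Sequence[bool],
    path: str | Path,
    seed: int | None = None,
) -> None:
    """Truth flags aligned 1:1 with the measurement list, by compound_id."""
    with open(path, "w", encoding="utf-8") as fh:
        if seed is not None:
            fh.write(f"# seed={seed}\n")
        fh.write("compound_id\ttarget_id\twithin_cutoff\n")
        for m, flag in zip(measurements, flags):
            fh.write(f"{m.compound_id}\t{m.target_id}\t{str(flag).lower()}\n")
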