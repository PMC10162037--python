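"""Potency normalization and IDG Tchem cut-off evaluation.

A target qualifies for promotion from Tdark/Tbio to Tchem when at least one
small molecule modulates it with a potency at or better than the cut-off of
its IDG family: ≤30 nM for kinases, ≤100 nM for GPCRs and nuclear
receptors, ≤10 μM for ion channels and ≤1 μM for all other families.

Measurements arrive either as concentrations (IC50/XC50/EC50/AC50/Ki/Kd
with pM–M units) or as negative log-molar p-values (pIC50 etc., unitless);
both are normalized to nM before comparison:

    nM = value × unit_factor          (concentration types)
    nM = 10^(9 − p)                   (p-types; pIC50 7 → 100 nM)

Censored values are handled conservatively: "<"/"≤" concentrations qualify
when the bound itself meets the cut-off, ">"/"≥" concentrations never do
(and symmetrically for p-types, where larger is more potent).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .corpus import IDGFamily, TargetEntry
from .errors import ParseError, ValidationError

__all__ = [
    "ActivityType",
    "CONCENTRATION_TYPES",
    "P_TYPES",
    "ActivityMeasurement",
    "CutoffPolicy",
    "CutoffVerdict",
    "PromotionRecord",
    "normalize_to_nM",
    "evaluate_cutoff",
    "promote_targets",
    "load_activities",
    "write_activities_csv",
    "write_verdicts_csv",
    "write_promotions_tsv",
]

CONCENTRATION_TYPES = frozenset({"IC50", "XC50", "EC50", "AC50", "Ki", "Kd"})
P_TYPES = frozenset({"pIC50", "pXC50", "pEC50", "pAC50"})
ActivityType = str  # member of CONCENTRATION_TYPES | P_TYPES

_UNIT_TO_NM = {"pM": 1e-3, "nM": 1.0, "uM": 1e3, "mM": 1e6, "M": 1e9}

# tolerated spellings on input
_UNIT_ALIASES = {
    "pm": "pM", "nm": "nM", "um": "uM", "µm": "uM", "μm": "uM",
    "mm": "mM", "m": "M", "": "none", "none": "none",
}
_RELATION_ALIASES = {
    "=": "=", "<": "<", ">": ">",
    "<=": "<=", "≤": "<=", "=<": "<=",
    ">=": ">=", "≥": ">=", "=>": ">=",
}


def _canon_relation(rel: str) -> str:
    try:
        return _RELATION_ALIASES[rel.strip()]
    except KeyError:
        raise ValidationError(f"unknown relation {rel!r}") from None


def _canon_units(units: str) -> str:
    u = units.strip()
    if u in _UNIT_TO_NM or u == "none":
        return u
    try:
        return _UNIT_ALIASES[u.lower()]
    except KeyError:
        raise ValidationError(f"unknown units {units!r}") from None


@dataclass(frozen=True)
class ActivityMeasurement:
    """One potency measurement of a compound against a target."""

    target_id: str
    compound_id: str
    activity_type: ActivityType
    relation: str  # one of = < <= > >=
    value: float
    units: str  # pM/nM/uM/mM/M for concentration types, "none" for p-types

    def __post_init__(self) -> None:
        object.__setattr__(self, "relation", _canon_relation(self.relation))
        object.__setattr__(self, "units", _canon_units(self.units))
        if self.activity_type not in CONCENTRATION_TYPES | P_TYPES:
            raise ValidationError(f"unknown activity_type {self.activity_type!r}")
        if not (self.value > 0):
            raise ValidationError(f"value must be positive, got {self.value!r}")
        if self.activity_type in P_TYPES and self.units != "none":
            raise ValidationError(
                f"{self.activity_type} is unitless; got units {self.units!r}"
            )
        if self.activity_type in CONCENTRATION_TYPES and self.units == "none":
            raise ValidationError(
                f"{self.activity_type} requires concentration units"
            )

    @property
    def is_p_type(self) -> bool:
        return self.activity_type in P_TYPES


#: IDG Tchem potency thresholds in nM per target family.
DEFAULT_THRESHOLDS_NM: Mapping[IDGFamily, float] = {
    IDGFamily.kinase: 30.0,
    IDGFamily.gpcr: 100.0,
    IDGFamily.nuclear_receptor: 100.0,
    IDGFamily.ion_channel: 10_000.0,
    IDGFamily.other: 1_000.0,
}


@dataclass(frozen=True)
class CutoffPolicy:
    """Per-family potency thresholds (nM); boundary equality qualifies."""

    thresholds_nM: Mapping[IDGFamily, float] = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        th = dict(self.thresholds_nM or DEFAULT_THRESHOLDS_NM)
        missing = set(IDGFamily) - set(th)
        if missing:
            raise ValidationError(f"missing thresholds for {sorted(f.value for f in missing)}")
        if any(v <= 0 for v in th.values()):
            raise ValidationError("thresholds must be positive")
        object.__setattr__(self, "thresholds_nM", th)


def normalize_to_nM(m: ActivityMeasurement) -> float:
    """Express a measurement in nM (p-types via 10^(9 − p))."""
    if m.is_p_type:
        return 10.0 ** (9.0 - m.value)
    return m.value * _UNIT_TO_NM[m.units]


# relations under which the reported bound can certify potency
_QUALIFYING_CONC = {"=", "<", "<="}
_QUALIFYING_P = {"=", ">", ">="}


@dataclass(frozen=True)
class CutoffVerdict:
    measurement: ActivityMeasurement
    threshold_nM: float
    normalized_nM: float
    within_cutoff: bool


def evaluate_cutoff(
    m: ActivityMeasurement,
    family: IDGFamily,
    policy: CutoffPolicy | None = None,
) -> CutoffVerdict:
    """Decide whether one measurement meets its family's Tchem cut-off."""
    policy = policy or CutoffPolicy()
    threshold = policy.thresholds_nM[family]
    nm = normalize_to_nM(m)
    qualifying = _QUALIFYING_P if m.is_p_type else _QUALIFYING_CONC
    within = m.relation in qualifying and nm <= threshold
    return CutoffVerdict(m, threshold, nm, within)


@dataclass(frozen=True)
class PromotionRecord:
    target_id: str
    n_within: int
    promotable: bool


def promote_targets(
    measurements: Sequence[ActivityMeasurement],
    targets: Sequence[TargetEntry],
    policy: CutoffPolicy | None = None,
) -> list[PromotionRecord]:
    """Per-target cut-off tally; promotable = understudied with ≥1 hit.

    Targets already at Tchem/Tclin are never promotable, whatever their
    measured potencies.  Raises if a measurement references a target absent
    from the dictionary.
    """
    policy = policy or CutoffPolicy()
    by_id = {t.target_id: t for t in targets}
    n_within: dict[str, int] = {t.target_id: 0 for t in targets}
    for m in measurements:
        target = by_id.get(m.target_id)
        if target is None:
            raise ValidationError(
                f"measurement for unknown target {m.target_id!r}"
            )
        if evaluate_cutoff(m, target.idg_family, policy).within_cutoff:
            n_within[m.target_id] += 1
    return [
        PromotionRecord(
            target_id=t.target_id,
            n_within=n_within[t.target_id],
            promotable=t.is_understudied and n_within[t.target_id] >= 1,
        )
        for t in targets
    ]


# ---------------------------------------------------------------------------
# I/O

_ACTIVITY_COLUMNS = ["target_id", "compound_id", "activity_type", "relation", "value", "units"]


def load_activities(path: str | Path) -> list[ActivityMeasurement]:
    """Read the activity CSV (columns: target_id, compound_id,
    activity_type, relation, value, units)."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in _ACTIVITY_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"activity table missing columns: {missing}")
    out: list[ActivityMeasurement] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            out.append(
                ActivityMeasurement(
                    target_id=row.target_id,
                    compound_id=row.compound_id,
                    activity_type=row.activity_type,
                    relation=row.relation,
                    value=float(row.value),
                    units=row.units,
                )
            )
        except (ValidationError, ValueError) as exc:
            raise ValidationError(f"row {i}: {exc}") from exc
    return out


def write_activities_csv(
    measurements: Iterable[ActivityMeasurement], path: str | Path
) -> None:
    """Inverse of :func:`load_activities`."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(_ACTIVITY_COLUMNS)
        for m in measurements:
            w.writerow(
                [m.target_id, m.compound_id, m.activity_type, m.relation,
                 repr(m.value), m.units]
            )


def write_verdicts_csv(verdicts: Iterable[CutoffVerdict], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(_ACTIVITY_COLUMNS + ["normalized_nM", "threshold_nM", "within_cutoff"])
        for v in verdicts:
            m = v.measurement
            w.writerow(
                [m.target_id, m.compound_id, m.activity_type, m.relation,
                 repr(m.value), m.units,
                 f"{v.normalized_nM:.6g}", f"{v.threshold_nM:g}",
                 str(v.within_cutoff).lower()]
            )


def write_promotions_tsv(records: Iterable[PromotionRecord], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("target_id\tn_within\tpromotable\n")
        for r in records:
            fh.write(f"{r.target_id}\t{r.n_within}\t{str(r.promotable).lower()}\n")
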