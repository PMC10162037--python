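"""Summary statistics over triaged families: per-group curation yields,
corpus flag percentages, and two-source family-set comparisons.

Curation labels (whether a family was read, and whether reading found
quantitative bioactivity data on an understudied target) come from human
review and are supplied as input; this module only does the accounting.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .errors import ValidationError
from .triage import FamilyTriage, Group

__all__ = [
    "CurationLabel",
    "GroupSummary",
    "SetComparison",
    "summarize_groups",
    "flag_percentage",
    "compare_family_sets",
    "load_labels_tsv",
    "write_group_summaries",
]


@dataclass(frozen=True)
class CurationLabel:
    """Human-review outcome for one family."""

    read: bool
    positive: bool

    def __post_init__(self) -> None:
        if self.positive and not self.read:
            raise ValidationError("a family cannot be positive without being read")


@dataclass(frozen=True)
class GroupSummary:
    group: Group
    families_total: int
    families_read: int
    families_positive: int
    positive_rate_pct: float | None  # one decimal, absent when nothing read

    def __post_init__(self) -> None:
        if not 0 <= self.families_positive <= self.families_read <= self.families_total:
            raise ValidationError(
                f"{self.group.value}: need 0 <= positive <= read <= total"
            )


def _round_half_up(x: Decimal, places: str) -> Decimal:
    return x.quantize(Decimal(places), rounding=ROUND_HALF_UP)


def positive_rate_pct(n_positive: int, n_read: int) -> float:
    """100 × positive / read, rounded half-up to one decimal."""
    if n_read <= 0:
        raise ValidationError("rate undefined when no families were read")
    rate = Decimal(100 * n_positive) / Decimal(n_read)
    return float(_round_half_up(rate, "0.1"))


def summarize_groups(
    families: Sequence[FamilyTriage],
    curation_labels: Mapping[str, CurationLabel],
    *,
    multi_membership: bool = True,
) -> list[GroupSummary]:
    """Per-group family counts and positive rates.

    With ``multi_membership`` (default) a family contributes to every group
    in its union set, matching how cross-group overlaps are reported; with
    it off, each family counts only under its best_group.
    """
    known = {f.family_id for f in families}
    unknown = set(curation_labels) - known
    if unknown:
        raise ValidationError(f"labels reference unknown families: {sorted(unknown)[:5]}")
    out: list[GroupSummary] = []
    for g in Group:
        member_ids = [
            f.family_id
            for f in families
            if (g in f.groups if multi_membership else f.best_group is g)
        ]
        labels = [curation_labels.get(fid) for fid in member_ids]
        n_read = sum(1 for l in labels if l is not None and l.read)
        n_pos = sum(1 for l in labels if l is not None and l.positive)
        out.append(
            GroupSummary(
                group=g,
                families_total=len(member_ids),
                families_read=n_read,
                families_positive=n_pos,
                positive_rate_pct=positive_rate_pct(n_pos, n_read) if n_read else None,
            )
        )
    return out


def flag_percentage(n_flagged: int, n_corpus: int, *, headline: bool = False) -> float:
    """Share of the corpus that was flagged, as a percentage.

    ``headline=True`` rounds half-up to the nearest integer, the form used
    for corpus-level reporting.
    """
    if n_corpus <= 0:
        raise ValidationError("corpus size must be positive")
    if not 0 <= n_flagged <= n_corpus:
        raise ValidationError("need 0 <= n_flagged <= n_corpus")
    pct = Decimal(100 * n_flagged) / Decimal(n_corpus)
    if headline:
        return float(_round_half_up(pct, "1"))
    return float(pct)


@dataclass(frozen=True)
class SetComparison:
    """Overlap accounting between two family-id sets."""

    n_a: int
    n_b: int
    n_shared: int
    n_only_a: int
    n_only_b: int

    def __post_init__(self) -> None:
        if self.n_only_a != self.n_a - self.n_shared or self.n_only_a < 0:
            raise ValidationError("inconsistent A-side counts")
        if self.n_only_b != self.n_b - self.n_shared or self.n_only_b < 0:
            raise ValidationError("inconsistent B-side counts")

    def to_dict(self) -> dict:
        return {
            "n_a": self.n_a,
            "n_b": self.n_b,
            "n_shared": self.n_shared,
            "n_only_a": self.n_only_a,
            "n_only_b": self.n_only_b,
        }


def compare_family_sets(a: Iterable[str], b: Iterable[str]) -> SetComparison:
    """Exact intersection/difference sizes of two family-id sets."""
    sa, sb = set(a), set(b)
    shared = len(sa & sb)
    return SetComparison(
        n_a=len(sa),
        n_b=len(sb),
        n_shared=shared,
        n_only_a=len(sa) - shared,
        n_only_b=len(sb) - shared,
    )


# ---------------------------------------------------------------------------
# I/O

_TRUE = {"1", "true", "yes"}
_FALSE = {"0", "false", "no"}


def _parse_bool(token: str, lineno: int) -> bool:
    t = token.strip().lower()
    if t in _TRUE:
        return True
    if t in _FALSE:
        return False
    raise ValidationError(f"line {lineno}: expected boolean, got {token!r}")


def load_labels_tsv(path: str | Path) -> dict[str, CurationLabel]:
    """Read curation labels: TSV with header family_id, read, positive."""
    labels: dict[str, CurationLabel] = {}
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:3] != ["family_id", "read", "positive"]:
            raise ValidationError(
                f"labels file must start with header family_id/read/positive, got {header}"
            )
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise ValidationError(f"line {lineno}: expected 3 columns")
            fid = parts[0]
            if fid in labels:
                raise ValidationError(f"line {lineno}: duplicate family {fid!r}")
            try:
                labels[fid] = CurationLabel(
                    read=_parse_bool(parts[1], lineno),
                    positive=_parse_bool(parts[2], lineno),
                )
            except ValidationError as exc:
                raise ValidationError(f"line {lineno}: {exc}") from exc
    return labels


def write_group_summaries(
    summaries: Sequence[GroupSummary], tsv_path: str | Path, json_path: str | Path
) -> None:
    """Emit the group report as both TSV and a single JSON document."""
    with open(tsv_path, "w", encoding="utf-8") as fh:
        fh.write("group\tfamilies_total\tfamilies_read\tfamilies_positive\tpositive_rate_pct\n")
        for s in summaries:
            rate = "" if s.positive_rate_pct is None else f"{s.positive_rate_pct:.1f}"
            fh.write(
                f"{s.group.value}\t{s.families_total}\t{s.families_read}\t"
                f"{s.families_positive}\t{rate}\n"
            )
    payload = [
        {
            "group": s.group.value,
            "families_total": s.families_total,
            "families_read": s.families_read,
            "families_positive": s.families_positive,
            "positive_rate_pct": s.positive_rate_pct,
        }
        for s in summaries
    ]
    with open(json_path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2)
        fh.write("\n")
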