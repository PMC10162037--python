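"""Six-group triage of patents and aggregation to patent families.

Each patent lands in exactly one group, determined by two independent
signals: whether it has bioactivity-keyword tables, and in which sections
understudied targets are mentioned.  Title/abstract mentions outrank
description/claims mentions, so the groups partition the corpus:

===== ====================== ==========================================
group bioactivity tables     target mentions
===== ====================== ==========================================
G1    yes                    in title or abstract
G2    yes                    only in description or claims
G3    no                     in title or abstract
G4    no                     only in description or claims
G5    yes                    none
G6    no                     none
===== ====================== ==========================================

A patent family (a set of publications with identical content filed in
different offices or stages) is triaged as the union of its members'
groups, with ``best_group`` the highest-priority one (G1 > G2 > ... > G6);
curation effort is budgeted per family, not per publication.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

from .annotate import (
    KeywordPolicy,
    PhraseTemplate,
    TableHit,
    TargetMention,
    detect_bioactivity_tables,
    find_target_mentions,
)
from .corpus import PatentDocument, Section, TargetEntry
from .errors import ValidationError

__all__ = [
    "Group",
    "GROUP_PRIORITY",
    "PatentTriage",
    "FamilyTriage",
    "classify_patent",
    "triage_document",
    "triage_corpus",
    "aggregate_families",
    "write_triage_tsv",
    "write_families_tsv",
]


class Group(str, Enum):
    G1 = "G1"
    G2 = "G2"
    G3 = "G3"
    G4 = "G4"
    G5 = "G5"
    G6 = "G6"


#: lower value = higher curation priority
GROUP_PRIORITY = {g: i for i, g in enumerate(Group)}

_TITLE_ABSTRACT = {Section.title, Section.abstract}


def classify_patent(has_tables: bool, mention_sections: Iterable[Section]) -> Group:
    """Total classification of one patent from its two triage signals."""
    sections = set(mention_sections)
    bad = sections - set(Section)
    if bad:
        raise ValidationError(f"unknown sections: {sorted(s for s in bad)}")
    in_ta = bool(sections & _TITLE_ABSTRACT)
    if has_tables:
        if in_ta:
            return Group.G1
        if sections:
            return Group.G2
        return Group.G5
    if in_ta:
        return Group.G3
    if sections:
        return Group.G4
    return Group.G6


@dataclass(frozen=True)
class PatentTriage:
    """Group assignment for a single patent publication."""

    patent_id: str
    family_id: str
    group: Group
    has_bioactivity_tables: bool
    mention_sections: frozenset[Section]

    def __post_init__(self) -> None:
        expected = classify_patent(self.has_bioactivity_tables, self.mention_sections)
        if expected is not self.group:
            raise ValidationError(
                f"patent {self.patent_id!r}: group {self.group.value} inconsistent "
                f"with signals (expected {expected.value})"
            )


def triage_document(
    doc: PatentDocument,
    dictionary: Sequence[TargetEntry],
    templates: Sequence[PhraseTemplate] | None = None,
    keyword_policy: KeywordPolicy | None = None,
) -> tuple[PatentTriage, list[TableHit], list[TargetMention]]:
    """Run both scans on one document and classify it."""
    hits = detect_bioactivity_tables(doc, keyword_policy)
    mentions = find_target_mentions(doc, dictionary, templates)
    sections = frozenset(m.section for m in mentions)
    group = classify_patent(bool(hits), sections)
    return (
        PatentTriage(doc.patent_id, doc.family_id, group, bool(hits), sections),
        hits,
        mentions,
    )


def triage_corpus(
    docs: Sequence[PatentDocument],
    dictionary: Sequence[TargetEntry],
    templates: Sequence[PhraseTemplate] | None = None,
    keyword_policy: KeywordPolicy | None = None,
) -> tuple[list[PatentTriage], list[TableHit], list[TargetMention]]:
    """Triage every document of a corpus; outputs in corpus order."""
    triages, all_hits, all_mentions = [], [], []
    for doc in docs:
        t, hits, mentions = triage_document(doc, dictionary, templates, keyword_policy)
        triages.append(t)
        all_hits.extend(hits)
        all_mentions.extend(mentions)
    return triages, all_hits, all_mentions


@dataclass(frozen=True)
class FamilyTriage:
    """Union of member-patent groups for one patent family."""

    family_id: str
    member_patent_ids: tuple[str, ...]
    groups: frozenset[Group]
    best_group: Group

    def __post_init__(self) -> None:
        if not self.groups:
            raise ValidationError(f"family {self.family_id!r}: empty group set")
        if self.best_group not in self.groups:
            raise ValidationError(
                f"family {self.family_id!r}: best_group not in groups"
            )


def aggregate_families(triages: Sequence[PatentTriage]) -> list[FamilyTriage]:
    """One FamilyTriage per distinct family_id, sorted by family_id.

    A family's ``groups`` is the union over members, so one family can
    contribute to several per-group counts — this is what produces the
    observed overlap between adjacent groups when members disagree.
    """
    by_family: dict[str, list[PatentTriage]] = {}
    for t in triages:
        by_family.setdefault(t.family_id, []).append(t)
    out: list[FamilyTriage] = []
    for family_id in sorted(by_family):
        members = by_family[family_id]
        groups = frozenset(t.group for t in members)
        best = min(groups, key=GROUP_PRIORITY.__getitem__)
        out.append(
            FamilyTriage(
                family_id=family_id,
                member_patent_ids=tuple(sorted(t.patent_id for t in members)),
                groups=groups,
                best_group=best,
            )
        )
    return out


def read_triage_tsv(path: str | Path) -> list[PatentTriage]:
    """Read back a triage TSV written by :func:`write_triage_tsv`."""
    out: list[PatentTriage] = []
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        expected = ["patent_id", "family_id", "group", "has_bioactivity_tables", "mention_sections"]
        if header != expected:
            raise ValidationError(f"unexpected triage header: {header}")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 5:
                raise ValidationError(f"line {lineno}: expected 5 columns")
            pid, fid, grp, tables, secs = parts
            try:
                out.append(
                    PatentTriage(
                        patent_id=pid,
                        family_id=fid,
                        group=Group(grp),
                        has_bioactivity_tables=tables == "true",
                        mention_sections=frozenset(
                            Section(s) for s in secs.split(";") if s
                        ),
                    )
                )
            except (ValueError, ValidationError) as exc:
                raise ValidationError(f"line {lineno}: {exc}") from exc
    return out


def _sections_str(sections: frozenset[Section]) -> str:
    order = [Section.title, Section.abstract, Section.description, Section.claims]
    return ";".join(s.value for s in order if s in sections)


def write_triage_tsv(triages: Iterable[PatentTriage], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("patent_id\tfamily_id\tgroup\thas_bioactivity_tables\tmention_sections\n")
        for t in triages:
            fh.write(
                f"{t.patent_id}\t{t.family_id}\t{t.group.value}\t"
                f"{str(t.has_bioactivity_tables).lower()}\t{_sections_str(t.mention_sections)}\n"
            )


def write_families_tsv(families: Iterable[FamilyTriage], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("family_id\tn_members\tgroups\tbest_group\n")
        for f in families:
            groups = ";".join(sorted(g.value for g in f.groups))
            fh.write(
                f"{f.family_id}\t{len(f.member_patent_ids)}\t{groups}\t{f.best_group.value}\n"
            )
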