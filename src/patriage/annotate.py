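"""Bioactivity-keyword detection in patent tables and template-based
target-mention search in patent text sections.

Two independent scans drive the triage classification:

* **Table scan** — a patent is flagged as potentially carrying quantitative
  bioactivity data when any table cell contains one of the activity-type
  keywords (IC50, EC50, Ki, Kd, pIC50, "IC 50", ...).  Matching is
  token-bounded: a keyword never matches inside a longer alphanumeric token,
  so the "Ki" in "Kinase" and the "IC50" in "NIC50" do not fire, while
  "IC50-value" and "(IC50)" do.  Keywords in running text (description,
  claims) deliberately produce no hits.

* **Mention scan** — an understudied target counts as mentioned only when
  one of its dictionary names or gene symbols appears inside a phrase
  template such as "Inhibitors of X" or "Compounds that interact with X".
  A bare name with no template context is not a mention.  All four sections
  (title, abstract, description, claims) are scanned with the same template
  list; claims are scanned claim-by-claim with per-claim offsets.

Offsets in hits and mentions refer to the *normalized* text of the cell or
section (whitespace collapsed to single spaces, Unicode dashes folded to
ASCII hyphen), so the recorded [start, end) slice always reproduces the
matched phrase.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path
from typing import Iterable, Sequence

from .corpus import SECTION_ORDER, PatentDocument, Section, TargetEntry
from .errors import ValidationError

__all__ = [
    "DEFAULT_KEYWORDS",
    "DEFAULT_CASE_SENSITIVE_KEYWORDS",
    "DEFAULT_TEMPLATES_RAW",
    "KeywordPolicy",
    "TableHit",
    "PhraseTemplate",
    "TargetMention",
    "normalize_text",
    "detect_bioactivity_tables",
    "compile_templates",
    "default_templates",
    "find_target_mentions",
    "write_table_hits_tsv",
    "write_mentions_tsv",
]

# Activity-type keywords scanned for inside table cells.  The en-dash /
# minus variants in the -log() forms are folded to ASCII before matching.
DEFAULT_KEYWORDS: tuple[str, ...] = (
    "IC50", "XC50", "EC50", "AC50",
    "Ki", "Kd",
    "pIC50", "pXC50", "pEC50", "pAC50",
    "−log(IC50)", "−log(XC50)", "−log(EC50)", "−log(AC50)",
    "concentration to inhibit",
    "IC-50", "XC-50", "EC-50", "AC-50",
    "IC 50", "XC 50", "EC 50", "AC 50",
)

# Two-letter symbols are matched case-sensitively: lowercase "ki"/"kd" are
# far too common as word fragments and abbreviations to allow.
DEFAULT_CASE_SENSITIVE_KEYWORDS: frozenset[str] = frozenset({"Ki", "Kd"})

# Phrase templates signalling small-molecule bioactivity context around a
# target name X.  "a|b" marks an alternation expanded by compile_templates.
DEFAULT_TEMPLATES_RAW: tuple[str, ...] = (
    "X inhibitors",
    "Inhibitors of X",
    "X inhibitor",
    "Modulators of X",
    "Modulation of X",
    "Targeting X",
    "X modulators",
    "Binding specifically to X",
    "X mutants",
    "Inhibit X",
    "Antibodies recognis|zing X",
    "Modulating the X",
    "Selective X inhibitors",
    "X antagonists",
    "X agonist",
    "X selective binding compounds",
    "Activity of X",
    "X antibodies",
    "X activity",
    "Inhibitor of X",
    "X binding",
    "Antibodies directed against X",
    "Treatment of X related",
    "Antibody for X",
    "Anti-X antibody",
    "Human anti-X",
    "Antibodies to X",
    "High X affinity",
    "Inhibiting X",
    "Blocks|block X",
    "Blocking X",
    "Ligand|ligands for X",
    "Compounds that interact with X",
    "Modulating the function of X",
    "X ligand|ligands",
)

_DASHES = dict.fromkeys(map(ord, "‐‑‒–—―−"), "-")


def normalize_text(text: str) -> str:
    """Collapse whitespace to single spaces and fold Unicode dashes to '-'.

    All matching (and every recorded offset) operates on this form.
    """
    return " ".join(text.translate(_DASHES).split())


# token boundary: a match may not be flanked by letters or digits; hyphens,
# parentheses and punctuation all count as boundaries.
_LB = r"(?<![A-Za-z0-9])"
_RB = r"(?![A-Za-z0-9])"


@dataclass(frozen=True)
class KeywordPolicy:
    """The table-scan keyword list and its case-sensitivity rule."""

    keywords: tuple[str, ...] = DEFAULT_KEYWORDS
    case_sensitive_short: frozenset[str] = DEFAULT_CASE_SENSITIVE_KEYWORDS

    def __post_init__(self) -> None:
        if not self.keywords:
            raise ValidationError("keyword list must be non-empty")
        extra = self.case_sensitive_short - set(self.keywords)
        if extra:
            raise ValidationError(
                f"case-sensitive keywords not in keyword list: {sorted(extra)}"
            )

    def compiled(self) -> tuple[tuple[str, "re.Pattern[str]"], ...]:
        return tuple(
            (kw, _keyword_regex(normalize_text(kw), kw in self.case_sensitive_short))
            for kw in self.keywords
        )


@lru_cache(maxsize=4096)
def _keyword_regex(norm_kw: str, case_sensitive: bool) -> "re.Pattern[str]":
    flags = 0 if case_sensitive else re.IGNORECASE
    return re.compile(_LB + re.escape(norm_kw) + _RB, flags)


@dataclass(frozen=True)
class TableHit:
    """A keyword occurrence localized to one table cell."""

    patent_id: str
    table_id: str
    keyword: str
    cell_index: int
    char_offset: int  # 0-based, in the normalized cell text


def detect_bioactivity_tables(
    doc: PatentDocument, policy: KeywordPolicy | None = None
) -> list[TableHit]:
    """All keyword occurrences in the patent's table cells.

    A non-empty result is what flags a document as "has bioactivity
    tables".  Keywords in the description or claims never produce hits.
    """
    policy = policy or KeywordPolicy()
    compiled = policy.compiled()
    hits: list[TableHit] = []
    for table in doc.tables:
        for cell_index, cell in enumerate(table.cells):
            norm = normalize_text(cell)
            for kw, rx in compiled:
                for m in rx.finditer(norm):
                    hits.append(
                        TableHit(doc.patent_id, table.table_id, kw,
                                 cell_index, m.start())
                    )
    hits.sort(key=lambda h: (h.table_id, h.cell_index, h.char_offset, h.keyword))
    return hits


# ---------------------------------------------------------------------------
# phrase templates


@dataclass(frozen=True)
class PhraseTemplate:
    """One concrete phrase pattern with a single X placeholder."""

    pattern: str  # e.g. "Inhibitors of X", alternations already expanded
    raw: str  # the source string the pattern was expanded from

    def split(self) -> tuple[str, str]:
        """(prefix, suffix) around the X placeholder."""
        m = _PLACEHOLDER.search(self.pattern)
        assert m is not None
        return self.pattern[: m.start()], self.pattern[m.end():]


_PLACEHOLDER = re.compile(r"(?<![A-Za-z0-9])X(?![A-Za-z0-9])")


def _expand_alternation(raw: str) -> list[str]:
    tokens = raw.split(" ")
    out = [""]
    for i, tok in enumerate(tokens):
        if "|" not in tok:
            variants = [tok]
        else:
            left, right = tok.split("|", 1)
            if not left or not right:
                raise ValidationError(f"template {raw!r}: empty alternation side")
            if left.lower().startswith(right.lower()) or right.lower().startswith(
                left.lower()
            ):
                # whole-token alternation: "Blocks|block" -> Blocks / block
                variants = [left, right]
            else:
                # in-word alternation: "recognis|zing" -> recognising / recognizing
                variants = [left + right[1:], left[:-1] + right]
        sep = " " if i else ""
        out = [p + sep + v for p in out for v in variants]
    return out


def compile_templates(raw_templates: Iterable[str]) -> list[PhraseTemplate]:
    """Expand alternation groups and validate the single-X invariant."""
    templates: list[PhraseTemplate] = []
    for raw in raw_templates:
        for pattern in _expand_alternation(raw):
            n = len(_PLACEHOLDER.findall(pattern))
            if n != 1:
                raise ValidationError(
                    f"template {raw!r}: expected exactly one X placeholder, "
                    f"found {n} in {pattern!r}"
                )
            templates.append(PhraseTemplate(pattern=pattern, raw=raw))
    return templates


def default_templates() -> list[PhraseTemplate]:
    """The default phrase-template set, alternations expanded."""
    return compile_templates(DEFAULT_TEMPLATES_RAW)


# ---------------------------------------------------------------------------
# target mentions


@dataclass(frozen=True)
class TargetMention:
    """A dictionary name matched inside a template phrase in one section.

    ``start``/``end`` are 0-based half-open character offsets into the
    normalized section text; for claims they are per-claim, with
    ``claim_index`` recording which claim.
    """

    patent_id: str
    target_id: str
    matched_name: str
    template: PhraseTemplate
    section: Section
    start: int
    end: int
    claim_index: int | None = None


# Names of 4+ characters match case-insensitively; shorter strings (short
# gene symbols like "KIT") match case-sensitively to limit false positives.
_CASE_INSENSITIVE_MIN_LEN = 4


def _name_regex_fragment(name: str) -> str:
    # internal whitespace/hyphen variation is tolerated: "beta-2 adrenergic"
    # matches "beta 2-adrenergic" etc.
    parts = [re.escape(p) for p in re.split(r"[\s\-]+", normalize_text(name)) if p]
    body = "[ -]".join(parts)
    if len(name) >= _CASE_INSENSITIVE_MIN_LEN:
        return f"(?i:{body})"
    return body


@lru_cache(maxsize=65536)
def _phrase_regex(prefix: str, suffix: str, name: str) -> "re.Pattern[str]":
    pre = f"(?i:{re.escape(prefix)})" if prefix else ""
    suf = f"(?i:{re.escape(suffix)})" if suffix else ""
    return re.compile(_LB + pre + _name_regex_fragment(name) + suf + _RB)


def _scan_text(
    text: str,
    patent_id: str,
    section: Section,
    claim_index: int | None,
    entries: Sequence[TargetEntry],
    templates: Sequence[PhraseTemplate],
) -> list[TargetMention]:
    norm = normalize_text(text)
    if not norm:
        return []
    mentions: list[TargetMention] = []
    for tpl in templates:
        prefix, suffix = tpl.split()
        for entry in entries:
            for name in entry.names():
                rx = _phrase_regex(prefix, suffix, name)
                pos = 0
                while True:
                    m = rx.search(norm, pos)
                    if m is None:
                        break
                    mentions.append(
                        TargetMention(
                            patent_id=patent_id,
                            target_id=entry.target_id,
                            matched_name=name,
                            template=tpl,
                            section=section,
                            start=m.start(),
                            end=m.end(),
                            claim_index=claim_index,
                        )
                    )
                    pos = m.start() + 1  # allow overlapping occurrences
    return mentions


def find_target_mentions(
    doc: PatentDocument,
    dictionary: Sequence[TargetEntry],
    templates: Sequence[PhraseTemplate] | None = None,
    *,
    understudied_only: bool = True,
) -> list[TargetMention]:
    """All (target, template, position) matches in the four sections.

    Every combination is reported — overlapping mentions of different
    targets are not suppressed.  Output is deterministic, ordered by
    (section, claim index, start, target_id, pattern).
    """
    templates = templates if templates is not None else default_templates()
    entries = [e for e in dictionary if e.is_understudied] if understudied_only else list(dictionary)
    mentions: list[TargetMention] = []
    mentions += _scan_text(doc.title, doc.patent_id, Section.title, None, entries, templates)
    mentions += _scan_text(doc.abstract, doc.patent_id, Section.abstract, None, entries, templates)
    mentions += _scan_text(doc.description, doc.patent_id, Section.description, None, entries, templates)
    for ci, claim in enumerate(doc.claims):
        mentions += _scan_text(claim, doc.patent_id, Section.claims, ci, entries, templates)
    mentions.sort(
        key=lambda m: (
            SECTION_ORDER[m.section],
            -1 if m.claim_index is None else m.claim_index,
            m.start,
            m.target_id,
            m.template.pattern,
        )
    )
    return mentions


# ---------------------------------------------------------------------------
# standoff output


def write_table_hits_tsv(hits: Iterable[TableHit], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("patent_id\ttable_id\tkeyword\tcell_index\tchar_offset\n")
        for h in hits:
            fh.write(
                f"{h.patent_id}\t{h.table_id}\t{h.keyword}\t{h.cell_index}\t{h.char_offset}\n"
            )


def write_mentions_tsv(mentions: Iterable[TargetMention], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(
            "patent_id\ttarget_id\tmatched_name\ttemplate\tsection\t"
            "claim_index\tstart\tend\n"
        )
        for m in mentions:
            ci = "" if m.claim_index is None else str(m.claim_index)
            fh.write(
                f"{m.patent_id}\t{m.target_id}\t{m.matched_name}\t"
                f"{m.template.pattern}\t{m.section.value}\t{ci}\t{m.start}\t{m.end}\n"
            )
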