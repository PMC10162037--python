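"""Domain types and I/O for the normalized patent corpus and target dictionary.

The corpus dialect is JSON-lines: one UTF-8 JSON object per patent
publication with keys ``patent_id``, ``family_id``, ``publication_date``,
``classification_codes``, ``title``, ``abstract``, ``description``,
``claims`` (array of strings) and ``tables`` (array of
``{table_id, cells}``).  Every field except ``patent_id`` and ``family_id``
is optional and defaults to empty; JPO-style records carrying only a title
and abstract are valid documents.

The target dictionary is a TSV with header
``target_id  preferred_name  gene_symbol  tdl  idg_family`` emulating the
IDG target development level (TDL) export from TCRD: each row is one human
protein with its preferred name, HGNC-style gene symbol, TDL tier and IDG
family class.  Only Tdark/Tbio rows count as understudied, but all rows are
retained so a caller can reason about the full dictionary.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .errors import ParseError, ValidationError

__all__ = [
    "TDL",
    "IDGFamily",
    "Section",
    "PatentTable",
    "PatentDocument",
    "TargetEntry",
    "LifeScienceCodePolicy",
    "DEFAULT_LIFESCI_PREFIXES",
    "read_corpus",
    "write_corpus",
    "load_target_dictionary",
    "write_target_dictionary",
    "understudied",
    "is_life_science_relevant",
]


class TDL(str, Enum):
    """IDG target development level: how well studied a protein is."""

    Tdark = "Tdark"
    Tbio = "Tbio"
    Tchem = "Tchem"
    Tclin = "Tclin"


class IDGFamily(str, Enum):
    """IDG target family class, which fixes the Tchem potency cut-off."""

    kinase = "kinase"
    gpcr = "gpcr"
    nuclear_receptor = "nuclear_receptor"
    ion_channel = "ion_channel"
    other = "other"


class Section(str, Enum):
    """The four text sections of a patent that are scanned for mentions."""

    title = "title"
    abstract = "abstract"
    description = "description"
    claims = "claims"


#: Order used for deterministic sorting of annotations.
SECTION_ORDER = {
    Section.title: 0,
    Section.abstract: 1,
    Section.description: 2,
    Section.claims: 3,
}


@dataclass(frozen=True)
class PatentTable:
    """One table of a patent, flattened to row-major cell text."""

    table_id: str
    cells: tuple[str, ...] = ()


@dataclass
class PatentDocument:
    """One patent publication in the normalized corpus dialect."""

    patent_id: str
    family_id: str
    publication_date: str | None = None
    classification_codes: tuple[str, ...] = ()
    title: str = ""
    abstract: str = ""
    description: str = ""
    claims: tuple[str, ...] = ()
    tables: tuple[PatentTable, ...] = ()

    def __post_init__(self) -> None:
        if not self.patent_id:
            raise ValidationError("patent_id must be non-empty")
        if not self.family_id:
            raise ValidationError(
                f"family_id must be non-empty (patent {self.patent_id!r}); "
                "a singleton family uses its own patent_id"
            )
        seen: set[str] = set()
        for t in self.tables:
            if t.table_id in seen:
                raise ValidationError(
                    f"duplicate table_id {t.table_id!r} in patent {self.patent_id!r}"
                )
            seen.add(t.table_id)

    def section_text(self, section: Section) -> str | tuple[str, ...]:
        """Raw text of a section; claims come back as the per-claim tuple."""
        if section is Section.claims:
            return self.claims
        return getattr(self, section.value)


@dataclass(frozen=True)
class TargetEntry:
    """One protein target from the dictionary."""

    target_id: str
    preferred_name: str
    gene_symbol: str
    tdl: TDL
    idg_family: IDGFamily

    def __post_init__(self) -> None:
        if not self.preferred_name and not self.gene_symbol:
            raise ValidationError(
                f"target {self.target_id!r}: preferred_name and gene_symbol "
                "must not both be empty"
            )

    @property
    def is_understudied(self) -> bool:
        """True for Tdark/Tbio entries, the only ones that drive triage."""
        return self.tdl in (TDL.Tdark, TDL.Tbio)

    def names(self) -> tuple[str, ...]:
        """Distinct non-empty searchable strings for this target."""
        out = []
        for n in (self.preferred_name, self.gene_symbol):
            if n and n not in out:
                out.append(n)
        return tuple(out)


#: IPC/CPC prefixes treated as life-science relevant.
DEFAULT_LIFESCI_PREFIXES: tuple[str, ...] = (
    "A01", "A23", "A24", "A61", "A62B", "C05", "C06", "C07", "C08",
    "C09", "C10", "C11", "C12", "C13", "C14", "G01N",
)


@dataclass(frozen=True)
class LifeScienceCodePolicy:
    """Which IPC/CPC prefixes flag a patent as life-science relevant.

    Prefixes are either a 3-character section+class ("A61") or a
    4-character subclass ("A62B", "G01N"); matching is hierarchical, so
    "A61K 31/00" matches "A61" but "A62C" does not match "A62B".
    """

    allowed_prefixes: tuple[str, ...] = DEFAULT_LIFESCI_PREFIXES

    def __post_init__(self) -> None:
        for p in self.allowed_prefixes:
            if len(p) not in (3, 4):
                raise ValidationError(
                    f"prefix {p!r}: must be 3-char class or 4-char subclass"
                )


def _normalize_code(code: str) -> str:
    # Offices print IPC/CPC symbols with and without internal spaces.
    return "".join(code.split()).upper()


def is_life_science_relevant(
    doc: PatentDocument, policy: LifeScienceCodePolicy | None = None
) -> bool:
    """True iff any classification code starts with an allowed prefix."""
    policy = policy or LifeScienceCodePolicy()
    for code in doc.classification_codes:
        norm = _normalize_code(code)
        if any(norm.startswith(p) for p in policy.allowed_prefixes):
            return True
    return False


# ---------------------------------------------------------------------------
# corpus I/O


def _doc_from_obj(obj: dict, lineno: int) -> PatentDocument:
    if not isinstance(obj, dict):
        raise ParseError(f"line {lineno}: expected a JSON object")
    try:
        tables = tuple(
            PatentTable(
                table_id=str(t["table_id"]),
                cells=tuple(str(c) for c in t.get("cells", [])),
            )
            for t in obj.get("tables", [])
        )
        return PatentDocument(
            patent_id=str(obj.get("patent_id", "")),
            family_id=str(obj.get("family_id", "")),
            publication_date=obj.get("publication_date"),
            classification_codes=tuple(
                str(c) for c in obj.get("classification_codes", [])
            ),
            title=str(obj.get("title", "")),
            abstract=str(obj.get("abstract", "")),
            description=str(obj.get("description", "")),
            claims=tuple(str(c) for c in obj.get("claims", [])),
            tables=tables,
        )
    except (KeyError, TypeError) as exc:
        raise ParseError(f"line {lineno}: malformed record: {exc}") from exc
    except ValidationError as exc:
        raise ValidationError(f"line {lineno}: {exc}") from exc


def read_corpus(path: str | Path) -> list[PatentDocument]:
    """Read a JSON-lines corpus, rejecting duplicate patent_ids.

    Documents are returned in file order; blank lines are ignored.
    """
    docs: list[PatentDocument] = []
    seen: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as exc:
                raise ParseError(f"line {lineno}: invalid JSON: {exc.msg}") from exc
            doc = _doc_from_obj(obj, lineno)
            if doc.patent_id in seen:
                raise ValidationError(
                    f"line {lineno}: duplicate patent_id {doc.patent_id!r}"
                )
            seen.add(doc.patent_id)
            docs.append(doc)
    return docs


def _doc_to_obj(doc: PatentDocument) -> dict:
    obj: dict = {
        "patent_id": doc.patent_id,
        "family_id": doc.family_id,
    }
    if doc.publication_date is not None:
        obj["publication_date"] = doc.publication_date
    obj["classification_codes"] = list(doc.classification_codes)
    obj["title"] = doc.title
    obj["abstract"] = doc.abstract
    obj["description"] = doc.description
    obj["claims"] = list(doc.claims)
    obj["tables"] = [
        {"table_id": t.table_id, "cells": list(t.cells)} for t in doc.tables
    ]
    return obj


def write_corpus(docs: Iterable[PatentDocument], path: str | Path) -> None:
    """Write documents as JSON-lines; inverse of :func:`read_corpus`."""
    with open(path, "w", encoding="utf-8") as fh:
        for doc in docs:
            fh.write(json.dumps(_doc_to_obj(doc), ensure_ascii=False) + "\n")


# ---------------------------------------------------------------------------
# target dictionary I/O

_DICT_COLUMNS = ["target_id", "preferred_name", "gene_symbol", "tdl", "idg_family"]


def load_target_dictionary(path: str | Path) -> list[TargetEntry]:
    """Load the target dictionary TSV.

    Rows with a TDL outside {Tdark, Tbio} are retained but are excluded
    from the understudied subset (see :func:`understudied`).
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in _DICT_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"target dictionary missing columns: {missing}")
    entries: list[TargetEntry] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # 1 = header
        try:
            tdl = TDL(row.tdl)
        except ValueError:
            raise ValidationError(f"row {i}: unknown tdl token {row.tdl!r}") from None
        try:
            fam = IDGFamily(row.idg_family)
        except ValueError:
            raise ValidationError(
                f"row {i}: unknown idg_family token {row.idg_family!r}"
            ) from None
        try:
            entries.append(
                TargetEntry(
                    target_id=row.target_id,
                    preferred_name=row.preferred_name,
                    gene_symbol=row.gene_symbol,
                    tdl=tdl,
                    idg_family=fam,
                )
            )
        except ValidationError as exc:
            raise ValidationError(f"row {i}: {exc}") from exc
    return entries


def write_target_dictionary(entries: Iterable[TargetEntry], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(_DICT_COLUMNS) + "\n")
        for e in entries:
            fh.write(
                "\t".join(
                    [e.target_id, e.preferred_name, e.gene_symbol,
                     e.tdl.value, e.idg_family.value]
                )
                + "\n"
            )


def understudied(entries: Sequence[TargetEntry]) -> list[TargetEntry]:
    """The Tdark/Tbio subset of a dictionary — the entries that drive triage."""
    return [e for e in entries if e.is_understudied]
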