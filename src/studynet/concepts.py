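"""Multilingual concept table: term -> CUI resolution, synonym expansion,
and prefix autosuggestion.

The on-disk dialect is a pipe-delimited table in the style of the UMLS
concept-names file: ``CUI|LAT|SAB|CODE|STR|ISPREF``, one record per line,
no header.  A CUI (concept unique identifier, ``C`` + 7 digits) groups
synonymous surface strings across languages and source vocabularies;
``CODE`` carries the MeSH descriptor id when the source is MeSH-like, which
is the linkage used to match trial conditions and article MeSH headings.

Supported languages are the three-letter codes ENG, SPA, FRE, GER, ITA.
No licensed vocabulary content ships with the package; the bundled and
generated fixtures use invented CUIs.

Matching is exact on normalized surface forms (see :mod:`studynet._text`),
so "Herzinfarkt", "HERZINFARKT" and "ataque al corazon" (accent-stripped)
all hit their table rows.  Autosuggestion is served from a sorted-array
prefix index queried by binary search.
"""

from __future__ import annotations

import re
from bisect import bisect_left
from dataclasses import dataclass
from typing import IO, Iterable

from ._text import normalize
from .errors import ConceptTableError

__all__ = [
    "LANGUAGES",
    "CUI_PATTERN",
    "ConceptRecord",
    "ConceptIndex",
    "Suggestion",
    "load_concept_table",
    "resolve_term",
    "expand_cui",
    "suggest",
]

LANGUAGES = frozenset({"ENG", "SPA", "FRE", "GER", "ITA"})
CUI_PATTERN = re.compile(r"^C\d{7}$")


@dataclass(frozen=True)
class ConceptRecord:
    """One (concept, surface form, language) row of the table."""

    cui: str
    term: str
    language: str
    source: str
    mesh_descriptor: str | None
    preferred: bool


@dataclass(frozen=True)
class Suggestion:
    """One autosuggest hit; ``term`` starts (normalized) with the prefix."""

    term: str
    language: str
    cui: str
    preferred: bool
    mesh_descriptor: str | None


class ConceptIndex:
    """In-memory index over concept records.

    Maintains a normalized-term lookup, a CUI -> records map, a MeSH
    descriptor -> CUIs map, and a sorted array of normalized terms for
    prefix queries.
    """

    def __init__(self, records: Iterable[ConceptRecord]):
        self.records: list[ConceptRecord] = []
        self._by_norm: dict[str, list[ConceptRecord]] = {}
        self._by_cui: dict[str, list[ConceptRecord]] = {}
        self._by_descriptor: dict[str, set[str]] = {}
        seen: set[tuple[str, str, str]] = set()
        for rec in records:
            key = (rec.cui, rec.term, rec.language)
            if key in seen:
                continue
            seen.add(key)
            self.records.append(rec)
            self._by_norm.setdefault(normalize(rec.term), []).append(rec)
            self._by_cui.setdefault(rec.cui, []).append(rec)
            if rec.mesh_descriptor:
                self._by_descriptor.setdefault(rec.mesh_descriptor, set()).add(rec.cui)
        # sorted (normalized term, record) pairs back the prefix queries
        self._prefix_keys: list[str] = []
        self._prefix_recs: list[ConceptRecord] = []
        for norm_term, recs in sorted(self._by_norm.items()):
            for rec in recs:
                self._prefix_keys.append(norm_term)
                self._prefix_recs.append(rec)

    def __len__(self) -> int:
        return len(self.records)

    def cuis_for_descriptor(self, descriptor: str) -> set[str]:
        return set(self._by_descriptor.get(descriptor, set()))

    def records_for_norm(self, norm_term: str) -> list[ConceptRecord]:
        return list(self._by_norm.get(norm_term, []))

    def prefix_scan(self, norm_prefix: str) -> list[ConceptRecord]:
        """All records whose normalized term starts with ``norm_prefix``."""
        lo = bisect_left(self._prefix_keys, norm_prefix)
        out = []
        for i in range(lo, len(self._prefix_keys)):
            if not self._prefix_keys[i].startswith(norm_prefix):
                break
            out.append(self._prefix_recs[i])
        return out


def load_concept_table(source: IO | str) -> ConceptIndex:
    """Load a ``CUI|LAT|SAB|CODE|STR|ISPREF`` table into a ConceptIndex.

    Duplicate rows collapse; an unknown language code or a ragged row is an
    error naming the offending line.  Every CUI must carry at least one
    English record (the anchor used for display and MeSH linkage).
    """
    close = False
    if isinstance(source, str):
        fh = open(source, "r", encoding="utf-8")
        close = True
    else:
        fh = source
    records: list[ConceptRecord] = []
    try:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("|")
            if len(fields) != 6:
                raise ConceptTableError(
                    f"line {lineno}: expected 6 pipe-delimited fields, got {len(fields)}"
                )
            cui, lat, sab, code, term, ispref = (f.strip() for f in fields)
            if lat not in LANGUAGES:
                raise ConceptTableError(
                    f"line {lineno}: unknown language code {lat!r}"
                )
            if not CUI_PATTERN.match(cui):
                raise ConceptTableError(f"line {lineno}: bad CUI {cui!r}")
            if not term:
                raise ConceptTableError(f"line {lineno}: empty term")
            records.append(
                ConceptRecord(
                    cui=cui,
                    term=term,
                    language=lat,
                    source=sab,
                    mesh_descriptor=code or None,
                    preferred=ispref.upper() == "Y",
                )
            )
    finally:
        if close:
            fh.close()
    index = ConceptIndex(records)
    missing_eng = sorted(
        cui
        for cui, recs in index._by_cui.items()
        if not any(r.language == "ENG" for r in recs)
    )
    if missing_eng:
        raise ConceptTableError(
            f"CUIs without an English record: {', '.join(missing_eng)}"
        )
    return index


def resolve_term(index: ConceptIndex, term: str) -> list[str]:
    """CUIs whose records match ``term`` exactly after normalization.

    Case-, accent- and whitespace-insensitive; the result is sorted
    ascending by CUI.  A blank term is an argument error; an unmatched
    term yields an empty list.
    """
    norm = normalize(term)
    if not norm:
        raise ValueError("term is empty after normalization")
    return sorted({rec.cui for rec in index.records_for_norm(norm)})


def expand_cui(
    index: ConceptIndex, cui: str, languages: set[str] | None = None
) -> set[ConceptRecord]:
    """All records of a CUI, optionally restricted by language.

    An unknown CUI yields an empty set rather than an error.
    """
    recs = index._by_cui.get(cui, [])
    if languages is not None:
        return {r for r in recs if r.language in languages}
    return set(recs)


def suggest(
    index: ConceptIndex,
    prefix: str,
    language: str | None = None,
    limit: int = 10,
) -> list[Suggestion]:
    """Autosuggest indexed terms starting with ``prefix``.

    The normalized prefix must be at least two characters.  Hits are
    ranked preferred-first, then by term length, then lexicographically
    (with language and CUI as final tie-breaks) and truncated to ``limit``.
    """
    norm = normalize(prefix)
    if len(norm) < 2:
        raise ValueError("prefix must be at least 2 characters after normalization")
    if limit < 1:
        raise ValueError("limit must be >= 1")
    hits = index.prefix_scan(norm)
    if language is not None:
        hits = [r for r in hits if r.language == language]
    ranked = sorted(
        hits,
        key=lambda r: (not r.preferred, len(r.term), normalize(r.term), r.language, r.cui),
    )
    return [
        Suggestion(r.term, r.language, r.cui, r.preferred, r.mesh_descriptor)
        for r in ranked[:limit]
    ]
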