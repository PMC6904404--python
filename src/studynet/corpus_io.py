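"""Trial-registry and citation corpus I/O.

Two XML dialects are read and written:

* a documented subset of the ClinicalTrials.gov legacy full-study schema
  (``<clinical_studies>`` wrapping ``<clinical_study>`` records with
  ``id_info/nct_id``, ``brief_title``, repeated ``condition``,
  ``overall_status``, ``start_date``, ``completion_date`` and repeated
  ``location/facility`` blocks), and
* a subset of PubMed/MEDLINE citation XML (``PubmedArticleSet`` wrapping
  ``PubmedArticle`` records with PMID, ArticleTitle, AuthorList, PubDate,
  DataBankList accessions and MeshHeadingList).

Unknown elements are ignored on input, so real registry exports load
unchanged.  Trial-article linkage is taken only from structured data-bank
accession numbers matching the NCT pattern, the carrier used for duplicate
detection downstream.

Dates in registry exports mix granularities; they are parsed permissively
("May 2016" -> 2016-05-01, "2016" -> 2016-01-01) so that time-range
filtering has a total order to work with.
"""

from __future__ import annotations

import datetime as _dt
import logging
import re
from dataclasses import dataclass, field
from typing import IO, Iterable, Sequence

from lxml import etree

from .errors import CorpusParseError, CorpusValidationError

__all__ = [
    "Trial",
    "Facility",
    "Author",
    "Article",
    "NCT_PATTERN",
    "parse_trials",
    "parse_articles",
    "write_trials",
    "write_articles",
    "lead_authors",
    "parse_flex_date",
    "format_date",
]

log = logging.getLogger(__name__)

NCT_PATTERN = re.compile(r"^NCT\d{8}$")

_MONTHS = [
    "January", "February", "March", "April", "May", "June",
    "July", "August", "September", "October", "November", "December",
]
_MONTH_INDEX = {m.lower(): i + 1 for i, m in enumerate(_MONTHS)}


# ---------------------------------------------------------------------------
# Domain types


@dataclass
class Facility:
    """A named study site: free-text name plus city/zip/country address."""

    name: str = ""
    city: str = ""
    zip: str | None = None
    country: str = ""

    def __post_init__(self) -> None:
        if not (self.name.strip() or self.city.strip()):
            raise CorpusValidationError(
                "facility needs at least one of name/city non-empty"
            )


@dataclass
class Trial:
    """One registry record: identifier, conditions and study sites."""

    nct_id: str
    title: str = ""
    condition_terms: list[str] = field(default_factory=list)
    facilities: list[Facility] = field(default_factory=list)
    start_date: _dt.date | None = None
    completion_date: _dt.date | None = None
    status: str = ""

    def __post_init__(self) -> None:
        if not NCT_PATTERN.match(self.nct_id):
            raise CorpusValidationError(f"bad NCT id {self.nct_id!r}")
        if (
            self.start_date is not None
            and self.completion_date is not None
            and self.start_date > self.completion_date
        ):
            raise CorpusValidationError(
                f"{self.nct_id}: start_date after completion_date"
            )


@dataclass
class Author:
    """One author position of an article, with the raw affiliation string."""

    display_name: str
    ordinal: int
    affiliation_text: str | None = None


@dataclass
class Article:
    """One citation: PMID, MeSH indexing, ordered authors, NCT accessions."""

    pmid: str
    title: str = ""
    mesh_terms: list[str] = field(default_factory=list)
    authors: list[Author] = field(default_factory=list)
    pub_date: _dt.date | None = None
    linked_nct_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.pmid.isdigit():
            raise CorpusValidationError(f"bad PMID {self.pmid!r}")
        ordinals = [a.ordinal for a in self.authors]
        if ordinals != list(range(1, len(ordinals) + 1)):
            raise CorpusValidationError(
                f"PMID {self.pmid}: author ordinals must be 1..n in order"
            )
        for nct in self.linked_nct_ids:
            if not NCT_PATTERN.match(nct):
                raise CorpusValidationError(
                    f"PMID {self.pmid}: bad linked NCT id {nct!r}"
                )


# ---------------------------------------------------------------------------
# Dates


def parse_flex_date(text: str) -> _dt.date:
    """Parse the mixed date granularities found in registry exports.

    Accepted: ``YYYY-MM-DD``, ``Month D, YYYY``, ``Month YYYY`` (first of
    month) and ``YYYY`` (January 1).
    """
    s = " ".join(text.split())
    if not s:
        raise CorpusValidationError("empty date string")
    m = re.fullmatch(r"(\d{4})-(\d{2})-(\d{2})", s)
    if m:
        return _dt.date(int(m.group(1)), int(m.group(2)), int(m.group(3)))
    m = re.fullmatch(r"([A-Za-z]+) (\d{1,2}), (\d{4})", s)
    if m and m.group(1).lower() in _MONTH_INDEX:
        return _dt.date(int(m.group(3)), _MONTH_INDEX[m.group(1).lower()], int(m.group(2)))
    m = re.fullmatch(r"([A-Za-z]+) (\d{4})", s)
    if m and m.group(1).lower() in _MONTH_INDEX:
        return _dt.date(int(m.group(2)), _MONTH_INDEX[m.group(1).lower()], 1)
    m = re.fullmatch(r"\d{4}", s)
    if m:
        return _dt.date(int(s), 1, 1)
    raise CorpusValidationError(f"unparseable date {text!r}")


def format_date(d: _dt.date) -> str:
    """Emit a date registry-style, e.g. ``May 1, 2016``."""
    return f"{_MONTHS[d.month - 1]} {d.day}, {d.year}"


# ---------------------------------------------------------------------------
# Parsing helpers


def _parse_root(source: IO | str, what: str) -> etree._Element:
    import os

    if isinstance(source, str) and not os.path.exists(source):
        raise FileNotFoundError(2, "no such file", source)
    try:
        tree = etree.parse(source)
    except etree.XMLSyntaxError as exc:
        line, col = exc.position if exc.position else ("?", "?")
        raise CorpusParseError(
            f"malformed {what} XML at line {line}, column {col}: {exc.msg}"
        ) from exc
    return tree.getroot()


def _text(node: etree._Element | None) -> str:
    return (node.text or "").strip() if node is not None else ""


def parse_trials(source: IO | str, on_invalid: str = "raise") -> list[Trial]:
    """Read a trial corpus; one :class:`Trial` per ``clinical_study`` record.

    Records lacking an NCT identifier raise :class:`CorpusValidationError`
    by default; pass ``on_invalid="skip"`` to drop them with a warning.
    """
    if on_invalid not in ("raise", "skip"):
        raise ValueError("on_invalid must be 'raise' or 'skip'")
    root = _parse_root(source, "trial corpus")
    trials: list[Trial] = []
    for i, rec in enumerate(root.iter("clinical_study")):
        try:
            trials.append(_parse_trial_record(rec, i))
        except CorpusValidationError as exc:
            if on_invalid == "raise":
                raise
            log.warning("skipping invalid trial record %d: %s", i, exc)
    return trials


def _parse_trial_record(rec: etree._Element, index: int) -> Trial:
    nct = _text(rec.find("id_info/nct_id"))
    if not nct:
        title = _text(rec.find("brief_title"))
        raise CorpusValidationError(
            f"trial record {index} ({title or 'untitled'}) has no nct_id"
        )
    facilities = []
    for loc in rec.findall("location"):
        fac = loc.find("facility")
        if fac is None:
            continue
        facilities.append(
            Facility(
                name=_text(fac.find("name")),
                city=_text(fac.find("address/city")),
                zip=_text(fac.find("address/zip")) or None,
                country=_text(fac.find("address/country")),
            )
        )
    start = _text(rec.find("start_date"))
    comp = _text(rec.find("completion_date"))
    return Trial(
        nct_id=nct,
        title=_text(rec.find("brief_title")),
        condition_terms=[_text(c) for c in rec.findall("condition") if _text(c)],
        facilities=facilities,
        start_date=parse_flex_date(start) if start else None,
        completion_date=parse_flex_date(comp) if comp else None,
        status=_text(rec.find("overall_status")),
    )


def parse_articles(source: IO | str, on_invalid: str = "raise") -> list[Article]:
    """Read a citation corpus; one :class:`Article` per ``PubmedArticle``.

    Author order follows document order; NCT accession numbers found in
    DataBank blocks are harvested into ``linked_nct_ids``.
    """
    if on_invalid not in ("raise", "skip"):
        raise ValueError("on_invalid must be 'raise' or 'skip'")
    root = _parse_root(source, "citation corpus")
    articles: list[Article] = []
    for i, rec in enumerate(root.iter("PubmedArticle")):
        try:
            articles.append(_parse_article_record(rec, i))
        except CorpusValidationError as exc:
            if on_invalid == "raise":
                raise
            log.warning("skipping invalid citation record %d: %s", i, exc)
    return articles


def _parse_article_record(rec: etree._Element, index: int) -> Article:
    cit = rec.find("MedlineCitation")
    if cit is None:
        raise CorpusValidationError(f"citation record {index} has no MedlineCitation")
    pmid = _text(cit.find("PMID"))
    if not pmid:
        raise CorpusValidationError(f"citation record {index} has no PMID")
    art = cit.find("Article")
    authors: list[Author] = []
    if art is not None:
        for ordinal, a in enumerate(art.findall("AuthorList/Author"), start=1):
            last = _text(a.find("LastName"))
            fore = _text(a.find("ForeName"))
            name = " ".join(p for p in (fore, last) if p)
            affil = _text(a.find("AffiliationInfo/Affiliation"))
            authors.append(Author(name, ordinal, affil or None))
    pub_date = None
    if art is not None:
        pd = art.find("Journal/JournalIssue/PubDate")
        if pd is not None:
            year = _text(pd.find("Year"))
            if year:
                month = _text(pd.find("Month"))
                day = _text(pd.find("Day"))
                mnum = _MONTH_INDEX.get(month.lower(), None) if month else 1
                if mnum is None and month.isdigit():
                    mnum = int(month)
                pub_date = _dt.date(int(year), mnum or 1, int(day) if day else 1)
    linked = []
    if art is not None:
        for acc in art.findall(
            "DataBankList/DataBank/AccessionNumberList/AccessionNumber"
        ):
            val = _text(acc)
            if NCT_PATTERN.match(val):
                linked.append(val)
    mesh = [
        _text(d)
        for d in cit.findall("MeshHeadingList/MeshHeading/DescriptorName")
        if _text(d)
    ]
    return Article(
        pmid=pmid,
        title=_text(art.find("ArticleTitle")) if art is not None else "",
        mesh_terms=mesh,
        authors=authors,
        pub_date=pub_date,
        linked_nct_ids=linked,
    )


# ---------------------------------------------------------------------------
# Lead authors


def lead_authors(article: Article) -> list[Author]:
    """The first two and last two authors, duplicate-free, ordinal order.

    With four or fewer authors the two windows overlap and every author is
    a lead author; an empty author list yields an empty result.
    """
    n = len(article.authors)
    wanted = sorted({1, 2, n - 1, n} & set(range(1, n + 1)))
    return [article.authors[i - 1] for i in wanted]


# ---------------------------------------------------------------------------
# Writers


def _sub(parent: etree._Element, tag: str, text: str | None = None) -> etree._Element:
    el = etree.SubElement(parent, tag)
    if text is not None:
        el.text = text
    return el


def write_trials(trials: Iterable[Trial], sink: IO | str) -> None:
    """Emit a trial corpus that re-parses to field-identical records."""
    root = etree.Element("clinical_studies")
    for t in trials:
        rec = _sub(root, "clinical_study")
        _sub(_sub(rec, "id_info"), "nct_id", t.nct_id)
        if t.title:
            _sub(rec, "brief_title", t.title)
        for c in t.condition_terms:
            _sub(rec, "condition", c)
        if t.status:
            _sub(rec, "overall_status", t.status)
        if t.start_date:
            _sub(rec, "start_date", format_date(t.start_date))
        if t.completion_date:
            _sub(rec, "completion_date", format_date(t.completion_date))
        for f in t.facilities:
            fac = _sub(_sub(rec, "location"), "facility")
            if f.name:
                _sub(fac, "name", f.name)
            addr = _sub(fac, "address")
            if f.city:
                _sub(addr, "city", f.city)
            if f.zip:
                _sub(addr, "zip", f.zip)
            if f.country:
                _sub(addr, "country", f.country)
    _dump(root, sink)


def write_articles(articles: Iterable[Article], sink: IO | str) -> None:
    """Emit a citation corpus that re-parses to field-identical records."""
    root = etree.Element("PubmedArticleSet")
    for a in articles:
        cit = _sub(_sub(root, "PubmedArticle"), "MedlineCitation")
        _sub(cit, "PMID", a.pmid)
        art = _sub(cit, "Article")
        if a.title:
            _sub(art, "ArticleTitle", a.title)
        if a.pub_date:
            pd = _sub(_sub(_sub(art, "Journal"), "JournalIssue"), "PubDate")
            _sub(pd, "Year", str(a.pub_date.year))
            _sub(pd, "Month", _MONTHS[a.pub_date.month - 1])
            _sub(pd, "Day", str(a.pub_date.day))
        if a.authors:
            alist = _sub(art, "AuthorList")
            for au in a.authors:
                el = _sub(alist, "Author")
                parts = au.display_name.rsplit(" ", 1)
                if len(parts) == 2:
                    _sub(el, "ForeName", parts[0])
                    _sub(el, "LastName", parts[1])
                else:
                    _sub(el, "LastName", au.display_name)
                if au.affiliation_text:
                    _sub(_sub(el, "AffiliationInfo"), "Affiliation", au.affiliation_text)
        if a.linked_nct_ids:
            accl = _sub(_sub(_sub(art, "DataBankList"), "DataBank"), "AccessionNumberList")
            for nct in a.linked_nct_ids:
                _sub(accl, "AccessionNumber", nct)
        if a.mesh_terms:
            ml = _sub(cit, "MeshHeadingList")
            for term in a.mesh_terms:
                _sub(_sub(ml, "MeshHeading"), "DescriptorName", term)
    _dump(root, sink)


def _dump(root: etree._Element, sink: IO | str) -> None:
    data = etree.tostring(
        root, pretty_print=True, xml_declaration=True, encoding="UTF-8"
    )
    if isinstance(sink, str):
        with open(sink, "wb") as fh:
            fh.write(data)
    elif hasattr(sink, "buffer"):
        sink.buffer.write(data)
    else:
        try:
            sink.write(data)
        except TypeError:
            sink.write(data.decode("utf-8"))
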