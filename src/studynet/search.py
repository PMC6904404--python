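"""End-to-end study search: concept matching, time-range and perimeter
filters, producing a geolocated research network.

The pipeline is: match trials/articles against the queried concepts
(ANY/ALL logic over CUI synonym sets plus MeSH descriptor equality),
restrict to the requested time range, build the trial and article
networks, merge them with NCT/PMID deduplication, then drop nodes outside
the great-circle radius (edges losing an endpoint are pruned with them).

Distances use the haversine formula on a sphere with the mean Earth
radius 6371.0088 km — city-scale perimeter search ("studies within
200 km of here") does not need ellipsoidal precision, and a fixed,
documented constant keeps results exactly reproducible.
"""

from __future__ import annotations

import datetime as _dt
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from ._text import normalize
from .concepts import ConceptIndex, expand_cui
from .corpus_io import Article, Trial
from .geocode import GeoPoint
from .network import (
    CoverageReport,
    GeocoderContext,
    ResearchNetwork,
    SiteNode,
    build_article_network,
    build_trial_network,
    merge_networks,
)

__all__ = [
    "EARTH_RADIUS_KM",
    "MAX_GREAT_CIRCLE_KM",
    "SearchQuery",
    "haversine_km",
    "filter_within_radius",
    "match_condition",
    "filter_by_dates",
    "run_search",
]

#: Mean Earth radius (km); the sphere on which all distances are measured.
EARTH_RADIUS_KM = 6371.0088

#: Upper bound on any great-circle distance: half the sphere circumference.
MAX_GREAT_CIRCLE_KM = math.pi * EARTH_RADIUS_KM


@dataclass(frozen=True)
class SearchQuery:
    """A validated search request.

    ``logic`` is ANY (at least one queried concept matches) or ALL (every
    one matches); ANY is the default since related conditions are usually
    queried together disjunctively.  A radius requires a center.
    """

    cuis: tuple[str, ...]
    logic: str = "ANY"
    center: GeoPoint | None = None
    radius_km: float | None = None
    date_from: _dt.date | None = None
    date_to: _dt.date | None = None
    include_articles: bool = True

    def __post_init__(self) -> None:
        if not self.cuis:
            raise ValueError("query needs at least one concept id")
        if self.logic not in ("ANY", "ALL"):
            raise ValueError(f"bad logic {self.logic!r}")
        if self.radius_km is not None:
            if self.center is None:
                raise ValueError("radius_km requires a center")
            if self.radius_km <= 0:
                raise ValueError("radius_km must be positive")
        if (
            self.date_from is not None
            and self.date_to is not None
            and self.date_from > self.date_to
        ):
            raise ValueError("date_from after date_to")


# ---------------------------------------------------------------------------
# Great-circle geometry


def haversine_km(a: GeoPoint, b: GeoPoint) -> float:
    """Great-circle distance between two WGS84 points, in kilometres."""
    phi1, phi2 = math.radians(a.lat), math.radians(b.lat)
    dphi = phi2 - phi1
    dlam = math.radians(b.lon - a.lon)
    h = math.sin(dphi / 2.0) ** 2 + math.cos(phi1) * math.cos(phi2) * math.sin(dlam / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * math.asin(min(1.0, math.sqrt(h)))


def filter_within_radius(
    nodes: Iterable[SiteNode], center: GeoPoint, radius_km: float
) -> list[SiteNode]:
    """Exactly the nodes within ``radius_km`` of ``center`` (inclusive)."""
    if radius_km <= 0:
        raise ValueError("radius_km must be positive")
    return [n for n in nodes if haversine_km(n.point, center) <= radius_km]


# ---------------------------------------------------------------------------
# Concept and date filters


def _record_terms(record: Trial | Article) -> list[str]:
    return record.condition_terms if isinstance(record, Trial) else record.mesh_terms


def match_condition(
    record: Trial | Article,
    cuis: Sequence[str],
    index: ConceptIndex,
    logic: str = "ANY",
) -> bool:
    """Whether a record's condition/MeSH terms match the queried concepts.

    A record matches concept ``c`` when any of its terms normalizes to a
    surface form of ``c`` in any supported language, or equals ``c``'s
    MeSH descriptor id.  ANY/ALL combine per-concept matches.
    """
    if not cuis:
        raise ValueError("cuis must be non-empty")
    if logic not in ("ANY", "ALL"):
        raise ValueError(f"bad logic {logic!r}")
    terms = _record_terms(record)
    norm_terms = {normalize(t) for t in terms}
    raw_terms = {t.strip().upper() for t in terms}

    def matches(cui: str) -> bool:
        records = expand_cui(index, cui)
        surfaces = {normalize(r.term) for r in records}
        descriptors = {r.mesh_descriptor.upper() for r in records if r.mesh_descriptor}
        return bool(norm_terms & surfaces) or bool(raw_terms & descriptors)

    if logic == "ANY":
        return any(matches(c) for c in cuis)
    return all(matches(c) for c in cuis)


def _record_date(record: Trial | Article) -> _dt.date | None:
    return record.start_date if isinstance(record, Trial) else record.pub_date


def filter_by_dates(
    records: Sequence[Trial | Article],
    date_from: _dt.date | None,
    date_to: _dt.date | None,
) -> list[Trial | Article]:
    """Keep records whose date falls in [date_from, date_to].

    Trials filter on start date, articles on publication date.  With no
    bounds set the input passes through unchanged; with an active range,
    undated records are excluded (callers count them in the coverage
    report).
    """
    if date_from is not None and date_to is not None and date_from > date_to:
        raise ValueError("date_from after date_to")
    if date_from is None and date_to is None:
        return list(records)
    out = []
    for rec in records:
        d = _record_date(rec)
        if d is None:
            continue
        if date_from is not None and d < date_from:
            continue
        if date_to is not None and d > date_to:
            continue
        out.append(rec)
    return out


# ---------------------------------------------------------------------------
# Pipeline


@dataclass
class SearchReport(CoverageReport):
    """Coverage report extended with per-stage pipeline counts."""

    trials_matched: int = 0
    articles_matched: int = 0
    undated_excluded: int = 0
    nodes_dropped_by_radius: int = 0


def run_search(
    query: SearchQuery,
    trials: Sequence[Trial],
    articles: Sequence[Article],
    index: ConceptIndex,
    ctx: GeocoderContext,
) -> tuple[ResearchNetwork, SearchReport]:
    """Execute the full search pipeline and return network plus report."""
    report = SearchReport()

    m_trials = [t for t in trials if match_condition(t, query.cuis, index, query.logic)]
    if query.include_articles:
        m_articles = [
            a for a in articles if match_condition(a, query.cuis, index, query.logic)
        ]
    else:
        m_articles = []
    report.trials_matched = len(m_trials)
    report.articles_matched = len(m_articles)

    bounded = query.date_from is not None or query.date_to is not None
    if bounded:
        report.undated_excluded = sum(
            1 for r in [*m_trials, *m_articles] if _record_date(r) is None
        )
    f_trials = filter_by_dates(m_trials, query.date_from, query.date_to)
    f_articles = filter_by_dates(m_articles, query.date_from, query.date_to)

    tnet, treport = build_trial_network(f_trials, ctx)
    anet, areport = build_article_network(f_articles, ctx)
    report.extend(treport)
    report.extend(areport)
    net = merge_networks(tnet, anet, f_articles)

    if query.radius_km is not None and query.center is not None:
        keep = {
            n.node_key
            for n in filter_within_radius(
                net.nodes.values(), query.center, query.radius_km
            )
        }
        report.nodes_dropped_by_radius = len(net.nodes) - len(keep)
        pruned = ResearchNetwork()
        for key in keep:
            n = net.nodes[key]
            pruned.nodes[key] = SiteNode(key, n.point, set(n.labels), set(n.studies))
        for pair, refs in net._edges.items():
            if all(k in keep for k in pair):
                pruned._edges[pair] = set(refs)
        net = pruned
    return net, report
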