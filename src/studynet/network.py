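"""Geolocated research-network graphs.

A research network is an undirected graph whose nodes are study sites —
one node per (normalized city, country), since multiple facilities of one
city share a map location — and whose edges denote co-participation of two
sites in one study.  Every study therefore induces a clique: a trial with
k distinct cities contributes k·(k−1)/2 edges, each supported by that
trial's reference.  Articles contribute in exactly the same way through
the geocoded affiliations of their lead authors.

Merging a trial network with an article network deduplicates studies via
the NCT accession numbers carried by articles: an article linked to a
trial already present contributes its sites to that trial's reference
rather than double-counting a second study.

Exports: GraphML (via networkx) and a GeoJSON FeatureCollection with
Point features for nodes and LineString features for edges.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from typing import IO, Iterable, Mapping, Sequence

import networkx as nx

from ._text import normalize
from .corpus_io import Article, Trial, lead_authors, NCT_PATTERN
from .geocode import (
    FacilityIndex,
    Gazetteer,
    GeocodeResult,
    GeoPoint,
    geocode_affiliation,
    geocode_facility,
)

__all__ = [
    "StudyKind",
    "StudyRef",
    "SiteNode",
    "CollabEdge",
    "ResearchNetwork",
    "GeocoderContext",
    "CoverageReport",
    "build_trial_network",
    "build_article_network",
    "merge_networks",
    "subnetwork_for_study",
    "network_from_ids",
    "render_check",
    "to_geojson",
    "to_graphml",
    "validate_geojson",
]

_PMID_PATTERN = re.compile(r"^\d+$")


@dataclass(frozen=True)
class StudyRef:
    """Reference to a trial (NCT id) or article (PMID)."""

    kind: str  # "TRIAL" | "ARTICLE"
    id: str

    def __post_init__(self) -> None:
        if self.kind == "TRIAL":
            if not NCT_PATTERN.match(self.id):
                raise ValueError(f"bad NCT id {self.id!r}")
        elif self.kind == "ARTICLE":
            if not _PMID_PATTERN.match(self.id):
                raise ValueError(f"bad PMID {self.id!r}")
        else:
            raise ValueError(f"bad study kind {self.kind!r}")

    def __str__(self) -> str:
        return f"{self.kind}:{self.id}"


@dataclass
class SiteNode:
    """One map location aggregating all facilities/affiliations there."""

    node_key: str  # "normalized city|CC"
    point: GeoPoint
    labels: set[str] = field(default_factory=set)
    studies: set[StudyRef] = field(default_factory=set)


@dataclass(frozen=True)
class CollabEdge:
    """Co-participation of two sites; supports lists the shared studies."""

    endpoints: frozenset[str]
    supports: frozenset[StudyRef]


def node_key_for(result: GeocodeResult) -> str:
    """Location identity of a geocode hit: normalized city + country."""
    entry = result.matched_entry
    assert entry is not None
    return f"{normalize(entry.name)}|{entry.country}"


class ResearchNetwork:
    """Mutable node/edge container with clique-building primitives."""

    def __init__(self) -> None:
        self.nodes: dict[str, SiteNode] = {}
        self._edges: dict[frozenset[str], set[StudyRef]] = {}

    # -- construction ------------------------------------------------------

    def add_site(self, key: str, point: GeoPoint, label: str, ref: StudyRef) -> None:
        node = self.nodes.get(key)
        if node is None:
            node = SiteNode(key, point)
            self.nodes[key] = node
        node.studies.add(ref)
        if label:
            node.labels.add(label)

    def add_clique(self, keys: Iterable[str], ref: StudyRef) -> None:
        uniq = sorted(set(keys))
        for i, a in enumerate(uniq):
            for b in uniq[i + 1:]:
                self._edges.setdefault(frozenset((a, b)), set()).add(ref)

    # -- views -------------------------------------------------------------

    @property
    def edges(self) -> list[CollabEdge]:
        return [
            CollabEdge(pair, frozenset(refs))
            for pair, refs in sorted(
                self._edges.items(), key=lambda kv: tuple(sorted(kv[0]))
            )
        ]

    def study_refs(self) -> set[StudyRef]:
        refs: set[StudyRef] = set()
        for node in self.nodes.values():
            refs |= node.studies
        return refs

    def n_edges(self) -> int:
        return len(self._edges)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ResearchNetwork):
            return NotImplemented
        return (
            {k: (v.point, frozenset(v.labels), frozenset(v.studies))
             for k, v in self.nodes.items()}
            == {k: (v.point, frozenset(v.labels), frozenset(v.studies))
                for k, v in other.nodes.items()}
            and {k: frozenset(v) for k, v in self._edges.items()}
            == {k: frozenset(v) for k, v in other._edges.items()}
        )

    def same_topology(self, other: "ResearchNetwork") -> bool:
        """Equality on node keys, points, studies and edge supports.

        Labels are display metadata (facility vs affiliation strings) and
        are ignored, so a trial network and its deduplicated merge with
        linked articles compare equal.
        """
        return (
            {k: (v.point, frozenset(v.studies)) for k, v in self.nodes.items()}
            == {k: (v.point, frozenset(v.studies)) for k, v in other.nodes.items()}
            and {k: frozenset(v) for k, v in self._edges.items()}
            == {k: frozenset(v) for k, v in other._edges.items()}
        )

    def copy(self) -> "ResearchNetwork":
        out = ResearchNetwork()
        for k, n in self.nodes.items():
            out.nodes[k] = SiteNode(k, n.point, set(n.labels), set(n.studies))
        out._edges = {pair: set(refs) for pair, refs in self._edges.items()}
        return out


@dataclass
class GeocoderContext:
    """Everything geocoding needs: gazetteer plus the facility index."""

    gazetteer: Gazetteer
    facilities: FacilityIndex | None = None


@dataclass
class CoverageReport:
    """Structured account of what could not be located or was filtered.

    Geocoding misses are data gaps in the sources, not errors, so they
    are reported rather than raised.
    """

    unresolved_facilities: list[tuple[str, str]] = field(default_factory=list)
    unresolved_affiliations: list[tuple[str, str]] = field(default_factory=list)
    missing_ids: list[str] = field(default_factory=list)
    trials_seen: int = 0
    articles_seen: int = 0
    trials_geocoded: int = 0
    articles_geocoded: int = 0

    def extend(self, other: "CoverageReport") -> None:
        self.unresolved_facilities.extend(other.unresolved_facilities)
        self.unresolved_affiliations.extend(other.unresolved_affiliations)
        self.missing_ids.extend(other.missing_ids)
        self.trials_seen += other.trials_seen
        self.articles_seen += other.articles_seen
        self.trials_geocoded += other.trials_geocoded
        self.articles_geocoded += other.articles_geocoded


# ---------------------------------------------------------------------------
# Builders


def build_trial_network(
    trials: Sequence[Trial], ctx: GeocoderContext
) -> tuple[ResearchNetwork, CoverageReport]:
    """Geocode every trial facility and form one clique per trial.

    Facilities resolving to the same (city, country) collapse into one
    node; unresolvable facilities land in the coverage report.
    """
    net = ResearchNetwork()
    report = CoverageReport()
    for trial in trials:
        report.trials_seen += 1
        ref = StudyRef("TRIAL", trial.nct_id)
        keys = []
        fully = True
        for fac in trial.facilities:
            res = geocode_facility(fac, ctx.gazetteer)
            if not res.resolved:
                report.unresolved_facilities.append(
                    (trial.nct_id, fac.name or fac.city)
                )
                fully = False
                continue
            key = node_key_for(res)
            net.add_site(key, res.point, fac.name, ref)
            keys.append(key)
        if keys and fully:
            report.trials_geocoded += 1
        net.add_clique(keys, ref)
    return net, report


def build_article_network(
    articles: Sequence[Article], ctx: GeocoderContext
) -> tuple[ResearchNetwork, CoverageReport]:
    """Geocode lead-author affiliations and form one clique per article."""
    net = ResearchNetwork()
    report = CoverageReport()
    for article in articles:
        report.articles_seen += 1
        ref = StudyRef("ARTICLE", article.pmid)
        keys = []
        fully = True
        for author in lead_authors(article):
            if not author.affiliation_text:
                continue
            res = geocode_affiliation(
                author.affiliation_text, ctx.gazetteer, ctx.facilities
            )
            if not res.resolved:
                report.unresolved_affiliations.append(
                    (article.pmid, author.affiliation_text)
                )
                fully = False
                continue
            key = node_key_for(res)
            label = author.affiliation_text.split(",")[0].strip()
            net.add_site(key, res.point, label, ref)
            keys.append(key)
        if keys and fully:
            report.articles_geocoded += 1
        net.add_clique(keys, ref)
    return net, report


# ---------------------------------------------------------------------------
# Merge with NCT/PMID deduplication


def merge_networks(
    trial_net: ResearchNetwork,
    article_net: ResearchNetwork,
    articles: Sequence[Article] = (),
) -> ResearchNetwork:
    """Union two networks, deduplicating articles against linked trials.

    An article whose accession-linked NCT ids intersect the TRIAL refs
    present in either input contributes no ARTICLE ref of its own: its
    nodes and edges are re-attributed to the linked trial refs.  The
    remap is computed against the union of both inputs, which makes the
    operation commutative and idempotent.
    """
    merged = trial_net.copy()
    for key, node in article_net.nodes.items():
        if key in merged.nodes:
            merged.nodes[key].labels |= node.labels
            merged.nodes[key].studies |= node.studies
        else:
            merged.nodes[key] = SiteNode(
                key, node.point, set(node.labels), set(node.studies)
            )
    for pair, refs in article_net._edges.items():
        merged._edges.setdefault(pair, set()).update(refs)

    trial_ids = {r.id for r in merged.study_refs() if r.kind == "TRIAL"}
    remap: dict[StudyRef, set[StudyRef]] = {}
    for article in articles:
        linked = [n for n in article.linked_nct_ids if n in trial_ids]
        if linked:
            remap[StudyRef("ARTICLE", article.pmid)] = {
                StudyRef("TRIAL", n) for n in linked
            }
    if remap:
        for node in merged.nodes.values():
            for old, new in remap.items():
                if old in node.studies:
                    node.studies.discard(old)
                    node.studies |= new
        for pair, refs in merged._edges.items():
            for old, new in remap.items():
                if old in refs:
                    refs.discard(old)
                    refs |= new
    return merged


# ---------------------------------------------------------------------------
# Subnetworks and direct-ID rendering


def subnetwork_for_study(net: ResearchNetwork, ref: StudyRef) -> ResearchNetwork:
    """The induced graph on the sites of one study — always a clique.

    Node studies and edge supports are restricted to ``ref``; an unknown
    ref yields an empty network.
    """
    sub = ResearchNetwork()
    for key, node in net.nodes.items():
        if ref in node.studies:
            sub.nodes[key] = SiteNode(key, node.point, set(node.labels), {ref})
    for pair, refs in net._edges.items():
        if ref in refs and all(k in sub.nodes for k in pair):
            sub._edges[pair] = {ref}
    return sub


def network_from_ids(
    nct_ids: Sequence[str],
    pmids: Sequence[str],
    trials: Sequence[Trial],
    articles: Sequence[Article],
    ctx: GeocoderContext,
) -> tuple[ResearchNetwork, CoverageReport]:
    """Build the merged network for directly entered NCT ids and PMIDs.

    Ids absent from the corpora are listed in the report's missing_ids;
    a syntactically malformed id is an argument error.
    """
    for nct in nct_ids:
        if not NCT_PATTERN.match(nct):
            raise ValueError(f"malformed NCT id {nct!r}")
    for pmid in pmids:
        if not _PMID_PATTERN.match(pmid):
            raise ValueError(f"malformed PMID {pmid!r}")
    trial_by_id = {t.nct_id: t for t in trials}
    article_by_id = {a.pmid: a for a in articles}
    sel_trials = [trial_by_id[n] for n in nct_ids if n in trial_by_id]
    sel_articles = [article_by_id[p] for p in pmids if p in article_by_id]
    missing = [n for n in nct_ids if n not in trial_by_id] + [
        p for p in pmids if p not in article_by_id
    ]
    tnet, treport = build_trial_network(sel_trials, ctx)
    anet, areport = build_article_network(sel_articles, ctx)
    merged = merge_networks(tnet, anet, sel_articles)
    treport.extend(areport)
    treport.missing_ids.extend(missing)
    return merged, treport


def render_check(
    record: Trial | Article, net: ResearchNetwork, ctx: GeocoderContext
) -> bool:
    """Whether a record renders correctly: every site (trial) or every
    lead-author affiliation (article) geocodes and appears as a node."""
    if isinstance(record, Trial):
        sites = [geocode_facility(f, ctx.gazetteer) for f in record.facilities]
    else:
        sites = [
            geocode_affiliation(a.affiliation_text, ctx.gazetteer, ctx.facilities)
            for a in lead_authors(record)
            if a.affiliation_text
        ]
    if not sites:
        return False
    return all(r.resolved and node_key_for(r) in net.nodes for r in sites)


# ---------------------------------------------------------------------------
# Exports


def _ref_list(refs: Iterable[StudyRef]) -> list[str]:
    return sorted(str(r) for r in refs)


def to_geojson(net: ResearchNetwork) -> dict:
    """GeoJSON FeatureCollection: Point per node, LineString per edge."""
    features = []
    for key in sorted(net.nodes):
        node = net.nodes[key]
        features.append(
            {
                "type": "Feature",
                "geometry": {
                    "type": "Point",
                    "coordinates": [node.point.lon, node.point.lat],
                },
                "properties": {
                    "node_key": key,
                    "labels": sorted(node.labels),
                    "studies": _ref_list(node.studies),
                },
            }
        )
    for edge in net.edges:
        a, b = sorted(edge.endpoints)
        pa, pb = net.nodes[a].point, net.nodes[b].point
        features.append(
            {
                "type": "Feature",
                "geometry": {
                    "type": "LineString",
                    "coordinates": [[pa.lon, pa.lat], [pb.lon, pb.lat]],
                },
                "properties": {
                    "endpoints": [a, b],
                    "supports": _ref_list(edge.supports),
                },
            }
        )
    return {"type": "FeatureCollection", "features": features}


def write_geojson(net: ResearchNetwork, sink: IO | str) -> None:
    doc = json.dumps(to_geojson(net), ensure_ascii=False, indent=2, sort_keys=True)
    if isinstance(sink, str):
        with open(sink, "w", encoding="utf-8") as fh:
            fh.write(doc + "\n")
    else:
        sink.write(doc + "\n")


def to_graphml_graph(net: ResearchNetwork) -> nx.Graph:
    """The networkx graph backing the GraphML export."""
    g = nx.Graph()
    for key in sorted(net.nodes):
        node = net.nodes[key]
        g.add_node(
            key,
            lat=node.point.lat,
            lon=node.point.lon,
            label="|".join(sorted(node.labels)),
            studies=",".join(_ref_list(node.studies)),
        )
    for edge in net.edges:
        a, b = sorted(edge.endpoints)
        g.add_edge(a, b, supports=",".join(_ref_list(edge.supports)))
    return g


def to_graphml(net: ResearchNetwork, sink: IO | str) -> None:
    nx.write_graphml(to_graphml_graph(net), sink)


def validate_geojson(doc: object) -> None:
    """Structural check of the exported GeoJSON dialect; raises ValueError."""
    if not isinstance(doc, dict) or doc.get("type") != "FeatureCollection":
        raise ValueError("not a FeatureCollection")
    feats = doc.get("features")
    if not isinstance(feats, list):
        raise ValueError("features must be a list")
    for i, f in enumerate(feats):
        if f.get("type") != "Feature":
            raise ValueError(f"feature {i}: type must be Feature")
        geom = f.get("geometry", {})
        gtype, coords = geom.get("type"), geom.get("coordinates")
        if gtype == "Point":
            if not (isinstance(coords, list) and len(coords) == 2):
                raise ValueError(f"feature {i}: bad Point coordinates")
            pts = [coords]
        elif gtype == "LineString":
            if not (isinstance(coords, list) and len(coords) >= 2):
                raise ValueError(f"feature {i}: bad LineString coordinates")
            pts = coords
        else:
            raise ValueError(f"feature {i}: unsupported geometry {gtype!r}")
        for lon, lat in pts:
            if not (-180.0 <= lon <= 180.0 and -90.0 <= lat <= 90.0):
                raise ValueError(f"feature {i}: coordinate out of bounds")
        if "properties" not in f:
            raise ValueError(f"feature {i}: missing properties")
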