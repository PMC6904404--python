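"""Research-network construction, merging/dedup, subnetworks, exports."""

import io
import itertools
import json

import networkx as nx
import pytest

from studynet.corpus_io import Article, Author, Facility, Trial
from studynet.fixtures import FixtureSpec, generate
from studynet.network import (
    GeocoderContext,
    StudyRef,
    build_article_network,
    build_trial_network,
    merge_networks,
    network_from_ids,
    render_check,
    subnetwork_for_study,
    to_geojson,
    to_graphml,
    to_graphml_graph,
    validate_geojson,
)


def _trial(nct, cities, condition="Hemophilia A"):
    return Trial(
        nct_id=nct,
        condition_terms=[condition],
        facilities=[
            Facility(name=f"Clinic {c}", city=c, country=cc) for c, cc in cities
        ],
    )


def test_one_trial_three_cities_is_a_triangle(worked):
    trial = _trial("NCT00000001", [("Leeds", "GB"), ("Berlin", "DE"), ("Madrid", "ES")])
    net, report = build_trial_network([trial], worked.context)
    ref = StudyRef("TRIAL", "NCT00000001")
    assert len(net.nodes) == 3
    assert net.n_edges() == 3
    assert all(ref in e.supports for e in net.edges)
    assert report.unresolved_facilities == []


def test_single_city_trial_has_no_edges(worked):
    net, _ = build_trial_network(
        [_trial("NCT00000001", [("Leeds", "GB")])], worked.context
    )
    assert (len(net.nodes), net.n_edges()) == (1, 0)


def test_two_trials_sharing_a_city_union_of_cliques(worked):
    t1 = _trial("NCT00000001", [("Leeds", "GB"), ("Berlin", "DE")])
    t2 = _trial("NCT00000002", [("Berlin", "DE"), ("Madrid", "ES")])
    net, _ = build_trial_network([t1, t2], worked.context)
    shared = net.nodes["berlin|DE"]
    assert {r.id for r in shared.studies} == {"NCT00000001", "NCT00000002"}
    # brute-force pairwise enumeration over both cliques
    expected_edges = set()
    for t in (t1, t2):
        keys = [f"{f.city.lower()}|{f.country}" for f in t.facilities]
        expected_edges |= {frozenset(p) for p in itertools.combinations(keys, 2)}
    assert {e.endpoints for e in net.edges} == expected_edges


def test_unresolvable_facility_reported_not_dropped_silently(worked):
    t = _trial("NCT00000001", [("Leeds", "GB"), ("Atlantis", "XX")])
    net, report = build_trial_network([t], worked.context)
    assert len(net.nodes) == 1
    assert report.unresolved_facilities == [("NCT00000001", "Clinic Atlantis")]


def _article(pmid, affils, linked=()):
    authors = [
        Author(f"A{i}", i, a) for i, a in enumerate(affils, start=1)
    ]
    return Article(pmid=pmid, mesh_terms=["Hemophilia A"], authors=authors,
                   linked_nct_ids=list(linked))


def test_article_lead_affiliations_in_two_cities_one_edge(worked):
    art = _article("101", [
        "Department, Leeds, United Kingdom",
        "Department, Berlin, Germany",
        "Department, Madrid, Spain",   # middle author: not a lead, ignored
        None, None,
        "Institute, Leeds, United Kingdom",
    ])
    net, _ = build_article_network([art], worked.context)
    assert set(net.nodes) == {"leeds|GB", "berlin|DE"}
    assert net.n_edges() == 1


def test_article_single_city_no_edges(worked):
    art = _article("102", ["Department, Berlin, Germany", "Institute, Berlin, Germany"])
    net, _ = build_article_network([art], worked.context)
    assert (len(net.nodes), net.n_edges()) == (1, 0)


def test_merge_with_empty_network_is_identity(worked):
    net, _ = build_trial_network(
        [_trial("NCT00000001", [("Leeds", "GB"), ("Berlin", "DE")])], worked.context
    )
    from studynet.network import ResearchNetwork

    assert merge_networks(net, ResearchNetwork()) == net
    assert merge_networks(ResearchNetwork(), net) == net


def test_linked_article_contributes_no_extra_study_ref(worked):
    trial = _trial("NCT00000001", [("Leeds", "GB"), ("Berlin", "DE")])
    art = _article(
        "103",
        ["Department, Leeds, United Kingdom", "Department, Berlin, Germany"],
        linked=["NCT00000001"],
    )
    tnet, _ = build_trial_network([trial], worked.context)
    anet, _ = build_article_network([art], worked.context)
    merged = merge_networks(tnet, anet, [art])
    refs = merged.study_refs()
    assert StudyRef("TRIAL", "NCT00000001") in refs
    assert StudyRef("ARTICLE", "103") not in refs
    assert merged.same_topology(tnet)


def test_merge_is_idempotent_and_commutative(corpus):
    ctx = corpus.context
    tnet, _ = build_trial_network(corpus.trials, ctx)
    anet, _ = build_article_network(corpus.articles, ctx)
    assert merge_networks(tnet, tnet) == tnet
    ab = merge_networks(tnet, anet, corpus.articles)
    ba = merge_networks(anet, tnet, corpus.articles)
    assert ab == ba


def test_subnetwork_is_complete_and_matches_brute_force(corpus):
    ctx = corpus.context
    tnet, _ = build_trial_network(corpus.trials, ctx)
    anet, _ = build_article_network(corpus.articles, ctx)
    net = merge_networks(tnet, anet, corpus.articles)
    for ref in sorted(net.study_refs(), key=str):
        sub = subnetwork_for_study(net, ref)
        k = len(sub.nodes)
        assert sub.n_edges() == k * (k - 1) // 2
        # brute-force filter oracle
        assert set(sub.nodes) == {k_ for k_, n in net.nodes.items() if ref in n.studies}
        assert {e.endpoints for e in sub.edges} == {
            pair for pair, refs in net._edges.items() if ref in refs
        }


def test_subnetwork_of_unknown_ref_is_empty(corpus):
    net, _ = build_trial_network(corpus.trials, corpus.context)
    sub = subnetwork_for_study(net, StudyRef("TRIAL", "NCT99999998"))
    assert (len(sub.nodes), sub.n_edges()) == (0, 0)


def test_network_from_ids_triangle_and_missing_report(worked):
    net, report = network_from_ids(
        ["NCT01234567"], [], worked.trials, worked.articles, worked.context
    )
    assert (len(net.nodes), net.n_edges()) == (3, 3)
    assert report.missing_ids == []
    net2, report2 = network_from_ids(
        ["NCT99999997"], [], worked.trials, worked.articles, worked.context
    )
    assert len(net2.nodes) == 0
    assert report2.missing_ids == ["NCT99999997"]


def test_network_from_ids_rejects_malformed_ids(worked):
    with pytest.raises(ValueError):
        network_from_ids(["NCT123"], [], worked.trials, worked.articles, worked.context)
    with pytest.raises(ValueError):
        network_from_ids([], ["12x4"], worked.trials, worked.articles, worked.context)


def test_trial_with_linked_pmid_renders_identically_to_trial_alone(worked):
    alone, _ = network_from_ids(
        ["NCT01234567"], [], worked.trials, worked.articles, worked.context
    )
    paired, _ = network_from_ids(
        ["NCT01234567"], ["31000001"], worked.trials, worked.articles, worked.context
    )
    assert alone.same_topology(paired)


def test_render_check_accepts_full_and_rejects_partial_localization(worked):
    trial = worked.trials[0]
    net, _ = network_from_ids(
        [trial.nct_id], [], worked.trials, worked.articles, worked.context
    )
    assert render_check(trial, net, worked.context)
    broken = _trial("NCT00000009", [("Leeds", "GB"), ("Atlantis", "XX")])
    bnet, _ = build_trial_network([broken], worked.context)
    assert not render_check(broken, bnet, worked.context)


def test_edge_supports_subset_of_endpoint_studies(corpus):
    ctx = corpus.context
    tnet, _ = build_trial_network(corpus.trials, ctx)
    anet, _ = build_article_network(corpus.articles, ctx)
    net = merge_networks(tnet, anet, corpus.articles)
    for edge in net.edges:
        a, b = edge.endpoints
        assert edge.endpoints <= set(net.nodes)
        assert a != b
        assert edge.supports <= net.nodes[a].studies & net.nodes[b].studies


def test_geojson_export_validates_and_is_deterministic(corpus):
    net, _ = build_trial_network(corpus.trials, corpus.context)
    doc = to_geojson(net)
    validate_geojson(doc)
    assert json.dumps(doc, sort_keys=True) == json.dumps(to_geojson(net), sort_keys=True)
    points = [f for f in doc["features"] if f["geometry"]["type"] == "Point"]
    lines = [f for f in doc["features"] if f["geometry"]["type"] == "LineString"]
    assert len(points) == len(net.nodes)
    assert len(lines) == net.n_edges()


def same_labeled_graph(a: nx.Graph, b: nx.Graph) -> bool:
    """Node/edge structure and attributes match (graph-level metadata,
    which the GraphML reader pads with defaults, is ignored)."""
    return dict(a.nodes(data=True)) == dict(b.nodes(data=True)) and {
        frozenset(e): d for *e, d in a.edges(data=True)
    } == {frozenset(e): d for *e, d in b.edges(data=True)}


def test_graphml_export_reparses_to_the_same_graph(corpus):
    net, _ = build_trial_network(corpus.trials, corpus.context)
    buf = io.BytesIO()
    to_graphml(net, buf)
    buf.seek(0)
    assert same_labeled_graph(nx.read_graphml(buf), to_graphml_graph(net))
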