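"""Great-circle geometry, concept/date filters and the search pipeline."""

import datetime as dt
import math
import random

import pytest
from hypothesis import given, settings, strategies as st

from studynet.concepts import resolve_term
from studynet.corpus_io import Article, Author, Trial
from studynet.geocode import GeoPoint
from studynet.network import build_article_network, build_trial_network, merge_networks
from studynet.search import (
    EARTH_RADIUS_KM,
    MAX_GREAT_CIRCLE_KM,
    SearchQuery,
    filter_by_dates,
    filter_within_radius,
    haversine_km,
    match_condition,
    run_search,
)

BERLIN = GeoPoint(52.52, 13.40)


def law_of_cosines_km(a: GeoPoint, b: GeoPoint) -> float:
    """Independent second-formula oracle for great-circle distance."""
    p1, p2 = math.radians(a.lat), math.radians(b.lat)
    dl = math.radians(b.lon - a.lon)
    x = math.sin(p1) * math.sin(p2) + math.cos(p1) * math.cos(p2) * math.cos(dl)
    return EARTH_RADIUS_KM * math.acos(max(-1.0, min(1.0, x)))


def test_haversine_identity_and_antipodes():
    p = GeoPoint(48.1, 11.6)
    assert haversine_km(p, p) == 0.0
    half = haversine_km(GeoPoint(90, 0), GeoPoint(-90, 0))
    assert half == pytest.approx(math.pi * 6371.0088, rel=1e-12)
    assert half <= MAX_GREAT_CIRCLE_KM + 1e-9


def test_haversine_is_symmetric():
    a, b = GeoPoint(10.0, 20.0), GeoPoint(-30.0, 140.0)
    assert haversine_km(a, b) == haversine_km(b, a)


@settings(max_examples=200, deadline=None, derandomize=True)
@given(
    lat1=st.floats(-85, 85), lon1=st.floats(-180, 180),
    lat2=st.floats(-85, 85), lon2=st.floats(-180, 180),
)
def test_haversine_agrees_with_law_of_cosines(lat1, lon1, lat2, lon2):
    a, b = GeoPoint(lat1, lon1), GeoPoint(lat2, lon2)
    d = haversine_km(a, b)
    if 1.0 < d < 19_900.0:  # both formulas are well-conditioned here
        assert d == pytest.approx(law_of_cosines_km(a, b), rel=1e-6)


def test_radius_filter_keeps_oracle_verified_near_site(corpus):
    net, _ = build_trial_network(corpus.trials, corpus.context)
    near = [n for n in net.nodes.values() if haversine_km(n.point, BERLIN) <= 200]
    kept = filter_within_radius(net.nodes.values(), BERLIN, 200)
    assert sorted(n.node_key for n in kept) == sorted(n.node_key for n in near)
    assert {"avalon|DE", "brighthelm|DE", "corwen|DE"} <= {n.node_key for n in kept}
    assert "dunwick|ES" not in {n.node_key for n in kept}


def test_radius_upper_bound_keeps_everything(corpus):
    net, _ = build_trial_network(corpus.trials, corpus.context)
    kept = filter_within_radius(net.nodes.values(), BERLIN, 20015.1)
    assert len(kept) == len(net.nodes)


def test_radius_inclusive_at_zero_distance_and_positive_required(corpus):
    net, _ = build_trial_network(corpus.trials, corpus.context)
    node = next(iter(net.nodes.values()))
    assert node in filter_within_radius(net.nodes.values(), node.point, 0.001)
    with pytest.raises(ValueError):
        filter_within_radius(net.nodes.values(), BERLIN, 0)


def test_radius_monotone_in_radius(corpus):
    net, _ = build_trial_network(corpus.trials, corpus.context)
    rng = random.Random(5)
    for _ in range(20):
        center = GeoPoint(rng.uniform(-60, 60), rng.uniform(-180, 180))
        r1, r2 = sorted([rng.uniform(10, 5000), rng.uniform(10, 15000)])
        small = {n.node_key for n in filter_within_radius(net.nodes.values(), center, r1)}
        large = {n.node_key for n in filter_within_radius(net.nodes.values(), center, r2)}
        assert small <= large


def test_match_condition_direct_synonym_and_descriptor(worked):
    cui = resolve_term(worked.index, "Hemophilia A")[0]
    trial = Trial(nct_id="NCT00000001", condition_terms=["Hemophilia A"])
    assert match_condition(trial, [cui], worked.index)
    german = Article(
        pmid="7",
        mesh_terms=["Hämophilie A"],
        authors=[],
    )
    assert match_condition(german, [cui], worked.index)
    by_descriptor = Trial(nct_id="NCT00000002", condition_terms=["D1000003"])
    assert match_condition(by_descriptor, [cui], worked.index)
    assert not match_condition(
        Trial(nct_id="NCT00000003", condition_terms=["Hemophilia B"]),
        [cui],
        worked.index,
    )


def test_any_all_logic_table(worked):
    c_a = resolve_term(worked.index, "Hemophilia A")[0]
    c_b = resolve_term(worked.index, "Hemophilia B")[0]
    only_a = Trial(nct_id="NCT00000001", condition_terms=["Hemophilia A"])
    assert match_condition(only_a, [c_a, c_b], worked.index, "ANY")
    assert not match_condition(only_a, [c_a, c_b], worked.index, "ALL")
    both = Trial(nct_id="NCT00000002",
                 condition_terms=["Hemophilia A", "Hemophilia B"])
    assert match_condition(both, [c_a, c_b], worked.index, "ALL")


def test_all_results_subset_of_any_results(corpus):
    cuis = [corpus.truth.planted_cui, "C1000004"]
    any_hits = {t.nct_id for t in corpus.trials
                if match_condition(t, cuis, corpus.index, "ANY")}
    all_hits = {t.nct_id for t in corpus.trials
                if match_condition(t, cuis, corpus.index, "ALL")}
    assert all_hits <= any_hits


def test_date_filter_bounds_and_undated_exclusion():
    dated = Trial(nct_id="NCT00000001", start_date=dt.date(2016, 5, 1))
    undated = Trial(nct_id="NCT00000002")
    records = [dated, undated]
    assert filter_by_dates(records, None, None) == records
    kept = filter_by_dates(records, dt.date(2014, 1, 1), dt.date(2018, 9, 30))
    assert kept == [dated]
    with pytest.raises(ValueError):
        filter_by_dates(records, dt.date(2018, 1, 1), dt.date(2014, 1, 1))


def test_query_invariants():
    with pytest.raises(ValueError):
        SearchQuery(cuis=())
    with pytest.raises(ValueError):
        SearchQuery(cuis=("C1",), radius_km=100.0)  # radius without center
    with pytest.raises(ValueError):
        SearchQuery(cuis=("C1",), center=BERLIN, radius_km=-5.0)
    with pytest.raises(ValueError):
        SearchQuery(
            cuis=("C1",),
            date_from=dt.date(2020, 1, 1),
            date_to=dt.date(2019, 1, 1),
        )


def test_search_recovers_planted_inner_clique_within_radius(corpus):
    query = SearchQuery(
        cuis=(corpus.truth.planted_cui,), center=BERLIN, radius_km=200.0
    )
    net, report = run_search(
        query, corpus.trials, corpus.articles, corpus.index, corpus.context
    )
    truth = corpus.truth
    expected_nodes = {
        key
        for key, v in truth.expected_nodes.items()
        if haversine_km(GeoPoint(v["lat"], v["lon"]), BERLIN) <= 200.0
    }
    assert set(net.nodes) == expected_nodes
    expected_edges = {
        frozenset(e["endpoints"]): set(e["supports"])
        for e in truth.expected_edges
        if set(e["endpoints"]) <= expected_nodes
    }
    got_edges = {e.endpoints: {str(r) for r in e.supports} for e in net.edges}
    assert got_edges == expected_edges
    assert report.nodes_dropped_by_radius == 2  # the planted out-of-radius pair


def test_search_without_radius_returns_unrestricted_network(corpus):
    query = SearchQuery(cuis=(corpus.truth.planted_cui,))
    net, _ = run_search(
        query, corpus.trials, corpus.articles, corpus.index, corpus.context
    )
    assert set(net.nodes) == set(corpus.truth.expected_nodes)


def test_exclude_articles_drops_article_refs(corpus):
    query = SearchQuery(cuis=(corpus.truth.planted_cui,), include_articles=False)
    net, _ = run_search(
        query, corpus.trials, corpus.articles, corpus.index, corpus.context
    )
    assert all(r.kind == "TRIAL" for r in net.study_refs())


def test_pipeline_is_deterministic(corpus):
    from studynet.network import to_geojson
    import json

    query = SearchQuery(cuis=(corpus.truth.planted_cui,), center=BERLIN,
                        radius_km=500.0)
    nets = [
        run_search(query, corpus.trials, corpus.articles, corpus.index,
                   corpus.context)[0]
        for _ in range(2)
    ]
    assert json.dumps(to_geojson(nets[0]), sort_keys=True) == json.dumps(
        to_geojson(nets[1]), sort_keys=True
    )
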