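"""Gazetteer loading and the facility/affiliation geocoding cascade."""

import io
import random

import pytest

from studynet.corpus_io import Facility
from studynet.errors import GazetteerError
from studynet.fixtures import FixtureSpec, generate
from studynet.geocode import (
    FacilityIndex,
    GeocodeMethod,
    GeoPoint,
    build_facility_index,
    geocode_affiliation,
    geocode_facility,
    load_gazetteer,
)

TWO_ROWS = (
    "1\tLeeds\tLeeds\tLoidis\t53.79648\t-1.54785\tGB\t474632\n"
    "2\tBerlin\tBerlin\t\t52.52437\t13.41053\tDE\t3426354\n"
)


def test_lookup_by_name_or_alternate_name():
    gaz = load_gazetteer(io.StringIO(TWO_ROWS))
    assert gaz.lookup("Leeds")[0].entry_id == 1
    assert gaz.lookup("Loidis")[0].entry_id == 1
    assert gaz.lookup("berlin")[0].entry_id == 2


def test_out_of_bounds_coordinate_names_the_row():
    bad = "1\tNowhere\tNowhere\t\t95.0\t0.0\tGB\t10\n"
    with pytest.raises(GazetteerError, match="row 1"):
        load_gazetteer(io.StringIO(bad))


def test_geopoint_rejects_nan_and_out_of_range():
    with pytest.raises(ValueError):
        GeoPoint(float("nan"), 0.0)
    with pytest.raises(ValueError):
        GeoPoint(0.0, 181.0)


def test_seeded_gazetteer_every_surface_form_retrieves_its_entry(tmp_path):
    corpus = generate(FixtureSpec(seed=17, n_cities=80), tmp_path)
    for entry in corpus.gazetteer.entries.values():  # exhaustive scan oracle
        for form in entry.surface_forms():
            assert entry in corpus.gazetteer.lookup(form)


def test_facility_city_country_match(worked):
    res = geocode_facility(
        Facility(name="x", city="Leeds", country="GB"), worked.gazetteer
    )
    assert res.method is GeocodeMethod.CITY_COUNTRY
    assert res.point == GeoPoint(53.79648, -1.54785)


def test_facility_unknown_city_is_method_none(worked):
    res = geocode_facility(Facility(name="x", city="Atlantis"), worked.gazetteer)
    assert res.method is GeocodeMethod.NONE
    assert res.point is None


def test_facility_alternate_name_resolves_like_canonical(worked):
    canonical = geocode_facility(
        Facility(name="x", city="Münster", country="Germany"), worked.gazetteer
    )
    alt = geocode_facility(
        Facility(name="x", city="Muenster in Westfalen", country="Germany"),
        worked.gazetteer,
    )
    assert alt.method is GeocodeMethod.CITY_COUNTRY
    assert (alt.point, alt.matched_entry) == (canonical.point, canonical.matched_entry)


def test_affiliation_priority1_facility_from_trial_corpus(worked):
    res = geocode_affiliation(
        "Institute of Cardiology, University of Leeds, Leeds LS184AB, United Kingdom",
        worked.gazetteer,
        worked.facility_index,
    )
    assert res.method is GeocodeMethod.FACILITY
    assert res.matched_city == "Leeds"


def test_affiliation_priority2_country_evidence_disambiguates(worked):
    res = geocode_affiliation(
        "Dept. of Medicine, Springfield, United States",
        worked.gazetteer,
        worked.facility_index,
    )
    assert res.method is GeocodeMethod.CITY_COUNTRY
    assert res.matched_entry.country == "US"


def test_affiliation_priority3_population_fallback(worked):
    res = geocode_affiliation("Springfield", worked.gazetteer, worked.facility_index)
    assert res.method is GeocodeMethod.CITY_POPULATION
    assert res.matched_entry.population == 167000


def test_unresolvable_affiliation_is_none_not_an_error(worked):
    res = geocode_affiliation("", worked.gazetteer, worked.facility_index)
    assert res.method is GeocodeMethod.NONE
    res = geocode_affiliation("Nowhere Institute", worked.gazetteer, None)
    assert res.method is GeocodeMethod.NONE


def test_facility_match_dominates_other_cascade_evidence(worked):
    # the same string also carries city+country evidence for Berlin, but a
    # facility hit must win regardless
    res = geocode_affiliation(
        "University of Leeds, Berlin, Germany", worked.gazetteer, worked.facility_index
    )
    assert res.method is GeocodeMethod.FACILITY
    assert res.matched_city == "Leeds"


def test_planted_corpus_affiliations_resolve_with_expected_method(corpus):
    fi = build_facility_index(corpus.trials)
    for exp in corpus.truth.expected_methods:
        res = geocode_affiliation(exp["affiliation"], corpus.gazetteer, fi)
        assert res.method.value == exp["method"], exp["affiliation"]


def test_priority3_equals_brute_force_maximum_population(tmp_path):
    corpus = generate(
        FixtureSpec(seed=23, n_cities=120, n_ambiguous_city_names=25), tmp_path
    )
    gaz = corpus.gazetteer
    names = sorted({e.name for e in gaz.entries.values() if len(gaz.lookup(e.name)) > 1})
    rng = random.Random(23)
    for _ in range(300):
        name = rng.choice(names)
        res = geocode_affiliation(name, gaz, None)
        assert res.method is GeocodeMethod.CITY_POPULATION
        candidates = [e for e in gaz.entries.values() if name in e.surface_forms()]
        best = min(candidates, key=lambda e: (-e.population, e.entry_id))
        assert res.matched_entry == best


def test_geocoding_is_deterministic(worked):
    a = geocode_affiliation("Springfield", worked.gazetteer, worked.facility_index)
    b = geocode_affiliation("Springfield", worked.gazetteer, worked.facility_index)
    assert a == b


def test_facility_index_first_ingested_wins(caplog):
    fi = FacilityIndex()
    fi.add("General Hospital", "Leeds", "GB")
    fi.add("General Hospital", "Berlin", "DE")
    assert fi.lookup("general  hospital")[0] == "Leeds"
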