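"""Gazetteer geocoding of study facilities and author affiliations.

The gazetteer dialect is a column subset of the geonames.org
``allCountries`` dump: tab-separated ``geonameid, name, asciiname,
alternatenames (comma-joined), latitude, longitude, country_code,
population``, no header, so real extracts load unchanged.  All surface
forms (name, ascii name, alternates) are indexed under normalization.

Unstructured affiliation strings resolve through a descending-priority
cascade:

1. FACILITY — a phrase matches a facility name already known from the
   trial corpus; that facility's registered city is geocoded.
2. CITY_COUNTRY — a phrase matches a gazetteer city while another phrase
   names that city's country (ISO alpha-2 code or a known country name).
3. CITY_POPULATION — a phrase matches one or more gazetteer cities with
   no country evidence; the most populous candidate wins (ties broken by
   ascending gazetteer id, for determinism).

Facilities from structured trial records use the same rules minus the
facility step.  Unresolvable inputs produce a ``NONE`` result, never an
exception; callers accumulate them in coverage reports.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field
from enum import Enum
from typing import IO, Iterable, Mapping

from ._text import normalize
from .corpus_io import Facility, Trial
from .errors import GazetteerError

__all__ = [
    "GeoPoint",
    "GazetteerEntry",
    "Gazetteer",
    "FacilityIndex",
    "GeocodeMethod",
    "GeocodeResult",
    "COUNTRY_NAMES",
    "load_gazetteer",
    "build_facility_index",
    "geocode_facility",
    "geocode_affiliation",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class GeoPoint:
    """A WGS84 coordinate pair in decimal degrees."""

    lat: float
    lon: float

    def __post_init__(self) -> None:
        if math.isnan(self.lat) or math.isnan(self.lon):
            raise ValueError("GeoPoint components must not be NaN")
        if not -90.0 <= self.lat <= 90.0:
            raise ValueError(f"latitude {self.lat} outside [-90, 90]")
        if not -180.0 <= self.lon <= 180.0:
            raise ValueError(f"longitude {self.lon} outside [-180, 180]")


@dataclass(frozen=True)
class GazetteerEntry:
    """A named populated place with coordinates, country and population."""

    entry_id: int
    name: str
    ascii_name: str
    alternate_names: tuple[str, ...]
    country: str
    population: int
    point: GeoPoint
    zip_codes: tuple[str, ...] = ()

    def surface_forms(self) -> set[str]:
        forms = {self.name, self.ascii_name, *self.alternate_names}
        return {f for f in forms if f}


# Minimal ISO 3166-1 alpha-2 -> common English names/aliases, used as
# country evidence in cascade priority 2 and to normalize the free-text
# country field of trial facilities.
COUNTRY_NAMES: Mapping[str, tuple[str, ...]] = {
    "US": ("United States", "United States of America", "USA"),
    "GB": ("United Kingdom", "Great Britain", "UK", "England", "Scotland", "Wales"),
    "DE": ("Germany", "Deutschland"),
    "FR": ("France",),
    "ES": ("Spain", "España"),
    "IT": ("Italy", "Italia"),
    "AU": ("Australia",),
    "CA": ("Canada",),
    "JP": ("Japan",),
    "CN": ("China",),
    "CH": ("Switzerland", "Schweiz", "Suisse"),
    "AT": ("Austria", "Österreich"),
    "NL": ("Netherlands", "The Netherlands", "Holland"),
    "BE": ("Belgium",),
    "SE": ("Sweden",),
    "NO": ("Norway",),
    "DK": ("Denmark",),
    "FI": ("Finland",),
    "PL": ("Poland",),
    "PT": ("Portugal",),
    "GR": ("Greece",),
    "IE": ("Ireland",),
    "NZ": ("New Zealand",),
    "BR": ("Brazil", "Brasil"),
    "MX": ("Mexico", "México"),
    "AR": ("Argentina",),
    "IN": ("India",),
    "KR": ("South Korea", "Korea, Republic of", "Republic of Korea"),
    "RU": ("Russia", "Russian Federation"),
    "TR": ("Turkey", "Türkiye"),
    "ZA": ("South Africa",),
    "IL": ("Israel",),
    "SG": ("Singapore",),
    "CZ": ("Czech Republic", "Czechia"),
    "HU": ("Hungary",),
}

_NAME_TO_CODE: dict[str, str] = {}
for _code, _names in COUNTRY_NAMES.items():
    _NAME_TO_CODE[normalize(_code)] = _code
    for _n in _names:
        _NAME_TO_CODE[normalize(_n)] = _code


def country_code(text: str) -> str | None:
    """Resolve a country name or alpha-2 code to its alpha-2 code."""
    return _NAME_TO_CODE.get(normalize(text))


class Gazetteer:
    """Indexed gazetteer supporting lookup by name and by (name, country)."""

    def __init__(self, entries: Iterable[GazetteerEntry]):
        self.entries: dict[int, GazetteerEntry] = {}
        self._by_name: dict[str, list[GazetteerEntry]] = {}
        for e in entries:
            if e.entry_id in self.entries:
                raise GazetteerError(f"duplicate gazetteer id {e.entry_id}")
            self.entries[e.entry_id] = e
            for form in e.surface_forms():
                self._by_name.setdefault(normalize(form), []).append(e)

    def __len__(self) -> int:
        return len(self.entries)

    def lookup(self, name: str, country: str | None = None) -> list[GazetteerEntry]:
        """Entries matching a place name, optionally restricted by country.

        ``country`` may be an alpha-2 code or a known country name.
        Results are ordered by descending population then ascending id,
        so the head of the list is the cascade's deterministic pick.
        """
        hits = self._by_name.get(normalize(name), [])
        if country is not None:
            code = country_code(country) or country.strip().upper()
            hits = [e for e in hits if e.country == code]
        return sorted(hits, key=lambda e: (-e.population, e.entry_id))


def load_gazetteer(source: IO | str) -> Gazetteer:
    """Load the tab-separated gazetteer dialect.

    Rows: geonameid, name, asciiname, alternatenames (comma-joined),
    latitude, longitude, country_code, population.  An out-of-bounds
    coordinate or malformed field is an error naming the row.
    """
    close = False
    if isinstance(source, str):
        fh = open(source, "r", encoding="utf-8")
        close = True
    else:
        fh = source
    entries: list[GazetteerEntry] = []
    try:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            cols = line.split("\t")
            if len(cols) != 8:
                raise GazetteerError(
                    f"row {lineno}: expected 8 tab-separated columns, got {len(cols)}"
                )
            gid, name, ascii_name, alts, lat_s, lon_s, cc, pop_s = cols
            try:
                lat, lon = float(lat_s), float(lon_s)
                population = int(pop_s)
                entry_id = int(gid)
            except ValueError as exc:
                raise GazetteerError(f"row {lineno}: {exc}") from exc
            try:
                point = GeoPoint(lat, lon)
            except ValueError as exc:
                raise GazetteerError(f"row {lineno}: {exc}") from exc
            if population < 0:
                raise GazetteerError(f"row {lineno}: negative population")
            entries.append(
                GazetteerEntry(
                    entry_id=entry_id,
                    name=name,
                    ascii_name=ascii_name,
                    alternate_names=tuple(a for a in alts.split(",") if a),
                    country=cc.strip().upper(),
                    population=population,
                    point=point,
                )
            )
    finally:
        if close:
            fh.close()
    return Gazetteer(entries)


# ---------------------------------------------------------------------------
# Facility index


class FacilityIndex:
    """Exact lookup from normalized facility name to its registered city.

    Built from the trial corpus; the first-ingested record wins on a
    collision (with a warning), mirroring how the registry itself keys
    facilities by name.
    """

    def __init__(self) -> None:
        self._map: dict[str, tuple[str, str, str | None]] = {}

    def add(self, name: str, city: str, country: str, zip_code: str | None = None) -> None:
        key = normalize(name)
        if not key:
            return
        if key in self._map:
            if self._map[key][:2] != (city, country):
                log.warning(
                    "facility name collision for %r: keeping first-ingested city %r",
                    name, self._map[key][0],
                )
            return
        self._map[key] = (city, country, zip_code)

    def lookup(self, name: str) -> tuple[str, str, str | None] | None:
        return self._map.get(normalize(name))

    def __len__(self) -> int:
        return len(self._map)


def build_facility_index(trials: Iterable[Trial]) -> FacilityIndex:
    """Index every named facility of a trial corpus by normalized name."""
    index = FacilityIndex()
    for t in trials:
        for f in t.facilities:
            if f.name and f.city:
                index.add(f.name, f.city, f.country, f.zip)
    return index


# ---------------------------------------------------------------------------
# Geocoding


class GeocodeMethod(Enum):
    FACILITY = "FACILITY"
    CITY_COUNTRY = "CITY_COUNTRY"
    CITY_POPULATION = "CITY_POPULATION"
    NONE = "NONE"


@dataclass(frozen=True)
class GeocodeResult:
    """Outcome of one geocoding attempt; method NONE iff no point found."""

    point: GeoPoint | None
    matched_entry: GazetteerEntry | None
    method: GeocodeMethod
    matched_city: str | None

    @property
    def resolved(self) -> bool:
        return self.method is not GeocodeMethod.NONE


_NO_MATCH = GeocodeResult(None, None, GeocodeMethod.NONE, None)


def _result(entry: GazetteerEntry, method: GeocodeMethod) -> GeocodeResult:
    return GeocodeResult(entry.point, entry, method, entry.name)


def _lookup_city(
    gazetteer: Gazetteer, city: str, country: str | None
) -> GeocodeResult:
    """City+country first; fall back to most-populous same-named city."""
    if country and country.strip():
        hits = gazetteer.lookup(city, country)
        if hits:
            return _result(hits[0], GeocodeMethod.CITY_COUNTRY)
    hits = gazetteer.lookup(city)
    if hits:
        return _result(hits[0], GeocodeMethod.CITY_POPULATION)
    return _NO_MATCH


def geocode_facility(facility: Facility, gazetteer: Gazetteer) -> GeocodeResult:
    """Geocode a structured trial facility by its city and country."""
    if not facility.city.strip():
        return _NO_MATCH
    return _lookup_city(gazetteer, facility.city, facility.country or None)


_POSTAL_TOKEN = re.compile(r".*\d.*")


def _phrases(text: str) -> list[str]:
    """Split an affiliation on commas/semicolons; strip postal-code-like
    trailing tokens (any token containing a digit) from each phrase."""
    out = []
    for raw in re.split(r"[,;]", text):
        tokens = raw.split()
        while tokens and _POSTAL_TOKEN.match(tokens[-1]):
            tokens.pop()
        phrase = " ".join(tokens)
        if phrase:
            out.append(phrase)
    return out


def geocode_affiliation(
    text: str, gazetteer: Gazetteer, facilities: FacilityIndex | None = None
) -> GeocodeResult:
    """Resolve an unstructured affiliation through the priority cascade.

    See the module docstring for the three priorities.  When two cities
    both carry country evidence, the first phrase in reading order wins.
    """
    phrases = _phrases(text or "")
    if not phrases:
        return _NO_MATCH

    # Priority 1: known facility name anywhere in the phrase list.
    if facilities is not None:
        for phrase in phrases:
            hit = facilities.lookup(phrase)
            if hit is not None:
                city, country, _zip = hit
                located = _lookup_city(gazetteer, city, country or None)
                if located.resolved:
                    return GeocodeResult(
                        located.point,
                        located.matched_entry,
                        GeocodeMethod.FACILITY,
                        located.matched_city,
                    )

    # Country evidence: alpha-2 codes or known country names among phrases.
    evidence: dict[str, set[str]] = {}  # country code -> phrases providing it
    for phrase in phrases:
        code = country_code(phrase)
        if code:
            evidence.setdefault(code, set()).add(phrase)

    # Priority 2: city whose country is named by *another* phrase.
    for phrase in phrases:
        hits = gazetteer.lookup(phrase)
        for entry in hits:  # ordered by population desc, id asc
            providers = evidence.get(entry.country, set())
            if providers - {phrase}:
                return _result(entry, GeocodeMethod.CITY_COUNTRY)

    # Priority 3: most populous city matching any phrase.
    candidates: list[GazetteerEntry] = []
    for phrase in phrases:
        candidates.extend(gazetteer.lookup(phrase))
    if candidates:
        best = min(candidates, key=lambda e: (-e.population, e.entry_id))
        return _result(best, GeocodeMethod.CITY_POPULATION)
    return _NO_MATCH
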