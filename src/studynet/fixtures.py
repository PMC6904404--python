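"""Seeded synthetic corpora with planted ground truth.

Everything the package consumes — trial registry XML, citation XML, a
gazetteer and a multilingual concept table — can be generated offline in
format-valid form, with known structure planted so that every pipeline
stage is testable without live databases:

* ambiguous city names (same name, different countries) get distinct
  populations with a unique maximum, so the most-populous-city fallback
  has a well-defined expected answer;
* a configurable fraction of articles carries structured NCT accessions
  pointing at generated trials, exercising duplicate removal;
* the multilingual exemplar synonym groups — "heart attack" /
  "Herzinfarkt" / "ataque al corazón" under one CUI, and "Hemophilia" /
  "Hemophilia A" / "Hemophilia B" as distinct CUIs — are always present;
* planted study cliques (trials or articles spanning chosen cities)
  define the exact research network a search must recover.

Outputs are a pure function of (seed, spec): each artifact type draws
from its own pseudo-random stream derived from the master seed, so e.g.
changing the article count never perturbs the gazetteer.  Names are
drawn from fixed word lists; no real-world person data is used.
"""

from __future__ import annotations

import datetime as _dt
import json
import random
from dataclasses import dataclass, field, asdict
from importlib import resources
from pathlib import Path

from ._text import normalize
from .concepts import ConceptIndex, load_concept_table
from .corpus_io import (
    Article,
    Author,
    Facility,
    Trial,
    parse_articles,
    parse_trials,
    write_articles,
    write_trials,
)
from .errors import FixtureSpecError
from .geocode import (
    COUNTRY_NAMES,
    FacilityIndex,
    Gazetteer,
    build_facility_index,
    load_gazetteer,
)
from .network import GeocoderContext

__all__ = [
    "PlantedCity",
    "PlantedNetwork",
    "FixtureSpec",
    "GroundTruth",
    "GeneratedCorpus",
    "generate",
    "paper_worked_examples",
    "WorkedExamples",
]

ALL_LANGUAGES = ("ENG", "SPA", "FRE", "GER", "ITA")

_CITY_STEMS = [
    "Alder", "Birch", "Cedar", "Dunmore", "Elm", "Fern", "Glen", "Hazel",
    "Iron", "Juniper", "Kestrel", "Larch", "Maple", "Nettle", "Oak",
    "Pine", "Quarry", "Rowan", "Sorrel", "Thorn", "Umber", "Vale",
    "Willow", "Yarrow", "Aspen", "Bracken", "Clover", "Dray", "Ember",
    "Frost", "Gorse", "Heath", "Ivy", "Jade", "Kiln", "Moor",
]
_CITY_SUFFIXES = ["ford", "ton", "ville", "burg", "field", "haven", "port", "stead"]

_DISEASE_STEMS = [
    "Aldro", "Brachy", "Cervo", "Dactyl", "Entero", "Fibro", "Gastro",
    "Hepato", "Immuno", "Kerato", "Lipo", "Myelo", "Neuro", "Osteo",
    "Pulmo", "Reno", "Sclero", "Thrombo", "Vaso", "Xantho",
]
_DISEASE_SUFFIXES = ["itis", "oma", "osis", "pathy", "plasia", "trophy"]
_LANG_VARIANT_SUFFIX = {"SPA": "a", "FRE": "e", "GER": "krankheit", "ITA": "o"}

_FORENAMES = [
    "Alba", "Boris", "Clara", "Dmitri", "Elena", "Farid", "Greta",
    "Hugo", "Ines", "Jonas", "Katja", "Lars", "Mira", "Nils", "Olga",
    "Pavel", "Runa", "Sven", "Tessa", "Ulric",
]
_SURNAMES = [
    "Aldercroft", "Birchwald", "Cedergren", "Dunholm", "Elmqvist",
    "Fernside", "Glenmore", "Hazelton", "Ironfield", "Junberg",
    "Kestrelli", "Larchmont", "Mapleson", "Nettlefold", "Oakhurst",
    "Pinewald", "Rowanson", "Sorrelle", "Thornquist", "Umberto",
]

_COUNTRY_CODES = sorted(COUNTRY_NAMES)


def _rng(seed: int, label: str) -> random.Random:
    # string seeds hash via SHA-512 in CPython: process-stable determinism
    return random.Random(f"{seed}:{label}")


def _country_name(code: str) -> str:
    return COUNTRY_NAMES[code][0]


# ---------------------------------------------------------------------------
# Spec and ground truth


@dataclass(frozen=True)
class PlantedCity:
    """A gazetteer city with fixed coordinates for planted structure."""

    name: str
    country: str  # ISO alpha-2
    lat: float
    lon: float
    population: int = 500_000


@dataclass(frozen=True)
class PlantedNetwork:
    """One study spanning the named planted cities (a clique)."""

    kind: str  # "TRIAL" | "ARTICLE"
    cities: tuple[str, ...]


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic corpus.

    ``n_trials``/``n_articles`` are background records on top of any
    planted studies; ``n_cities`` is the total gazetteer size including
    planted and ambiguous entries.  ``linked_fraction`` of background
    articles is generated *from* a background trial, carrying its NCT id
    as a structured accession and reusing its cities.
    """

    seed: int = 0
    n_trials: int = 20
    n_articles: int = 20
    n_cities: int = 50
    n_ambiguous_city_names: int = 5
    n_background_concepts: int = 30
    languages: tuple[str, ...] = ALL_LANGUAGES
    planted_networks: tuple[PlantedNetwork, ...] = ()
    planted_cities: tuple[PlantedCity, ...] = ()
    planted_synonym_groups: tuple[tuple[str, tuple[tuple[str, str], ...]], ...] = ()
    planted_condition: str = "Hemophilia A"
    linked_fraction: float = 0.3

    def validate(self) -> None:
        if min(self.n_trials, self.n_articles, self.n_cities,
               self.n_ambiguous_city_names, self.n_background_concepts) < 0:
            raise FixtureSpecError("counts must be non-negative")
        unknown = set(self.languages) - set(ALL_LANGUAGES)
        if unknown:
            raise FixtureSpecError(f"unsupported languages {sorted(unknown)}")
        if not 0.0 <= self.linked_fraction <= 1.0:
            raise FixtureSpecError("linked_fraction must be in [0, 1]")
        planted_names = {c.name for c in self.planted_cities}
        if len(planted_names) != len(self.planted_cities):
            raise FixtureSpecError("planted city names must be unique")
        for pc in self.planted_cities:
            if pc.country not in COUNTRY_NAMES:
                raise FixtureSpecError(f"unknown country code {pc.country!r}")
        for net in self.planted_networks:
            if net.kind not in ("TRIAL", "ARTICLE"):
                raise FixtureSpecError(f"bad planted study kind {net.kind!r}")
            missing = set(net.cities) - planted_names
            if missing:
                raise FixtureSpecError(
                    f"planted cities not in gazetteer spec: {sorted(missing)}"
                )
            if net.kind == "ARTICLE" and len(net.cities) > 4:
                raise FixtureSpecError(
                    "an article has at most 4 lead authors; "
                    f"cannot plant {len(net.cities)} cities"
                )
        ambiguous_entries = 2 * self.n_ambiguous_city_names
        if len(self.planted_cities) + ambiguous_entries > self.n_cities:
            raise FixtureSpecError("n_cities too small for planted + ambiguous entries")


@dataclass
class GroundTruth:
    """What the generated corpus is known to contain, by construction."""

    expected_nodes: dict[str, dict]          # node_key -> {lat, lon, studies}
    expected_edges: list[dict]               # {endpoints, supports}
    expected_methods: list[dict]             # {pmid, ordinal, affiliation, method, node_key}
    term_cuis: dict[str, str]                # generated term -> CUI
    planted_trial_ids: list[str]
    planted_article_ids: list[str]
    linked_pairs: list[dict]                 # {pmid, nct_id}
    planted_cui: str

    def to_json(self) -> str:
        return json.dumps(asdict(self), ensure_ascii=False, sort_keys=True, indent=1)


@dataclass
class GeneratedCorpus:
    """Paths plus parsed artifacts of one generated corpus."""

    out_dir: Path
    trials: list[Trial]
    articles: list[Article]
    gazetteer: Gazetteer
    index: ConceptIndex
    truth: GroundTruth

    @property
    def context(self) -> GeocoderContext:
        return GeocoderContext(self.gazetteer, build_facility_index(self.trials))


# ---------------------------------------------------------------------------
# Generation


def _node_key(city: str, country: str) -> str:
    return f"{normalize(city)}|{country}"


def _gen_gazetteer_rows(
    spec: FixtureSpec,
) -> tuple[
    list[str], dict[str, PlantedCity], list[tuple[str, str]], list[tuple[str, str]]
]:
    """Rows, planted-city map, ambiguous (name, most-populous country)
    pairs, and background (name, country) pairs."""
    rng = _rng(spec.seed, "gazetteer")
    rows: list[str] = []
    used_names: set[str] = set()
    next_id = 1

    def emit(name: str, alts: list[str], lat: float, lon: float, cc: str, pop: int) -> int:
        nonlocal next_id
        eid = next_id
        next_id += 1
        rows.append(
            "\t".join(
                [str(eid), name, normalize(name).title().replace(" ", ""),
                 ",".join(alts), f"{lat:.5f}", f"{lon:.5f}", cc, str(pop)]
            )
        )
        return eid

    planted = {c.name: c for c in spec.planted_cities}
    for c in spec.planted_cities:
        used_names.add(c.name)
        emit(c.name, [], c.lat, c.lon, c.country, c.population)

    def fresh_name() -> str:
        while True:
            name = rng.choice(_CITY_STEMS) + rng.choice(_CITY_SUFFIXES)
            if name not in used_names:
                used_names.add(name)
                return name

    ambiguous: list[tuple[str, str]] = []
    for _ in range(spec.n_ambiguous_city_names):
        name = fresh_name()
        cc_a, cc_b = rng.sample(_COUNTRY_CODES, 2)
        pops = rng.sample(range(5_000, 3_000_000), 2)
        big, small = max(pops), min(pops)
        if big == small:  # rng.sample is without replacement, but be safe
            big += 1
        emit(name, [], rng.uniform(-55, 65), rng.uniform(-175, 175), cc_a, big)
        emit(name, [], rng.uniform(-55, 65), rng.uniform(-175, 175), cc_b, small)
        ambiguous.append((name, cc_a))

    n_background = spec.n_cities - len(spec.planted_cities) - 2 * spec.n_ambiguous_city_names
    background: list[tuple[str, str]] = []
    for i in range(n_background):
        name = fresh_name()
        alts = []
        if i % 3 == 0:
            alts.append("Saint " + name)
        if i % 4 == 0:
            alts.append(name.replace("a", "á", 1) if "a" in name else name + "ä")
        cc = rng.choice(_COUNTRY_CODES)
        emit(name, alts, rng.uniform(-55, 65), rng.uniform(-175, 175), cc,
             rng.randrange(10_000, 2_000_000))
        background.append((name, cc))
    return rows, planted, ambiguous, background


_EXEMPLAR_ROWS = [
    # the multilingual worked example: one concept, many languages
    ("C1000001", "ENG", "MSH", "D1000001", "Myocardial Infarction", "Y"),
    ("C1000001", "ENG", "MSH", "D1000001", "heart attack", "N"),
    ("C1000001", "GER", "MSH", "D1000001", "Herzinfarkt", "N"),
    ("C1000001", "SPA", "MSH", "D1000001", "ataque al corazón", "N"),
    ("C1000001", "FRE", "MSH", "D1000001", "infarctus du myocarde", "N"),
    ("C1000001", "ITA", "MSH", "D1000001", "infarto miocardico", "N"),
    # distinct concepts sharing a prefix: the autosuggest worked example
    ("C1000002", "ENG", "MSH", "D1000002", "Hemophilia", "Y"),
    ("C1000002", "GER", "MSH", "D1000002", "Hämophilie", "N"),
    ("C1000002", "SPA", "MSH", "D1000002", "Hemofilia", "N"),
    ("C1000003", "ENG", "MSH", "D1000003", "Hemophilia A", "Y"),
    ("C1000003", "GER", "MSH", "D1000003", "Hämophilie A", "N"),
    ("C1000004", "ENG", "MSH", "D1000004", "Hemophilia B", "Y"),
    ("C1000004", "GER", "MSH", "D1000004", "Hämophilie B", "N"),
]


def _gen_concept_rows(spec: FixtureSpec) -> tuple[list[str], dict[str, str], list[str]]:
    """Concept-table lines, term->cui truth, background English terms."""
    rng = _rng(spec.seed, "concepts")
    lines: list[str] = []
    term_cuis: dict[str, str] = {}

    def emit(cui: str, lat: str, sab: str, code: str, term: str, pref: str) -> None:
        lines.append("|".join([cui, lat, sab, code, term, pref]))
        term_cuis[term] = cui

    for row in _EXEMPLAR_ROWS:
        emit(*row)
    for cui, terms in spec.planted_synonym_groups:
        for i, (lang, term) in enumerate(terms):
            emit(cui, lang, "MSH", f"D{cui[1:]}", term, "Y" if i == 0 else "N")

    background_terms: list[str] = []
    stems = rng.sample(_DISEASE_STEMS, min(len(_DISEASE_STEMS), spec.n_background_concepts))
    i = 0
    while len(background_terms) < spec.n_background_concepts:
        stem = stems[i % len(stems)]
        suffix = _DISEASE_SUFFIXES[(i // len(stems)) % len(_DISEASE_SUFFIXES)]
        term = stem + suffix
        i += 1
        if term in term_cuis:
            continue
        cui = f"C2{len(background_terms):06d}"
        code = f"D2{len(background_terms):06d}"
        emit(cui, "ENG", "MSH", code, term, "Y")
        for lang in spec.languages:
            if lang == "ENG":
                continue
            variant = term + _LANG_VARIANT_SUFFIX.get(lang, "x")
            emit(cui, lang, "MSH", code, variant, "N")
        background_terms.append(term)
    return lines, term_cuis, background_terms


def generate(spec: FixtureSpec, out_dir: str | Path) -> GeneratedCorpus:
    """Write the four corpus files plus a ground-truth sidecar.

    Emits ``trials.xml``, ``articles.xml``, ``gazetteer.tsv``,
    ``concepts.psv`` and ``ground_truth.json`` under ``out_dir`` and
    returns the parsed corpus with its :class:`GroundTruth`.  Same seed
    and spec give byte-identical files.
    """
    spec.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    gaz_rows, planted_cities, ambiguous, background_cities = _gen_gazetteer_rows(spec)
    concept_lines, term_cuis, background_terms = _gen_concept_rows(spec)
    planted_cui = term_cuis.get(spec.planted_condition)
    if planted_cui is None:
        raise FixtureSpecError(
            f"planted condition {spec.planted_condition!r} is not a generated term"
        )

    # ---- trials ----------------------------------------------------------
    rng_t = _rng(spec.seed, "trials")
    trials: list[Trial] = []
    planted_trial_ids: list[str] = []
    expected_nodes: dict[str, dict] = {}
    expected_edges: dict[frozenset, set[str]] = {}

    def plant_node(city: PlantedCity, ref: str) -> str:
        key = _node_key(city.name, city.country)
        entry = expected_nodes.setdefault(
            key, {"lat": round(city.lat, 5), "lon": round(city.lon, 5), "studies": []}
        )
        if ref not in entry["studies"]:
            entry["studies"].append(ref)
        return key

    def plant_clique(keys: list[str], ref: str) -> None:
        uniq = sorted(set(keys))
        for i, a in enumerate(uniq):
            for b in uniq[i + 1:]:
                expected_edges.setdefault(frozenset((a, b)), set()).add(ref)

    planted_trial_nets = [n for n in spec.planted_networks if n.kind == "TRIAL"]
    planted_article_nets = [n for n in spec.planted_networks if n.kind == "ARTICLE"]

    for i, pnet in enumerate(planted_trial_nets):
        nct = f"NCT{90000000 + i}"
        planted_trial_ids.append(nct)
        ref = f"TRIAL:{nct}"
        keys = []
        facilities = []
        for cname in pnet.cities:
            city = planted_cities[cname]
            facilities.append(
                Facility(
                    name=f"University of {cname}",
                    city=cname,
                    zip=f"{10000 + i:05d}",
                    country=_country_name(city.country),
                )
            )
            keys.append(plant_node(city, ref))
        plant_clique(keys, ref)
        start = _dt.date(2016, 5, 1) + _dt.timedelta(days=i)
        trials.append(
            Trial(
                nct_id=nct,
                title=f"Planted multicentre study {i + 1}",
                condition_terms=[spec.planted_condition],
                facilities=facilities,
                start_date=start,
                completion_date=start + _dt.timedelta(days=900),
                status="Recruiting",
            )
        )

    background_trials: list[Trial] = []
    for i in range(spec.n_trials):
        nct = f"NCT{10000000 + i}"
        k = rng_t.randint(1, 4)
        cities = rng_t.sample(background_cities, min(k, len(background_cities)))
        facilities = [
            Facility(
                name=rng_t.choice(
                    [f"University of {name}", f"{name} Medical Center",
                     f"{name} General Hospital"]
                ),
                city=name,
                zip=f"{rng_t.randrange(10000, 99999)}",
                country=_country_name(cc),
            )
            for name, cc in cities
        ]
        start = _dt.date(2010, 1, 1) + _dt.timedelta(days=rng_t.randrange(0, 3650))
        t = Trial(
            nct_id=nct,
            title=f"Background study {i + 1}",
            condition_terms=rng_t.sample(background_terms, min(2, len(background_terms))),
            facilities=facilities,
            start_date=start,
            completion_date=start + _dt.timedelta(days=rng_t.randrange(30, 2000)),
            status=rng_t.choice(["Recruiting", "Completed", "Active, not recruiting"]),
        )
        background_trials.append(t)
        trials.append(t)

    # ---- articles --------------------------------------------------------
    rng_a = _rng(spec.seed, "articles")
    articles: list[Article] = []
    planted_article_ids: list[str] = []
    expected_methods: list[dict] = []
    linked_pairs: list[dict] = []

    def person(rng: random.Random) -> str:
        return f"{rng.choice(_FORENAMES)} {rng.choice(_SURNAMES)}"

    def lead_ordinals(n: int) -> list[int]:
        return sorted({1, 2, n - 1, n} & set(range(1, n + 1)))

    for i, pnet in enumerate(planted_article_nets):
        pmid = f"9{i:07d}"
        planted_article_ids.append(pmid)
        ref = f"ARTICLE:{pmid}"
        n_auth = max(5, len(pnet.cities) + 1)
        leads = lead_ordinals(n_auth)
        authors = []
        keys = []
        for ordinal in range(1, n_auth + 1):
            affil = None
            if ordinal in leads:
                city = planted_cities[pnet.cities[leads.index(ordinal) % len(pnet.cities)]]
                affil = (
                    f"Department of Medicine, {city.name}, {_country_name(city.country)}"
                )
                key = plant_node(city, ref)
                keys.append(key)
                expected_methods.append(
                    {"pmid": pmid, "ordinal": ordinal, "affiliation": affil,
                     "method": "CITY_COUNTRY", "node_key": key}
                )
            authors.append(Author(person(rng_a), ordinal, affil))
        plant_clique(keys, ref)
        articles.append(
            Article(
                pmid=pmid,
                title=f"Planted article {i + 1}",
                mesh_terms=[spec.planted_condition],
                authors=authors,
                pub_date=_dt.date(2017, 3, 1) + _dt.timedelta(days=i),
            )
        )

    background_facilities = [
        (f.name, f.city, f.country)
        for t in background_trials
        for f in t.facilities
    ]
    n_linked = round(spec.linked_fraction * spec.n_articles)
    for i in range(spec.n_articles):
        pmid = f"{20000000 + i}"
        n_auth = rng_a.randint(1, 8)
        leads = lead_ordinals(n_auth)
        linked_to: Trial | None = None
        if i < n_linked and background_trials:
            linked_to = background_trials[i % len(background_trials)]
        authors = []
        for ordinal in range(1, n_auth + 1):
            affil = None
            method = None
            key = None
            if ordinal in leads:
                if linked_to is not None:
                    fac = linked_to.facilities[
                        leads.index(ordinal) % len(linked_to.facilities)
                    ]
                    affil = f"Clinical Unit, {fac.city}, {fac.country}"
                    method = "CITY_COUNTRY"
                else:
                    style = rng_a.random()
                    if style < 0.35 and background_facilities:
                        fname, fcity, fcountry = rng_a.choice(background_facilities)
                        affil = f"{fname}, {fcity} {rng_a.randrange(10000, 99999)}, {fcountry}"
                        method = "FACILITY"
                    elif style < 0.7 or not ambiguous:
                        cname, cc = rng_a.choice(background_cities)
                        affil = f"Research Institute, {cname}, {_country_name(cc)}"
                        method = "CITY_COUNTRY"
                    else:
                        cname, _best_cc = rng_a.choice(ambiguous)
                        affil = f"Laboratory of Biology, {cname}"
                        method = "CITY_POPULATION"
                if affil is not None and method is not None:
                    expected_methods.append(
                        {"pmid": pmid, "ordinal": ordinal, "affiliation": affil,
                         "method": method, "node_key": None}
                    )
            authors.append(Author(person(rng_a), ordinal, affil))
        articles.append(
            Article(
                pmid=pmid,
                title=f"Background article {i + 1}",
                mesh_terms=rng_a.sample(background_terms, min(2, len(background_terms))),
                authors=authors,
                pub_date=_dt.date(2012, 1, 1) + _dt.timedelta(days=rng_a.randrange(0, 3000)),
                linked_nct_ids=[linked_to.nct_id] if linked_to is not None else [],
            )
        )
        if linked_to is not None:
            linked_pairs.append({"pmid": pmid, "nct_id": linked_to.nct_id})

    # ---- write everything ------------------------------------------------
    (out / "gazetteer.tsv").write_text("\n".join(gaz_rows) + "\n", encoding="utf-8")
    (out / "concepts.psv").write_text("\n".join(concept_lines) + "\n", encoding="utf-8")
    write_trials(trials, str(out / "trials.xml"))
    write_articles(articles, str(out / "articles.xml"))

    truth = GroundTruth(
        expected_nodes=expected_nodes,
        expected_edges=[
            {"endpoints": sorted(pair), "supports": sorted(refs)}
            for pair, refs in sorted(
                expected_edges.items(), key=lambda kv: sorted(kv[0])
            )
        ],
        expected_methods=expected_methods,
        term_cuis=term_cuis,
        planted_trial_ids=planted_trial_ids,
        planted_article_ids=planted_article_ids,
        linked_pairs=linked_pairs,
        planted_cui=planted_cui,
    )
    (out / "ground_truth.json").write_text(truth.to_json() + "\n", encoding="utf-8")

    return GeneratedCorpus(
        out_dir=out,
        trials=parse_trials(str(out / "trials.xml")),
        articles=parse_articles(str(out / "articles.xml")),
        gazetteer=load_gazetteer(str(out / "gazetteer.tsv")),
        index=load_concept_table(str(out / "concepts.psv")),
        truth=truth,
    )


# ---------------------------------------------------------------------------
# Bundled worked-example mini-fixture


@dataclass
class WorkedExamples:
    """The static bundled mini-corpus with the canonical worked examples.

    Contains the multilingual myocardial-infarction synonym group, the
    Hemophilia A/B autosuggest pair, a University-of-Leeds-style trial
    facility, and an ambiguous Springfield pair for the population
    fallback.
    """

    trials: list[Trial]
    articles: list[Article]
    gazetteer: Gazetteer
    index: ConceptIndex

    @property
    def facility_index(self) -> FacilityIndex:
        return build_facility_index(self.trials)

    @property
    def context(self) -> GeocoderContext:
        return GeocoderContext(self.gazetteer, self.facility_index)


def paper_worked_examples() -> WorkedExamples:
    """Load the in-repo mini-fixture used by examples, docs and the CLI."""
    pkg = resources.files("studynet.data")
    with (pkg / "trials_mini.xml").open("rb") as fh:
        trials = parse_trials(fh)
    with (pkg / "articles_mini.xml").open("rb") as fh:
        articles = parse_articles(fh)
    with (pkg / "gazetteer_mini.tsv").open("r", encoding="utf-8") as fh:
        gaz = load_gazetteer(fh)
    with (pkg / "concepts_mini.psv").open("r", encoding="utf-8") as fh:
        index = load_concept_table(fh)
    return WorkedExamples(trials, articles, gaz, index)
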