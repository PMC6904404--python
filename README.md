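# studynet

Offline geospatial mining of clinical-trial registries and biomedical
literature: multilingual disease-term normalization, gazetteer geocoding of
study sites and author affiliations, and construction of geolocated
research-network graphs with great-circle perimeter search.

## Who this is for

Two groups routinely need a *map view* of clinical research that registry
search engines do not provide. Patients and clinicians want suitable trials
near a place of residence ("studies within 200 km of here"). Researchers
forming or extending collaborations want to see which sites have worked
together on a condition. Both views require linking trial records and
publications to geographic coordinates, which the source databases do not
carry. `studynet` implements that linkage as a self-contained, fully
testable Python library: no web services, no live downloads — real exports
load unchanged, and a seeded synthetic-corpus generator provides
format-identical data with planted ground truth.

## The model

**Concept layer.** Disease terms in five languages (ENG, SPA, FRE, GER, ITA)
are loaded from a pipe-delimited concept table (`CUI|LAT|SAB|CODE|STR|ISPREF`,
in the style of the UMLS concept-names file). A CUI groups synonymous surface
forms across languages, so *heart attack*, *Herzinfarkt* and *ataque al
corazón* all resolve to one concept; the attached MeSH descriptor is the key
that matches trial condition terms and article MeSH headings. Autosuggestion
is exact-prefix over normalized forms (diacritics stripped, casefolded),
served from a sorted-array index.

**Geocoding cascade.** Structured trial facilities geocode by city + country
against a geonames-style gazetteer. Unstructured author affiliations pass
through a descending-priority cascade:

1. **FACILITY** — a phrase matches a facility name known from the trial
   corpus (e.g. *University of Leeds* → Leeds);
2. **CITY_COUNTRY** — a phrase matches a gazetteer city and another phrase
   names that city's country;
3. **CITY_POPULATION** — among same-named candidate cities with no country
   evidence, the most populous wins.

**Network layer.** A research network is an undirected graph. A node is a
study site, identified by (normalized city, country) — all facilities of one
city share a node. An edge records co-participation of two sites in one
study, so every study with *k* distinct sites induces a *k*-clique with
*k·(k−1)/2* edges. Articles contribute through the affiliations of their
**lead authors** (the first two and last two of the author list). Merging
trial and article networks deduplicates via the NCT accession numbers in
article records: an article reporting a registered trial re-attributes its
sites to the trial instead of counting as a second study. Perimeter filters
use the haversine great-circle distance on a sphere of radius 6371.0088 km.

## Worked example

```bash
python examples/02_geocode_affiliations.py
```

```
Institute of Cardiology, University of Leeds, Leeds LS184AB, United Kingdom
  -> FACILITY         Leeds (53.7965, -1.5478) country=GB

Dept. of Medicine, Springfield, United States
  -> CITY_COUNTRY     Springfield (39.8017, -89.6437) country=US

Laboratory of Medicine, Springfield
  -> CITY_POPULATION  Springfield (39.8017, -89.6437) country=US
```

Each line shows which cascade step fired: a known facility name wins
outright; an ambiguous city is settled by a country phrase when present, and
by population otherwise (the 167,000-inhabitant US Springfield beats the
5,000-inhabitant Australian one). Likewise:

```bash
python examples/03_research_network.py
```

```
trial alone:
  3 site nodes, 3 collaboration edges
...
trial + its linked article (PMID 31000001):
  3 nodes, 3 edges, study refs = ['TRIAL:NCT01234567']
  same topology as trial alone: True
```

The trial's three sites form a triangle; adding the article linked to it by
accession number changes nothing — deduplication recognised it as the same
study. `examples/01_multilingual_concepts.py` and
`examples/04_radius_search.py` cover concept resolution/autosuggestion and
the 200-km perimeter search over a generated corpus.

A thin CLI mirrors the library (`studynet ingest | suggest | locate |
search | network | fixtures-generate`), emitting JSON on stdout and
optional GeoJSON/GraphML files.

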