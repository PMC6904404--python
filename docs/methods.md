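# Methods

## Data model and procedure

`studynet` links three record types through two lookup structures.

Trial records (a documented subset of the ClinicalTrials.gov legacy
full-study XML) carry an NCT identifier, condition terms, and facilities
with city/ZIP/country. Citation records (a subset of PubMed XML) carry a
PMID, MeSH headings, an ordered author list with raw affiliation strings,
and data-bank accession numbers; accessions matching `NCT` + 8 digits are
the only carrier of article→trial linkage — free-text NCT mentions in
abstracts are not mined, since only the structured field is reliable enough
for deduplication. Unknown XML elements are ignored so real exports load
unchanged. Registry dates mix granularities; they parse permissively
("May 2016" → 2016-05-01, "2016" → 2016-01-01) to give time-range filtering
a total order.

The **concept index** maps normalized surface strings to CUIs and CUIs to
their full synonym sets with MeSH descriptors. Normalization is NFKD
decomposition, diacritic stripping, casefolding and whitespace collapse —
chosen because cross-language entry ("ataque al corazón") makes accent
handling unavoidable; it is idempotent and shared by every matching path in
the package. Record matching against a queried concept accepts any synonym
in any supported language *or* descriptor-id equality, maximizing recall of
semantically equivalent records; English-only matching would be a strict
subset and can be emulated via `expand_cui(..., languages={"ENG"})`.

The **gazetteer** indexes every surface form (name, ASCII name, alternates)
of each populated place. The affiliation cascade tokenizes on commas and
semicolons, strips trailing tokens containing digits (postal codes), then
tries: known facility name → city-with-country-evidence → most populous
same-named city. Country evidence is an ISO alpha-2 code or an English/common
country name from a small built-in table; the gazetteer dialect itself has no
country-name rows to draw on. Facility matching is exact on normalized names,
not fuzzy: fuzzy matching would need similarity thresholds for which there is
no principled setting here, and a miss falls through to the city-based
priorities rather than failing. When two different cities both carry country
evidence, the first in reading order wins (affiliations conventionally lead
with the authors' own institution). Population ties break by ascending
gazetteer id; both tie-breaks exist purely for determinism.

**Networks.** Node identity is (normalized city, country), not facility: a
map shows one selectable marker per city, and facility names are retained as
node labels. Edges are undirected and unweighted with a support set of study
references; multiplicity is recoverable as the support count. Studies never
create cross-study edges — connectivity between studies arises only through
shared site nodes. Merging re-attributes any article whose linked NCT ids
intersect the trial references present in *either* input; computing the
remap against the union makes the merge commutative and idempotent, which
the tests exploit as an oracle. Per-study subnetworks restrict node studies
and edge supports to the selected reference and are complete graphs by
construction. Geocoding failures never raise: they accumulate in a coverage
report (unresolved facilities/affiliations, undated-excluded, dropped by
radius), because a miss reflects an information gap in the source record,
not a pipeline error.

**Search pipeline.** Concept match (ANY/ALL logic; ANY default — users add
related conditions like Hemophilia A *and* B, which only makes sense
disjunctively) → date filter (trials by start date, articles by publication
date; undated records are excluded only when a range is active, and counted)
→ network build and merge → radius filter. Distances use haversine on a
sphere of mean radius **6371.0088 km**; city-scale perimeter queries do not
need ellipsoidal precision, and the fixed documented constant makes results
exactly reproducible (antipodal distance π·6371.0088 ≈ 20015.09 km). The
radius applies to node locations after network construction; an edge losing
an endpoint is pruned even if its other endpoint survives, since a
perimeter view has nowhere to draw it. The boundary is inclusive.

## Synthetic corpora

The generator emits the four dialects plus a ground-truth JSON sidecar as a
pure function of (seed, spec); each artifact type draws from its own
pseudo-random stream derived from the master seed, so growing one corpus
never perturbs another. Defaults: 20 background trials (1–4 facilities
each), 20 background articles (1–8 authors), a 50-entry gazetteer with 5
ambiguous city-name pairs, 30 background disease concepts in all five
languages, and 30% of background articles linked to a generated trial —
small enough to generate in milliseconds, large enough that cliques,
ambiguity and dedup all occur. Ambiguous names receive distinct populations
with a unique maximum so the population rule has a well-defined expected
answer. The exemplar synonym groups (myocardial infarction across five
languages; Hemophilia/A/B as distinct concepts) are always present. Planted
study cliques reference planted cities with fixed coordinates, which is what
makes radius-separation experiments exact.

What the generator does **not** emulate: realistic spelling noise or
abbreviations in affiliation strings (real MEDLINE affiliations are far
messier), facility-name variants, missing/partial addresses beyond simple
absence, realistic trial-size or authorship distributions, and gazetteer
scale (thousands, not millions, of places). Passing tests therefore certify
the *rules* — cascade priorities, clique/dedup semantics, filter
correctness — on clean structured inputs, not recall on noisy real-world
text. Quantities like the expected-method accuracy are properties of the
planted conditions, not estimates of real-data performance.

## Numerical and degenerate-input choices

- Haversine is used over the spherical law of cosines as the primary
  formula for its stability at small angles; the law of cosines serves as
  the independent cross-check away from antipodes.
- Lead authors are the first two plus last two ordinals; with ≤ 4 authors
  the windows overlap and every author is a lead author. Zero authors yield
  an empty result, a single-site study yields a 1-node, 0-edge network, and
  an unknown study reference yields an empty subnetwork — none are errors.
- Suggestion ranking is preferred-flag, then term length, then
  lexicographic normalized form (language and CUI as final tie-breaks):
  deterministic and test-stable where a relevance engine would be neither.
  Prefixes shorter than two normalized characters are rejected as
  meaningless.
- Facility-name collisions in the index keep the first-ingested city and
  log a warning, mirroring registry behaviour of treating the name as a key.
- ZIP codes are carried through parsing and the facility index but are
  never a matching key; the cascade has no postal step.

## Problem sizes

The test suite and acceptance script size their corpora for exhaustive
checking: 200 trials + 200 articles for the quantified clique invariant,
20 independent corpora for merge algebra, 1,000 randomized ambiguous
geocoding cases against a brute-force scan, and 10,000 random point pairs
for the distance cross-check. The whole suite runs in a few seconds.

## Known limitations

- No fuzzy facility matching and no street-level geocoding; a facility
  whose name is spelled differently in an affiliation resolves through the
  city priorities instead.
- The built-in country-name table covers 35 countries; affiliations naming
  a country outside it fall back from priority 2 to priority 3.
- Concept equivalence is strictly CUI-level: no ontology hierarchy
  traversal or relation expansion.
- No relevance ranking, recruitment-status/phase filters, centrality
  analytics or temporal network evolution.
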