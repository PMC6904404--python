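import pytest

from studynet.fixtures import (
    FixtureSpec,
    PlantedCity,
    PlantedNetwork,
    generate,
    paper_worked_examples,
)

# Five planted cities: three clustered around Berlin (within ~60 km of the
# center used in perimeter tests) and two near Madrid (~1800 km away), so a
# 200-km perimeter cleanly separates the planted cliques.
PLANTED_CITIES = (
    PlantedCity("Avalon", "DE", 52.40, 13.10),
    PlantedCity("Brighthelm", "DE", 52.60, 13.60),
    PlantedCity("Corwen", "DE", 52.30, 13.90),
    PlantedCity("Dunwick", "ES", 40.40, -3.70),
    PlantedCity("Eastmere", "ES", 41.00, -3.20),
)

STANDARD_SPEC = FixtureSpec(
    seed=7,
    planted_cities=PLANTED_CITIES,
    planted_networks=(
        PlantedNetwork("TRIAL", ("Avalon", "Brighthelm", "Corwen")),
        PlantedNetwork("ARTICLE", ("Avalon", "Brighthelm")),
        PlantedNetwork("TRIAL", ("Dunwick", "Eastmere")),
    ),
)


@pytest.fixture(scope="session")
def worked():
    """The bundled mini-corpus with the canonical worked examples."""
    return paper_worked_examples()


@pytest.fixture(scope="session")
def corpus(tmp_path_factory):
    """Standard seeded corpus with planted in/out-of-radius cliques."""
    return generate(STANDARD_SPEC, tmp_path_factory.mktemp("corpus"))


@pytest.fixture(scope="session")
def big_corpus(tmp_path_factory):
    """A larger corpus for quantified invariants (200 trials, 200 articles)."""
    spec = FixtureSpec(
        seed=11,
        n_trials=200,
        n_articles=200,
        n_cities=120,
        n_ambiguous_city_names=10,
        linked_fraction=0.25,
    )
    return generate(spec, tmp_path_factory.mktemp("big"))
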