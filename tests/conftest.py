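import pytest

from taxonym.fixtures import FixtureSpec, generate_reference
from taxonym.reference import flatten_synonym_chains


@pytest.fixture(scope="session")
def rich_spec():
    return FixtureSpec(
        n_genera=12,
        species_per_genus=(3, 7),
        synonym_fraction=0.35,
        chain_fraction=0.25,
        infraspecific_fraction=0.2,
        hybrid_fraction=0.08,
        unresolved_fraction=0.08,
        homonym_pairs=2,
        seed=11,
    )


@pytest.fixture(scope="session")
def rich_fixture(rich_spec):
    return generate_reference(rich_spec)


@pytest.fixture(scope="session")
def rich_table(rich_fixture):
    return rich_fixture[0]


@pytest.fixture(scope="session")
def flat_table(rich_table):
    return flatten_synonym_chains(rich_table)


@pytest.fixture(scope="session")
def clean_fixture():
    """No homonyms, no defects: safe for recovery experiments."""
    spec = FixtureSpec(
        n_genera=10,
        species_per_genus=(3, 6),
        synonym_fraction=0.3,
        infraspecific_fraction=0.15,
        hybrid_fraction=0.05,
        seed=5,
    )
    table, truth = generate_reference(spec)
    return flatten_synonym_chains(table), truth
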