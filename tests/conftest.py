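import pytest

from epitopatch import fixtures
from epitopatch.structure import AntigenStructure, Atom, Residue, ResidueId


@pytest.fixture(scope="session")
def helix_fixture():
    return fixtures.generate_structure(
        fixtures.FixtureSpec(seed=7, geometry="helix", n_residues=30))


@pytest.fixture(scope="session")
def globule_fixture():
    return fixtures.generate_structure(
        fixtures.FixtureSpec(seed=5, geometry="globule", n_residues=64))


@pytest.fixture(scope="session")
def two_chain_fixture():
    return fixtures.generate_structure(
        fixtures.FixtureSpec(seed=9, geometry="two_chain", n_residues=24))


@pytest.fixture(scope="session")
def small_corpus():
    """Four annotated targets with the planted epitope signal."""
    return fixtures.generate_training_corpus(4, seed=21)


@pytest.fixture(scope="session")
def small_prepared(small_corpus):
    return [fixtures.as_prepared_target(t) for t in small_corpus]


def random_point_structure(rng, n_residues, spread=25.0) -> AntigenStructure:
    """Bare point-cloud structure for geometric oracles: each residue gets a
    CA and a CB at random coordinates (no meaningful backbone)."""
    residues = []
    for i in range(n_residues):
        ca = rng.uniform(0, spread, 3)
        cb = ca + rng.normal(0, 1.0, 3)
        residues.append(Residue(
            ResidueId("A", i + 1),
            "ALA",
            [Atom("CA", "C", tuple(ca)), Atom("CB", "C", tuple(cb))],
        ))
    return AntigenStructure(residues)
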