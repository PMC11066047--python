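import numpy as np
import pytest

from xlorg import structure_map, synthetic


@pytest.fixture(scope="session")
def small_complex():
    """Three single-copy proteins, seeded; used wherever copy ambiguity
    is irrelevant."""
    return synthetic.make_complex(n_proteins=3, copies=1, n_residues=150, seed=101)


@pytest.fixture(scope="session")
def dimer_complex():
    """One homodimer plus a single-copy partner, for ambiguity-rule tests."""
    return synthetic.make_complex(
        n_proteins=2, copies={"SYN001": 2, "SYN002": 1}, n_residues=150, seed=102
    )


@pytest.fixture(scope="session")
def small_assignment(small_complex):
    return structure_map.build_chain_assignment(
        small_complex.structure, small_complex.sequences, min_identity=0.99
    )


@pytest.fixture(scope="session")
def dimer_assignment(dimer_complex):
    return structure_map.build_chain_assignment(
        dimer_complex.structure, dimer_complex.sequences, min_identity=0.99
    )


@pytest.fixture(scope="session")
def planted_links(small_complex):
    """40 restraint-satisfying + 10 violating + 5 decoy links."""
    return synthetic.sample_crosslinks(
        small_complex, n_satisfying=40, n_violating=10,
        n_decoy_protein_pairs=5, seed=103,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
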