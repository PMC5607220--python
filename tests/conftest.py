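"""Shared fixtures: worked-example DAGs and small simulated datasets.

The two policy-example DAGs are synthetic reconstructions assembled from
their published class-pattern facts (the original drawings are not
machine-readable); every stated fact about them is asserted in the tests
that use them.
"""

import numpy as np
import pytest

from genie_dag import Dag


@pytest.fixture(scope="session")
def chain3() -> Dag:
    """a -> b -> c -> R: the minimal linear pathway."""
    return Dag(("a", "b", "c"), [("a", "b"), ("b", "c"), ("c", "R")])


@pytest.fixture(scope="session")
def optional_edge_dag() -> Dag:
    """Synthetic reconstruction of the optional-edge worked example.

    g1 heads a linear chain g2 -> g3 -> g4 -> g5 and owns a bypass edge
    straight to g5, so g1 is partially upstream (class 4) of g2, g3, g4
    and linearly upstream (class 1) of g5.  The bypass makes direct edges
    g1 -> g3 and g1 -> g4 optional: adding them would not change the class
    pattern, and the sparse policy must not emit them.
    """
    genes = tuple(f"g{n}" for n in range(1, 6))
    edges = [("g1", "g2"), ("g2", "g3"), ("g3", "g4"), ("g4", "g5"),
             ("g1", "g5"), ("g5", "R")]
    return Dag(genes, edges)


@pytest.fixture(scope="session")
def reporter_edge_dag() -> Dag:
    """Synthetic reconstruction of the reporter-edge worked example.

    g3 carries a direct reporter edge (necessary: its only class-4 partner
    set is {g4}, with no independent pair inside), while g1's reporter
    edge is optional because g1 is class 4 with every other gene and two
    of those partners (g5 and anything in the chain) are mutually
    independent.
    """
    genes = tuple(f"g{n}" for n in range(1, 6))
    edges = [("g1", "g2"), ("g1", "g5"), ("g1", "R"),
             ("g2", "g3"), ("g3", "g4"), ("g3", "R"),
             ("g4", "R"), ("g5", "R")]
    return Dag(genes, edges)


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20260929)
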