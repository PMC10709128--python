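import numpy as np
import pytest

from srdkit.graph import build_graph
from srdkit.synth import (
    BRANCHED,
    MULTI,
    PathwayGenSpec,
    generate_pathway,
    toy_enzyme_neighborhood,
)


@pytest.fixture(scope="session")
def toy_doc():
    """One enzyme's reaction neighborhood: reactants at 0, then 1, then 2."""
    return toy_enzyme_neighborhood()


@pytest.fixture(scope="session")
def toy_graph(toy_doc):
    return build_graph(toy_doc)


@pytest.fixture(scope="session")
def branched_pathway():
    """A connected random branched pathway with oracle truth."""
    return generate_pathway(
        PathwayGenSpec(n_compounds=40, n_reactions=55, n_genes=15, topology=BRANCHED, seed=11)
    )


@pytest.fixture(scope="session")
def split_pathway():
    """A multi-component pathway (guaranteed infinite SRDs across parts)."""
    return generate_pathway(
        PathwayGenSpec(n_compounds=24, n_reactions=21, n_genes=8, topology=MULTI, seed=5)
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
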