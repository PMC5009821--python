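import pytest

from gosimnet import FixtureSpec, random_ontology, toy1
from gosimnet.annotations import build_corpus

import numpy as np


@pytest.fixture(scope="session")
def toy():
    """The frozen 7-term / 8-gene hand-checkable fixture."""
    return toy1()


@pytest.fixture(scope="session")
def toy_dag(toy):
    return toy[0]


@pytest.fixture(scope="session")
def toy_corpus(toy):
    return toy[1]


def make_random_corpus(seed: int, n_terms: int = 20, n_genes: int = 12):
    """A seeded random DAG plus a corpus annotating genes to random terms."""
    spec = FixtureSpec(n_terms=n_terms, max_parents=3, seed=seed)
    dag = random_ontology(spec)
    rng = np.random.default_rng(seed + 1000)
    terms = sorted(dag.terms)
    direct = {
        f"g{i}": {terms[int(j)] for j in rng.integers(0, len(terms), size=3)}
        for i in range(n_genes)
    }
    return dag, build_corpus(dag, direct)
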