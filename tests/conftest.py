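import numpy as np
import pytest

from ppinet import domains, interolog, knn_filter
from ppinet.synthetic import generate_universe

# parameters of the packaged demo universe used across the suite
DEMO = dict(n_proteins=200, n_domains=60, n_ddi_rules=30, noise_rate=0.1)


@pytest.fixture(scope="session")
def universe():
    return generate_universe(seed=42, **DEMO)


@pytest.fixture(scope="session")
def architectures(universe):
    return {
        p: domains.DomainArchitecture(p, d)
        for p, d in universe.architectures.items()
    }


@pytest.fixture(scope="session")
def ref_architectures(universe):
    return {
        p: domains.DomainArchitecture(p, d)
        for p, d in universe.ref_architectures.items()
    }


@pytest.fixture(scope="session")
def dc_table(universe, ref_architectures):
    return domains.build_score_table(universe.ref_ppis, ref_architectures)


@pytest.fixture(scope="session")
def ortho_map(universe):
    return interolog.build_ortholog_map(universe.ortholog_rows)


@pytest.fixture(scope="session")
def featurizer(universe, ortho_map, architectures, dc_table):
    return knn_filter.PairFeaturizer(
        ortho_map,
        universe.ref_ppis,
        architectures,
        dc_table,
        expression=universe.expression,
        annotations=universe.annotations,
        ontology=universe.ontology,
    )


@pytest.fixture(scope="session")
def projected_positives(universe):
    """Reference PPIs projected into target space (the KNN positive set)."""
    positives = set()
    for organism, edges in universe.ref_ppis.items():
        prefix = organism + "_"
        for ra, rb in edges:
            positives.add(
                interolog.canonical_pair(
                    ra.removeprefix(prefix), rb.removeprefix(prefix)
                )
            )
    return sorted(positives)


@pytest.fixture(scope="session")
def training_splits(universe, featurizer, projected_positives):
    return knn_filter.build_training_splits(
        projected_positives, universe.proteins, featurizer,
        universe.expression, seed=42,
    )


def random_nonedges(universe, n, seed):
    """Uniformly sampled unordered pairs not in the planted true edges."""
    rng = np.random.default_rng(seed)
    out = set()
    while len(out) < n:
        a, b = rng.choice(universe.proteins, size=2, replace=False)
        pair = interolog.canonical_pair(str(a), str(b))
        if pair not in universe.true_edges:
            out.add(pair)
    return sorted(out)


def degree_matched_nonedges(universe, n, seed):
    """Non-edges whose endpoints are drawn degree-proportionally
    (one endpoint from each of two random true edges)."""
    rng = np.random.default_rng(seed)
    edges = sorted(universe.true_edges.edges)
    out = set()
    budget = 200 * n
    while len(out) < n and budget > 0:
        budget -= 1
        e1, e2 = rng.integers(len(edges), size=2)
        a = edges[int(e1)][int(rng.integers(2))]
        b = edges[int(e2)][int(rng.integers(2))]
        if a == b:
            continue
        pair = interolog.canonical_pair(a, b)
        if pair not in universe.true_edges:
            out.add(pair)
    return sorted(out)
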