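import numpy as np
import pytest

import ldaeagcn as L


def random_similarity(rng: np.random.Generator, n: int) -> np.ndarray:
    """Random symmetric [0,1] matrix with unit diagonal."""
    m = rng.random((n, n))
    m = (m + m.T) / 2.0
    np.fill_diagonal(m, 1.0)
    return m


def random_tree_edges(rng: np.random.Generator, n: int) -> list[tuple[str, str]]:
    """Random rooted tree over terms t0..t{n-1} (parent index < child index)."""
    return [(f"t{rng.integers(k)}", f"t{k}") for k in range(1, n)]


def random_dag(rng: np.random.Generator, n: int, extra: float = 0.3) -> L.DiseaseDAG:
    """Random tree plus extra forward edges (always acyclic)."""
    edges = set(random_tree_edges(rng, n))
    for _ in range(int(extra * n)):
        a, b = sorted(rng.choice(n, size=2, replace=False))
        if a != b:
            edges.add((f"t{a}", f"t{b}"))
    return L.DiseaseDAG({f"t{k}" for k in range(n)}, edges)


def make_toy_graph(label: int, dense_nomal: bool, n: int = 2, m: int = 2) -> L.PairGraph:
    """Hand-built fixed-shape pair graph; positives carry dense cross edges."""
    size = n + m
    core = np.zeros((size, size, 2))
    core[0, n] = core[n, 0] = (1.0, 1.0)
    nomal = np.zeros((size, size, 2))
    if dense_nomal:
        for i in range(n):
            for j in range(n, size):
                if (i, j) != (0, n):
                    nomal[i, j] = nomal[j, i] = (1.0, 1.0)
    ll = np.zeros((size, size, 2))
    dd = np.zeros((size, size, 2))
    for a in range(n):
        for b in range(n):
            if a != b:
                ll[a, b] = (1.0, 0.5)
    for a in range(n, size):
        for b in range(n, size):
            if a != b:
                dd[a, b] = (1.0, 0.5)
    feats = np.zeros((size, 4))
    feats[:n, 0] = 1.0
    feats[n:, 1] = 1.0
    feats[:, 2] = 0.5
    return L.PairGraph(0, 0, list(range(n)), list(range(m)), core, nomal, ll, dd,
                       node_features=feats, label=label)


@pytest.fixture(scope="session")
def separable_toy() -> list[L.PairGraph]:
    return [make_toy_graph(1, True) for _ in range(10)] + [
        make_toy_graph(0, False) for _ in range(10)
    ]


@pytest.fixture(scope="session")
def random_pair_universe():
    """Small random similarity/association matrices for pair-graph tests."""
    rng = np.random.default_rng(11)
    nl, nd = 15, 12
    llcm = random_similarity(rng, nl)
    ddscm = random_similarity(rng, nd)
    ldcm = (rng.random((nl, nd)) < 0.25).astype(float)
    return llcm, ddscm, ldcm


@pytest.fixture(scope="session")
def smoke_benchmark():
    bench = L.make_benchmark(L.SimulationConfig(seed=1))
    dataset = L.assemble_dataset(bench.table, bench.dag, seed=1)
    return bench, dataset


@pytest.fixture(scope="session")
def smoke_model_config():
    return L.ModelConfig(epochs=60, seed=1)


@pytest.fixture(scope="session")
def small_dataset():
    """A faster benchmark for protocol-shape tests."""
    cfg = L.SimulationConfig(n_terms=40, n_lncrnas=30, n_diseases=20, seed=7)
    bench = L.make_benchmark(cfg)
    dataset = L.assemble_dataset(bench.table, bench.dag, seed=7)
    return bench, dataset


@pytest.fixture(scope="session")
def fast_model_config():
    return L.ModelConfig(epochs=8, seed=3)
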