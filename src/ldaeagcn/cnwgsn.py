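"""Closest-node weight graphs of the spatial neighborhood (per-pair subgraphs).

Each candidate (lncRNA, disease) pair is embedded in a fixed-size graph of
N lncRNA nodes and M disease nodes: the query lncRNA at position 0 followed
by its N-1 most functionally similar lncRNAs, and the query disease at
position N followed by its M-1 most semantically similar diseases.  Four
typed edge tensors of shape (N+M, N+M, 2) describe the graph; channel 0 is
an existence indicator, channel 1 a weight in [0, 1]:

* ``core_att`` — the query edge itself, (1, 1) at (0, N) and (N, 0);
* ``nomal_att`` — known lncRNA-disease associations straddling the blocks,
  excluding the query pair itself (label-leakage mask);
* ``ll_att`` — lncRNA-block similarity edges, (1, LLCM value);
* ``dd_att`` — disease-block similarity edges, (1, DDSCM value).

Node features (F = 4): block indicator pair, similarity to the own-block
query node, and association degree scaled by the global maximum degree.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data_io import logger

DEFAULT_N = 10
DEFAULT_M = 10
EDGE_CATEGORIES = ("core_att", "nomal_att", "ll_att", "dd_att")
N_FEATURES = 4


@dataclass
class PairGraph:
    query_lncrna: int
    query_disease: int
    lnc_nodes: list[int]   # query at position 0
    dis_nodes: list[int]   # query at position len(lnc_nodes)
    core_att: np.ndarray
    nomal_att: np.ndarray
    ll_att: np.ndarray
    dd_att: np.ndarray
    node_features: np.ndarray | None = None
    label: int | None = None
    padded: bool = False

    @property
    def n_nodes(self) -> int:
        return len(self.lnc_nodes) + len(self.dis_nodes)

    def edge_tensor(self, category: str) -> np.ndarray:
        if category not in EDGE_CATEGORIES:
            raise KeyError(f"unknown edge category: {category!r}")
        return getattr(self, category)


def select_neighbors(
    sim_values: np.ndarray, query: int, k: int, pad: bool = True
) -> tuple[list[int], bool]:
    """The k indices most similar to ``query`` (query excluded), descending.

    Ties break by ascending index.  With fewer than k candidates the list is
    padded by repeating the last neighbour (flagged); with padding disabled
    that is an error.
    """
    if k < 1:
        raise ValueError("k must be at least 1")
    sims = np.asarray(sim_values, float)[query]
    candidates = np.array([i for i in range(sims.size) if i != query])
    if candidates.size == 0:
        raise ValueError("no neighbour candidates available")
    order = candidates[np.lexsort((candidates, -sims[candidates]))]
    chosen = list(order[:k])
    padded = False
    if len(chosen) < k:
        if not pad:
            raise ValueError(
                f"requested {k} neighbours but only {len(chosen)} candidates exist"
            )
        padded = True
        chosen += [chosen[-1]] * (k - len(chosen))
    return [int(i) for i in chosen], padded


def build_pair_graph(
    l: int,
    d: int,
    llcm: np.ndarray,
    ddscm: np.ndarray,
    ldcm: np.ndarray,
    n_lnc_nodes: int = DEFAULT_N,
    n_dis_nodes: int = DEFAULT_M,
    label: int | None = None,
    mask_query_edge: bool = True,
    featurize: bool = True,
) -> PairGraph:
    """Assemble the fixed-size pair graph for candidate pair (l, d)."""
    llcm = np.asarray(llcm, float)
    ddscm = np.asarray(ddscm, float)
    ldcm = np.asarray(ldcm, float)
    if n_lnc_nodes < 2 or n_dis_nodes < 2:
        raise ValueError("both node counts must be at least 2")
    if llcm.shape[0] != ldcm.shape[0] or ddscm.shape[0] != ldcm.shape[1]:
        raise ValueError("similarity matrices inconsistent with the association matrix")

    lnc_neigh, pad_l = select_neighbors(llcm, l, n_lnc_nodes - 1)
    dis_neigh, pad_d = select_neighbors(ddscm, d, n_dis_nodes - 1)
    lnc_nodes = [l] + lnc_neigh
    dis_nodes = [d] + dis_neigh
    padded = pad_l or pad_d
    if padded:
        logger.debug("pair graph (%d, %d) padded to (%d, %d) nodes", l, d, n_lnc_nodes, n_dis_nodes)

    n, m = n_lnc_nodes, n_dis_nodes
    size = n + m
    core = np.zeros((size, size, 2))
    nomal = np.zeros((size, size, 2))
    ll = np.zeros((size, size, 2))
    dd = np.zeros((size, size, 2))

    core[0, n] = core[n, 0] = (1.0, 1.0)

    lnc_idx = np.asarray(lnc_nodes)
    dis_idx = np.asarray(dis_nodes)
    ll_vals = llcm[np.ix_(lnc_idx, lnc_idx)]
    dd_vals = ddscm[np.ix_(dis_idx, dis_idx)]
    off_l = ~np.eye(n, dtype=bool)
    off_d = ~np.eye(m, dtype=bool)
    ll[:n, :n, 0][off_l] = 1.0
    ll[:n, :n, 1][off_l] = ll_vals[off_l]
    dd[n:, n:, 0][off_d] = 1.0
    dd[n:, n:, 1][off_d] = dd_vals[off_d]

    assoc = ldcm[np.ix_(lnc_idx, dis_idx)] > 0
    if mask_query_edge:
        assoc = assoc.copy()
        assoc[0, 0] = False  # never encode the query pair's own label
    nomal[:n, n:, 0] = assoc
    nomal[:n, n:, 1] = assoc
    nomal[n:, :n, 0] = assoc.T
    nomal[n:, :n, 1] = assoc.T

    graph = PairGraph(l, d, lnc_nodes, dis_nodes, core, nomal, ll, dd,
                      label=label, padded=padded)
    if featurize:
        featurize_nodes(graph, llcm, ddscm, ldcm)
    return graph


def featurize_nodes(
    graph: PairGraph, llcm: np.ndarray, ddscm: np.ndarray, ldcm: np.ndarray
) -> np.ndarray:
    """Attach the (N+M) x 4 node feature matrix and return it.

    Features: [is_lncRNA, is_disease, similarity to own-block query node,
    association degree / global max degree].
    """
    ldcm = np.asarray(ldcm, float)
    lnc_deg = ldcm.sum(axis=1)
    dis_deg = ldcm.sum(axis=0)
    max_deg = max(lnc_deg.max(initial=0.0), dis_deg.max(initial=0.0))
    scale = max_deg if max_deg > 0 else 1.0

    n = len(graph.lnc_nodes)
    feats = np.zeros((graph.n_nodes, N_FEATURES))
    ql, qd = graph.lnc_nodes[0], graph.dis_nodes[0]
    for pos, li in enumerate(graph.lnc_nodes):
        sim = 1.0 if li == ql else float(np.asarray(llcm)[li, ql])
        feats[pos] = (1.0, 0.0, sim, lnc_deg[li] / scale)
    for pos, dj in enumerate(graph.dis_nodes):
        sim = 1.0 if dj == qd else float(np.asarray(ddscm)[dj, qd])
        feats[n + pos] = (0.0, 1.0, sim, dis_deg[dj] / scale)
    graph.node_features = feats
    return feats
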