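"""Disease semantic similarity and lncRNA functional similarity.

Disease similarity follows the classic hierarchy-based scheme: each disease
``d`` induces the subgraph of its ancestor terms ``Td`` (``d`` included).
Within that subgraph the semantic contribution of a term decays by a factor
``delta`` per parent->child hop, taking the maximum over a term's children
when several paths to ``d`` exist::

    D_d(d) = 1
    D_d(t) = max(delta * D_d(t') for t' in children(t) ∩ Td)   (t != d)

The semantic value DV(d) is the sum of contributions over Td, and the
similarity of two diseases is the shared contribution mass normalised by the
two semantic values::

    DS(A, B) = sum_{t in TA ∩ TB} (D_A(t) + D_B(t)) / (DV(A) + DV(B))

lncRNA functional similarity rests on the premise that functionally similar
lncRNAs associate with semantically similar diseases: for lncRNAs with
associated disease sets DTm and DTn,

    SCORE(Lm, Ln) = [ sum_{d in DTm} max_{d' in DTn} DS(d, d')
                    + sum_{d in DTn} max_{d' in DTm} DS(d, d') ]
                    / (|DTm| + |DTn|)

Conventions for degenerate inputs: an lncRNA with no associated diseases has
SCORE 0 against everything, with its self-similarity forced to 1; a disease
absent from the hierarchy is treated as an isolated term (contributions
``{d: 1}``, DV = 1) with a logged warning.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import networkx as nx
import numpy as np

from .data_io import AssociationTable, DiseaseDAG, logger

DEFAULT_DELTA = 0.5


@dataclass
class SemanticContribution:
    """Per-term contributions D_d(t) over Td and their sum DV(d)."""

    disease: str
    contributions: dict[str, float]
    semantic_value: float


@dataclass
class SimilarityMatrix:
    """Square symmetric similarity matrix over an ordered id list."""

    ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("similarity matrix shape does not match id list")
        if not np.allclose(self.values, self.values.T, atol=1e-9, rtol=0.0):
            raise ValueError("similarity matrix must be symmetric")
        if self.values.min() < -1e-12 or self.values.max() > 1.0 + 1e-12:
            raise ValueError("similarity values must lie in [0, 1]")
        self._index = {i: k for k, i in enumerate(self.ids)}

    def index(self, id_: str) -> int:
        return self._index[id_]

    def value(self, a: str, b: str) -> float:
        return float(self.values[self._index[a], self._index[b]])


def semantic_contribution(
    dag: DiseaseDAG, disease: str, delta: float = DEFAULT_DELTA
) -> SemanticContribution:
    """Contributions of every ancestor term to ``disease`` and their sum DV."""
    if not 0.0 < delta < 1.0:
        raise ValueError("delta must lie strictly between 0 and 1")
    ancestors = dag.ancestors(disease)  # raises KeyError for unknown terms
    sub = dag.graph.subgraph(ancestors)
    contrib: dict[str, float] = {}
    # children must be resolved before their parents: reverse topological order
    for term in reversed(list(nx.topological_sort(sub))):
        if term == disease:
            contrib[term] = 1.0
        else:
            contrib[term] = max(delta * contrib[c] for c in sub.successors(term))
    return SemanticContribution(disease, contrib, float(sum(contrib.values())))


def _isolated_contribution(disease: str) -> SemanticContribution:
    return SemanticContribution(disease, {disease: 1.0}, 1.0)


def disease_semantic_similarity(
    sa: SemanticContribution, sb: SemanticContribution
) -> float:
    """DS(A, B): shared contribution mass over combined semantic value."""
    shared = sa.contributions.keys() & sb.contributions.keys()
    if not shared:
        return 0.0
    num = sum(sa.contributions[t] + sb.contributions[t] for t in shared)
    return num / (sa.semantic_value + sb.semantic_value)


def disease_similarity_matrix(
    dag: DiseaseDAG,
    diseases: Sequence[str],
    delta: float = DEFAULT_DELTA,
    allow_missing: bool = True,
) -> SimilarityMatrix:
    """Pairwise DS over ``diseases``, contributions memoized per disease.

    Diseases not present in the hierarchy are treated as isolated terms when
    ``allow_missing`` (a warning is logged); otherwise they raise ``KeyError``
    before any computation starts.
    """
    missing = [d for d in diseases if d not in dag.terms]
    if missing and not allow_missing:
        raise KeyError(f"diseases absent from the hierarchy: {missing}")
    if missing:
        logger.warning(
            "%d disease(s) absent from the hierarchy treated as isolated terms: %s",
            len(missing), missing[:5],
        )
    contribs = [
        _isolated_contribution(d) if d not in dag.terms else semantic_contribution(dag, d, delta)
        for d in diseases
    ]
    n = len(diseases)
    values = np.eye(n)
    for a in range(n):
        for b in range(a + 1, n):
            values[a, b] = values[b, a] = disease_semantic_similarity(contribs[a], contribs[b])
    return SimilarityMatrix(list(diseases), values)


def lncrna_functional_similarity(
    dtm: Iterable[int], dtn: Iterable[int], ddscm: SimilarityMatrix
) -> float:
    """SCORE of two lncRNAs from their associated disease index sets.

    Either set empty -> 0 (avoids the 0/0 of the defining ratio).
    """
    dtm, dtn = sorted(set(dtm)), sorted(set(dtn))
    if not dtm or not dtn:
        return 0.0
    block = ddscm.values[np.ix_(dtm, dtn)]
    score = block.max(axis=1).sum() + block.max(axis=0).sum()
    return float(score / (len(dtm) + len(dtn)))


def lncrna_similarity_matrix(
    table: AssociationTable, ddscm: SimilarityMatrix
) -> SimilarityMatrix:
    """Pairwise SCORE over the table's lncRNA ordering.

    The diagonal is forced to 1 for every lncRNA, including those with no
    associations (self-similarity by convention); rows of association-free
    lncRNAs are otherwise all zero.
    """
    if ddscm.ids != list(table.disease_ids):
        raise ValueError("disease similarity matrix ordering must match the association table")
    sets = [sorted(table.disease_set(i)) for i in range(table.n_lncrnas)]
    n = table.n_lncrnas
    values = np.eye(n)
    for a in range(n):
        for b in range(a + 1, n):
            values[a, b] = values[b, a] = lncrna_functional_similarity(
                sets[a], sets[b], ddscm
            )
    return SimilarityMatrix(list(table.lncrna_ids), values)
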