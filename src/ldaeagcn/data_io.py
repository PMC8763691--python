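"""Loading, normalisation and serialisation of the pipeline's inputs.

Three plain-text formats are understood:

* association TSV — ``lncRNA_id<TAB>disease_id`` per line, optional
  ``lncRNA<TAB>disease`` header;
* disease-hierarchy TSV — ``parent_id<TAB>child_id`` edge list; a
  single-column line declares an isolated term;
* similarity TSV — square numeric matrix with an id header row and an id
  first column.

Identifiers are normalised by trimming and collapsing internal whitespace;
case is preserved (disease vocabularies are case-significant).  An optional
synonym map can be applied before de-duplication to emulate a controlled
vocabulary's name standardisation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

logger = logging.getLogger("ldaeagcn")

SYMMETRY_TOL = 1e-9


def normalize_id(raw: str) -> str:
    """Trim and collapse internal whitespace runs; case is preserved."""
    return " ".join(raw.split())


@dataclass
class AssociationTable:
    """The curated lncRNA / disease id universe plus the known pairs.

    ``pairs`` holds (lncRNA index, disease index) tuples into the two ordered
    id lists; ordering is first appearance in the source file, which makes
    every downstream matrix reproducible without sorting assumptions.
    """

    lncrna_ids: list[str]
    disease_ids: list[str]
    pairs: set[tuple[int, int]]

    def __post_init__(self) -> None:
        if not self.lncrna_ids or not self.disease_ids:
            raise ValueError("association table needs at least one lncRNA and one disease")
        if len(set(self.lncrna_ids)) != len(self.lncrna_ids):
            raise ValueError("duplicate lncRNA ids after normalization")
        if len(set(self.disease_ids)) != len(self.disease_ids):
            raise ValueError("duplicate disease ids after normalization")
        nl, nd = len(self.lncrna_ids), len(self.disease_ids)
        for i, j in self.pairs:
            if not (0 <= i < nl and 0 <= j < nd):
                raise ValueError(f"pair index out of bounds: {(i, j)}")

    @property
    def n_lncrnas(self) -> int:
        return len(self.lncrna_ids)

    @property
    def n_diseases(self) -> int:
        return len(self.disease_ids)

    def disease_set(self, lncrna_index: int) -> set[int]:
        """Indices of diseases associated with one lncRNA."""
        return {j for i, j in self.pairs if i == lncrna_index}

    @classmethod
    def from_records(
        cls,
        records: Iterable[tuple[str, str]],
        synonym_map: Mapping[str, str] | None = None,
        normalize: bool = True,
    ) -> "AssociationTable":
        lnc_index: dict[str, int] = {}
        dis_index: dict[str, int] = {}
        pairs: set[tuple[int, int]] = set()
        for lnc, dis in records:
            if normalize:
                lnc, dis = normalize_id(lnc), normalize_id(dis)
            if synonym_map:
                lnc = synonym_map.get(lnc, lnc)
                dis = synonym_map.get(dis, dis)
            if lnc not in lnc_index:
                lnc_index[lnc] = len(lnc_index)
            if dis not in dis_index:
                dis_index[dis] = len(dis_index)
            pairs.add((lnc_index[lnc], dis_index[dis]))
        return cls(list(lnc_index), list(dis_index), pairs)


@dataclass
class CorrelationMatrix:
    """Binary lncRNA x disease correlation matrix (1 iff pair is known)."""

    values: np.ndarray
    row_ids: list[str]
    col_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.row_ids), len(self.col_ids)):
            raise ValueError("correlation matrix shape does not match id lists")
        if not np.isin(self.values, (0.0, 1.0)).all():
            raise ValueError("correlation matrix entries must be 0 or 1")


@dataclass
class DiseaseDAG:
    """Disease-term hierarchy: directed edges run parent -> child."""

    terms: set[str]
    edges: set[tuple[str, str]]
    _graph: nx.DiGraph = field(init=False, repr=False)

    def __post_init__(self) -> None:
        g = nx.DiGraph()
        g.add_nodes_from(self.terms)
        for parent, child in self.edges:
            if parent not in self.terms or child not in self.terms:
                raise ValueError(f"edge endpoint not a known term: {(parent, child)}")
            g.add_edge(parent, child)
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            raise ValueError(f"disease hierarchy contains a cycle: {cycle}")
        self._graph = g

    @property
    def graph(self) -> nx.DiGraph:
        return self._graph

    def ancestors(self, term: str) -> set[str]:
        """All ancestors of ``term`` plus the term itself."""
        if term not in self.terms:
            raise KeyError(f"unknown disease term: {term!r}")
        return nx.ancestors(self._graph, term) | {term}

    def children(self, term: str) -> set[str]:
        return set(self._graph.successors(term))


def load_associations(
    path: str | Path,
    normalize: bool = True,
    synonym_map: Mapping[str, str] | None = None,
) -> AssociationTable:
    """Read an association TSV, normalise ids and collapse duplicate rows.

    The first line is treated as a header when its first tab field equals
    the literal token ``lncRNA`` (case-insensitive).
    """
    path = Path(path)
    records: list[tuple[str, str]] = []
    with path.open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ValueError(
                    f"{path}:{lineno}: expected 2 tab-separated columns, got {len(fields)}"
                )
            if lineno == 1 and fields[0].strip().lower() == "lncrna":
                continue
            records.append((fields[0], fields[1]))
    if not records:
        raise ValueError(f"{path}: no association records found")
    return AssociationTable.from_records(records, synonym_map=synonym_map, normalize=normalize)


def build_ldcm(table: AssociationTable) -> CorrelationMatrix:
    """Binary correlation matrix: entry (i, j) = 1 iff lncRNA i is associated with disease j."""
    values = np.zeros((table.n_lncrnas, table.n_diseases))
    for i, j in table.pairs:
        values[i, j] = 1.0
    return CorrelationMatrix(values, list(table.lncrna_ids), list(table.disease_ids))


def load_disease_dag(path: str | Path) -> DiseaseDAG:
    """Read a parent->child TSV edge list; single-column lines declare isolated terms."""
    path = Path(path)
    terms: set[str] = set()
    edges: set[tuple[str, str]] = set()
    with path.open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = [normalize_id(f) for f in line.split("\t") if f.strip()]
            if len(fields) == 1:
                terms.add(fields[0])
            elif len(fields) == 2:
                terms.update(fields)
                edges.add((fields[0], fields[1]))
            else:
                raise ValueError(f"{path}:{lineno}: expected 1 or 2 columns, got {len(fields)}")
    return DiseaseDAG(terms, edges)


def write_similarity(matrix, path: str | Path) -> None:
    """Write a similarity matrix as TSV with id header row and id first column."""
    path = Path(path)
    vals = np.asarray(matrix.values)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("\t" + "\t".join(matrix.ids) + "\n")
        for i, rid in enumerate(matrix.ids):
            row = "\t".join(repr(float(v)) for v in vals[i])
            fh.write(f"{rid}\t{row}\n")


def read_similarity(path: str | Path):
    """Read a similarity TSV; rejects non-square or asymmetric matrices."""
    from .similarity import SimilarityMatrix

    path = Path(path)
    with path.open(encoding="utf-8") as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        raise ValueError(f"{path}: empty similarity file")
    ids = lines[0].split("\t")[1:]
    rows = []
    for ln in lines[1:]:
        fields = ln.split("\t")
        rows.append([float(v) for v in fields[1:]])
    values = np.asarray(rows, dtype=float)
    if values.shape != (len(ids), len(ids)):
        raise ValueError(f"{path}: similarity matrix is not square")
    if not np.allclose(values, values.T, atol=SYMMETRY_TOL, rtol=0.0):
        raise ValueError(f"{path}: similarity matrix is asymmetric beyond {SYMMETRY_TOL}")
    return SimilarityMatrix(ids, values)


def write_associations(table: AssociationTable, path: str | Path) -> None:
    """Write an association table back to the two-column TSV format."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("lncRNA\tdisease\n")
        for i, j in sorted(table.pairs):
            fh.write(f"{table.lncrna_ids[i]}\t{table.disease_ids[j]}\n")


def write_dag(dag: DiseaseDAG, path: str | Path) -> None:
    path = Path(path)
    attached = {t for e in dag.edges for t in e}
    with path.open("w", encoding="utf-8") as fh:
        for parent, child in sorted(dag.edges):
            fh.write(f"{parent}\t{child}\n")
        for term in sorted(dag.terms - attached):
            fh.write(f"{term}\n")
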