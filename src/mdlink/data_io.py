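"""Readers, writers and validated containers for association data.

Input formats are plain TSV/CSV (delimiter auto-detected between tab and
comma): a two-column microbe/disease association table, a three-column
gene-gene interaction table with log-likelihood scores (LLS), a
two-column disease-gene map and a two-column child/parent disease DAG
edge list. Names are whitespace-trimmed and matched case-insensitively,
with the original casing of the first occurrence preserved for output.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "AssociationTable",
    "AssociationMatrix",
    "GeneInteractionNet",
    "DiseaseGeneMap",
    "DiseaseDAG",
    "read_associations",
    "build_adjacency",
    "read_gene_interactions",
    "read_disease_gene_map",
    "read_disease_dag",
    "write_associations",
    "write_score_matrix",
    "write_rankings",
]


class ParseError(ValueError):
    """A malformed line in an input table."""


def _normalize(name: str) -> str:
    return name.strip().casefold()


def _split_line(line: str, lineno: int, min_cols: int, path: str) -> list[str]:
    delim = "\t" if "\t" in line else ","
    fields = [f.strip() for f in line.rstrip("\n").split(delim)]
    if len(fields) < min_cols or any(not f for f in fields[:min_cols]):
        raise ParseError(
            f"{path}: line {lineno}: expected >= {min_cols} non-empty "
            f"tab/comma-separated fields, got {line!r}"
        )
    return fields


@dataclass
class AssociationTable:
    """Deduplicated (microbe, disease) record list in first-seen order."""

    records: list[tuple[str, str]]
    source_label: str = ""

    def __post_init__(self):
        keys = {( _normalize(m), _normalize(d)) for m, d in self.records}
        if len(keys) != len(self.records):
            raise ValueError("association table contains duplicate pairs")


@dataclass
class AssociationMatrix:
    """Binary microbe x disease adjacency with ordered name indices."""

    values: np.ndarray
    microbe_index: dict[str, int]
    disease_index: dict[str, int]

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.shape != (len(self.microbe_index), len(self.disease_index)):
            raise ValueError("adjacency shape does not match index sizes")
        if not np.isin(self.values, (0, 1)).all():
            raise ValueError("adjacency entries must be 0/1")

    @property
    def n_microbes(self) -> int:
        return self.values.shape[0]

    @property
    def n_diseases(self) -> int:
        return self.values.shape[1]

    @property
    def microbes(self) -> list[str]:
        return list(self.microbe_index)

    @property
    def diseases(self) -> list[str]:
        return list(self.disease_index)

    def masked(self, pairs: set[tuple[int, int]]) -> "AssociationMatrix":
        """Copy with the given (row, col) positive entries zeroed."""
        values = self.values.copy()
        for i, j in pairs:
            values[i, j] = 0
        return AssociationMatrix(values, dict(self.microbe_index), dict(self.disease_index))


@dataclass
class GeneInteractionNet:
    """Undirected gene-gene interactions scored by log-likelihood (LLS)."""

    edges: list[tuple[str, str, float]]
    lls_min: float = field(init=False, default=np.nan)
    lls_max: float = field(init=False, default=np.nan)

    def __post_init__(self):
        scores: dict[frozenset[str], float] = {}
        for p, q, s in self.edges:
            key = frozenset((_normalize(p), _normalize(q)))
            if key in scores and scores[key] != s:
                raise ValueError(f"conflicting LLS for gene pair {p!r}/{q!r}")
            scores[key] = float(s)
        self._scores = scores
        if self.edges:
            values = [s for _, _, s in self.edges]
            self.lls_min = float(min(values))
            self.lls_max = float(max(values))

    def score(self, p: str, q: str) -> float | None:
        return self._scores.get(frozenset((_normalize(p), _normalize(q))))


@dataclass
class DiseaseGeneMap:
    """disease name -> set of associated gene names."""

    mapping: dict[str, set[str]]

    def genes(self, disease: str) -> set[str]:
        return self.mapping.get(_normalize(disease), set())


@dataclass
class DiseaseDAG:
    """Disease ontology fragment as a child -> parent edge list."""

    edges: list[tuple[str, str]]
    nodes: set[str] = field(default_factory=set)

    def __post_init__(self):
        self.edges = [(_normalize(c), _normalize(p)) for c, p in self.edges]
        self.nodes = {_normalize(n) for n in self.nodes}
        for c, p in self.edges:
            self.nodes.update((c, p))
        g = self.graph
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            raise ValueError(f"disease hierarchy contains a cycle: {cycle}")

    @property
    def graph(self) -> nx.DiGraph:
        """Directed graph with edges child -> parent."""
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges)
        return g

    def ancestors(self, node: str) -> set[str]:
        return nx.descendants(self.graph, _normalize(node))

    def __contains__(self, node: str) -> bool:
        return _normalize(node) in self.nodes


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def read_associations(path: str | Path, source_label: str = "") -> AssociationTable:
    """Read a two-column microbe/disease table, dropping duplicate pairs.

    Duplicates are matched case-insensitively after trimming; the first
    occurrence wins and fixes both the stored casing and the ordering.
    """
    path = Path(path)
    records: list[tuple[str, str]] = []
    seen: set[tuple[str, str]] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            microbe, disease = _split_line(line, lineno, 2, str(path))[:2]
            key = (_normalize(microbe), _normalize(disease))
            if key in seen:
                continue
            seen.add(key)
            records.append((microbe.strip(), disease.strip()))
    return AssociationTable(records, source_label or path.name)


def build_adjacency(table: AssociationTable) -> AssociationMatrix:
    """Build the binary adjacency A (microbes x diseases) from a table.

    Row/column order is the order of first appearance in the table; this
    ordering also fixes the node sequence seen by the recurrent layer,
    so it is part of the reproducibility contract.
    """
    microbe_index: dict[str, int] = {}
    disease_index: dict[str, int] = {}
    micro_norm: dict[str, int] = {}
    dis_norm: dict[str, int] = {}
    for m, d in table.records:
        mk, dk = _normalize(m), _normalize(d)
        if mk not in micro_norm:
            micro_norm[mk] = len(micro_norm)
            microbe_index[m] = micro_norm[mk]
        if dk not in dis_norm:
            dis_norm[dk] = len(dis_norm)
            disease_index[d] = dis_norm[dk]
    values = np.zeros((len(micro_norm), len(dis_norm)), dtype=np.int8)
    for m, d in table.records:
        values[micro_norm[_normalize(m)], dis_norm[_normalize(d)]] = 1
    return AssociationMatrix(values, microbe_index, disease_index)


def read_gene_interactions(path: str | Path) -> GeneInteractionNet:
    """Read a three-column (geneA, geneB, LLS) interaction table."""
    path = Path(path)
    edges: list[tuple[str, str, float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            a, b, score = _split_line(line, lineno, 3, str(path))[:3]
            try:
                lls = float(score)
            except ValueError as exc:
                raise ParseError(
                    f"{path}: line {lineno}: non-numeric LLS {score!r}"
                ) from exc
            edges.append((a, b, lls))
    return GeneInteractionNet(edges)


def read_disease_gene_map(path: str | Path) -> DiseaseGeneMap:
    """Read a two-column (disease, gene) table into a disease -> gene-set map."""
    path = Path(path)
    mapping: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            disease, gene = _split_line(line, lineno, 2, str(path))[:2]
            mapping.setdefault(_normalize(disease), set()).add(_normalize(gene))
    return DiseaseGeneMap(mapping)


def read_disease_dag(path: str | Path) -> DiseaseDAG:
    """Read a two-column (child, parent) edge list; validates acyclicity."""
    path = Path(path)
    edges: list[tuple[str, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            child, parent = _split_line(line, lineno, 2, str(path))[:2]
            edges.append((child, parent))
    return DiseaseDAG(edges)


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def write_associations(table: AssociationTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        for m, d in table.records:
            fh.write(f"{m}\t{d}\n")


def write_score_matrix(
    scores: np.ndarray,
    microbe_names: list[str],
    disease_names: list[str],
    path: str | Path,
) -> None:
    """Write an Nm x Nd score matrix as TSV (microbe rows, disease columns)."""
    scores = np.asarray(scores)
    if scores.shape != (len(microbe_names), len(disease_names)):
        raise ValueError("score matrix shape does not match name lists")
    frame = pd.DataFrame(scores, index=microbe_names, columns=disease_names)
    frame.to_csv(path, sep="\t", index_label="microbe")


def write_rankings(
    scores: np.ndarray,
    adjacency: AssociationMatrix,
    disease_name: str,
    top_k: int,
    path: str | Path,
) -> pd.DataFrame:
    """Rank candidate microbes for one disease, excluding known positives.

    Ties are broken alphabetically by microbe name; ``top_k`` larger than
    the candidate count truncates with a warning.
    """
    j = adjacency.disease_index[disease_name]
    microbes = adjacency.microbes
    rows = [
        (microbes[i], float(scores[i, j]))
        for i in range(adjacency.n_microbes)
        if adjacency.values[i, j] == 0
    ]
    rows.sort(key=lambda r: (-r[1], r[0]))
    if top_k > len(rows):
        warnings.warn(
            f"top_k={top_k} exceeds the {len(rows)} available candidates; truncating"
        )
        top_k = len(rows)
    frame = pd.DataFrame(rows[:top_k], columns=["microbe", "score"])
    frame.insert(0, "rank", np.arange(1, len(frame) + 1))
    frame.to_csv(path, sep="\t", index=False)
    return frame
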