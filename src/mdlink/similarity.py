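"""Similarity kernels over association profiles, gene nets and disease DAGs.

Three similarity views are computed for each side of the bipartite
network and averaged into one integrated matrix per side:

* Gaussian interaction profile (GIP) kernel similarity over binary
  association profiles, ``exp(-lambda * ||p_i - p_j||^2)`` with the
  kernel bandwidth normalized by the mean squared profile norm.
* Cosine similarity over the same profiles.
* A functional view: for diseases, gene-set similarity built from
  min-max-normalized log-likelihood scores (LLS) of a gene interaction
  net; for microbes, semantic similarity of their associated disease
  sets over a disease DAG with a per-edge 0.5 contribution decay.

When the functional inputs (gene net / DAG) are absent the integration
falls back to the mean of the two profile-based views, so the pipeline
stays runnable on association data alone.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .data_io import AssociationMatrix, DiseaseDAG, DiseaseGeneMap, GeneInteractionNet

__all__ = [
    "SimilarityMatrix",
    "gip_bandwidth",
    "gip_similarity",
    "cosine_similarity",
    "gene_fss",
    "disease_functional_similarity",
    "semantic_contributions",
    "semantic_value",
    "disease_semantic_similarity",
    "microbe_functional_similarity",
    "integrate",
    "integrated_similarities",
]

logger = logging.getLogger(__name__)

#: per-edge decay of the semantic contribution toward DAG ancestors
SEMANTIC_DECAY = 0.5


@dataclass
class SimilarityMatrix:
    """Square symmetric per-entity similarity with an ordered name index."""

    values: np.ndarray
    entity_index: dict[str, int]
    kind: str = "integrated"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        n = len(self.entity_index)
        if self.values.shape != (n, n):
            raise ValueError("similarity matrix shape does not match index")
        if not np.allclose(self.values, self.values.T, atol=1e-9):
            raise ValueError("similarity matrix is not symmetric")


def gip_bandwidth(profiles: np.ndarray) -> float:
    """Normalized GIP kernel bandwidth: 1 / mean squared profile norm."""
    profiles = np.asarray(profiles, dtype=np.float64)
    mean_sq = float((profiles**2).sum(axis=1).mean())
    if mean_sq == 0.0:
        raise ValueError("all profiles are zero; GIP bandwidth undefined")
    return 1.0 / mean_sq


def gip_similarity(
    profiles: np.ndarray,
    names: list[str],
    bandwidth: float | None = None,
) -> SimilarityMatrix:
    """GIP kernel matrix ``exp(-bw * ||p_i - p_j||^2)`` over profile rows."""
    profiles = np.asarray(profiles, dtype=np.float64)
    bw = gip_bandwidth(profiles) if bandwidth is None else float(bandwidth)
    if bw <= 0:
        raise ValueError("bandwidth must be positive")
    sq_norms = (profiles**2).sum(axis=1)
    d2 = sq_norms[:, None] + sq_norms[None, :] - 2.0 * profiles @ profiles.T
    np.maximum(d2, 0.0, out=d2)
    values = np.exp(-bw * d2)
    np.fill_diagonal(values, 1.0)
    values = 0.5 * (values + values.T)
    return SimilarityMatrix(values, {n: i for i, n in enumerate(names)}, kind="GIP")


def cosine_similarity(profiles: np.ndarray, names: list[str]) -> SimilarityMatrix:
    """Cosine similarity over profile rows.

    All-zero profiles have undefined cosine; such pairs score 0
    off-diagonal and 1 on the diagonal.
    """
    profiles = np.asarray(profiles, dtype=np.float64)
    norms = np.linalg.norm(profiles, axis=1)
    safe = np.where(norms == 0, 1.0, norms)
    values = (profiles @ profiles.T) / np.outer(safe, safe)
    zero = norms == 0
    values[zero, :] = 0.0
    values[:, zero] = 0.0
    np.fill_diagonal(values, 1.0)
    values = 0.5 * (values + values.T)
    return SimilarityMatrix(values, {n: i for i, n in enumerate(names)}, kind="cosine")


# ---------------------------------------------------------------------------
# gene-functional disease similarity
# ---------------------------------------------------------------------------

class GeneFssTable:
    """Pairwise gene functional similarity scores (FSS) in [0, 1].

    ``FSS(g, g) = 1``; a scored interaction maps to its min-max
    normalized LLS; gene pairs absent from the net score 0.
    """

    def __init__(self, scores: dict[frozenset[str], float]):
        self._scores = scores

    def __call__(self, p: str, q: str) -> float:
        if p == q:
            return 1.0
        return self._scores.get(frozenset((p, q)), 0.0)


def gene_fss(net: GeneInteractionNet) -> GeneFssTable:
    """Min-max normalize the net's LLS scores into a gene FSS table."""
    span = net.lls_max - net.lls_min
    if net.edges and span == 0.0 and len(net.edges) > 1:
        logger.warning(
            "all LLS scores equal (%s); every connected gene pair scores 1",
            net.lls_max,
        )
    scores: dict[frozenset[str], float] = {}
    for key, lls in net._scores.items():
        if len(key) == 1:  # self-interaction, FSS fixed at 1
            continue
        scores[key] = 1.0 if span == 0.0 else (lls - net.lls_min) / span
    return GeneFssTable(scores)


def _best_match_sum(source: set[str], target: set[str], fss: GeneFssTable) -> float:
    """Sum over source genes of their best FSS against the target set."""
    return sum(max(fss(gp, gk) for gp in target) for gk in source)


def disease_functional_similarity(
    gene_map: DiseaseGeneMap,
    fss: GeneFssTable,
    names: list[str],
) -> SimilarityMatrix:
    """Best-match-average gene-set similarity between diseases.

    ``DFS(di, dj) = (sum_{g in Gi} max FSS(g, Gj) + sum_{g in Gj} max
    FSS(g, Gi)) / (|Gi| + |Gj|)``. Pairs where either gene set is empty
    score 0; the diagonal is 1.
    """
    n = len(names)
    values = np.eye(n)
    gene_sets = [gene_map.genes(name) for name in names]
    for i in range(n):
        for j in range(i + 1, n):
            gi, gj = gene_sets[i], gene_sets[j]
            if not gi or not gj:
                continue
            num = _best_match_sum(gi, gj, fss) + _best_match_sum(gj, gi, fss)
            values[i, j] = values[j, i] = num / (len(gi) + len(gj))
    return SimilarityMatrix(values, {n_: i for i, n_ in enumerate(names)}, kind="functional")


# ---------------------------------------------------------------------------
# DAG semantic disease similarity
# ---------------------------------------------------------------------------

def semantic_contributions(
    dag: DiseaseDAG, dt: str, decay: float = SEMANTIC_DECAY
) -> dict[str, float]:
    """Semantic contribution of each term in V(dt) = {dt} + ancestors(dt).

    ``SC_dt(dt) = 1``; every ancestor contributes ``decay`` times the
    best contribution among its children inside V(dt), i.e. the decay
    raised to the shortest upward path length from dt.
    """
    key = dt.strip().casefold()
    if key not in dag.nodes:
        raise KeyError(f"disease {dt!r} not in DAG")
    graph = dag.graph  # edges child -> parent
    sc: dict[str, float] = {key: 1.0}
    frontier = [key]
    while frontier:
        next_frontier = []
        for node in frontier:
            for parent in graph.successors(node):
                contrib = decay * sc[node]
                if contrib > sc.get(parent, 0.0):
                    sc[parent] = contrib
                    next_frontier.append(parent)
        frontier = next_frontier
    return sc


def semantic_value(contributions: dict[str, float]) -> float:
    """Semantic value SV: total contribution over V(dt)."""
    return float(sum(contributions.values()))


def disease_semantic_similarity(
    dag: DiseaseDAG, di: str, dj: str, decay: float = SEMANTIC_DECAY
) -> float:
    """DAG semantic similarity DSS between two diseases.

    Shared-ancestor contributions from both sides, normalized by the two
    semantic values. Diseases missing from the DAG score 0 against
    everything else and 1 against themselves.
    """
    ki, kj = di.strip().casefold(), dj.strip().casefold()
    if ki == kj:
        return 1.0
    if ki not in dag.nodes or kj not in dag.nodes:
        return 0.0
    sci = semantic_contributions(dag, di, decay)
    scj = semantic_contributions(dag, dj, decay)
    shared = set(sci) & set(scj)
    if not shared:
        return 0.0
    num = sum(sci[d] + scj[d] for d in shared)
    return num / (semantic_value(sci) + semantic_value(scj))


def _disease_set_similarity(d: str, targets: set[str], dss: dict[tuple[str, str], float]) -> float:
    """DS(d, D): best DSS between disease d and any disease in D."""
    return max(dss[(d, t)] for t in targets)


def microbe_functional_similarity(
    adjacency: AssociationMatrix,
    dag: DiseaseDAG,
    decay: float = SEMANTIC_DECAY,
) -> SimilarityMatrix:
    """Microbe similarity from the DAG similarity of their disease sets.

    With ``Di`` the diseases associated with microbe ``mi``:
    ``MFS(mi, mj) = (sum_{d in Dj} DS(d, Di) + sum_{d in Di} DS(d, Dj))
    / (|Di| + |Dj|)``. Microbes with no associations score 0
    off-diagonal.
    """
    diseases = adjacency.diseases
    nm = adjacency.n_microbes
    disease_sets: list[set[str]] = [
        {diseases[j] for j in np.flatnonzero(adjacency.values[i])} for i in range(nm)
    ]
    # pairwise DSS cache over diseases that actually occur
    used = sorted(set().union(*disease_sets)) if disease_sets else []
    dss: dict[tuple[str, str], float] = {}
    for a in used:
        for b in used:
            dss[(a, b)] = disease_semantic_similarity(dag, a, b, decay)
    values = np.eye(nm)
    for i in range(nm):
        for j in range(i + 1, nm):
            di, dj = disease_sets[i], disease_sets[j]
            if not di or not dj:
                continue
            num = sum(_disease_set_similarity(d, di, dss) for d in dj)
            num += sum(_disease_set_similarity(d, dj, dss) for d in di)
            values[i, j] = values[j, i] = num / (len(di) + len(dj))
    index = {m: i for i, m in enumerate(adjacency.microbes)}
    return SimilarityMatrix(values, index, kind="functional")


# ---------------------------------------------------------------------------
# integration
# ---------------------------------------------------------------------------

def integrate(*similarities: SimilarityMatrix) -> SimilarityMatrix:
    """Element-wise mean of similarity matrices sharing one entity index."""
    if not similarities:
        raise ValueError("nothing to integrate")
    first = similarities[0]
    for s in similarities[1:]:
        if list(s.entity_index) != list(first.entity_index):
            raise ValueError("similarity matrices have mismatched entity indices")
        if s.values.shape != first.values.shape:
            raise ValueError("similarity matrices have mismatched shapes")
    values = np.mean([s.values for s in similarities], axis=0)
    return SimilarityMatrix(values, dict(first.entity_index), kind="integrated")


def integrated_similarities(
    adjacency: AssociationMatrix,
    gene_map: DiseaseGeneMap | None = None,
    gene_net: GeneInteractionNet | None = None,
    dag: DiseaseDAG | None = None,
) -> tuple[SimilarityMatrix, SimilarityMatrix]:
    """Integrated microbe (MS) and disease (DS) similarity from one adjacency.

    Microbe profiles are the rows of A, disease profiles its columns.
    Each side averages GIP, cosine and (when its functional inputs are
    supplied) the functional view; otherwise the mean of the two
    profile-based views is used.
    """
    a = adjacency.values.astype(np.float64)
    microbes, diseases = adjacency.microbes, adjacency.diseases

    md = gip_similarity(a, microbes)
    cm = cosine_similarity(a, microbes)
    if dag is not None:
        mfs = microbe_functional_similarity(adjacency, dag)
        ms = integrate(md, cm, mfs)
    else:
        logger.info("no disease DAG supplied; microbe similarity = mean(GIP, cosine)")
        ms = integrate(md, cm)

    gd = gip_similarity(a.T, diseases)
    cd = cosine_similarity(a.T, diseases)
    if gene_map is not None and gene_net is not None:
        dfs = disease_functional_similarity(gene_map, gene_fss(gene_net), diseases)
        ds = integrate(gd, cd, dfs)
    else:
        logger.info("no gene inputs supplied; disease similarity = mean(GIP, cosine)")
        ds = integrate(gd, cd)
    return ms, ds
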