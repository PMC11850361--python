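"""Seeded synthetic fixtures: planted-block association matrices, scored
gene nets, disease DAGs and disease-gene maps.

The generators emulate the shapes of curated microbe-disease resources
without any download: microbes and diseases are assigned round-robin to
latent blocks and associate with probability ``p_in`` inside their
block and ``p_out`` outside. The same block labels drive the gene map
(same-block diseases share genes more often) and the DAG (same-block
diseases sit under a shared subtree), so every similarity view carries
signal about the planted structure. All generators are pure functions
of (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_io import (
    AssociationMatrix,
    DiseaseDAG,
    DiseaseGeneMap,
    GeneInteractionNet,
)

__all__ = ["FixtureSpec", "gen_association", "gen_gene_fixture", "gen_dag_fixture"]


@dataclass
class FixtureSpec:
    """Parameters of the planted-block fixture.

    Defaults give the benchmark used throughout the test suite: a
    60 x 20 association matrix with 4 blocks, within-block association
    probability 0.5 against a 0.02 background — dense enough signal for
    profile-kernel similarities to be informative, sparse enough that
    recovery is not trivial.
    """

    n_microbes: int = 60
    n_diseases: int = 20
    n_blocks: int = 4
    p_in: float = 0.5
    p_out: float = 0.02
    n_genes: int = 40
    dag_depth: int = 3
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.p_out < self.p_in <= 1.0:
            raise ValueError("need 0 <= p_out < p_in <= 1")
        if self.n_blocks > min(self.n_microbes, self.n_diseases):
            raise ValueError("more blocks than entities on one side")

    def microbe_blocks(self) -> np.ndarray:
        return np.arange(self.n_microbes) % self.n_blocks

    def disease_blocks(self) -> np.ndarray:
        return np.arange(self.n_diseases) % self.n_blocks


def _names(prefix: str, n: int) -> list[str]:
    return [f"{prefix}{i:03d}" for i in range(n)]


def gen_association(spec: FixtureSpec) -> AssociationMatrix:
    """Planted-block binary association matrix (round-robin block labels)."""
    rng = np.random.default_rng(spec.seed)
    same = spec.microbe_blocks()[:, None] == spec.disease_blocks()[None, :]
    prob = np.where(same, spec.p_in, spec.p_out)
    values = (rng.random((spec.n_microbes, spec.n_diseases)) < prob).astype(np.int8)
    return AssociationMatrix(
        values,
        {n: i for i, n in enumerate(_names("microbe_", spec.n_microbes))},
        {n: i for i, n in enumerate(_names("disease_", spec.n_diseases))},
    )


def gen_gene_fixture(spec: FixtureSpec) -> tuple[GeneInteractionNet, DiseaseGeneMap]:
    """Random scored gene net plus a block-correlated disease-gene map.

    Gene pairs carry uniform LLS in [0, 5]. Each disease draws 1-5
    genes, mostly from a pool shared by its block, so same-block
    disease pairs have systematically higher functional similarity.
    """
    rng = np.random.default_rng([spec.seed, 1])
    genes = _names("gene_", spec.n_genes)
    edges: list[tuple[str, str, float]] = []
    seen: set[frozenset[str]] = set()
    n_edges = max(spec.n_genes, 3 * spec.n_genes // 2)
    while len(edges) < n_edges:
        p, q = rng.choice(spec.n_genes, size=2, replace=False)
        key = frozenset((genes[p], genes[q]))
        if key in seen:
            continue
        seen.add(key)
        edges.append((genes[p], genes[q], float(rng.uniform(0.0, 5.0))))
    net = GeneInteractionNet(edges)

    # block-private gene pools, drawn with high probability by own-block diseases
    pools = np.array_split(np.arange(spec.n_genes), spec.n_blocks)
    mapping: dict[str, set[str]] = {}
    for j, block in enumerate(spec.disease_blocks()):
        chosen: set[str] = set()
        for _ in range(int(rng.integers(1, 6))):
            pool = pools[block] if rng.random() < 0.8 else np.arange(spec.n_genes)
            chosen.add(genes[int(rng.choice(pool))])
        mapping[f"disease_{j:03d}"] = chosen
    return net, DiseaseGeneMap(mapping)


def gen_dag_fixture(spec: FixtureSpec) -> DiseaseDAG:
    """Rooted disease tree with one subtree per block.

    Depth is bounded by ``dag_depth``: root -> block ancestors ->
    chains of intermediate terms -> the disease leaves of that block.
    """
    rng = np.random.default_rng([spec.seed, 2])
    edges: list[tuple[str, str]] = []
    root = "dag_root"
    for block in range(spec.n_blocks):
        anchor = f"dag_block{block}"
        edges.append((anchor, root))
        members = [
            f"disease_{j:03d}" for j, b in enumerate(spec.disease_blocks()) if b == block
        ]
        for term in members:
            parent = anchor
            # optional intermediate terms keep leaves within dag_depth of the root
            for level in range(int(rng.integers(0, max(spec.dag_depth - 2, 0) + 1))):
                mid = f"dag_block{block}_mid{level}"
                if (mid, parent) not in edges:
                    edges.append((mid, parent))
                parent = mid
            edges.append((term, parent))
    return DiseaseDAG(edges)
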