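"""Heterogeneous network assembly and graph normalization.

The two integrated similarity matrices and the bipartite adjacency are
stacked into one symmetric block matrix over all nodes (microbes first,
then diseases):

    Y = [[w * MS,  A ],
         [A^T,  w * DS]]

where ``w`` is the similarity weight that puts the similarity blocks on
a comparable scale with the binary association block (default 6). Both
encoder channels consume the symmetric normalization of ``Y + I``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_io import AssociationMatrix
from .similarity import SimilarityMatrix

__all__ = [
    "HeterogeneousNetwork",
    "assemble_hetnet",
    "init_features",
    "normalize_adjacency",
]


@dataclass
class HeterogeneousNetwork:
    """Block matrix Y over microbe+disease nodes, microbes first."""

    values: np.ndarray
    node_names: list[str]
    n_microbes: int
    sim_weight: float

    def __post_init__(self):
        n = len(self.node_names)
        if self.values.shape != (n, n):
            raise ValueError("heterogeneous matrix shape mismatch")

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]

    def blocks(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Recover (w*MS, A, w*DS) from the block layout."""
        nm = self.n_microbes
        return (
            self.values[:nm, :nm],
            self.values[:nm, nm:],
            self.values[nm:, nm:],
        )


def assemble_hetnet(
    ms: SimilarityMatrix,
    ds: SimilarityMatrix,
    adjacency: AssociationMatrix,
    sim_weight: float = 6.0,
) -> HeterogeneousNetwork:
    """Stack similarity and association blocks into the network matrix Y."""
    nm, nd = adjacency.n_microbes, adjacency.n_diseases
    if ms.values.shape != (nm, nm) or ds.values.shape != (nd, nd):
        raise ValueError("similarity block shapes do not match the adjacency")
    a = adjacency.values.astype(np.float64)
    top = np.hstack([sim_weight * ms.values, a])
    bottom = np.hstack([a.T, sim_weight * ds.values])
    values = np.vstack([top, bottom])
    return HeterogeneousNetwork(
        values=values,
        node_names=adjacency.microbes + adjacency.diseases,
        n_microbes=nm,
        sim_weight=float(sim_weight),
    )


def init_features(net: HeterogeneousNetwork, scheme: str = "hetnet") -> np.ndarray:
    """Initial node features X.

    ``hetnet`` (default): each node's feature vector is its row of Y,
    injecting all similarity and association information with no extra
    parameters. ``onehot``: identity features.
    """
    if scheme == "hetnet":
        return net.values.copy()
    if scheme == "onehot":
        return np.eye(net.n_nodes)
    raise ValueError(f"unknown feature scheme {scheme!r}")


def normalize_adjacency(values: np.ndarray) -> np.ndarray:
    """Symmetric normalization D^(-1/2) (Y + I) D^(-1/2) with self-loops."""
    values = np.asarray(values, dtype=np.float64)
    if (values < 0).any():
        raise ValueError("graph weights must be non-negative")
    a_hat = values + np.eye(values.shape[0])
    d_inv_sqrt = 1.0 / np.sqrt(a_hat.sum(axis=1))
    return a_hat * np.outer(d_inv_sqrt, d_inv_sqrt)
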