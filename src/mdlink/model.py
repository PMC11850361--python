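"""Dual graph-embedded fusion model for bipartite link prediction.

Two parallel encoders read the heterogeneous microbe-disease network: a
graph convolutional channel (symmetric-normalized neighborhood
aggregation, capturing local-to-global spatial structure) and a graph
attention channel (per-edge softmax attention, weighting neighbors by
learned importance). Their outputs are concatenated, passed through a
(bi)directional LSTM along the node axis, and decoded into an
``Nm x Nd`` matrix of association probabilities by a fully connected
projection followed by a logistic inner-product head.

The public surface follows the Model/Results convention: build a
:class:`MicrobeDiseaseGraphModel` from an association matrix (plus
optional gene-net and disease-DAG inputs), call :meth:`fit`, and read
estimates and diagnostics off the returned
:class:`MicrobeDiseaseGraphResults`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._autodiff import Tensor, concat, stack_rows
from .data_io import AssociationMatrix, DiseaseDAG, DiseaseGeneMap, GeneInteractionNet
from .hetnet import HeterogeneousNetwork, assemble_hetnet, init_features, normalize_adjacency
from .similarity import integrated_similarities

__all__ = [
    "ModelConfig",
    "ModelState",
    "EncoderOutput",
    "gcn_layer",
    "gat_attention",
    "gat_layer",
    "fuse",
    "lstm_step",
    "sequence_forward",
    "decode",
    "forward",
    "init_state",
    "MicrobeDiseaseGraphModel",
    "MicrobeDiseaseGraphResults",
]

_VALID_ABLATIONS = {"no_gcn", "no_gat", "no_lstm"}


@dataclass
class ModelConfig:
    """Architecture hyperparameters.

    ``embed_dim`` (k) and ``num_layers`` (L) size the two encoder
    channels; ``lstm_hidden`` (dl) is the total width of the recurrent
    output (split across directions when ``bidirectional``);
    ``dropout_adj``/``dropout_feat`` are the training-time deactivation
    rates for graph edges and features; ``ablation`` switches off
    individual sub-modules for component analysis.
    """

    embed_dim: int = 128
    num_layers: int = 2
    lstm_hidden: int = 128
    bidirectional: bool = True
    dropout_adj: float = 0.5
    dropout_feat: float = 0.5
    leakyrelu_slope: float = 0.2
    similarity_weight: float = 6.0
    feature_scheme: str = "hetnet"
    ablation: frozenset[str] = frozenset()
    seed: int = 0

    def __post_init__(self):
        self.ablation = frozenset(self.ablation)
        unknown = self.ablation - _VALID_ABLATIONS
        if unknown:
            raise ValueError(f"unknown ablation flags: {sorted(unknown)}")
        if {"no_gcn", "no_gat"} <= self.ablation:
            raise ValueError("cannot ablate both encoder channels")
        if self.embed_dim < 1 or self.num_layers < 1 or self.lstm_hidden < 1:
            raise ValueError("embed_dim, num_layers and lstm_hidden must be positive")
        for rate in (self.dropout_adj, self.dropout_feat):
            if not 0.0 <= rate < 1.0:
                raise ValueError("dropout rates must lie in [0, 1)")
        if self.bidirectional and self.lstm_hidden % 2:
            raise ValueError("bidirectional lstm_hidden must be even")


class ModelState(dict):
    """Named learnable parameters (name -> Tensor)."""

    def weight_matrices(self) -> list[Tensor]:
        """Weight matrices subject to L2 decay (biases and attention
        vectors excluded)."""
        return [
            t
            for name, t in self.items()
            if not name.endswith("_b") and not name.endswith("_a")
        ]

    def parameters(self) -> list[Tensor]:
        return list(self.values())

    def zero_grad(self) -> None:
        for t in self.values():
            t.grad = None

    def copy_values(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.items()}


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


def init_state(config: ModelConfig, d0: int, rng: np.random.Generator) -> ModelState:
    """Seeded fan-based uniform initialization of all parameters."""
    k, L = config.embed_dim, config.num_layers
    state = ModelState()
    dims = [d0] + [k] * L
    for layer in range(L):
        state[f"gcn{layer}_w"] = Tensor(_glorot(rng, dims[layer], dims[layer + 1]), True)
    for layer in range(L):
        state[f"gat{layer}_w"] = Tensor(_glorot(rng, dims[layer], dims[layer + 1]), True)
        state[f"gat{layer}_a"] = Tensor(_glorot(rng, 2 * dims[layer + 1], 1), True)
    if "no_lstm" not in config.ablation:
        directions = ("fwd", "bwd") if config.bidirectional else ("fwd",)
        hidden = config.lstm_hidden // len(directions)
        for d in directions:
            # per-gate Glorot fan (each of the four gates is an
            # independent hidden-wide map, so fan_out is `hidden`)
            w = np.hstack([_glorot(rng, 2 * k, hidden) for _ in range(4)])
            u = np.hstack([_glorot(rng, hidden, hidden) for _ in range(4)])
            state[f"lstm_{d}_w"] = Tensor(w, True)
            state[f"lstm_{d}_u"] = Tensor(u, True)
            # near-feedforward start: input/output gates biased open,
            # forget gate biased shut, so node features reach the
            # decoder from epoch 0 and recurrence is learned in
            b = np.concatenate(
                [2.0 * np.ones(hidden), -2.0 * np.ones(hidden), 2.0 * np.ones(hidden), np.zeros(hidden)]
            )
            state[f"lstm_{d}_b"] = Tensor(b, True)
        dec_in = config.lstm_hidden
    else:
        dec_in = 2 * k
    state["fc_w"] = Tensor(_glorot(rng, dec_in, k), True)
    state["fc_b"] = Tensor(np.zeros(k), True)
    # shared scalar head bias: absorbs the association-prior logit
    state["fc_bias_b"] = Tensor(np.zeros(1), True)
    return state


# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------

def gcn_layer(h: Tensor, norm_adj: Tensor, w: Tensor) -> Tensor:
    """One graph convolution: ReLU(D^-1/2 A^ D^-1/2 . H . W)."""
    return (norm_adj @ h @ w).relu()


def gat_attention(
    h: Tensor,
    adj_mask: np.ndarray,
    w: Tensor,
    a: Tensor,
    slope: float = 0.2,
) -> tuple[Tensor, Tensor]:
    """Per-edge attention coefficients and the projected features.

    The attention logit for edge (i, j) is
    ``LeakyReLU(a^T [W h_i || W h_j])``, decomposed as
    ``a_src^T W h_i + a_dst^T W h_j``; a masked row softmax over each
    node's neighborhood yields coefficients that sum to one per node.
    Returns ``(alpha, W h)``.
    """
    wh = h @ w
    k = wh.data.shape[1]
    src = wh @ a[:k]          # (n, 1): contribution of node i as source
    dst = wh @ a[k:]          # (n, 1): contribution of node j as target
    logits = (src + dst.T).leaky_relu(slope)
    alpha = logits.masked_row_softmax(np.asarray(adj_mask, dtype=bool))
    return alpha, wh


def gat_layer(wh: Tensor, alpha: Tensor) -> Tensor:
    """Attention-weighted aggregation: ReLU(sum_j alpha_ij W h_j)."""
    return (alpha @ wh).relu()


def fuse(h_gcn: Tensor | None, h_gat: Tensor | None) -> Tensor:
    """Concatenate the two channel outputs column-wise.

    Under a single-channel ablation the surviving channel is duplicated
    so downstream shapes are unchanged.
    """
    if h_gcn is None and h_gat is None:
        raise ValueError("at least one encoder channel is required")
    left = h_gcn if h_gcn is not None else h_gat
    right = h_gat if h_gat is not None else h_gcn
    if left.data.shape[0] != right.data.shape[0]:
        raise ValueError("channel outputs disagree on node count")
    return concat([left, right], axis=1)


def lstm_step(
    x_t: Tensor,
    h_prev: Tensor,
    c_prev: Tensor,
    w: Tensor,
    u: Tensor,
    b: Tensor,
) -> tuple[Tensor, Tensor]:
    """One LSTM cell update (gate order: input, forget, output, candidate).

    ``i,f,o = logistic(...)``; ``c~ = tanh(...)``;
    ``c_t = f * c_prev + i * c~``; ``h_t = o * tanh(c_t)``.
    """
    hidden = c_prev.data.shape[1]
    z = x_t @ w + h_prev @ u + b
    i = z[:, 0 * hidden : 1 * hidden].sigmoid()
    f = z[:, 1 * hidden : 2 * hidden].sigmoid()
    o = z[:, 2 * hidden : 3 * hidden].sigmoid()
    c_tilde = z[:, 3 * hidden : 4 * hidden].tanh()
    c_t = f * c_prev + i * c_tilde
    h_t = o * c_t.tanh()
    return h_t, c_t


def _run_direction(xs: list[Tensor], w: Tensor, u: Tensor, b: Tensor) -> list[Tensor]:
    hidden = w.data.shape[1] // 4
    h = Tensor(np.zeros((1, hidden)))
    c = Tensor(np.zeros((1, hidden)))
    outputs = []
    for x_t in xs:
        h, c = lstm_step(x_t, h, c, w, u, b)
        outputs.append(h)
    return outputs


def sequence_forward(
    h_fused: Tensor, state: ModelState, bidirectional: bool
) -> Tensor:
    """Run the LSTM along the node axis of the fused embedding matrix.

    Each node is one time step, in the fixed node ordering of the
    heterogeneous network. Bidirectional output row t is
    ``[h_t^fwd || h_t^bwd]``.
    """
    n = h_fused.data.shape[0]
    xs = [h_fused[t : t + 1, :] for t in range(n)]
    fwd = _run_direction(xs, state["lstm_fwd_w"], state["lstm_fwd_u"], state["lstm_fwd_b"])
    if not bidirectional:
        return stack_rows(fwd)
    bwd = _run_direction(
        xs[::-1], state["lstm_bwd_w"], state["lstm_bwd_u"], state["lstm_bwd_b"]
    )[::-1]
    return concat([stack_rows(fwd), stack_rows(bwd)], axis=1)


def decode(
    h: Tensor,
    w_fc: Tensor,
    b_fc: Tensor,
    n_microbes: int,
    bias: Tensor | None = None,
) -> Tensor:
    """Project node embeddings and score all microbe-disease pairs.

    The fully connected layer maps each node embedding to a k-dim
    vector z; the score for pair (i, j) is
    ``logistic(z_mi . z_dj + b0)``, reconstructing the association
    matrix A'. The shared scalar ``b0`` absorbs the association prior.
    """
    z = h @ w_fc + b_fc
    z_m = z[:n_microbes, :]
    z_d = z[n_microbes:, :]
    logits = z_m @ z_d.T
    if bias is not None:
        logits = logits + bias
    return logits.sigmoid()


@dataclass
class EncoderOutput:
    """Intermediate representations of one forward pass (as arrays)."""

    h_gcn: np.ndarray | None
    h_gat: np.ndarray | None
    h_fused: np.ndarray
    h_lstm: np.ndarray | None


def forward(
    features: np.ndarray,
    norm_adj: np.ndarray,
    adj_mask: np.ndarray,
    n_microbes: int,
    config: ModelConfig,
    state: ModelState,
    rng: np.random.Generator | None = None,
    training: bool = False,
) -> tuple[Tensor, EncoderOutput]:
    """Full forward pass; dropout is active only when ``training``.

    Training-time regularization randomly deactivates graph edges
    (rate ``dropout_adj``, inverted scaling, no degree renormalization)
    and features after every encoder layer (rate ``dropout_feat``).
    """

    def drop(t: Tensor, rate: float) -> Tensor:
        if not training or rate == 0.0:
            return t
        mask = (rng.random(t.data.shape) >= rate) / (1.0 - rate)
        return t * Tensor(mask)

    adj_t = drop(Tensor(norm_adj), config.dropout_adj)
    h0 = Tensor(features)

    h_gcn: Tensor | None = None
    if "no_gcn" not in config.ablation:
        h_gcn = h0
        for layer in range(config.num_layers):
            h_gcn = gcn_layer(h_gcn, adj_t, state[f"gcn{layer}_w"])
            h_gcn = drop(h_gcn, config.dropout_feat)

    h_gat: Tensor | None = None
    if "no_gat" not in config.ablation:
        h_gat = h0
        for layer in range(config.num_layers):
            alpha, wh = gat_attention(
                h_gat,
                adj_mask,
                state[f"gat{layer}_w"],
                state[f"gat{layer}_a"],
                config.leakyrelu_slope,
            )
            h_gat = gat_layer(wh, alpha)
            h_gat = drop(h_gat, config.dropout_feat)

    h_fused = fuse(h_gcn, h_gat)
    if "no_lstm" in config.ablation:
        h_final = h_fused
        h_lstm = None
    else:
        h_final = sequence_forward(h_fused, state, config.bidirectional)
        h_lstm = h_final.data
    scores = decode(
        h_final, state["fc_w"], state["fc_b"], n_microbes, state.get("fc_bias_b")
    )
    encoder_out = EncoderOutput(
        h_gcn=None if h_gcn is None else h_gcn.data,
        h_gat=None if h_gat is None else h_gat.data,
        h_fused=h_fused.data,
        h_lstm=h_lstm,
    )
    return scores, encoder_out


# ---------------------------------------------------------------------------
# Model / Results objects
# ---------------------------------------------------------------------------

class MicrobeDiseaseGraphModel:
    """Dual graph-embedding link-prediction model over one association matrix.

    Parameters
    ----------
    adjacency
        Binary microbe x disease association matrix.
    gene_map, gene_net
        Optional disease->gene map and scored gene interaction net for
        the functional disease-similarity view.
    dag
        Optional disease DAG for the microbe functional-similarity view.
    config
        Architecture hyperparameters (:class:`ModelConfig`).

    Examples
    --------
    >>> model = MicrobeDiseaseGraphModel(adjacency, config=ModelConfig(embed_dim=32))
    >>> results = model.fit()          # doctest: +SKIP
    >>> print(results.summary())       # doctest: +SKIP
    """

    def __init__(
        self,
        adjacency: AssociationMatrix,
        gene_map: DiseaseGeneMap | None = None,
        gene_net: GeneInteractionNet | None = None,
        dag: DiseaseDAG | None = None,
        config: ModelConfig | None = None,
    ):
        self.adjacency = adjacency
        self.gene_map = gene_map
        self.gene_net = gene_net
        self.dag = dag
        self.config = config or ModelConfig()
        self._graph_cache: tuple[HeterogeneousNetwork, np.ndarray, np.ndarray, np.ndarray] | None = None

    @classmethod
    def from_dataframe(cls, frame, microbe_col="microbe", disease_col="disease", **kwargs):
        """Build from a two-column pandas DataFrame of associations."""
        from .data_io import AssociationTable, build_adjacency

        records: list[tuple[str, str]] = []
        seen: set[tuple[str, str]] = set()
        for m, d in zip(frame[microbe_col], frame[disease_col]):
            key = (str(m).strip().casefold(), str(d).strip().casefold())
            if key not in seen:
                seen.add(key)
                records.append((str(m), str(d)))
        table = AssociationTable(records, source_label="dataframe")
        return cls(build_adjacency(table), **kwargs)

    # -- graph assembly -------------------------------------------------------

    def build_graph(self) -> tuple[HeterogeneousNetwork, np.ndarray, np.ndarray, np.ndarray]:
        """Assemble (hetnet, features, normalized adjacency, neighbor mask)."""
        if self._graph_cache is None:
            ms, ds = integrated_similarities(
                self.adjacency, self.gene_map, self.gene_net, self.dag
            )
            net = assemble_hetnet(ms, ds, self.adjacency, self.config.similarity_weight)
            features = init_features(net, self.config.feature_scheme)
            norm_adj = normalize_adjacency(net.values)
            adj_mask = norm_adj > 0
            self._graph_cache = (net, features, norm_adj, adj_mask)
        return self._graph_cache

    # -- estimation -----------------------------------------------------------

    def fit(self, train_config=None, callback=None) -> "MicrobeDiseaseGraphResults":
        """Train the model and return a results object.

        ``train_config`` is a :class:`~mdlink.training_eval.TrainConfig`
        (defaults used when omitted); ``callback(epoch, loss)`` is
        invoked once per epoch when given.
        """
        from .training_eval import TrainConfig, train

        train_config = train_config or TrainConfig()
        state, losses = train(self, train_config, callback=callback)
        scores = self.predict(state)
        return MicrobeDiseaseGraphResults(self, train_config, state, losses, scores)

    def predict(self, state: ModelState) -> np.ndarray:
        """Score every microbe-disease pair (inference; dropout off)."""
        _, features, norm_adj, adj_mask = self.build_graph()
        scores, _ = forward(
            features,
            norm_adj,
            adj_mask,
            self.adjacency.n_microbes,
            self.config,
            state,
            training=False,
        )
        return scores.data


@dataclass
class MicrobeDiseaseGraphResults:
    """Fitted parameters, diagnostics and predictions.

    ``scores`` is the reconstructed association-probability matrix A'
    (microbes x diseases); ``loss_trajectory`` records the total
    training loss per epoch.
    """

    model: MicrobeDiseaseGraphModel
    train_config: object
    state: ModelState
    loss_trajectory: list[float] = field(repr=False)
    scores: np.ndarray = field(repr=False)

    @property
    def n_parameters(self) -> int:
        return int(sum(t.data.size for t in self.state.values()))

    def rankings(self, disease_name: str, top_k: int = 20):
        """Top candidate microbes for a disease (known positives excluded)."""
        import pandas as pd

        adjacency = self.model.adjacency
        j = adjacency.disease_index[disease_name]
        microbes = adjacency.microbes
        rows = [
            (microbes[i], float(self.scores[i, j]))
            for i in range(adjacency.n_microbes)
            if adjacency.values[i, j] == 0
        ]
        rows.sort(key=lambda r: (-r[1], r[0]))
        frame = pd.DataFrame(rows[:top_k], columns=["microbe", "score"])
        frame.insert(0, "rank", np.arange(1, len(frame) + 1))
        return frame

    def summary(self) -> str:
        """Human-readable fit summary."""
        cfg = self.model.config
        adjacency = self.model.adjacency
        lines = [
            "Dual graph-embedded fusion model: fit summary",
            "=" * 46,
            f"nodes:            {adjacency.n_microbes} microbes, {adjacency.n_diseases} diseases",
            f"known positives:  {int(adjacency.values.sum())}",
            f"encoders:         L={cfg.num_layers}, k={cfg.embed_dim}"
            + (f", ablation={sorted(cfg.ablation)}" if cfg.ablation else ""),
            f"sequence layer:   {'BiLSTM' if cfg.bidirectional else 'LSTM'}"
            + ("(disabled)" if "no_lstm" in cfg.ablation else f", width {cfg.lstm_hidden}"),
            f"parameters:       {self.n_parameters}",
            f"epochs:           {len(self.loss_trajectory)}",
            f"final loss:       {self.loss_trajectory[-1]:.6f}"
            if self.loss_trajectory
            else "final loss:       n/a",
            f"score range:      [{self.scores.min():.4f}, {self.scores.max():.4f}]",
        ]
        return "\n".join(lines)
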