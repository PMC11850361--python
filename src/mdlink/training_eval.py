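"""Loss, optimization, cross-validation and ranking metrics.

Training minimizes mean binary cross-entropy between the reconstructed
probability matrix A' and the (masked) association matrix, plus an L2
penalty on the weight matrices, with Adam. Evaluation follows the usual
link-prediction protocol: k-fold splits over the known positives, the
test fold's edges removed from the training adjacency *and* from every
similarity computed from it (no leakage), and held-out positives scored
against all pairs unknown in the full data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from ._autodiff import Tensor
from .data_io import AssociationMatrix
from .model import (
    MicrobeDiseaseGraphModel,
    ModelConfig,
    ModelState,
    forward,
    init_state,
)

__all__ = [
    "TrainConfig",
    "FoldSplit",
    "EvalReport",
    "cross_entropy",
    "l2_penalty",
    "make_folds",
    "train",
    "confusion",
    "accuracy",
    "specificity",
    "tpr",
    "fpr",
    "auc",
    "cross_validate",
    "run_ablations",
]

_CLAMP = 1e-12


@dataclass
class TrainConfig:
    """Optimization and cross-validation settings.

    Defaults follow the reference protocol: 4,000 epochs at learning
    rate 0.01, 5-fold cross-validation repeated 5 times. ``l2_lambda``
    weighs the L2 penalty; ``negative_mode`` selects whether every
    unknown pair counts as a negative (``all``) or an equally sized
    negative sample is drawn per epoch (``balanced``). ``grad_clip``
    bounds the global gradient norm per step (0 disables); clipping
    keeps the recurrent stage stable at the reference learning rate.
    """

    epochs: int = 4000
    learning_rate: float = 0.01
    l2_lambda: float = 5e-4
    negative_mode: str = "all"
    folds: int = 5
    repeats: int = 5
    seed: int = 0
    threshold: float = 0.5
    grad_clip: float = 5.0

    def __post_init__(self):
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be positive")
        if self.negative_mode not in ("all", "balanced"):
            raise ValueError("negative_mode must be 'all' or 'balanced'")
        if not 0.0 < self.threshold < 1.0:
            raise ValueError("threshold must lie in (0, 1)")


# ---------------------------------------------------------------------------
# loss
# ---------------------------------------------------------------------------

def cross_entropy(labels, predictions) -> float:
    """Mean binary cross-entropy; predictions clamped away from {0, 1}."""
    y = np.asarray(labels, dtype=np.float64).ravel()
    p = np.asarray(
        predictions.data if isinstance(predictions, Tensor) else predictions,
        dtype=np.float64,
    ).ravel()
    if y.shape != p.shape:
        raise ValueError("labels and predictions differ in length")
    p = np.clip(p, _CLAMP, 1.0 - _CLAMP)
    return float(-np.mean(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))


def _cross_entropy_tensor(labels: np.ndarray, predictions: Tensor) -> Tensor:
    y = Tensor(labels)
    p = predictions.clip(_CLAMP, 1.0 - _CLAMP)
    return -(y * p.log() + (1.0 - y) * (1.0 - p).log()).mean()


def _l2_tensor(state: ModelState) -> Tensor:
    total = Tensor(0.0)
    for w in state.weight_matrices():
        total = total + w.square().sum()
    return total


def l2_penalty(state: ModelState) -> float:
    """Sum of squared entries over all weight matrices (biases and
    attention vectors excluded)."""
    return float(_l2_tensor(state).data)


# ---------------------------------------------------------------------------
# optimizer
# ---------------------------------------------------------------------------

class _Adam:
    """Adam with cosine decay of the initial learning rate over the run."""

    def __init__(self, params: list[Tensor], lr: float, total_steps: int,
                 b1=0.9, b2=0.999, eps=1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, b1, b2, eps
        self.total_steps = max(total_steps, 1)
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def step(self) -> None:
        lr = self.lr * 0.5 * (1.0 + np.cos(np.pi * self.t / self.total_steps))
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * p.grad
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * p.grad**2
            m_hat = self.m[i] / (1 - self.b1**self.t)
            v_hat = self.v[i] / (1 - self.b2**self.t)
            p.data -= lr * m_hat / (np.sqrt(v_hat) + self.eps)


# ---------------------------------------------------------------------------
# training loop
# ---------------------------------------------------------------------------

def _clip_gradients(state: ModelState, max_norm: float) -> None:
    total = np.sqrt(
        sum(float((p.grad**2).sum()) for p in state.values() if p.grad is not None)
    )
    if total > max_norm:
        scale = max_norm / total
        for p in state.values():
            if p.grad is not None:
                p.grad *= scale

def train(
    model: MicrobeDiseaseGraphModel,
    train_config: TrainConfig,
    callback=None,
) -> tuple[ModelState, list[float]]:
    """Fit the model on its (possibly masked) adjacency.

    Returns the final parameter state and the per-epoch total-loss
    trajectory. Deterministic for fixed model/training seeds on one
    platform. Raises ``RuntimeError`` on a NaN loss.
    """
    _, features, norm_adj, adj_mask = model.build_graph()
    adjacency = model.adjacency
    labels_full = adjacency.values.astype(np.float64)
    nm = adjacency.n_microbes
    config = model.config

    rng = np.random.default_rng([model.config.seed, train_config.seed])
    state = init_state(config, features.shape[1], rng)
    optimizer = _Adam(
        state.parameters(), train_config.learning_rate, train_config.epochs
    )

    pos = np.argwhere(labels_full == 1)
    neg = np.argwhere(labels_full == 0)
    losses: list[float] = []
    for epoch in range(train_config.epochs):
        scores, _ = forward(
            features, norm_adj, adj_mask, nm, config, state, rng=rng, training=True
        )
        if train_config.negative_mode == "all":
            loss_ce = _cross_entropy_tensor(labels_full, scores)
        else:
            pick = rng.choice(len(neg), size=min(len(pos), len(neg)), replace=False)
            sel = np.concatenate([pos, neg[pick]])
            y_sel = labels_full[sel[:, 0], sel[:, 1]]
            p_sel = scores[(sel[:, 0], sel[:, 1])]
            loss_ce = _cross_entropy_tensor(y_sel, p_sel)
        loss = loss_ce + train_config.l2_lambda * _l2_tensor(state)
        value = float(loss.data)
        if not np.isfinite(value):
            raise RuntimeError(
                f"training diverged: loss={value} at epoch {epoch} "
                f"(lr={train_config.learning_rate}, l2={train_config.l2_lambda})"
            )
        losses.append(value)
        state.zero_grad()
        loss.backward()
        if train_config.grad_clip > 0:
            _clip_gradients(state, train_config.grad_clip)
        optimizer.step()
        if callback is not None:
            callback(epoch, value)
    return state, losses


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def confusion(labels, predictions, threshold: float = 0.5) -> tuple[int, int, int, int]:
    """(TP, FP, TN, FN) with predictions >= threshold called positive."""
    y = np.asarray(labels).ravel().astype(bool)
    yhat = np.asarray(predictions).ravel() >= threshold
    tp = int(np.sum(y & yhat))
    fp = int(np.sum(~y & yhat))
    tn = int(np.sum(~y & ~yhat))
    fn = int(np.sum(y & ~yhat))
    return tp, fp, tn, fn


def _ratio(num: int, den: int, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name}: zero denominator; returning 0")
        return 0.0
    return num / den


def accuracy(counts: tuple[int, int, int, int]) -> float:
    tp, fp, tn, fn = counts
    return _ratio(tp + tn, tp + fp + tn + fn, "accuracy")


def specificity(counts: tuple[int, int, int, int]) -> float:
    tp, fp, tn, fn = counts
    return _ratio(tn, fp + tn, "specificity")


def tpr(counts: tuple[int, int, int, int]) -> float:
    tp, fp, tn, fn = counts
    return _ratio(tp, tp + fn, "TPR")


def fpr(counts: tuple[int, int, int, int]) -> float:
    tp, fp, tn, fn = counts
    return _ratio(fp, fp + tn, "FPR")


def auc(labels, scores) -> float:
    """Rank-based (Mann-Whitney) AUC with ties counted one half.

    Equals the trapezoidal area under the ROC curve over all
    thresholds. Raises on single-class input.
    """
    y = np.asarray(labels).ravel().astype(bool)
    s = np.asarray(scores, dtype=np.float64).ravel()
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC requires both classes present")
    ranks = rankdata(s)
    return float((ranks[y].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def roc_curve(labels, scores) -> tuple[np.ndarray, np.ndarray]:
    """(FPR, TPR) points over all score thresholds, descending."""
    y = np.asarray(labels).ravel().astype(bool)
    s = np.asarray(scores, dtype=np.float64).ravel()
    order = np.argsort(-s, kind="mergesort")
    y = y[order]
    tps = np.cumsum(y)
    fps = np.cumsum(~y)
    tpr_pts = np.concatenate([[0.0], tps / max(tps[-1], 1)])
    fpr_pts = np.concatenate([[0.0], fps / max(fps[-1], 1)])
    return fpr_pts, tpr_pts


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------

@dataclass
class FoldSplit:
    """One CV fold: held-out positives and the masked training adjacency."""

    train_positive: set[tuple[int, int]]
    test_positive: set[tuple[int, int]]
    masked_adjacency: AssociationMatrix


def make_folds(
    adjacency: AssociationMatrix, folds: int, seed: int
) -> list[FoldSplit]:
    """Shuffle the known positives and partition them into ``folds`` test
    sets; each split's adjacency has exactly its test positives zeroed."""
    positives = [tuple(p) for p in np.argwhere(adjacency.values == 1)]
    if folds > len(positives):
        raise ValueError(f"{folds} folds but only {len(positives)} positives")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(positives))
    splits: list[FoldSplit] = []
    for chunk in np.array_split(order, folds):
        test = {positives[i] for i in chunk}
        train_pos = {p for p in positives if p not in test}
        splits.append(FoldSplit(train_pos, test, adjacency.masked(test)))
    return splits


@dataclass
class EvalReport:
    """Per-fold and aggregate cross-validation metrics."""

    records: pd.DataFrame = field(repr=False)
    roc_points: list[tuple[np.ndarray, np.ndarray]] = field(default_factory=list, repr=False)
    loss_logs: list[list[float]] = field(default_factory=list, repr=False)

    def mean(self, metric: str = "auc") -> float:
        return float(self.records[metric].mean())

    def std(self, metric: str = "auc") -> float:
        return float(self.records[metric].std(ddof=0))

    def to_frame(self) -> pd.DataFrame:
        return self.records.copy()

    def plot_roc(self, path) -> None:
        """Write per-fold ROC curves as a PNG (requires matplotlib)."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(5, 5))
        for k, (fpr_pts, tpr_pts) in enumerate(self.roc_points):
            ax.plot(fpr_pts, tpr_pts, lw=1, alpha=0.8, label=f"eval {k}")
        ax.plot([0, 1], [0, 1], "k--", lw=0.8)
        ax.set_xlabel("false positive rate")
        ax.set_ylabel("true positive rate")
        ax.set_title(f"ROC (mean AUC {self.mean('auc'):.3f})")
        if len(self.roc_points) <= 10:
            ax.legend(fontsize=7)
        fig.tight_layout()
        fig.savefig(path, dpi=120)
        plt.close(fig)

    def summary(self) -> str:
        lines = ["Cross-validation report", "=" * 42]
        lines.append(
            f"{len(self.records)} evaluations "
            f"({self.records['repeat'].nunique()} repeats x "
            f"{self.records['fold'].nunique()} folds)"
        )
        for metric in ("auc", "accuracy", "specificity"):
            lines.append(
                f"{metric:12s} {self.mean(metric):.4f} +/- {self.std(metric):.4f}"
            )
        return "\n".join(lines)


def _evaluate_fold(
    scores: np.ndarray,
    full_adjacency: AssociationMatrix,
    test_positive: set[tuple[int, int]],
    threshold: float,
) -> tuple[dict, tuple[np.ndarray, np.ndarray]]:
    """Score test positives against all pairs unknown in the full data."""
    unknown = np.argwhere(full_adjacency.values == 0)
    test = np.array(sorted(test_positive))
    eval_pairs = np.vstack([test, unknown])
    y = np.concatenate([np.ones(len(test)), np.zeros(len(unknown))])
    s = scores[eval_pairs[:, 0], eval_pairs[:, 1]]
    counts = confusion(y, s, threshold)
    record = {
        "auc": auc(y, s),
        "accuracy": accuracy(counts),
        "specificity": specificity(counts),
        "n_test_pos": len(test),
        "n_neg": len(unknown),
    }
    return record, roc_curve(y, s)


def cross_validate(
    adjacency: AssociationMatrix,
    model_config: ModelConfig,
    train_config: TrainConfig,
    gene_map=None,
    gene_net=None,
    dag=None,
) -> EvalReport:
    """Repeated k-fold cross-validation over the known positives.

    For every repeat and fold, the similarity matrices and the
    heterogeneous network are rebuilt from the masked adjacency, a
    fresh model is trained, and the held-out positives are ranked
    against all unknown pairs.
    """
    rows, rocs, logs = [], [], []
    for repeat in range(train_config.repeats):
        fold_seed = int(np.random.default_rng([train_config.seed, repeat]).integers(2**31))
        for fold_id, split in enumerate(
            make_folds(adjacency, train_config.folds, fold_seed)
        ):
            model = MicrobeDiseaseGraphModel(
                split.masked_adjacency,
                gene_map=gene_map,
                gene_net=gene_net,
                dag=dag,
                config=model_config,
            )
            state, losses = train(model, train_config)
            scores = model.predict(state)
            record, roc = _evaluate_fold(
                scores, adjacency, split.test_positive, train_config.threshold
            )
            record.update({"repeat": repeat, "fold": fold_id})
            rows.append(record)
            rocs.append(roc)
            logs.append(losses)
    return EvalReport(pd.DataFrame(rows), rocs, logs)


def run_ablations(
    adjacency: AssociationMatrix,
    model_config: ModelConfig,
    train_config: TrainConfig,
    gene_map=None,
    gene_net=None,
    dag=None,
) -> pd.DataFrame:
    """Cross-validate the full model and each single-ablation variant
    under identical seeds; returns one row per variant."""
    from dataclasses import replace

    variants = {
        "full": frozenset(),
        "-GCN": frozenset({"no_gcn"}),
        "-GAT": frozenset({"no_gat"}),
        "-BiLSTM": frozenset({"no_lstm"}),
    }
    rows = []
    for name, ablation in variants.items():
        cfg = replace(model_config, ablation=ablation)
        report = cross_validate(
            adjacency, cfg, train_config, gene_map=gene_map, gene_net=gene_net, dag=dag
        )
        rows.append(
            {
                "variant": name,
                "auc_mean": report.mean("auc"),
                "auc_std": report.std("auc"),
                "accuracy_mean": report.mean("accuracy"),
                "specificity_mean": report.mean("specificity"),
            }
        )
    return pd.DataFrame(rows)
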