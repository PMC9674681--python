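"""One-class training, anomaly scoring, AUC evaluation, and CV experiments.

The protocol: train on *normal graphs only* so the model captures the
normal-graph representation distribution; at test time, score every graph by
the error between its own representations and those of its re-encoded
reconstruction.  Graphs the model never learned to reconstruct — the
anomalies — receive bigger errors, and AUC measures how well that raw score
ranks anomalies above normals.  There is no thresholding: the method emits
scores and AUC only.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.metrics import roc_auc_score

from .autodiff import Tensor
from .data_io import BatchedGraphs, FoldSplit, Graph, GraphDataset, pad_and_batch, split_folds
from .losses import ABLATABLE, LossBreakdown, contrastive_loss, error_loss, reconstruction_loss, total_loss
from .model import ModelState, forward, init_model

__all__ = [
    "TrainConfig",
    "ScoreReport",
    "Adam",
    "train",
    "anomaly_score",
    "score_dataset",
    "evaluate_auc",
    "run_holdout_experiment",
    "run_cv_experiment",
]


@dataclass
class TrainConfig:
    """Hyperparameters of one training run.

    Defaults follow the reference setting: Adam at learning rate 1e-4,
    batch size 300, 100 epochs, encoder widths d-256-128 (decoder mirrored),
    perturbation coefficient eta = 1 and temperature tau = 0.2.
    """

    learning_rate: float = 1e-4
    batch_size: int = 300
    epochs: int = 100
    eta: float = 1.0
    tau: float = 0.2
    encoder_dims: tuple[int, ...] = (256, 128)
    proj_dim: int = 128
    seed: int = 0
    ablation: frozenset = field(default_factory=frozenset)
    negatives: str = "perturbed"
    sigma_override: float | None = None
    activation: str = "relu"
    optimizer_name: str = "adam"

    def __post_init__(self):
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.batch_size < 2:
            raise ValueError("batch_size must be >= 2 (contrastive loss needs pairs)")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        unknown = set(self.ablation) - ABLATABLE
        if unknown:
            raise ValueError(f"unknown ablation flags {sorted(unknown)}")
        if self.optimizer_name not in ("adam", "sgd"):
            raise ValueError(f"unknown optimizer {self.optimizer_name!r}")

    def as_dict(self) -> dict:
        d = self.__dict__.copy()
        d["encoder_dims"] = list(self.encoder_dims)
        d["ablation"] = sorted(self.ablation)
        return d


@dataclass
class ScoreReport:
    """Per-graph anomaly scores for one held-out fold, plus the fold AUC."""

    records: list[tuple[int, int, float]]  # (graph_id, label, score)
    auc: float
    fold_index: int
    seed: int


class Adam:
    """Adaptive-moment gradient descent over a list of parameter tensors."""

    def __init__(self, params: list[Tensor], lr: float,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            m_hat = self.m[i] / (1 - self.b1**self.t)
            v_hat = self.v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)


class _SGD:
    def __init__(self, params: list[Tensor], lr: float):
        self.params, self.lr = params, lr

    def step(self) -> None:
        for p in self.params:
            if p.grad is not None:
                p.data -= self.lr * p.grad


def _batch_losses(batch: BatchedGraphs, state: ModelState, config: TrainConfig,
                  rng) -> tuple[Tensor, LossBreakdown]:
    out = forward(batch, state, rng=rng,
                  with_perturbed="cl" not in config.ablation)
    l1 = reconstruction_loss(batch.adjacency_stack, out["a_hat"],
                             batch.feature_stack, out["x_hat"], batch.node_mask)
    l2 = None
    if "cl" not in config.ablation:
        l2 = contrastive_loss(out["z_proj"], out["zh_proj"], config.tau,
                              negatives=config.negatives)
    l_node, l_graph, _ = error_loss(out["z_node"], out["zr_node"],
                                    out["z_g"], out["zr_g"], batch.node_mask)
    lt = total_loss(l1, l2, l_node, l_graph, config.ablation)
    breakdown = LossBreakdown(
        l_recon=l1.item(),
        l_contrast=l2.item() if l2 is not None else 0.0,
        l_node=l_node.item(), l_graph=l_graph.item(),
        l_total=lt.item(), ablation=frozenset(config.ablation))
    return lt, breakdown


def train(train_dataset: GraphDataset, config: TrainConfig,
          max_nodes: int | None = None) -> tuple[ModelState, list[LossBreakdown]]:
    """Fit the model on a normal-only graph set.

    ``max_nodes`` should be the *full* dataset's maximum node count when the
    model will later score held-out graphs, so train and test batches share
    padding geometry.  Returns the final state and one mean LossBreakdown
    per epoch.  Fully deterministic under ``config.seed``.
    """
    if any(g.label != 0 for g in train_dataset):
        raise ValueError("one-class protocol violated: anomalous graph in training set")
    if len(train_dataset) < 2:
        raise ValueError("need at least 2 training graphs")
    if train_dataset.feature_dim < 1:
        raise ValueError("dataset has no node features; attach degree features first")
    M = max_nodes if max_nodes is not None else train_dataset.max_nodes
    state = init_model(train_dataset.feature_dim,
                       encoder_dims=config.encoder_dims,
                       proj_dim=config.proj_dim, eta=config.eta,
                       seed=config.seed, activation=config.activation,
                       sigma_override=config.sigma_override)
    state.config["train"] = config.as_dict()
    params = state.parameters()
    opt = (Adam(params, config.learning_rate) if config.optimizer_name == "adam"
           else _SGD(params, config.learning_rate))
    rng = np.random.default_rng(config.seed)
    graphs = list(train_dataset.graphs)
    history: list[LossBreakdown] = []
    for _ in range(config.epochs):
        order = rng.permutation(len(graphs))
        epoch_parts: list[LossBreakdown] = []
        for start in range(0, len(order), config.batch_size):
            idx = order[start:start + config.batch_size]
            if len(idx) < 2:
                continue  # a singleton batch has no contrastive negatives
            batch = pad_and_batch([graphs[i] for i in idx], M)
            lt, breakdown = _batch_losses(batch, state, config, rng)
            state.zero_grad()
            lt.backward()
            opt.step()
            epoch_parts.append(breakdown)
        if not epoch_parts:
            raise ValueError("no usable minibatch (all batches of size < 2)")
        history.append(LossBreakdown(
            l_recon=float(np.mean([b.l_recon for b in epoch_parts])),
            l_contrast=float(np.mean([b.l_contrast for b in epoch_parts])),
            l_node=float(np.mean([b.l_node for b in epoch_parts])),
            l_graph=float(np.mean([b.l_graph for b in epoch_parts])),
            l_total=float(np.mean([b.l_total for b in epoch_parts])),
            ablation=frozenset(config.ablation)))
    return state, history


def anomaly_score(graph: Graph, state: ModelState,
                  max_nodes: int | None = None) -> float:
    """Representation-error anomaly score of one graph (higher = more anomalous).

    Mean over nodes of the squared node-representation error plus the squared
    graph-representation error, computed with the unperturbed shared encoder
    only — scoring is deterministic given the trained state.
    """
    return float(score_dataset(GraphDataset([graph]), state,
                               max_nodes=max_nodes)[0])


def score_dataset(dataset: GraphDataset, state: ModelState,
                  max_nodes: int | None = None,
                  batch_size: int = 256) -> np.ndarray:
    """Vector of anomaly scores for every graph, in dataset order."""
    if dataset.feature_dim != state.feature_dim:
        raise ValueError(f"feature_dim mismatch: dataset {dataset.feature_dim} "
                         f"vs model {state.feature_dim}")
    M = max_nodes if max_nodes is not None else dataset.max_nodes
    scores = []
    graphs = dataset.graphs
    for start in range(0, len(graphs), batch_size):
        batch = pad_and_batch(graphs[start:start + batch_size], M)
        out = forward(batch, state, with_perturbed=False)
        m = batch.node_mask
        ndiff = (out["z_node"].data - out["zr_node"].data) * m[..., None]
        node_term = (ndiff**2).sum(axis=(-1, -2)) / m.sum(axis=-1)
        gdiff = out["z_g"].data - out["zr_g"].data
        scores.append(node_term + (gdiff**2).sum(axis=-1))
    return np.concatenate(scores)


def evaluate_auc(records) -> float:
    """Area under the ROC curve of score as a ranking statistic for label 1.

    ``records`` is an iterable of (label, score) pairs; ties follow the
    midrank convention (rank-sum equivalence).  Both classes must appear.
    """
    pairs = list(records)
    labels = np.array([int(l) for l, _ in pairs])
    scores = np.array([float(s) for _, s in pairs])
    if len(np.unique(labels)) < 2:
        raise ValueError("AUC undefined: only one class present")
    return float(roc_auc_score(labels, scores))


def _score_fold(dataset: GraphDataset, fold: FoldSplit, config: TrainConfig,
                seed: int) -> ScoreReport:
    cfg = replace(config, seed=seed)
    train_set = dataset.subset(fold.train_ids)
    assert all(g.label == 0 for g in train_set), "training fold contains an anomaly"
    state, _ = train(train_set, cfg, max_nodes=dataset.max_nodes)
    test_set = dataset.subset(fold.test_ids)
    scores = score_dataset(test_set, state, max_nodes=dataset.max_nodes)
    records = [(g.graph_id, g.label, float(s))
               for g, s in zip(test_set.graphs, scores)]
    auc = evaluate_auc([(l, s) for _, l, s in records])
    return ScoreReport(records=records, auc=auc, fold_index=fold.fold_index,
                       seed=seed)


def run_holdout_experiment(dataset: GraphDataset, config: TrainConfig,
                           k: int = 5, fold_index: int = 0) -> ScoreReport:
    """Train on the normal graphs outside one stratified fold, score that fold."""
    folds = split_folds(dataset, k, config.seed)
    return _score_fold(dataset, folds[fold_index], config, config.seed)


def run_cv_experiment(dataset: GraphDataset, config: TrainConfig,
                      k: int = 5, n_repeats: int = 1
                      ) -> tuple[list[ScoreReport], dict]:
    """k-fold cross-validated evaluation, repeated with shifted seeds.

    Each repeat reshuffles the folds *and* reseeds initialization (seed =
    config.seed + repeat).  Anomalies are removed from every training fold.
    Returns all fold reports and a summary with mean and std AUC.
    """
    if len(np.unique(dataset.labels)) < 2:
        raise ValueError("cross-validated AUC needs both classes in the dataset")
    reports: list[ScoreReport] = []
    for rep in range(n_repeats):
        seed = config.seed + rep
        for fold in split_folds(dataset, k, seed):
            reports.append(_score_fold(dataset, fold, config, seed))
    aucs = np.array([r.auc for r in reports])
    summary = {"mean_auc": float(aucs.mean()), "std_auc": float(aucs.std()),
               "n_folds": k, "n_repeats": n_repeats,
               "aucs": [float(a) for a in aucs]}
    return reports, summary
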