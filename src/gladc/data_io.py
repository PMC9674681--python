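"""Graph-set containers, TUDataset-layout I/O, batching, and CV splits.

A *graph set* is an ordered collection of small undirected graphs, each with
a symmetric hollow 0/1 adjacency matrix, a node-feature matrix, and a binary
anomaly label (0 = normal, 1 = anomalous).  Datasets arrive in the de-facto
standard multi-file plain-text layout used by the public graph-classification
repositories: ``<name>_A.txt`` (comma-separated 1-based edge pairs),
``<name>_graph_indicator.txt`` (1-based graph id per node),
``<name>_graph_labels.txt``, and optionally ``<name>_node_attributes.txt``
and ``<name>_node_labels.txt``.

Training is one-class: anomalous graphs are removed from every training fold
while held-out folds keep both classes, so ranking quality (AUC) is
measurable on each test fold.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "Graph",
    "GraphDataset",
    "BatchedGraphs",
    "FoldSplit",
    "TUFormatError",
    "read_tudataset",
    "write_tudataset",
    "degree_features",
    "pad_and_batch",
    "split_folds",
]


class TUFormatError(ValueError):
    """A mandatory file is missing or the files are mutually inconsistent."""


@dataclass
class Graph:
    """One undirected graph with node features and a binary anomaly label."""

    adjacency: np.ndarray  # (n, n) symmetric 0/1, zero diagonal
    features: np.ndarray   # (n, d)
    label: int             # 0 normal, 1 anomalous
    graph_id: int

    def __post_init__(self):
        self.adjacency = np.asarray(self.adjacency, dtype=np.float64)
        self.features = np.asarray(self.features, dtype=np.float64)
        a = self.adjacency
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError("adjacency must be square")
        if not np.array_equal(a, a.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(a) != 0):
            raise ValueError("adjacency must have a zero diagonal (no self-loops)")
        if self.features.ndim != 2 or self.features.shape[0] != a.shape[0]:
            raise ValueError("features must have one row per node")
        if self.label not in (0, 1):
            raise ValueError("label must be 0 (normal) or 1 (anomalous)")

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2

    def degrees(self) -> np.ndarray:
        return self.adjacency.sum(axis=1).astype(int)


@dataclass
class GraphDataset:
    """Ordered list of graphs sharing one feature dimensionality."""

    graphs: list[Graph]
    name: str = "dataset"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        dims = {g.features.shape[1] for g in self.graphs}
        if len(dims) > 1:
            raise ValueError(f"graphs disagree on feature_dim: {sorted(dims)}")

    @property
    def feature_dim(self) -> int:
        return self.graphs[0].features.shape[1] if self.graphs else 0

    @property
    def max_nodes(self) -> int:
        return max(g.n_nodes for g in self.graphs) if self.graphs else 0

    @property
    def labels(self) -> np.ndarray:
        return np.array([g.label for g in self.graphs], dtype=int)

    def __len__(self) -> int:
        return len(self.graphs)

    def __iter__(self):
        return iter(self.graphs)

    def subset(self, graph_ids: Iterable[int]) -> "GraphDataset":
        by_id = {g.graph_id: g for g in self.graphs}
        return GraphDataset([by_id[i] for i in graph_ids], name=self.name,
                            metadata=dict(self.metadata))


@dataclass
class BatchedGraphs:
    """Zero-padded stacks of adjacency/feature matrices with validity masks."""

    adjacency_stack: np.ndarray  # (B, M, M)
    feature_stack: np.ndarray    # (B, M, d)
    node_mask: np.ndarray        # (B, M) 0/1
    labels: np.ndarray           # (B,)
    graph_ids: np.ndarray        # (B,)

    @property
    def n_graphs(self) -> int:
        return self.adjacency_stack.shape[0]

    @property
    def n_nodes_per_graph(self) -> np.ndarray:
        return self.node_mask.sum(axis=1).astype(int)

    def unbatch(self) -> list[Graph]:
        out = []
        for i in range(self.n_graphs):
            n = int(self.node_mask[i].sum())
            out.append(Graph(self.adjacency_stack[i, :n, :n].copy(),
                             self.feature_stack[i, :n].copy(),
                             int(self.labels[i]), int(self.graph_ids[i])))
        return out


@dataclass
class FoldSplit:
    """One cross-validation fold: anomaly-free training ids, mixed test ids."""

    fold_index: int
    train_ids: list[int]
    test_ids: list[int]


def _read_int_lines(path: str) -> list[int]:
    with open(path) as fh:
        return [int(float(line.strip())) for line in fh if line.strip()]


def read_tudataset(
    directory_path: str,
    dataset_name: str,
    anomaly_classes: Iterable[int] | Mapping[int, int] | None = None,
) -> GraphDataset:
    """Read a graph set from the multi-file plain-text layout.

    Parameters
    ----------
    anomaly_classes
        Either an iterable of raw graph labels to flag as anomalous (1), a
        full mapping raw label -> {0, 1}, or None.  None is only valid when
        the raw labels are already {0, 1}; otherwise the caller must say
        which class is the anomaly — the convention varies per dataset.
    """
    def p(suffix: str) -> str:
        return os.path.join(directory_path, f"{dataset_name}{suffix}")

    for suffix in ("_A.txt", "_graph_indicator.txt", "_graph_labels.txt"):
        if not os.path.exists(p(suffix)):
            raise TUFormatError(f"missing mandatory file {dataset_name}{suffix}")

    indicator = _read_int_lines(p("_graph_indicator.txt"))
    raw_labels = _read_int_lines(p("_graph_labels.txt"))
    n_graphs = len(raw_labels)
    if n_graphs == 0:
        raise TUFormatError("empty graph label file")
    if indicator and (min(indicator) < 1 or max(indicator) > n_graphs):
        raise TUFormatError("graph_indicator references a nonexistent graph")

    # node bookkeeping: global 1-based node id -> (graph index, local index)
    counts = np.zeros(n_graphs, dtype=int)
    local_index = np.empty(len(indicator), dtype=int)
    owner = np.asarray(indicator, dtype=int) - 1
    for v, g in enumerate(owner):
        local_index[v] = counts[g]
        counts[g] += 1

    adjs = [np.zeros((c, c)) for c in counts]
    with open(p("_A.txt")) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            try:
                a, b = (int(float(t)) for t in line.split(","))
            except ValueError as exc:
                raise TUFormatError(f"_A.txt line {lineno}: {line!r}") from exc
            u, v = a - 1, b - 1
            if not (0 <= u < len(owner) and 0 <= v < len(owner)):
                raise TUFormatError(f"_A.txt line {lineno}: node id out of range")
            if owner[u] != owner[v]:
                raise TUFormatError(
                    f"_A.txt line {lineno}: edge crosses graphs "
                    f"{owner[u] + 1} and {owner[v] + 1}")
            if u == v:
                continue  # stored self-loops are dropped; added only inside the encoder
            g = owner[u]
            adjs[g][local_index[u], local_index[v]] = 1.0
            adjs[g][local_index[v], local_index[u]] = 1.0  # OR-symmetrize

    # features: native attributes > one-hot node labels > empty (d = 0)
    feats: list[np.ndarray]
    if os.path.exists(p("_node_attributes.txt")):
        rows = []
        with open(p("_node_attributes.txt")) as fh:
            for line in fh:
                if line.strip():
                    rows.append([float(t) for t in line.strip().split(",")])
        mat = np.asarray(rows, dtype=np.float64)
        if mat.shape[0] != len(owner):
            raise TUFormatError("node_attributes row count != node count")
        feats = [mat[owner == g] for g in range(n_graphs)]
    elif os.path.exists(p("_node_labels.txt")):
        nl = np.asarray(_read_int_lines(p("_node_labels.txt")), dtype=int)
        if nl.shape[0] != len(owner):
            raise TUFormatError("node_labels row count != node count")
        values = np.unique(nl)
        onehot = (nl[:, None] == values[None, :]).astype(np.float64)
        feats = [onehot[owner == g] for g in range(n_graphs)]
    else:
        feats = [np.zeros((c, 0)) for c in counts]

    if anomaly_classes is None:
        mapping = {0: 0, 1: 1}
    elif isinstance(anomaly_classes, Mapping):
        mapping = {int(k): int(v) for k, v in anomaly_classes.items()}
    else:
        flagged = {int(c) for c in anomaly_classes}
        mapping = {int(r): int(int(r) in flagged) for r in set(raw_labels)}
    try:
        labels = [mapping[r] for r in raw_labels]
    except KeyError as exc:
        raise TUFormatError(
            f"raw graph label {exc.args[0]} has no anomaly mapping; "
            "pass anomaly_classes") from exc

    graphs = [Graph(adjs[g], feats[g], labels[g], graph_id=g)
              for g in range(n_graphs)]
    return GraphDataset(graphs, name=dataset_name)


def write_tudataset(dataset: GraphDataset, directory_path: str, name: str) -> None:
    """Write a graph set in the same multi-file layout (1-based indices).

    Inverse of :func:`read_tudataset` up to node ordering; used by tests and
    by the synthetic module's export.
    """
    if len(dataset) == 0:
        raise ValueError("refusing to export an empty dataset")
    os.makedirs(directory_path, exist_ok=True)

    def p(suffix: str) -> str:
        return os.path.join(directory_path, f"{name}{suffix}")

    offsets = np.cumsum([0] + [g.n_nodes for g in dataset.graphs])
    with open(p("_A.txt"), "w") as fa:
        for gi, g in enumerate(dataset.graphs):
            us, vs = np.nonzero(np.triu(g.adjacency))
            for u, v in zip(us, vs):
                base = offsets[gi] + 1
                fa.write(f"{base + u}, {base + v}\n")
                fa.write(f"{base + v}, {base + u}\n")
    with open(p("_graph_indicator.txt"), "w") as fi:
        for gi, g in enumerate(dataset.graphs, start=1):
            fi.write(f"{gi}\n" * g.n_nodes)
    with open(p("_graph_labels.txt"), "w") as fl:
        for g in dataset.graphs:
            fl.write(f"{g.label}\n")
    if dataset.feature_dim > 0:
        with open(p("_node_attributes.txt"), "w") as ff:
            for g in dataset.graphs:
                for row in g.features:
                    ff.write(", ".join(repr(float(x)) for x in row) + "\n")


def degree_features(dataset: GraphDataset, encoding: str = "onehot",
                    force: bool = False) -> GraphDataset:
    """Attach degree-derived node features to a plain graph set.

    ``onehot`` gives each node the indicator of its degree in a width of
    (dataset-wide max degree + 1); ``scalar`` gives the raw degree as a
    single column.  Applies only when the dataset has no native features
    unless ``force`` is set.
    """
    if encoding not in ("onehot", "scalar"):
        raise ValueError(f"unknown encoding {encoding!r}")
    if dataset.feature_dim > 0 and not force:
        return dataset
    max_deg = max(int(g.degrees().max(initial=0)) for g in dataset.graphs)
    graphs = []
    for g in dataset.graphs:
        deg = g.degrees()
        if encoding == "onehot":
            feats = np.zeros((g.n_nodes, max_deg + 1))
            feats[np.arange(g.n_nodes), deg] = 1.0
        else:
            feats = deg[:, None].astype(np.float64)
        graphs.append(Graph(g.adjacency, feats, g.label, g.graph_id))
    meta = dict(dataset.metadata)
    meta["degree_encoding"] = encoding
    return GraphDataset(graphs, name=dataset.name, metadata=meta)


def pad_and_batch(graphs: Sequence[Graph], max_nodes: int) -> BatchedGraphs:
    """Stack graphs into zero-padded (B, M, ·) arrays with node masks."""
    for g in graphs:
        if g.n_nodes > max_nodes:
            raise ValueError(
                f"graph {g.graph_id} has {g.n_nodes} nodes > max_nodes={max_nodes}")
    B, M = len(graphs), max_nodes
    d = graphs[0].features.shape[1] if graphs else 0
    A = np.zeros((B, M, M))
    X = np.zeros((B, M, d))
    mask = np.zeros((B, M))
    for i, g in enumerate(graphs):
        n = g.n_nodes
        A[i, :n, :n] = g.adjacency
        X[i, :n] = g.features
        mask[i, :n] = 1.0
    return BatchedGraphs(A, X, mask,
                         labels=np.array([g.label for g in graphs], dtype=int),
                         graph_ids=np.array([g.graph_id for g in graphs], dtype=int))


def split_folds(dataset: GraphDataset, k: int, seed: int) -> list[FoldSplit]:
    """Stratified k-fold split with anomalies removed from every training side.

    Each held-out fold keeps both classes (so AUC is defined there); the
    complementary training folds keep only their normal graphs.
    """
    if k < 2:
        raise ValueError("k must be at least 2")
    if len(dataset) < k:
        raise ValueError(f"cannot make {k} folds from {len(dataset)} graphs")
    rng = np.random.default_rng(seed)
    labels = dataset.labels
    ids = np.array([g.graph_id for g in dataset.graphs])
    fold_of = np.empty(len(dataset), dtype=int)
    for cls in np.unique(labels):
        members = np.flatnonzero(labels == cls)
        rng.shuffle(members)
        fold_of[members] = np.arange(len(members)) % k
    splits = []
    for f in range(k):
        test = fold_of == f
        if not test.any():
            raise ValueError(f"fold {f} would have zero test graphs")
        train = ~test & (labels == 0)
        splits.append(FoldSplit(f, [int(i) for i in ids[train]],
                                [int(i) for i in ids[test]]))
    return splits
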