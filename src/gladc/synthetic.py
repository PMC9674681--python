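"""Seeded graph-set benchmarks with planted graph-level anomalies.

Two families are provided:

* **Motif sets** — every normal graph is a small ring and a large ring joined
  by bridge edges (the classic two-ring molecular surrogate).  *Local*
  anomalies rewire all links of one large-ring node, destroying the
  large-ring pattern while keeping the node count; *global* anomalies attach
  two extra nodes, changing the whole-graph pattern; *attribute* anomalies
  keep the normal topology but draw node features from a mean-shifted
  distribution.
* **Erdős–Rényi contrast sets** — normal and anomalous graphs drawn from
  G(n, p) at two different edge densities, a continuous-control benchmark.

These are structural surrogates only: no valence rules, atom types, or other
chemistry is emulated.  All generation is a pure function of the seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_io import Graph, GraphDataset, degree_features, write_tudataset

__all__ = [
    "MotifSpec",
    "SyntheticConfig",
    "generate_motif_set",
    "generate_er_contrast_set",
    "export_tudataset",
]

#: feature width for attribute-anomaly sets (features ~ N(mu, 1) per dim)
ATTRIBUTE_DIM = 4


@dataclass
class MotifSpec:
    """Shape of the normal two-ring motif."""

    small_ring: int = 3
    large_ring: int = 4
    bridge_edges: int = 1

    def __post_init__(self):
        if self.small_ring < 3 or self.large_ring < 3:
            raise ValueError("ring sizes must be at least 3")
        if not (1 <= self.bridge_edges <= self.small_ring * self.large_ring):
            raise ValueError("bridge_edges out of range")


@dataclass
class SyntheticConfig:
    """How many graphs to plant and what kind of anomaly."""

    n_normal: int
    n_anomalous: int = 0
    anomaly_type: str = "local"  # local | global | attribute | mixed
    jitter: float = 0.0          # P(one benign extra chord) in normal graphs
    mu_shift: float = 2.0        # feature mean shift for attribute anomalies
    seed: int = 0

    def __post_init__(self):
        if self.n_normal < 1 or self.n_anomalous < 0:
            raise ValueError("need n_normal >= 1 and n_anomalous >= 0")
        if self.anomaly_type not in ("local", "global", "attribute", "mixed"):
            raise ValueError(f"unknown anomaly_type {self.anomaly_type!r}")
        if not 0.0 <= self.jitter <= 1.0:
            raise ValueError("jitter must be a probability")


def _ring(adj: np.ndarray, nodes: list[int]) -> None:
    for a, b in zip(nodes, nodes[1:] + nodes[:1]):
        adj[a, b] = adj[b, a] = 1.0


def _normal_motif(spec: MotifSpec, rng: np.random.Generator,
                  jitter: float) -> np.ndarray:
    s, l = spec.small_ring, spec.large_ring
    n = s + l
    adj = np.zeros((n, n))
    _ring(adj, list(range(s)))
    _ring(adj, list(range(s, n)))
    # bridges join distinct (small, large) pairs; the first one is fixed so
    # every normal graph shares a backbone
    pairs = [(i, j) for i in range(s) for j in range(s, n)]
    chosen = [pairs[0]]
    if spec.bridge_edges > 1:
        extra = rng.choice(len(pairs) - 1, size=spec.bridge_edges - 1,
                           replace=False) + 1
        chosen += [pairs[e] for e in extra]
    for a, b in chosen:
        adj[a, b] = adj[b, a] = 1.0
    if jitter > 0 and rng.random() < jitter:
        free = np.argwhere(np.triu(adj == 0, k=1))
        if len(free):
            a, b = free[rng.integers(len(free))]
            adj[a, b] = adj[b, a] = 1.0
    return adj


def _plant_local(adj: np.ndarray, spec: MotifSpec,
                 rng: np.random.Generator) -> np.ndarray:
    """Rewire every link of one large-ring node onto the small ring.

    The victim is never a bridge endpoint, so the remaining large-ring path
    stays connected to the rest of the graph.
    """
    adj = adj.copy()
    s, n = spec.small_ring, adj.shape[0]
    large = [v for v in range(s, n) if not adj[v, :s].any()]
    v = int(rng.choice(large))
    adj[v, :] = 0.0
    adj[:, v] = 0.0
    targets = rng.choice(s, size=2, replace=False)
    for t in targets:
        adj[v, t] = adj[t, v] = 1.0
    return adj


def _plant_global(adj: np.ndarray, spec: MotifSpec,
                  rng: np.random.Generator) -> np.ndarray:
    """Attach a two-node pendant path to a random large-ring node."""
    n = adj.shape[0]
    out = np.zeros((n + 2, n + 2))
    out[:n, :n] = adj
    anchor = int(rng.integers(spec.small_ring, n))
    out[anchor, n] = out[n, anchor] = 1.0
    out[n, n + 1] = out[n + 1, n] = 1.0
    return out


def generate_motif_set(spec: MotifSpec, config: SyntheticConfig) -> GraphDataset:
    """Build a labeled two-ring motif benchmark, fully determined by the seed."""
    rng = np.random.default_rng(config.seed)
    # attribute / mixed sets carry Gaussian node features; pure structural
    # sets are plain graphs and get degree one-hots at the end
    attributed = config.anomaly_type in ("attribute", "mixed")
    graphs: list[Graph] = []

    def features(n: int, shifted: bool) -> np.ndarray:
        if not attributed:
            return np.zeros((n, 0))
        mu = config.mu_shift if shifted else 0.0
        return rng.normal(mu, 1.0, size=(n, ATTRIBUTE_DIM))

    for i in range(config.n_normal):
        adj = _normal_motif(spec, rng, config.jitter)
        graphs.append(Graph(adj, features(adj.shape[0], False), 0, graph_id=i))
    for j in range(config.n_anomalous):
        kind = config.anomaly_type
        if kind == "mixed":
            kind = ("local", "global", "attribute")[j % 3]
        base = _normal_motif(spec, rng, 0.0)
        if kind == "local":
            adj = _plant_local(base, spec, rng)
        elif kind == "global":
            adj = _plant_global(base, spec, rng)
        else:
            adj = base
        feats = features(adj.shape[0], shifted=(kind == "attribute"))
        graphs.append(Graph(adj, feats, 1, graph_id=config.n_normal + j))

    ds = GraphDataset(graphs, name="motif")
    if not attributed:
        ds = degree_features(ds, encoding="onehot")
    return ds


def generate_er_contrast_set(
    n_normal: int,
    n_anomalous: int,
    n_nodes: int,
    p_normal: float,
    p_anomalous: float,
    seed: int,
    degree_encoding: str = "scalar",
) -> GraphDataset:
    """Erdős–Rényi benchmark: two edge densities, degree-derived features.

    Features default to the *scalar* degree encoding: with a continuous
    density control the two classes must share feature support.  A one-hot
    encoding would let the densest (anomalous) graphs dictate the feature
    width and land on columns the one-class training never exercises, so
    the encoder would map them through untrained weights to near-zero
    representations and the error score would collapse — the benchmark
    would then measure feature-support leakage, not structural deviation.
    """
    if not (0.0 < p_normal < 1.0 and 0.0 < p_anomalous < 1.0):
        raise ValueError("edge probabilities must be in (0, 1)")
    if n_nodes < 3:
        raise ValueError("n_nodes must be at least 3")
    rng = np.random.default_rng(seed)

    def er(p: float) -> np.ndarray:
        upper = np.triu(rng.random((n_nodes, n_nodes)) < p, k=1)
        return (upper | upper.T).astype(np.float64)

    graphs = [Graph(er(p_normal), np.zeros((n_nodes, 0)), 0, graph_id=i)
              for i in range(n_normal)]
    graphs += [Graph(er(p_anomalous), np.zeros((n_nodes, 0)), 1,
                     graph_id=n_normal + j) for j in range(n_anomalous)]
    return degree_features(GraphDataset(graphs, name="er_contrast"),
                           encoding=degree_encoding)


def export_tudataset(dataset: GraphDataset, directory_path: str, name: str) -> None:
    """Write the dataset in the multi-file plain-text graph-set layout."""
    write_tudataset(dataset, directory_path, name)
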