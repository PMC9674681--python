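"""The four objective components and their unweighted sum.

* ``reconstruction_loss`` — per-graph squared Frobenius error of structure
  and attributes, averaged over the minibatch.  Diagonal adjacency entries
  are excluded (self-loops are not data) and padded entries never count.
* ``contrastive_loss`` — temperature-scaled cosine-similarity cross-entropy
  between each graph's plain and perturbed projected readouts, negatives
  drawn from the other graphs of the same minibatch.
* ``error_loss`` — mean squared distance between the input graph's
  representations and the re-encoded reconstruction's, at node level and at
  graph level.
* ``total_loss`` — the plain sum, minus whichever components an ablation
  disables (``cl``, ``node``, ``graph``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor, as_tensor, matmul

__all__ = [
    "LossBreakdown",
    "ABLATABLE",
    "reconstruction_loss",
    "contrastive_loss",
    "error_loss",
    "total_loss",
]

ABLATABLE = frozenset({"cl", "node", "graph"})


@dataclass
class LossBreakdown:
    """Scalar values of every loss component for one minibatch/epoch."""

    l_recon: float
    l_contrast: float
    l_node: float
    l_graph: float
    l_total: float
    ablation: frozenset = field(default_factory=frozenset)

    @property
    def l_error(self) -> float:
        return self.l_node + self.l_graph

    def as_dict(self) -> dict:
        return {"l_recon": self.l_recon, "l_contrast": self.l_contrast,
                "l_node": self.l_node, "l_graph": self.l_graph,
                "l_error": self.l_error, "l_total": self.l_total,
                "ablation": sorted(self.ablation)}


def reconstruction_loss(adjacency, a_hat, features, x_hat, mask) -> Tensor:
    """||A - A_hat||_F^2 + ||X - X_hat||_F^2 per graph, batch-averaged.

    Only masked-in, off-diagonal adjacency entries and masked-in feature
    rows contribute.
    """
    A = np.asarray(adjacency)
    X = np.asarray(features)
    m = np.asarray(mask)
    M = A.shape[-1]
    offdiag = (m[..., :, None] * m[..., None, :]) * (1.0 - np.eye(M))
    sdiff = (as_tensor(A) - as_tensor(a_hat)) * offdiag
    s_term = sdiff.power(2.0).sum(axis=(-1, -2))
    xdiff = (as_tensor(X) - as_tensor(x_hat)) * m[..., None]
    x_term = xdiff.power(2.0).sum(axis=(-1, -2))
    return (s_term + x_term).mean()


def _row_normalize(z: Tensor) -> Tensor:
    norms = z.power(2.0).sum(axis=-1, keepdims=True).sqrt()
    if np.any(norms.data == 0.0):
        raise ValueError("zero-norm projection vector: cosine similarity undefined")
    return z / norms


def contrastive_loss(z_proj, zh_proj, tau: float,
                     negatives: str = "perturbed") -> Tensor:
    """NT-Xent-style loss over a minibatch of N projected readout pairs.

    Anchor i is the plain view; the positive is its own perturbed view.  The
    N-1 negatives are the *other* graphs' perturbed views
    (``negatives="perturbed"``, following the textual description) or their
    plain views (``negatives="unperturbed"``, the printed-formula variant).
    The positive pair is excluded from the denominator, so the loss can go
    negative; it is not clamped.
    """
    if tau <= 0:
        raise ValueError("temperature must be positive")
    if negatives not in ("perturbed", "unperturbed"):
        raise ValueError(f"unknown negatives mode {negatives!r}")
    z = as_tensor(z_proj)
    zh = as_tensor(zh_proj)
    n = z.shape[0]
    if n < 2:
        raise ValueError("contrastive loss needs a minibatch of at least 2 graphs")
    zn = _row_normalize(z)
    zhn = _row_normalize(zh)
    cross = matmul(zn, zhn.transpose_last())          # sim(Z_i, Zh_j)
    eye = np.eye(n)
    pos = (cross * eye).sum(axis=-1)                  # sim(Z_i, Zh_i)
    neg_src = cross if negatives == "perturbed" else matmul(zn, zn.transpose_last())
    den = ((neg_src * (1.0 / tau)).exp() * (1.0 - eye)).sum(axis=-1)
    return (den.log() - pos * (1.0 / tau)).mean()


def error_loss(z_node, zr_node, z_g, zr_g, mask) -> tuple[Tensor, Tensor, Tensor]:
    """Node-level and graph-level representation-error losses and their sum.

    Node level: per graph, the mean over valid nodes of ||Z_i - Zr_i||^2;
    graph level: ||Z_G - Zr_G||^2; both averaged over the batch.
    """
    m = np.asarray(mask)
    n_nodes = m.sum(axis=-1)
    ndiff = (as_tensor(z_node) - as_tensor(zr_node)) * m[..., None]
    per_graph = ndiff.power(2.0).sum(axis=(-1, -2)) * (1.0 / n_nodes)
    l_node = per_graph.mean()
    gdiff = as_tensor(z_g) - as_tensor(zr_g)
    l_graph = gdiff.power(2.0).sum(axis=-1).mean()
    return l_node, l_graph, l_node + l_graph


def total_loss(l_recon: Tensor, l_contrast: Tensor | None,
               l_node: Tensor, l_graph: Tensor,
               ablation: frozenset = frozenset()) -> Tensor:
    """Unweighted sum of the enabled components (no tuning coefficients)."""
    unknown = set(ablation) - ABLATABLE
    if unknown:
        raise ValueError(f"unknown ablation flags {sorted(unknown)}; "
                         f"valid: {sorted(ABLATABLE)}")
    total = l_recon
    if "cl" not in ablation:
        if l_contrast is None:
            raise ValueError("contrastive term required unless ablated")
        total = total + l_contrast
    if "node" not in ablation:
        total = total + l_node
    if "graph" not in ablation:
        total = total + l_graph
    return total
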