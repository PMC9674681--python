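"""The dual graph-convolutional autoencoder with a perturbed twin encoder.

Architecture
------------
A two-layer GCN encoder f(.; theta) maps a graph (A, X) to node-level
representations Z_node; a coordinate-wise max over nodes gives the
graph-level readout Z_G.  A weight-space twin of the same encoder — each
layer's weights perturbed by Gaussian noise, theta' = theta + eta * dtheta —
produces a second view (Zh_node, Zh_G) without any data augmentation.  A
shared two-layer MLP projection head maps both readouts into the space where
the contrastive loss is computed.

Two decoders reconstruct the input: an inner-product structure decoder
A_hat = sigmoid(Z_node Z_node^T) and a GCN attribute decoder that runs on
the *original* graph's normalized adjacency.  The reconstruction (A_hat,
X_hat) is then re-encoded by the SAME (unperturbed) encoder — A_hat enters
as a continuous weighted adjacency, keeping the whole objective
differentiable — yielding (Zr_node, Zr_G), whose distance to (Z_node, Z_G)
drives both the training error loss and the anomaly score.

All GCN layers use the symmetric normalization phi(D~^{-1/2} A~ D~^{-1/2} Z
theta) with self-loops A~ = A + I, carry no biases, and zero out padded
rows.  The perturbed branch exists only for the contrastive objective; the
anomaly score never uses it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor, as_tensor, masked_max, matmul, relu, sigmoid
from .data_io import BatchedGraphs

__all__ = [
    "ModelState",
    "init_model",
    "gcn_layer",
    "encode",
    "max_pool",
    "project",
    "decode_structure",
    "decode_attributes",
    "encode_reconstruction",
    "forward",
    "save_checkpoint",
    "load_checkpoint",
]

_ACTIVATIONS = {"relu": relu, "sigmoid": sigmoid, "identity": lambda x: as_tensor(x)}

CHECKPOINT_VERSION = 1


@dataclass
class ModelState:
    """All learnable parameters plus the perturbation coefficient eta.

    The encoder weight list is a single parameter object: the reconstruction
    re-encoding and the perturbed twin both read from it, never from copies.
    """

    encoder_weights: list[Tensor]   # theta_l, dims d -> 256 -> 128 by default
    decoder_weights: list[Tensor]   # theta_d, dims 128 -> 256 -> d
    proj_w1: Tensor
    proj_b1: Tensor
    proj_w2: Tensor
    proj_b2: Tensor
    eta: float = 1.0
    activation: str = "relu"
    sigma_override: float | None = None
    config: dict = field(default_factory=dict)

    @property
    def feature_dim(self) -> int:
        return self.encoder_weights[0].shape[0]

    @property
    def hidden_dim(self) -> int:
        return self.encoder_weights[-1].shape[1]

    def parameters(self) -> list[Tensor]:
        return [*self.encoder_weights, *self.decoder_weights,
                self.proj_w1, self.proj_b1, self.proj_w2, self.proj_b2]

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


def init_model(
    feature_dim: int,
    encoder_dims: tuple[int, ...] = (256, 128),
    proj_dim: int = 128,
    eta: float = 1.0,
    seed: int = 0,
    activation: str = "relu",
    sigma_override: float | None = None,
) -> ModelState:
    """Glorot-initialize a model.  Decoder dims mirror the encoder reversed."""
    if feature_dim < 1:
        raise ValueError("feature_dim must be >= 1 (attach degree features first)")
    if activation not in _ACTIVATIONS:
        raise ValueError(f"unknown activation {activation!r}")
    rng = np.random.default_rng(seed)
    enc_dims = (feature_dim, *encoder_dims)
    dec_dims = (enc_dims[-1], *encoder_dims[-2::-1], feature_dim)
    enc = [Tensor(_glorot(rng, a, b), requires_grad=True)
           for a, b in zip(enc_dims, enc_dims[1:])]
    dec = [Tensor(_glorot(rng, a, b), requires_grad=True)
           for a, b in zip(dec_dims, dec_dims[1:])]
    h = enc_dims[-1]
    state = ModelState(
        encoder_weights=enc,
        decoder_weights=dec,
        proj_w1=Tensor(_glorot(rng, h, proj_dim), requires_grad=True),
        proj_b1=Tensor(np.zeros(proj_dim), requires_grad=True),
        proj_w2=Tensor(_glorot(rng, proj_dim, proj_dim), requires_grad=True),
        proj_b2=Tensor(np.zeros(proj_dim), requires_grad=True),
        eta=eta,
        activation=activation,
        sigma_override=sigma_override,
        config={"feature_dim": feature_dim, "encoder_dims": list(encoder_dims),
                "proj_dim": proj_dim, "eta": eta, "seed": seed,
                "activation": activation},
    )
    return state


def _normalized_adjacency(adjacency, mask: np.ndarray):
    """D~^{-1/2} (A + I) D~^{-1/2}, differentiable in A when A is a Tensor.

    Zero-padded rows get degree 1 from the self-loop, so there is never a
    division by zero; their (zero) features keep their output rows zero.
    """
    A = as_tensor(adjacency)
    M = A.shape[-1]
    A_tilde = A + np.eye(M)
    deg = A_tilde.sum(axis=-1, keepdims=True)      # (..., M, 1)
    d_inv_sqrt = deg.power(-0.5)
    return d_inv_sqrt * A_tilde * d_inv_sqrt.transpose_last()


def gcn_layer(adjacency, node_states, weight, activation="relu", mask=None):
    """One graph convolution phi(D~^{-1/2} A~ D~^{-1/2} Z theta) (no bias)."""
    phi = _ACTIVATIONS[activation]
    norm = _normalized_adjacency(adjacency, mask)
    out = phi(matmul(matmul(norm, as_tensor(node_states)), as_tensor(weight)))
    if mask is not None:
        out = out * np.asarray(mask)[..., None]
    return out


def _perturbed_weights(state: ModelState, rng: np.random.Generator) -> list[Tensor]:
    """theta'_l = theta_l + eta * dtheta_l, dtheta_l ~ N(0, sigma_l^2).

    sigma_l defaults to the empirical std of theta_l's entries at the moment
    of perturbation.  The draw is a constant: gradients flow to theta_l
    unchanged, never into the noise.
    """
    out = []
    for w in state.encoder_weights:
        sigma = (state.sigma_override if state.sigma_override is not None
                 else float(w.data.std()))
        noise = state.eta * rng.normal(0.0, sigma, size=w.shape)
        out.append(w + noise)
    return out


def encode(adjacency, features, mask, state: ModelState,
           perturbed: bool = False, rng=None, seed: int | None = None):
    """Run the (optionally perturbed) GCN encoder; returns node states.

    The perturbation is redrawn on every call from ``rng`` (or a generator
    seeded with ``seed``); with eta = 0 the perturbed branch is bit-equal to
    the plain one.
    """
    if perturbed:
        if rng is None:
            rng = np.random.default_rng(seed)
        weights = _perturbed_weights(state, rng)
    else:
        weights = state.encoder_weights
    z = as_tensor(features)
    for w in weights:
        z = gcn_layer(adjacency, z, w, state.activation, mask)
    return z


def max_pool(node_states, mask) -> Tensor:
    """Coordinate-wise max over valid nodes: the graph-level readout."""
    return masked_max(as_tensor(node_states), np.asarray(mask))


def project(graph_repr, state: ModelState) -> Tensor:
    """Shared two-layer MLP projection head for the contrastive space."""
    phi = _ACTIVATIONS[state.activation]
    h = phi(matmul(as_tensor(graph_repr), state.proj_w1) + state.proj_b1)
    return matmul(h, state.proj_w2) + state.proj_b2


def decode_structure(node_states, mask) -> Tensor:
    """Inner-product edge decoder: sigmoid(Z Z^T), padded block zeroed."""
    z = as_tensor(node_states)
    gram = sigmoid(matmul(z, z.transpose_last()))
    m = np.asarray(mask)
    return gram * (m[..., :, None] * m[..., None, :])


def decode_attributes(adjacency, node_states, state: ModelState, mask) -> Tensor:
    """GCN attribute decoder on the ORIGINAL graph's normalized adjacency.

    Hidden layers use the model activation; the output layer is linear so
    reconstructed features can take arbitrary sign.
    """
    z = as_tensor(node_states)
    last = len(state.decoder_weights) - 1
    for i, w in enumerate(state.decoder_weights):
        act = "identity" if i == last else state.activation
        z = gcn_layer(adjacency, z, w, act, mask)
    return z


def encode_reconstruction(a_hat, x_hat, state: ModelState, mask):
    """Re-encode the reconstruction with the shared, unperturbed encoder.

    ``a_hat`` enters as a continuous weighted adjacency (self-loops added,
    degrees = row sums); gradients flow through it into the decoders.
    """
    z_node = encode(a_hat, x_hat, mask, state, perturbed=False)
    return z_node, max_pool(z_node, mask)


def forward(batch: BatchedGraphs, state: ModelState,
            rng=None, with_perturbed: bool = True) -> dict:
    """Full forward pass over a padded batch.

    Returns a dict of Tensors: ``z_node, z_g, z_proj`` (plain encoder),
    ``zh_node, zh_g, zh_proj`` (perturbed twin, if requested), ``a_hat,
    x_hat`` (decoders) and ``zr_node, zr_g`` (reconstruction re-encoding).
    """
    if state.feature_dim != batch.feature_stack.shape[-1]:
        raise ValueError(
            f"model expects feature_dim {state.feature_dim}, "
            f"batch has {batch.feature_stack.shape[-1]}")
    A, X, mask = batch.adjacency_stack, batch.feature_stack, batch.node_mask
    out: dict = {}
    z_node = encode(A, X, mask, state)
    out["z_node"] = z_node
    out["z_g"] = max_pool(z_node, mask)
    out["z_proj"] = project(out["z_g"], state)
    if with_perturbed:
        zh_node = encode(A, X, mask, state, perturbed=True, rng=rng)
        out["zh_node"] = zh_node
        out["zh_g"] = max_pool(zh_node, mask)
        out["zh_proj"] = project(out["zh_g"], state)
    out["a_hat"] = decode_structure(z_node, mask)
    out["x_hat"] = decode_attributes(A, z_node, state, mask)
    out["zr_node"], out["zr_g"] = encode_reconstruction(
        out["a_hat"], out["x_hat"], state, mask)
    return out


def save_checkpoint(state: ModelState, path: str) -> None:
    """Serialize all weights and the config echo into one .npz container."""
    arrays = {f"enc_{i}": w.data for i, w in enumerate(state.encoder_weights)}
    arrays |= {f"dec_{i}": w.data for i, w in enumerate(state.decoder_weights)}
    arrays |= {"proj_w1": state.proj_w1.data, "proj_b1": state.proj_b1.data,
               "proj_w2": state.proj_w2.data, "proj_b2": state.proj_b2.data}
    meta = {"version": CHECKPOINT_VERSION, "eta": state.eta,
            "activation": state.activation,
            "sigma_override": state.sigma_override,
            "n_enc": len(state.encoder_weights),
            "n_dec": len(state.decoder_weights),
            "config": state.config}
    np.savez(path, _meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
             **arrays)


def load_checkpoint(path: str) -> ModelState:
    """Bit-faithful inverse of :func:`save_checkpoint`."""
    with np.load(path) as z:
        meta = json.loads(bytes(z["_meta"]).decode())
        if meta["version"] != CHECKPOINT_VERSION:
            raise ValueError(f"unsupported checkpoint version {meta['version']}")
        enc = [Tensor(z[f"enc_{i}"], requires_grad=True)
               for i in range(meta["n_enc"])]
        dec = [Tensor(z[f"dec_{i}"], requires_grad=True)
               for i in range(meta["n_dec"])]
        return ModelState(
            encoder_weights=enc, decoder_weights=dec,
            proj_w1=Tensor(z["proj_w1"], requires_grad=True),
            proj_b1=Tensor(z["proj_b1"], requires_grad=True),
            proj_w2=Tensor(z["proj_w2"], requires_grad=True),
            proj_b2=Tensor(z["proj_b2"], requires_grad=True),
            eta=meta["eta"], activation=meta["activation"],
            sigma_override=meta["sigma_override"], config=meta["config"])
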