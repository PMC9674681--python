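"""Encoder/decoder contracts: hand-computed oracles, equivariance, sharing."""

import numpy as np
import pytest

from gladc import (
    GraphDataset,
    decode_attributes,
    decode_structure,
    encode,
    encode_reconstruction,
    forward,
    init_model,
    load_checkpoint,
    max_pool,
    pad_and_batch,
    project,
    save_checkpoint,
)
from gladc.autodiff import Tensor
from gladc.model import gcn_layer

from conftest import ring_adjacency


def sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def dense_gcn_oracle(A, Z, W, act=np.tanh):
    """Straightforward dense computation of phi(D^-1/2 (A+I) D^-1/2 Z W)."""
    At = A + np.eye(A.shape[0])
    d = At.sum(axis=1)
    norm = At / np.sqrt(np.outer(d, d))
    return act(norm @ Z @ W)


def test_gcn_layer_edgeless_collapses_to_mlp():
    A = np.zeros((3, 3))
    Z = np.arange(6.0).reshape(3, 2)
    W = np.array([[1.0, -1.0], [0.5, 2.0]])
    out = gcn_layer(A, Z, W, activation="relu", mask=np.ones(3))
    assert np.allclose(out.data, np.maximum(Z @ W, 0.0))


def test_gcn_layer_matches_hand_computation_on_triangle():
    A = ring_adjacency(3)
    Z = np.eye(3)
    W = np.eye(3)
    out = gcn_layer(A, Z, W, activation="identity", mask=np.ones(3))
    # A~ = A + I is all-ones, D~ = 3I, so every entry is 1/3
    assert np.allclose(out.data, np.full((3, 3), 1.0 / 3.0))


def test_gcn_layer_node_permutation_equivariance():
    rng = np.random.default_rng(0)
    A = ring_adjacency(5)
    Z = rng.normal(size=(5, 3))
    W = rng.normal(size=(3, 4))
    perm = rng.permutation(5)
    P = np.eye(5)[perm]
    direct = gcn_layer(P @ A @ P.T, Z[perm], W, "relu", np.ones(5)).data
    permuted = gcn_layer(A, Z, W, "relu", np.ones(5)).data[perm]
    assert np.allclose(direct, permuted)


def test_encode_eta_zero_is_bit_identical(random_dataset):
    batch = pad_and_batch(random_dataset.graphs, random_dataset.max_nodes)
    state = init_model(3, eta=0.0, seed=1)
    plain = encode(batch.adjacency_stack, batch.feature_stack, batch.node_mask, state)
    pert = encode(batch.adjacency_stack, batch.feature_stack, batch.node_mask,
                  state, perturbed=True, seed=5)
    assert np.array_equal(plain.data, pert.data)


def test_encode_perturbed_reproducible(random_dataset):
    batch = pad_and_batch(random_dataset.graphs, random_dataset.max_nodes)
    state = init_model(3, eta=1.0, seed=1)
    args = (batch.adjacency_stack, batch.feature_stack, batch.node_mask, state)
    a = encode(*args, perturbed=True, seed=7)
    b = encode(*args, perturbed=True, seed=7)
    c = encode(*args, perturbed=True, seed=8)
    assert np.array_equal(a.data, b.data)
    assert not np.array_equal(a.data, c.data)


def test_perturbation_magnitude_half_normal():
    # with eta = 1, E|theta' - theta| / sigma = E|N(0,1)| = sqrt(2/pi)
    from gladc.model import _perturbed_weights
    state = init_model(8, encoder_dims=(64, 32), seed=0, eta=1.0)
    rng = np.random.default_rng(0)
    ratios = []
    for _ in range(200):
        for w, wp in zip(state.encoder_weights, _perturbed_weights(state, rng)):
            sigma = w.data.std()
            ratios.append(np.abs(wp.data - w.data).mean() / sigma)
    assert abs(np.mean(ratios) - np.sqrt(2 / np.pi)) < 0.02


def test_max_pool_basics():
    z = Tensor(np.array([[1.0, 0.0], [0.0, 1.0], [9.0, 9.0]]))
    assert np.allclose(max_pool(z, np.array([1, 1, 0])).data, [1.0, 1.0])
    assert np.allclose(max_pool(z, np.array([0, 1, 0])).data, [0.0, 1.0])


def test_projection_head_is_shared_and_sized():
    state = init_model(3, proj_dim=128, seed=0)
    z = Tensor(np.ones((4, 128)))
    out1, out2 = project(z, state), project(z, state)
    assert out1.shape == (4, 128)
    assert np.array_equal(out1.data, out2.data)  # same weight objects both calls


def test_decode_structure_contracts():
    rng = np.random.default_rng(3)
    z = Tensor(rng.normal(size=(2, 4, 5)))
    mask = np.array([[1, 1, 1, 0], [1, 1, 1, 1]], dtype=float)
    a_hat = decode_structure(z, mask).data
    assert np.allclose(a_hat, np.swapaxes(a_hat, -1, -2))
    valid = a_hat[0, :3, :3]
    assert ((valid > 0) & (valid < 1)).all()
    assert not a_hat[0, 3, :].any() and not a_hat[0, :, 3].any()


def test_decode_structure_zero_input_gives_half():
    a_hat = decode_structure(Tensor(np.zeros((3, 2))), np.ones(3)).data
    assert np.allclose(a_hat, 0.5)


def test_decode_structure_orthogonal_rows():
    z = Tensor(np.eye(2))
    a_hat = decode_structure(z, np.ones(2)).data
    assert np.allclose(a_hat[0, 1], sigmoid(0.0))
    assert np.allclose(np.diag(a_hat), sigmoid(1.0))


def test_decode_attributes_matches_dense_oracle():
    rng = np.random.default_rng(4)
    state = init_model(2, encoder_dims=(6, 4), seed=4)
    A = ring_adjacency(3)
    Z = rng.normal(size=(3, 4))
    out = decode_attributes(A, Tensor(Z), state, np.ones(3)).data
    h = dense_gcn_oracle(A, Z, state.decoder_weights[0].data,
                         act=lambda x: np.maximum(x, 0))
    expect = dense_gcn_oracle(A, h, state.decoder_weights[1].data,
                              act=lambda x: x)
    assert np.allclose(out, expect)
    assert out.shape == (3, 2)


def test_encode_reconstruction_identity_when_exact(random_dataset):
    # feeding the original (A, X) back through the shared encoder must
    # reproduce (Z_node, Z_G) bit-exactly: same parameter object
    batch = pad_and_batch(random_dataset.graphs, random_dataset.max_nodes)
    state = init_model(3, seed=2)
    z = encode(batch.adjacency_stack, batch.feature_stack, batch.node_mask, state)
    zr_node, zr_g = encode_reconstruction(
        Tensor(batch.adjacency_stack), Tensor(batch.feature_stack),
        state, batch.node_mask)
    assert np.array_equal(z.data, zr_node.data)
    assert np.array_equal(max_pool(z, batch.node_mask).data, zr_g.data)


def test_continuous_adjacency_normalization_matches_oracle():
    rng = np.random.default_rng(5)
    A = rng.random((3, 3))
    A = (A + A.T) / 2
    np.fill_diagonal(A, 0.0)
    W = rng.normal(size=(2, 4))
    Z = rng.normal(size=(3, 2))
    out = gcn_layer(Tensor(A), Tensor(Z), Tensor(W), "relu", np.ones(3)).data
    assert np.allclose(out, dense_gcn_oracle(A, Z, W, act=lambda x: np.maximum(x, 0)))


def test_forward_permutation_invariance_of_readouts(random_dataset):
    state = init_model(3, seed=6)
    rng = np.random.default_rng(6)
    g = random_dataset.graphs[1]
    batch = pad_and_batch([g], random_dataset.max_nodes)
    out = forward(batch, state, with_perturbed=False)
    perm = rng.permutation(g.n_nodes)
    from gladc import Graph
    gp = Graph(g.adjacency[np.ix_(perm, perm)], g.features[perm], g.label, g.graph_id)
    outp = forward(pad_and_batch([gp], random_dataset.max_nodes), state,
                   with_perturbed=False)
    assert np.allclose(out["z_g"].data, outp["z_g"].data, atol=1e-5)
    assert np.allclose(out["zr_g"].data, outp["zr_g"].data, atol=1e-5)


def test_batched_forward_equals_per_graph_loop(random_dataset):
    state = init_model(3, seed=8)
    M = random_dataset.max_nodes
    batch = pad_and_batch(random_dataset.graphs, M)
    out = forward(batch, state, with_perturbed=False)
    for i, g in enumerate(random_dataset.graphs):
        single = forward(pad_and_batch([g], M), state, with_perturbed=False)
        assert np.allclose(out["z_node"].data[i], single["z_node"].data[0], atol=1e-6)
        assert np.allclose(out["zr_g"].data[i], single["zr_g"].data[0], atol=1e-6)
        assert np.allclose(out["a_hat"].data[i], single["a_hat"].data[0], atol=1e-6)


def test_checkpoint_round_trip(tmp_path):
    state = init_model(4, seed=9, eta=0.7)
    path = str(tmp_path / "ckpt.npz")
    save_checkpoint(state, path)
    back = load_checkpoint(path)
    for a, b in zip(state.parameters(), back.parameters()):
        assert np.array_equal(a.data, b.data)
    assert back.eta == 0.7
    assert back.activation == state.activation


def test_init_model_rejects_zero_feature_dim():
    with pytest.raises(ValueError):
        init_model(0)
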