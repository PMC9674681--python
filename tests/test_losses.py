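"""Loss components against brute-force per-graph / per-pair oracles."""

import numpy as np
import pytest

from gladc import contrastive_loss, error_loss, reconstruction_loss, total_loss
from gladc.autodiff import Tensor
from gladc.losses import LossBreakdown


# -- reconstruction -----------------------------------------------------------

def test_reconstruction_zero_at_exact():
    rng = np.random.default_rng(0)
    A = np.zeros((2, 3, 3))
    A[:, 0, 1] = A[:, 1, 0] = 1.0
    X = rng.normal(size=(2, 3, 2))
    mask = np.ones((2, 3))
    assert reconstruction_loss(A, Tensor(A), X, Tensor(X), mask).item() == 0.0


def test_reconstruction_two_node_edgeless_hand_value():
    # A = 0 (2 valid nodes), A_hat = 0.5 everywhere, X = X_hat: diagonals are
    # excluded, so only the two off-diagonal 0.25 terms remain -> 0.5
    A = np.zeros((1, 2, 2))
    a_hat = Tensor(np.full((1, 2, 2), 0.5))
    X = np.zeros((1, 2, 1))
    out = reconstruction_loss(A, a_hat, X, Tensor(X), np.ones((1, 2)))
    assert np.isclose(out.item(), 0.5)


def test_reconstruction_attribute_homogeneity():
    rng = np.random.default_rng(1)
    A = np.zeros((1, 3, 3))
    X = rng.normal(size=(1, 3, 2))
    X_hat = X + rng.normal(size=X.shape)
    mask = np.ones((1, 3))
    base = reconstruction_loss(A, Tensor(A), X, Tensor(X_hat), mask).item()
    double = reconstruction_loss(A, Tensor(A), X, Tensor(X + 2 * (X_hat - X)),
                                 mask).item()
    assert np.isclose(double, 4 * base)


def test_reconstruction_ignores_padding():
    rng = np.random.default_rng(2)
    A = np.zeros((1, 4, 4))
    X = np.zeros((1, 4, 2))
    X[0, :2] = rng.normal(size=(2, 2))
    mask = np.array([[1.0, 1.0, 0.0, 0.0]])
    a_hat = np.zeros((1, 4, 4))
    a_hat[0, 2:, 2:] = 9.0  # garbage in the padded block must not count
    x_hat = X.copy()
    x_hat[0, 2:] = -5.0
    out = reconstruction_loss(A, Tensor(a_hat), X, Tensor(x_hat), mask)
    assert out.item() == 0.0


def test_reconstruction_batched_equals_per_graph_loop():
    rng = np.random.default_rng(3)
    B, M, d = 4, 5, 3
    A = np.zeros((B, M, M))
    mask = np.zeros((B, M))
    for i, n in enumerate([3, 5, 4, 2]):
        mask[i, :n] = 1
        up = np.triu(rng.random((n, n)) < 0.5, k=1)
        A[i, :n, :n] = up | up.T
    X = rng.normal(size=(B, M, d)) * mask[..., None]
    a_hat = rng.random((B, M, M))
    a_hat = (a_hat + a_hat.swapaxes(1, 2)) / 2 * (mask[:, :, None] * mask[:, None, :])
    x_hat = rng.normal(size=(B, M, d)) * mask[..., None]
    batched = reconstruction_loss(A, Tensor(a_hat), X, Tensor(x_hat), mask).item()
    per_graph = []
    for i in range(B):
        n = int(mask[i].sum())
        s = 0.0
        for u in range(n):
            for v in range(n):
                if u != v:
                    s += (A[i, u, v] - a_hat[i, u, v]) ** 2
        for u in range(n):
            s += ((X[i, u] - x_hat[i, u]) ** 2).sum()
        per_graph.append(s)
    assert abs(batched - np.mean(per_graph)) < 1e-6


# -- contrastive --------------------------------------------------------------

def naive_nt_xent(z, zh, tau, negatives="perturbed"):
    def cos(a, b):
        return float(a @ b / (np.linalg.norm(a) * np.linalg.norm(b)))
    n = len(z)
    losses = []
    for i in range(n):
        num = np.exp(cos(zh[i], z[i]) / tau)
        neg = zh if negatives == "perturbed" else z
        den = sum(np.exp(cos(z[i], neg[j]) / tau) for j in range(n) if j != i)
        losses.append(-np.log(num / den))
    return float(np.mean(losses))


@pytest.mark.parametrize("negatives", ["perturbed", "unperturbed"])
def test_contrastive_matches_pairwise_oracle(negatives):
    rng = np.random.default_rng(4)
    z = rng.normal(size=(3, 6))
    zh = rng.normal(size=(3, 6))
    got = contrastive_loss(Tensor(z), Tensor(zh), tau=0.2,
                           negatives=negatives).item()
    assert abs(got - naive_nt_xent(z, zh, 0.2, negatives)) < 1e-6


def test_contrastive_identical_views_two_graphs():
    # N=2, all four vectors identical: numerator = denominator -> loss 0
    z = np.ones((2, 4))
    assert abs(contrastive_loss(Tensor(z), Tensor(z.copy()), tau=0.2).item()) < 1e-12


def test_contrastive_scale_invariance():
    rng = np.random.default_rng(5)
    z = rng.normal(size=(4, 5))
    zh = rng.normal(size=(4, 5))
    a = contrastive_loss(Tensor(z), Tensor(zh), tau=0.5).item()
    b = contrastive_loss(Tensor(3.7 * z), Tensor(0.2 * zh), tau=0.5).item()
    assert abs(a - b) < 1e-9


def test_contrastive_decreasing_in_positive_similarity():
    # sweep the anchor toward its positive while negatives stay fixed
    base = np.array([[1.0, 0.0], [0.0, 1.0], [-1.0, 0.5]])
    target = base[0]
    prev = np.inf
    for t in np.linspace(0.0, 0.9, 10):
        zh = base.copy()
        zh[0] = (1 - t) * np.array([0.0, 1.0]) + t * target
        val = contrastive_loss(Tensor(base), Tensor(zh), tau=0.2).item()
        assert val < prev
        prev = val


def test_contrastive_contract_errors():
    with pytest.raises(ValueError):
        contrastive_loss(Tensor(np.ones((1, 3))), Tensor(np.ones((1, 3))), 0.2)
    z = np.ones((2, 3))
    z0 = z.copy()
    z0[1] = 0.0
    with pytest.raises(ValueError):
        contrastive_loss(Tensor(z), Tensor(z0), 0.2)
    with pytest.raises(ValueError):
        contrastive_loss(Tensor(z), Tensor(z.copy()), tau=0.0)


# -- representation error -----------------------------------------------------

def test_error_loss_zero_when_equal():
    rng = np.random.default_rng(6)
    z = rng.normal(size=(2, 3, 4))
    zg = rng.normal(size=(2, 4))
    mask = np.ones((2, 3))
    ln, lg, l3 = error_loss(Tensor(z), Tensor(z.copy()), Tensor(zg),
                            Tensor(zg.copy()), mask)
    assert ln.item() == lg.item() == l3.item() == 0.0


def test_error_loss_hand_value_single_node():
    z = np.array([[[1.0, 0.0]]])
    zr = np.array([[[0.0, 1.0]]])
    ln, lg, l3 = error_loss(Tensor(z), Tensor(zr),
                            Tensor(z[:, 0]), Tensor(zr[:, 0]), np.ones((1, 1)))
    assert np.isclose(ln.item(), 2.0)
    assert np.isclose(lg.item(), 2.0)
    assert np.isclose(l3.item(), 4.0)


def test_error_loss_zero_error_graph_halves_means():
    z = np.array([[[1.0, 0.0]]])
    zr = np.array([[[0.0, 1.0]]])
    two_z = np.concatenate([z, z])
    two_zr = np.concatenate([zr, z])  # second graph has zero error
    mask = np.ones((2, 1))
    ln2, lg2, _ = error_loss(Tensor(two_z), Tensor(two_zr),
                             Tensor(two_z[:, 0]), Tensor(two_zr[:, 0]), mask)
    assert np.isclose(ln2.item(), 1.0)
    assert np.isclose(lg2.item(), 1.0)


def test_error_loss_batched_equals_loop():
    rng = np.random.default_rng(7)
    B, M, h = 5, 4, 3
    mask = np.zeros((B, M))
    for i, n in enumerate([2, 4, 3, 1, 4]):
        mask[i, :n] = 1
    z = rng.normal(size=(B, M, h)) * mask[..., None]
    zr = rng.normal(size=(B, M, h)) * mask[..., None]
    zg = rng.normal(size=(B, h))
    zrg = rng.normal(size=(B, h))
    ln, lg, _ = error_loss(Tensor(z), Tensor(zr), Tensor(zg), Tensor(zrg), mask)
    exp_ln = np.mean([
        np.mean([((z[i, u] - zr[i, u]) ** 2).sum()
                 for u in range(int(mask[i].sum()))])
        for i in range(B)])
    exp_lg = np.mean([((zg[i] - zrg[i]) ** 2).sum() for i in range(B)])
    assert abs(ln.item() - exp_ln) < 1e-9
    assert abs(lg.item() - exp_lg) < 1e-9


# -- total --------------------------------------------------------------------

def parts():
    return (Tensor(np.array(1.0)), Tensor(np.array(2.0)),
            Tensor(np.array(1.5)), Tensor(np.array(1.5)))


def test_total_is_unweighted_sum():
    l1, l2, ln, lg = parts()
    assert total_loss(l1, l2, ln, lg).item() == 6.0


@pytest.mark.parametrize("ablate,expected", [
    (frozenset({"cl"}), 4.0),
    (frozenset({"node"}), 4.5),
    (frozenset({"node", "graph"}), 3.0),
])
def test_total_respects_ablation(ablate, expected):
    l1, l2, ln, lg = parts()
    assert total_loss(l1, l2, ln, lg, ablate).item() == expected


def test_total_rejects_unknown_flag():
    with pytest.raises(ValueError):
        total_loss(*parts(), frozenset({"recon"}))


def test_breakdown_error_sum():
    b = LossBreakdown(1.0, 2.0, 0.5, 0.25, 3.75)
    assert b.l_error == 0.75
    assert b.as_dict()["l_total"] == 3.75
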