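"""Model core: graph convolution against the dense formula, Hamiltonian
energies and gradients against finite differences and closed forms, and the
symplectic integrator against hand-computed updates and conservation laws."""

import numpy as np
import pytest

from hamgnn import _autodiff as ad
from hamgnn._autodiff import Tensor
from hamgnn.datatypes import CellGraph, PhaseState
from hamgnn.model import (
    ExampleHamiltonian,
    GCNHamiltonian,
    HamiltonianGraphNet,
    MLPHamiltonian,
    ModelConfig,
    build_model,
    example_hamiltonian,
    gcn_layer,
    hamiltonian_energy,
    hamiltonian_gradients,
    integrate,
    normalized_adjacency,
    symplectic_euler_step,
)


class QuadraticHamiltonian:
    """H = 1/2 (||q||^2 + ||p||^2): the analytically solvable oscillator."""

    def params(self):
        return []

    def energy(self, q, p):
        return Tensor(0.5) * (ad.tsum(q * q) + ad.tsum(p * p))


def random_graph(n, rng, p=0.3):
    edges = [(i, j) for i in range(n) for j in range(i + 1, n) if rng.random() < p]
    return CellGraph(n, np.array(edges, dtype=np.int64).reshape(-1, 2))


def dense_gcn(X, graph, W, relu=True):
    A = graph.adjacency().toarray() + np.eye(graph.n_nodes)
    d = A.sum(axis=1)
    S = A / np.sqrt(np.outer(d, d))
    out = S @ X @ W
    return np.maximum(out, 0) if relu else out


# ---------------------------------------------------------------------------
# GCN layer
# ---------------------------------------------------------------------------


def test_gcn_layer_two_node_hand_example():
    g = CellGraph(2, [[0, 1]])
    out = gcn_layer(np.eye(2), g, np.eye(2), activation="none")
    np.testing.assert_allclose(out.data, [[0.5, 0.5], [0.5, 0.5]], atol=1e-14)


def test_gcn_layer_no_edges_is_identity_propagation():
    g = CellGraph(3, np.zeros((0, 2)))
    X = np.array([[1.0, -2.0], [3.0, 4.0], [-1.0, 0.0]])
    out = gcn_layer(X, g, np.eye(2), activation="relu")
    np.testing.assert_allclose(out.data, np.maximum(X, 0), atol=1e-14)


def test_gcn_layer_sparse_equals_dense_oracle():
    rng = np.random.default_rng(0)
    for _ in range(10):
        g = random_graph(10, rng)
        X = rng.normal(size=(10, 6))
        W = rng.normal(size=(6, 4))
        ours = gcn_layer(X, g, W, activation="relu").data
        np.testing.assert_allclose(ours, dense_gcn(X, g, W), atol=1e-10)


def test_gcn_layer_shape_mismatch():
    g = CellGraph(2, [[0, 1]])
    with pytest.raises(ValueError):
        gcn_layer(np.eye(3), g, np.eye(3))


# ---------------------------------------------------------------------------
# Hamiltonian energies
# ---------------------------------------------------------------------------


def test_mlp_energy_zero_params_and_node_scaling():
    rng = np.random.default_rng(1)
    ham = MLPHamiltonian(3, rng)
    state = PhaseState(q=rng.normal(size=(4, 3)), p=rng.normal(size=(4, 3)))
    for p in ham.params():
        p.data[:] = 0.0
    assert hamiltonian_energy(state, ham) == pytest.approx(0.0, abs=1e-12)

    ham2 = MLPHamiltonian(3, np.random.default_rng(2))
    e1 = hamiltonian_energy(state, ham2)
    doubled = PhaseState(q=np.vstack([state.q, state.q]), p=np.vstack([state.p, state.p]))
    e2 = hamiltonian_energy(doubled, ham2)
    # l2 aggregation over nodes: duplicating all nodes scales H by sqrt(2)
    assert e2 == pytest.approx(np.sqrt(2) * e1, rel=1e-10)
    assert e1 >= 0


def test_gcn_energy_bounded_by_operator_norms():
    """tanh output is in (-1,1), so H <= ||S||^2 ||W1||_F^2 * N * d2."""
    rng = np.random.default_rng(3)
    g = random_graph(6, rng)
    ham = GCNHamiltonian(2, g, rng)
    n, d2 = 6, ham.W2.shape[1]
    bound = n * d2 * np.linalg.norm(ham.W1.data) ** 2  # ||S||_2 <= 1
    for _ in range(20):
        state = PhaseState(q=rng.normal(size=(6, 2)) * 10, p=rng.normal(size=(6, 2)) * 10)
        e = hamiltonian_energy(state, ham)
        assert 0 <= e <= bound


def test_energy_rejects_nonfinite_state():
    ham = QuadraticHamiltonian()
    with pytest.raises(ValueError):
        PhaseState(q=np.array([[np.inf]]), p=np.array([[0.0]]))


# ---------------------------------------------------------------------------
# gradients
# ---------------------------------------------------------------------------


@pytest.mark.parametrize("variant", ["mlp", "gcn"])
def test_hamiltonian_gradients_match_finite_differences(variant):
    rng = np.random.default_rng(4)
    g = random_graph(5, rng)
    ham = MLPHamiltonian(3, rng) if variant == "mlp" else GCNHamiltonian(3, g, rng)
    for trial in range(5):
        state = PhaseState(q=rng.normal(size=(5, 3)), p=rng.normal(size=(5, 3)))
        dq, dp = hamiltonian_gradients(state, ham)
        h = 1e-4
        for arr, grad_arr, which in ((state.q, dq, "q"), (state.p, dp, "p")):
            num = np.zeros_like(arr)
            for i in range(5):
                for j in range(3):
                    sp_, sm_ = arr.copy(), arr.copy()
                    sp_[i, j] += h
                    sm_[i, j] -= h
                    if which == "q":
                        ep = hamiltonian_energy(PhaseState(sp_, state.p), ham)
                        em = hamiltonian_energy(PhaseState(sm_, state.p), ham)
                    else:
                        ep = hamiltonian_energy(PhaseState(state.q, sp_), ham)
                        em = hamiltonian_energy(PhaseState(state.q, sm_), ham)
                    num[i, j] = (ep - em) / (2 * h)
            np.testing.assert_allclose(grad_arr, num, rtol=1e-4, atol=1e-7)


def test_quadratic_gradients_closed_form_and_zero_params():
    rng = np.random.default_rng(5)
    state = PhaseState(q=rng.normal(size=(3, 2)), p=rng.normal(size=(3, 2)))
    dq, dp = hamiltonian_gradients(state, QuadraticHamiltonian())
    np.testing.assert_allclose(dq, state.q, atol=1e-12)
    np.testing.assert_allclose(dp, state.p, atol=1e-12)

    ham = MLPHamiltonian(2, rng)
    for p in ham.params():
        p.data[:] = 0.0
    dq0, dp0 = hamiltonian_gradients(state, ham)
    assert np.all(dq0 == 0) and np.all(dp0 == 0)


# ---------------------------------------------------------------------------
# symplectic integration
# ---------------------------------------------------------------------------


def test_symplectic_step_hand_computation():
    """H = (q^2 + p^2)/2 from (1, 0), dt = 0.2: p' = -0.2, q' = 0.96."""
    s = PhaseState(q=np.array([[1.0]]), p=np.array([[0.0]]))
    out = symplectic_euler_step(s, QuadraticHamiltonian(), 0.2)
    assert out.p[0, 0] == pytest.approx(-0.2, abs=1e-14)
    assert out.q[0, 0] == pytest.approx(0.96, abs=1e-14)
    with pytest.raises(ValueError):
        symplectic_euler_step(s, QuadraticHamiltonian(), 0.0)


def test_zero_gradient_hamiltonian_leaves_state_fixed():
    class Constant:
        def energy(self, q, p):
            return Tensor(3.0)

    rng = np.random.default_rng(6)
    s = PhaseState(q=rng.normal(size=(4, 2)), p=rng.normal(size=(4, 2)))
    out = symplectic_euler_step(s, Constant(), 0.2)
    np.testing.assert_array_equal(out.q, s.q)
    np.testing.assert_array_equal(out.p, s.p)


def test_step_map_jacobian_determinant_is_one():
    """Area preservation on a 1-D separable system, via finite differences."""
    ham = QuadraticHamiltonian()
    dt = 0.2

    def step(v):
        s = symplectic_euler_step(
            PhaseState(q=np.array([[v[0]]]), p=np.array([[v[1]]])), ham, dt
        )
        return np.array([s.q[0, 0], s.p[0, 0]])

    v0 = np.array([0.37, -0.82])
    h = 1e-4
    J = np.zeros((2, 2))
    for j in range(2):
        vp, vm = v0.copy(), v0.copy()
        vp[j] += h
        vm[j] -= h
        J[:, j] = (step(vp) - step(vm)) / (2 * h)
    assert abs(np.linalg.det(J) - 1.0) < 1e-12


def test_integrate_step_count_and_identity_horizon():
    s = PhaseState(q=np.array([[1.0]]), p=np.array([[0.0]]))
    out, energies = integrate(s, QuadraticHamiltonian(), dt=0.2, horizon=(0, 1), record=True)
    assert len(energies) == 6  # initial + 5 steps
    out0 = integrate(s, QuadraticHamiltonian(), dt=0.2, horizon=(0, 0))
    np.testing.assert_array_equal(out0.q, s.q)


def test_long_horizon_energy_stays_bounded():
    """Symplectic Euler on the oscillator: energy within 1% over 10^4 steps."""
    s = PhaseState(q=np.array([[1.0]]), p=np.array([[0.0]]))
    _, energies = integrate(s, QuadraticHamiltonian(), dt=0.01, horizon=(0, 100), record=True)
    E = np.asarray(energies)
    assert np.abs(E - E[0]).max() / E[0] < 0.01


# ---------------------------------------------------------------------------
# constructive test Hamiltonian
# ---------------------------------------------------------------------------


def test_example_hamiltonian_structure():
    rng = np.random.default_rng(7)
    A = rng.normal(size=(4, 4))
    q = rng.normal(size=(4, 3))
    # kinetic term vanishes at p = 0
    assert example_hamiltonian(q, np.zeros((4, 3)), A, 0.1) == pytest.approx(
        float((np.sin(q) ** 2).sum())
    )
    # lattice minima: q = n*pi, p = 0 has zero energy and zero gradient
    qm = np.pi * rng.integers(-2, 3, size=(4, 3)).astype(float)
    ham = ExampleHamiltonian(A, 0.1)
    s = PhaseState(q=qm, p=np.zeros((4, 3)))
    assert hamiltonian_energy(s, ham) == pytest.approx(0.0, abs=1e-20)
    dq, dp = hamiltonian_gradients(s, ham)
    np.testing.assert_allclose(dq, 0, atol=1e-12)
    np.testing.assert_allclose(dp, 0, atol=1e-12)
    # positive definiteness: T >= sigma ||p||^2
    for _ in range(20):
        p = rng.normal(size=(4, 3))
        qq = rng.normal(size=(4, 3))
        T = example_hamiltonian(qq, p, A, 0.1) - float((np.sin(qq) ** 2).sum())
        assert T >= 0.1 * float((p**2).sum()) - 1e-10
    with pytest.raises(ValueError):
        example_hamiltonian(q, q, A, 0.0)


# ---------------------------------------------------------------------------
# full models
# ---------------------------------------------------------------------------


def _tiny_setup(seed=0, n=12, f=5, h=4):
    rng = np.random.default_rng(seed)
    g = random_graph(n, rng)
    X = rng.normal(size=(n, f))
    cfg = ModelConfig(hidden_dim=h, seed=seed)
    return X, g, cfg


def test_phase_init_contract():
    X, g, cfg = _tiny_setup()
    net = HamiltonianGraphNet(5, 3, g, cfg)
    q, p = net.phase_init(X, training=False)
    assert q.shape == (12, 4) and p.shape == (12, 4)
    # zero projection -> zero phase state
    net.W_proj.data[:] = 0
    net.b_proj.data[:] = 0
    q0, p0 = net.phase_init(X, training=False)
    assert np.all(q0.data == 0) and np.all(p0.data == 0)


def test_eval_forward_is_deterministic_train_forward_uses_dropout():
    X, g, cfg = _tiny_setup()
    net = HamiltonianGraphNet(5, 3, g, cfg)
    a = net.forward(X, training=False)[0].data
    b = net.forward(X, training=False)[0].data
    assert np.array_equal(a, b)
    rng = np.random.default_rng(0)
    c = net.forward(X, training=True, dropout_rng=rng)[0].data
    d = net.forward(X, training=True, dropout_rng=rng)[0].data
    assert not np.array_equal(c, d)


def test_degenerate_horizon_reduces_to_encoder_plus_head():
    X, g, _ = _tiny_setup()
    cfg = ModelConfig(hidden_dim=4, horizon=(0.0, 0.0), seed=1)
    net = HamiltonianGraphNet(5, 3, g, cfg)
    logits = net.forward(X, training=False)[0].data
    q, p = net.phase_init(X, training=False)
    rep = np.concatenate([q.data, p.data], axis=1)
    W, b = net.heads[0]
    np.testing.assert_allclose(logits, rep @ W.data + b.data, atol=1e-12)


def test_gcn_baseline_depth1_matches_dense_oracle():
    X, g, _ = _tiny_setup()
    cfg = ModelConfig(hidden_dim=4, gcn_depth=1, seed=2)
    net = build_model("gcn_baseline", 5, 3, g, cfg)
    logits = net.forward(X, training=False)[0].data
    W0, b0 = net.layers[0]
    hidden = np.maximum(dense_gcn(X, g, W0.data, relu=False) + b0.data, 0)
    Wh, bh = net.heads[0]
    np.testing.assert_allclose(logits, hidden @ Wh.data + bh.data, atol=1e-10)


def test_readout_zero_head_gives_uniform_probabilities():
    X, g, cfg = _tiny_setup()
    net = HamiltonianGraphNet(5, 16, g, cfg)
    for W, b in net.heads:
        W.data[:] = 0
        b.data[:] = 0
    logits = net.forward(X, training=False)[0].data
    probs = np.exp(logits) / np.exp(logits).sum(axis=1, keepdims=True)
    np.testing.assert_allclose(probs, 1 / 16, atol=1e-12)


def test_readout_on_q_only_changes_dimension():
    X, g, _ = _tiny_setup()
    cfg = ModelConfig(hidden_dim=4, readout_on="q", seed=3)
    net = HamiltonianGraphNet(5, 3, g, cfg)
    assert net.heads[0][0].shape == (4, 3)


def test_trained_model_energy_stays_bounded(sbm_tiny):
    """No catastrophic divergence: per-step energies recorded during
    training never exceed 10x the epoch's initial energy."""
    from hamgnn.train import fit

    cfg = ModelConfig(hidden_dim=8, epochs=15, patience=15, seed=4)
    res = fit("hgcn", sbm_tiny["X"], sbm_tiny["graph"], sbm_tiny["labelset"],
              sbm_tiny["split"], cfg, record_energy=True)
    assert res.energies_per_epoch
    for steps in res.energies_per_epoch:
        E = np.asarray(steps)
        assert len(E) == cfg.n_steps + 1
        assert np.all(np.isfinite(E))
        assert E.max() <= 10 * max(E[0], 1e-9)


def test_model_config_validation():
    with pytest.raises(ValueError):
        ModelConfig(dt=-0.1)
    with pytest.raises(ValueError):
        ModelConfig(horizon=(0.0, 0.5), dt=0.2)  # not divisible
    with pytest.raises(ValueError):
        ModelConfig(alpha=0.5, beta=0.3)
    assert ModelConfig().n_steps == 5
    assert ModelConfig(hidden_dim=256).phase_dim == 512
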