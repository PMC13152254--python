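"""Graph models: the Hamiltonian graph network and the plain GCN baseline.

Each cell's embedding is split into a position half ``q`` and a momentum
half ``p``; a learnable scalar energy H(q, p) drives staggered symplectic
Euler updates

    p' = p - dt * dH/dq(q, p)
    q' = q + dt * dH/dp(q, p')

which exactly preserve phase-space area for separable energies and keep
energy bounded (rather than drifting) for the learned one. The gradients
dH/dq, dH/dp are obtained by automatic differentiation and remain graph
nodes, so the training loss backpropagates through the integrator,
including the second-order terms.

Two energy parameterizations are provided: a per-node MLP
(2H -> 4H -> 1, ReLU) whose node energies are aggregated by an l2 norm
(the default), and a graph-convolutional form ||g1(tanh(g2(q || p)))||^2
whose tanh keeps the energy bounded for bounded inputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from . import _autodiff as ad
from ._autodiff import Tensor, grad
from .datatypes import CellGraph, PhaseState
from .nn import Parameter, dropout_mask, glorot

__all__ = [
    "ModelConfig",
    "normalized_adjacency",
    "gcn_layer",
    "hamiltonian_energy",
    "hamiltonian_gradients",
    "symplectic_euler_step",
    "integrate",
    "example_hamiltonian",
    "ExampleHamiltonian",
    "MLPHamiltonian",
    "GCNHamiltonian",
    "HamiltonianGraphNet",
    "GCNBaseline",
    "build_model",
]


@dataclass
class ModelConfig:
    """Hyperparameters shared by both models.

    Defaults follow the reference configuration: hidden width 256 (phase
    dimension 512), symplectic step 0.2 over horizon [0, 1] (5 steps),
    dropout 0.5 after the encoder layer, Adam at lr 0.01 with weight decay
    5e-4, and multi-task loss weights alpha = 0.7 / beta = 0.3.
    """

    hidden_dim: int = 256
    dt: float = 0.2
    horizon: tuple[float, float] = (0.0, 1.0)
    dropout: float = 0.5
    learning_rate: float = 0.01
    weight_decay: float = 5e-4
    epochs: int = 300
    patience: int = 50
    k: int = 15
    alpha: float = 0.7
    beta: float = 0.3
    hamiltonian_variant: str = "mlp"  # "mlp" | "gcn"
    gcn_depth: int = 2  # baseline depth
    readout_on: str = "qp"  # "qp" | "q"
    task: str = "single"  # "single" | "multi"
    seed: int = 0

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        start, end = self.horizon
        if end < start:
            raise ValueError("horizon end must be >= start")
        n = (end - start) / self.dt
        if abs(n - round(n)) > 1e-9:
            raise ValueError("horizon length must be divisible by dt")
        if abs(self.alpha + self.beta - 1.0) > 1e-9:
            raise ValueError("loss weights alpha + beta must equal 1")

    @property
    def n_steps(self) -> int:
        start, end = self.horizon
        return int(round((end - start) / self.dt))

    @property
    def phase_dim(self) -> int:
        return 2 * self.hidden_dim


# ---------------------------------------------------------------------------
# graph convolution
# ---------------------------------------------------------------------------


def normalized_adjacency(graph: CellGraph) -> sp.csr_matrix:
    """Symmetric normalization with self-loops: D^{-1/2} (A + I) D^{-1/2}."""
    A = graph.adjacency() + sp.identity(graph.n_nodes, format="csr")
    deg = np.asarray(A.sum(axis=1)).ravel()
    dinv = 1.0 / np.sqrt(deg)
    D = sp.diags(dinv)
    return sp.csr_matrix(D @ A @ D)


def gcn_layer(
    X,
    graph: CellGraph | sp.spmatrix,
    W,
    b=None,
    activation: str = "relu",
) -> Tensor:
    """One graph-convolution block: sigma(D^{-1/2}(A+I)D^{-1/2} X W [+ b]).

    ``graph`` may be a CellGraph or a precomputed normalized adjacency.
    Computed via sparse message passing; numerically equal to the dense
    formula.
    """
    S = graph if sp.issparse(graph) else normalized_adjacency(graph)
    X = ad.astensor(X)
    W = ad.astensor(W)
    if X.shape[0] != S.shape[0] or X.shape[1] != W.shape[0]:
        raise ValueError("shape mismatch in gcn_layer")
    out = ad.spmm(S, ad.matmul(X, W))
    if b is not None:
        out = out + ad.astensor(b)
    if activation == "relu":
        out = ad.relu(out)
    elif activation != "none":
        raise ValueError(f"unknown activation {activation!r}")
    return out


# ---------------------------------------------------------------------------
# learnable Hamiltonians
# ---------------------------------------------------------------------------


class MLPHamiltonian:
    """Per-node energy 2H -> 4H -> 1 (ReLU), aggregated by l2 over nodes."""

    variant = "mlp"

    def __init__(self, hidden_dim: int, rng: np.random.Generator):
        h = hidden_dim
        self.W1 = Parameter(glorot(rng, 2 * h, 4 * h), "ham.W1")
        self.b1 = Parameter(np.zeros(4 * h), "ham.b1")
        self.W2 = Parameter(glorot(rng, 4 * h, 1), "ham.W2")
        self.b2 = Parameter(np.zeros(1), "ham.b2")

    def params(self) -> list[Parameter]:
        return [self.W1, self.b1, self.W2, self.b2]

    def energy(self, q: Tensor, p: Tensor) -> Tensor:
        z = ad.concat([q, p], axis=1)
        hdn = ad.relu(ad.matmul(z, self.W1) + self.b1)
        e = ad.matmul(hdn, self.W2) + self.b2  # (N, 1) per-node energies
        # l2 over nodes; tiny epsilon keeps the gradient defined (and zero)
        # at the all-zero energy point without shifting nonzero values
        return (ad.tsum(e * e) + Tensor(1e-300)) ** 0.5


class GCNHamiltonian:
    """Graph-convolutional energy ||g1(tanh(g2(q || p)))||^2 (BIBO-stable)."""

    variant = "gcn"

    def __init__(
        self,
        hidden_dim: int,
        graph: CellGraph | sp.spmatrix,
        rng: np.random.Generator,
        inner_dim: int | None = None,
    ):
        h = hidden_dim
        d2 = inner_dim if inner_dim is not None else 2 * h
        self.S = graph if sp.issparse(graph) else normalized_adjacency(graph)
        self.W2 = Parameter(glorot(rng, 2 * h, d2), "ham.g2.W")
        self.W1 = Parameter(glorot(rng, d2, max(h // 2, 1)), "ham.g1.W")

    def params(self) -> list[Parameter]:
        return [self.W2, self.W1]

    def energy(self, q: Tensor, p: Tensor) -> Tensor:
        z = ad.concat([q, p], axis=1)
        inner = ad.tanh(ad.spmm(self.S, ad.matmul(z, self.W2)))
        outer = ad.spmm(self.S, ad.matmul(inner, self.W1))
        return ad.tsum(outer * outer)


def hamiltonian_energy(state: PhaseState, ham) -> float:
    """Scalar energy of a phase state under a Hamiltonian object."""
    if not (np.all(np.isfinite(state.q)) and np.all(np.isfinite(state.p))):
        raise ValueError("phase state must be finite")
    return float(ham.energy(Tensor(state.q), Tensor(state.p)).item())


def hamiltonian_gradients(state: PhaseState, ham) -> tuple[np.ndarray, np.ndarray]:
    """(dH/dq, dH/dp) by automatic differentiation."""
    q = Tensor(state.q, requires_grad=True)
    p = Tensor(state.p, requires_grad=True)
    e = ham.energy(q, p)
    dq, dp = grad(e, [q, p])
    return dq.data, dp.data


def _step(q: Tensor, p: Tensor, ham, dt: float) -> tuple[Tensor, Tensor]:
    """One staggered symplectic Euler update on graph tensors."""
    dq1, _ = grad(ham.energy(q, p), [q, p])
    p_new = p + Tensor(-dt) * dq1
    _, dp2 = grad(ham.energy(q, p_new), [q, p_new])
    q_new = q + Tensor(dt) * dp2
    return q_new, p_new


def symplectic_euler_step(state: PhaseState, ham, dt: float) -> PhaseState:
    """p' = p - dt dH/dq(q, p); q' = q + dt dH/dp(q, p')."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    q = Tensor(state.q, requires_grad=True)
    p = Tensor(state.p, requires_grad=True)
    q_new, p_new = _step(q, p, ham, dt)
    return PhaseState(q=q_new.data, p=p_new.data)


def integrate(
    state: PhaseState,
    ham,
    dt: float = 0.2,
    horizon: tuple[float, float] = (0.0, 1.0),
    record: bool = False,
):
    """Apply round((end-start)/dt) symplectic steps; optionally record the
    per-step energies (including the initial one)."""
    start, end = horizon
    if end < start:
        raise ValueError("horizon end must be >= start")
    n_steps = int(round((end - start) / dt))
    q = Tensor(state.q, requires_grad=True)
    p = Tensor(state.p, requires_grad=True)
    energies = [float(ham.energy(q, p).item())] if record else None
    for _ in range(n_steps):
        q, p = _step(q, p, ham, dt)
        # standalone integration returns numbers, not graph nodes: cut the
        # history each step so long horizons stay O(n_steps), not O(n^2)
        q = Tensor(q.data, requires_grad=True)
        p = Tensor(p.data, requires_grad=True)
        if record:
            energies.append(float(ham.energy(q, p).item()))
    out = PhaseState(q=q.data, p=p.data)
    return (out, energies) if record else out


class ExampleHamiltonian:
    """Separable test energy with provable stability structure.

    Kinetic term T = sum_k p_k^T ((A q_k)(A q_k)^T + sigma I) p_k over
    feature columns k (positive definite in p: T >= sigma ||p||^2);
    potential V = ||sin q||^2 with minima on the lattice q = n*pi.
    Used only as a fixed Hamiltonian for integrator validation, never in
    training.
    """

    variant = "example"

    def __init__(self, A_G: np.ndarray, sigma: float):
        if sigma <= 0:
            raise ValueError("sigma must be positive")
        self.A = np.asarray(A_G, dtype=float)
        self.sigma = float(sigma)

    def params(self) -> list:
        return []

    def energy(self, qt: Tensor, pt: Tensor) -> Tensor:
        u = ad.matmul(Tensor(self.A), qt)
        c = ad.tsum(u * pt, axis=0)  # one coefficient per column
        T = ad.tsum(c * c) + Tensor(self.sigma) * ad.tsum(pt * pt)
        V = ad.tsum(ad.sin(qt) * ad.sin(qt))
        return T + V


def example_hamiltonian(q: np.ndarray, p: np.ndarray, A_G: np.ndarray, sigma: float) -> float:
    """Scalar value of the constructive kinetic + potential test energy."""
    ham = ExampleHamiltonian(A_G, sigma)
    return float(
        ham.energy(
            Tensor(np.atleast_2d(np.asarray(q, float))),
            Tensor(np.atleast_2d(np.asarray(p, float))),
        ).item()
    )


# ---------------------------------------------------------------------------
# full models
# ---------------------------------------------------------------------------


class HamiltonianGraphNet:
    """Encoder GCN -> phase-space projection -> symplectic flow -> readout."""

    mode = "hgcn"

    def __init__(
        self,
        n_features: int,
        n_classes,
        graph: CellGraph,
        config: ModelConfig,
        rng: np.random.Generator | None = None,
    ):
        cfg = config
        self.config = cfg
        self.S = normalized_adjacency(graph)
        rng = rng if rng is not None else np.random.default_rng(cfg.seed)
        h = cfg.hidden_dim
        self.W_enc = Parameter(glorot(rng, n_features, h), "enc.W")
        self.b_enc = Parameter(np.zeros(h), "enc.b")
        self.W_proj = Parameter(glorot(rng, h, 2 * h), "proj.W")
        self.b_proj = Parameter(np.zeros(2 * h), "proj.b")
        if cfg.hamiltonian_variant == "mlp":
            self.ham = MLPHamiltonian(h, rng)
        elif cfg.hamiltonian_variant == "gcn":
            self.ham = GCNHamiltonian(h, self.S, rng)
        else:
            raise ValueError(f"unknown Hamiltonian variant {cfg.hamiltonian_variant!r}")
        rep_dim = 2 * h if cfg.readout_on == "qp" else h
        self.n_classes = [n_classes] if np.isscalar(n_classes) else list(n_classes)
        self.heads = [
            (
                Parameter(glorot(rng, rep_dim, c), f"head{t}.W"),
                Parameter(np.zeros(c), f"head{t}.b"),
            )
            for t, c in enumerate(self.n_classes)
        ]
        self._last_energies: list[float] | None = None

    def params(self) -> list[Parameter]:
        ps = [self.W_enc, self.b_enc, self.W_proj, self.b_proj]
        ps += self.ham.params()
        for W, b in self.heads:
            ps += [W, b]
        return ps

    def phase_init(self, X: np.ndarray, training: bool = False,
                   dropout_rng: np.random.Generator | None = None) -> tuple[Tensor, Tensor]:
        Z = gcn_layer(Tensor(np.asarray(X, float)), self.S, self.W_enc, self.b_enc,
                      activation="relu")
        if training and self.config.dropout > 0:
            if dropout_rng is None:
                raise ValueError("training-mode forward needs a dropout rng")
            mask = dropout_mask(dropout_rng, Z.shape, self.config.dropout)
            Z = Z * Tensor(mask)
        Y0 = ad.matmul(Z, self.W_proj) + self.b_proj
        h = self.config.hidden_dim
        q0 = Y0[:, :h]
        p0 = Y0[:, h:]
        return q0, p0

    def forward(
        self,
        X: np.ndarray,
        training: bool = False,
        dropout_rng: np.random.Generator | None = None,
        record_energy: bool = False,
    ) -> list[Tensor]:
        cfg = self.config
        q, p = self.phase_init(X, training=training, dropout_rng=dropout_rng)
        energies = [float(self.ham.energy(q, p).item())] if record_energy else None
        for _ in range(cfg.n_steps):
            q, p = _step(q, p, self.ham, cfg.dt)
            if record_energy:
                energies.append(float(self.ham.energy(q, p).item()))
        self._last_energies = energies
        self._last_phase = PhaseState(q=q.data.copy(), p=p.data.copy())
        rep = ad.concat([q, p], axis=1) if cfg.readout_on == "qp" else q
        return [ad.matmul(rep, W) + b for W, b in self.heads]

    def embeddings(self, X: np.ndarray) -> np.ndarray:
        """Final phase-space representation (eval mode), for diagnostics."""
        self.forward(X, training=False)
        return self._last_phase.concat()


class GCNBaseline:
    """Stack of GCN blocks with the same width, dropout and readout."""

    mode = "gcn_baseline"

    def __init__(
        self,
        n_features: int,
        n_classes,
        graph: CellGraph,
        config: ModelConfig,
        rng: np.random.Generator | None = None,
    ):
        cfg = config
        self.config = cfg
        self.S = normalized_adjacency(graph)
        rng = rng if rng is not None else np.random.default_rng(cfg.seed)
        h = cfg.hidden_dim
        dims = [n_features] + [h] * cfg.gcn_depth
        self.layers = [
            (
                Parameter(glorot(rng, dims[i], dims[i + 1]), f"gcn{i}.W"),
                Parameter(np.zeros(dims[i + 1]), f"gcn{i}.b"),
            )
            for i in range(cfg.gcn_depth)
        ]
        self.n_classes = [n_classes] if np.isscalar(n_classes) else list(n_classes)
        self.heads = [
            (
                Parameter(glorot(rng, h, c), f"head{t}.W"),
                Parameter(np.zeros(c), f"head{t}.b"),
            )
            for t, c in enumerate(self.n_classes)
        ]
        self._last_energies = None

    def params(self) -> list[Parameter]:
        ps = []
        for W, b in self.layers:
            ps += [W, b]
        for W, b in self.heads:
            ps += [W, b]
        return ps

    def forward(
        self,
        X: np.ndarray,
        training: bool = False,
        dropout_rng: np.random.Generator | None = None,
        record_energy: bool = False,
    ) -> list[Tensor]:
        H = Tensor(np.asarray(X, float))
        for W, b in self.layers:
            H = gcn_layer(H, self.S, W, b, activation="relu")
            if training and self.config.dropout > 0:
                if dropout_rng is None:
                    raise ValueError("training-mode forward needs a dropout rng")
                H = H * Tensor(dropout_mask(dropout_rng, H.shape, self.config.dropout))
        self._last_hidden = H.data.copy()
        return [ad.matmul(H, W) + b for W, b in self.heads]

    def embeddings(self, X: np.ndarray) -> np.ndarray:
        self.forward(X, training=False)
        return self._last_hidden


def build_model(mode: str, n_features: int, n_classes, graph: CellGraph,
                config: ModelConfig, rng: np.random.Generator | None = None):
    if mode == "hgcn":
        return HamiltonianGraphNet(n_features, n_classes, graph, config, rng)
    if mode == "gcn_baseline":
        return GCNBaseline(n_features, n_classes, graph, config, rng)
    raise ValueError(f"unknown model mode {mode!r}")
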