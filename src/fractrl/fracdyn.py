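"""Discrete-time fractional-order dynamics with power-law memory.

Implements the memory kernel, the expanded system matrices, full-history
trajectory simulation, and a numeric T-step controllability oracle used to
verify structural claims.

Model: ``x[k+1] = sum_{j=0..k} A_j x[k-j] + B u[k]`` with
``A_0 = A - D(alpha, 1)`` and ``A_j = -D(alpha, j+1)`` for ``j >= 1``,
where ``D(alpha, j) = diag(psi(alpha_i, j))`` is the memory-weight diagonal.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .netio import DirectedPattern

__all__ = [
    "FractionalNetwork",
    "MemoryKernel",
    "ExpandedMatrices",
    "Trajectory",
    "psi_weights",
    "expansion_matrices",
    "simulate",
    "reachability_matrix",
    "is_controllable_numeric",
    "sample_realization",
    "numeric_rank",
]

# weight-sampling bounds: bounded away from 0 to avoid spurious numeric
# rank loss; alpha bounds keep every exponent strictly non-integer
WEIGHT_LOW, WEIGHT_HIGH = 0.5, 1.5
ALPHA_LOW, ALPHA_HIGH = 0.2, 0.8
DEFAULT_TRIALS = 8


@dataclass
class FractionalNetwork:
    """A pattern plus per-node fractional exponents and optional weights.

    ``weights`` is a dense N x N array supported exactly on pattern arcs
    (entry ``[i, j]`` nonzero iff arc ``(j, i)`` is in the pattern).
    """

    pattern: DirectedPattern
    alpha: np.ndarray
    weights: np.ndarray | None = None

    def __post_init__(self):
        self.alpha = np.asarray(self.alpha, dtype=float)
        if self.alpha.shape != (self.pattern.n_nodes,):
            raise ValueError("alpha must have one entry per node")
        if self.weights is not None:
            self.weights = np.asarray(self.weights, dtype=float)
            n = self.pattern.n_nodes
            if self.weights.shape != (n, n):
                raise ValueError("weights must be N x N")
            support = {(j, i) for i, j in zip(*np.nonzero(self.weights))}
            if not support <= set(self.pattern.arcs):
                raise ValueError("weights must be supported on pattern arcs")

    @property
    def n_nodes(self) -> int:
        return self.pattern.n_nodes

    def is_long_memory(self) -> bool:
        return not np.any(self.alpha == np.round(self.alpha))


@dataclass(frozen=True)
class MemoryKernel:
    """Power-law memory weights psi(alpha, j) for j = 0..J."""

    alpha: float
    J: int
    psi: np.ndarray


@dataclass(frozen=True)
class ExpandedMatrices:
    """The sequence A_0..A_K of the expanded recursion.

    A_0 is dense (A minus the lag-1 memory diagonal); A_j for j >= 1 is
    diagonal, stored as the full matrix for clarity at small N.
    """

    A_seq: tuple[np.ndarray, ...]


@dataclass(frozen=True)
class Trajectory:
    states: np.ndarray  # (K+1, N)
    inputs: np.ndarray  # (K, N)


def psi_weights(alpha: float, J: int) -> MemoryKernel:
    """Memory weights psi(alpha, j), j = 0..J, by the Gamma-ratio recurrence.

    ``psi[0] = 1`` and ``psi[j] = psi[j-1] * (j - 1 - alpha) / j``.  This
    equals Gamma(j - alpha) / (Gamma(-alpha) Gamma(j + 1)) wherever the
    latter is finite, handles integer alpha exactly via the zero factor,
    and never overflows (each factor has magnitude <= 1 for j > alpha + 1).
    """
    if J < 0:
        raise ValueError("J must be >= 0")
    alpha = float(alpha)
    psi = np.empty(J + 1)
    psi[0] = 1.0
    if J >= 1:
        j = np.arange(1, J + 1, dtype=float)
        factors = (j - 1.0 - alpha) / j
        psi[1:] = np.cumprod(factors)
    return MemoryKernel(alpha=alpha, J=J, psi=psi)


def _psi_table(alpha: np.ndarray, J: int) -> np.ndarray:
    """Per-node kernel table, shape (N, J+1); row i is psi(alpha_i, 0..J)."""
    alpha = np.asarray(alpha, dtype=float)
    out = np.empty((alpha.size, J + 1))
    out[:, 0] = 1.0
    if J >= 1:
        j = np.arange(1, J + 1, dtype=float)
        factors = (j[None, :] - 1.0 - alpha[:, None]) / j[None, :]
        out[:, 1:] = np.cumprod(factors, axis=1)
    return out


def _require_weights(net: FractionalNetwork) -> np.ndarray:
    if net.weights is None:
        raise ValueError(
            "network has no numeric weights; call sample_realization first"
        )
    return net.weights


def expansion_matrices(net: FractionalNetwork, K: int) -> ExpandedMatrices:
    """A_0..A_K: A_0 = A - D(alpha,1); A_j = -D(alpha, j+1), j >= 1."""
    A = _require_weights(net)
    table = _psi_table(net.alpha, K + 1)
    seq = [A - np.diag(table[:, 1])]
    for j in range(1, K + 1):
        seq.append(np.diag(-table[:, j + 1]))
    return ExpandedMatrices(tuple(seq))


def _b_matrix(n: int, driven: Sequence[int], b_gains: Sequence[float] | None) -> np.ndarray:
    driven = list(driven)
    B = np.zeros((n, len(driven)))
    gains = np.ones(len(driven)) if b_gains is None else np.asarray(b_gains, float)
    if gains.shape != (len(driven),):
        raise ValueError("b_gains must have one entry per driven node")
    for c, (i, g) in enumerate(zip(driven, gains)):
        B[i, c] = g
    return B


def simulate(
    net: FractionalNetwork,
    driven: Sequence[int],
    b_gains: Sequence[float] | None,
    inputs: np.ndarray,
    x0: np.ndarray,
    K: int,
    truncation: int | None = None,
) -> Trajectory:
    """Evaluate the full-history convolution recursion for K steps.

    ``inputs`` has shape (K, |driven|); B is diagonal with gains on the
    driven nodes (one dedicated input per driven node).  ``truncation``
    optionally limits the memory window to the last L lags; the neglected
    tail of the kernel is O(L**-alpha).
    """
    A = _require_weights(net)
    n = net.n_nodes
    driven = list(driven)
    x0 = np.asarray(x0, dtype=float)
    if x0.shape != (n,):
        raise ValueError(f"x0 must have shape ({n},)")
    inputs = np.asarray(inputs, dtype=float)
    if inputs.size == 0:
        inputs = np.zeros((K, len(driven)))
    if inputs.shape != (K, len(driven)):
        raise ValueError(f"inputs must have shape ({K}, {len(driven)})")
    B = _b_matrix(n, driven, b_gains)

    table = _psi_table(net.alpha, K + 1)  # (N, K+2)
    A0 = A - np.diag(table[:, 1])
    states = np.zeros((K + 1, n))
    states[0] = x0
    for k in range(K):
        acc = A0 @ states[k]
        lag_hi = k if truncation is None else min(k, truncation)
        for j in range(1, lag_hi + 1):
            # A_j x[k-j] with A_j = -diag(psi(:, j+1))
            acc -= table[:, j + 1] * states[k - j]
        if driven:
            acc += B @ inputs[k]
        states[k + 1] = acc
    return Trajectory(states=states, inputs=inputs)


def _propagators(net: FractionalNetwork, T: int) -> list[np.ndarray]:
    """G_0..G_{T-1} with G_0 = I, G_m = sum_{j<m} A_j G_{m-1-j}."""
    A = _require_weights(net)
    n = net.n_nodes
    table = _psi_table(net.alpha, T + 1)
    A0 = A - np.diag(table[:, 1])
    G = [np.eye(n)]
    for m in range(1, T):
        acc = A0 @ G[m - 1]
        for j in range(1, m):
            acc -= table[:, j + 1][:, None] * G[m - 1 - j]
        G.append(acc)
    return G


def reachability_matrix(
    net: FractionalNetwork,
    driven: Sequence[int],
    T: int,
    b_gains: Sequence[float] | None = None,
) -> np.ndarray:
    """Linear map from stacked inputs u[0..T-1] to x[T] with x0 = 0.

    Columns are ``[G_{T-1} B, G_{T-2} B, ..., G_0 B]``; full column rank N
    means the realization is controllable in T steps.
    """
    if T < 1:
        raise ValueError("T must be >= 1")
    driven = list(driven)
    n = net.n_nodes
    B = _b_matrix(n, driven, b_gains)
    G = _propagators(net, T)
    if not driven:
        return np.zeros((n, 0))
    blocks = [G[T - 1 - k] @ B for k in range(T)]
    return np.hstack(blocks)


def numeric_rank(M: np.ndarray, tol: float | None = None) -> int:
    """Numerical rank: singular values below max(dims)*eps*sigma_max are zero."""
    if M.size == 0:
        return 0
    s = np.linalg.svd(M, compute_uv=False)
    if s[0] == 0:
        return 0
    if tol is None:
        tol = max(M.shape) * np.finfo(float).eps * s[0]
    return int(np.sum(s > tol))


def sample_realization(
    pattern: DirectedPattern,
    rng: np.random.Generator,
    alpha: np.ndarray | None = None,
) -> FractionalNetwork:
    """Random numeric realization of a pattern.

    Arc weights i.i.d. uniform on [0.5, 1.5] with random sign; alpha i.i.d.
    uniform on (0.2, 0.8) unless given.
    """
    n = pattern.n_nodes
    W = np.zeros((n, n))
    for u, v in pattern.sorted_arcs():
        mag = rng.uniform(WEIGHT_LOW, WEIGHT_HIGH)
        W[v, u] = mag if rng.random() < 0.5 else -mag
    if alpha is None:
        alpha = rng.uniform(ALPHA_LOW, ALPHA_HIGH, size=n)
    return FractionalNetwork(pattern=pattern, alpha=np.asarray(alpha, float), weights=W)


def is_controllable_numeric(
    pattern_or_net: DirectedPattern | FractionalNetwork,
    driven: Sequence[int],
    T: int,
    trials: int = DEFAULT_TRIALS,
    seed: int = 0,
    tol: float | None = None,
) -> bool:
    """Probabilistic numeric oracle for T-step controllability.

    True iff any of ``trials`` random realizations yields a full-rank
    reachability matrix.  Accepts a bare pattern (weights and alpha sampled
    per trial) or a fixed :class:`FractionalNetwork` (single evaluation).
    """
    driven = list(driven)
    if isinstance(pattern_or_net, FractionalNetwork) and pattern_or_net.weights is not None:
        net = pattern_or_net
        R = reachability_matrix(net, driven, T)
        return numeric_rank(R, tol) == net.n_nodes
    pattern = (
        pattern_or_net.pattern
        if isinstance(pattern_or_net, FractionalNetwork)
        else pattern_or_net
    )
    if not driven:
        return False
    rng = np.random.default_rng(seed)
    for _ in range(trials):
        net = sample_realization(pattern, rng)
        R = reachability_matrix(net, driven, T)
        if numeric_rank(R, tol) == pattern.n_nodes:
            return True
    return False
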