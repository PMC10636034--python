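"""Network topology I/O, synthetic generators, and graph decompositions.

The central type is :class:`DirectedPattern`, a sparse boolean adjacency
pattern.  Convention used throughout the package: an arc ``(j, i)`` means
node ``j`` influences node ``i``, i.e. entry ``(row i, column j)`` of the
state matrix is a free (nonzero) parameter, so ``x_i[k+1]`` depends on
``x_j[k]``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Iterable

import networkx as nx
import numpy as np
import scipy.io
import scipy.sparse as sp

__all__ = [
    "DirectedPattern",
    "SCCDecomposition",
    "read_edgelist",
    "write_edgelist",
    "read_matrix_market",
    "generate_erdos_renyi",
    "generate_barabasi_albert",
    "generate_watts_strogatz",
    "generate_from_config",
    "source_sccs",
]


class EdgeListParseError(ValueError):
    """Raised when an edge-list file cannot be parsed."""


@dataclass(frozen=True)
class DirectedPattern:
    """Sparse boolean N x N structural adjacency (the free pattern of A).

    Parameters
    ----------
    n_nodes:
        Number of nodes; indices run over ``range(n_nodes)``.
    arcs:
        Set of ordered pairs ``(source, target)``.  Self-loops permitted.
    node_labels:
        Optional original labels, one per node.
    """

    n_nodes: int
    arcs: frozenset[tuple[int, int]]
    node_labels: tuple[str, ...] | None = None

    def __post_init__(self):
        if self.n_nodes <= 0:
            raise ValueError("n_nodes must be positive")
        object.__setattr__(self, "arcs", frozenset(self.arcs))
        for u, v in self.arcs:
            if not (0 <= u < self.n_nodes and 0 <= v < self.n_nodes):
                raise ValueError(f"arc ({u}, {v}) out of range [0, {self.n_nodes})")
        if self.node_labels is not None:
            labels = tuple(self.node_labels)
            if len(labels) != self.n_nodes:
                raise ValueError("node_labels length must equal n_nodes")
            object.__setattr__(self, "node_labels", labels)

    @property
    def n_arcs(self) -> int:
        return len(self.arcs)

    def labels(self) -> tuple[str, ...]:
        if self.node_labels is not None:
            return self.node_labels
        return tuple(str(i) for i in range(self.n_nodes))

    def has_all_selfloops(self) -> bool:
        return all((v, v) in self.arcs for v in range(self.n_nodes))

    def sorted_arcs(self) -> list[tuple[int, int]]:
        return sorted(self.arcs)

    def to_sparse(self) -> sp.csr_matrix:
        """Adjacency as CSR with entry (target, source) = 1 per arc."""
        if not self.arcs:
            return sp.csr_matrix((self.n_nodes, self.n_nodes), dtype=np.int8)
        src, dst = zip(*self.sorted_arcs())
        data = np.ones(len(src), dtype=np.int8)
        return sp.csr_matrix(
            (data, (np.asarray(dst), np.asarray(src))),
            shape=(self.n_nodes, self.n_nodes),
        )

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(range(self.n_nodes))
        g.add_edges_from(self.arcs)
        return g

    def symmetrized(self) -> "DirectedPattern":
        """Every arc paired with its reversal (self-loops unchanged)."""
        arcs = set(self.arcs) | {(v, u) for u, v in self.arcs}
        return DirectedPattern(self.n_nodes, frozenset(arcs), self.node_labels)


@dataclass(frozen=True)
class SCCDecomposition:
    """Strongly connected components and their source flags.

    ``is_source[c]`` is true iff component ``c`` has no incoming arcs from
    other components in the condensation.
    """

    components: tuple[frozenset[int], ...]
    is_source: tuple[bool, ...]

    def source_components(self) -> list[frozenset[int]]:
        return [c for c, s in zip(self.components, self.is_source) if s]


def _pattern_from_labelled_pairs(
    pairs: Iterable[tuple[str, str]], directed: bool
) -> DirectedPattern:
    index: dict[str, int] = {}
    arcs: set[tuple[int, int]] = set()
    for a, b in pairs:
        for lbl in (a, b):
            if lbl not in index:
                index[lbl] = len(index)
        u, v = index[a], index[b]
        arcs.add((u, v))
        if not directed:
            arcs.add((v, u))
    labels = tuple(sorted(index, key=index.get))
    return DirectedPattern(len(index), frozenset(arcs), labels)


def read_edgelist(path, directed: bool = True) -> DirectedPattern:
    """Read a whitespace-separated ``src dst`` edge list.

    Lines starting with ``#`` are ignored; labels are arbitrary strings
    mapped to indices in first-appearance order.  Duplicate arcs collapse
    silently (pattern semantics).  When ``directed`` is false each edge
    becomes two opposing arcs.
    """
    pairs: list[tuple[str, str]] = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 2:
                raise EdgeListParseError(
                    f"{path}: line {lineno}: expected 'src dst', got {line!r}"
                )
            pairs.append((parts[0], parts[1]))
    if not pairs:
        raise EdgeListParseError(f"{path}: no edges found")
    return _pattern_from_labelled_pairs(pairs, directed)


def write_edgelist(pattern: DirectedPattern, path) -> None:
    """Write arcs as ``src<TAB>dst`` lines using the pattern's labels.

    Isolated nodes are recorded in a header comment so a round-trip through
    :func:`read_edgelist` preserves ``n_nodes`` (read_edgelist itself only
    sees labelled endpoints; the comment documents the full node set).
    """
    labels = pattern.labels()
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# nodes: {pattern.n_nodes}\n")
        for u, v in pattern.sorted_arcs():
            fh.write(f"{labels[u]}\t{labels[v]}\n")


def read_matrix_market(path, directed: bool = True) -> DirectedPattern:
    """Read a coordinate-format Matrix Market file as a pattern.

    Stored entry ``(i, j)`` (1-based) with a nonzero value becomes arc
    ``(j-1, i-1)`` — column influences row.  Symmetric-header files are
    expanded by scipy; explicit zeros are dropped.
    """
    mat = scipy.io.mmread(path)
    if not sp.issparse(mat):
        raise ValueError(f"{path}: unsupported Matrix Market format (need coordinate)")
    mat = mat.tocoo()
    if mat.shape[0] != mat.shape[1]:
        raise ValueError(f"{path}: adjacency must be square, got {mat.shape}")
    arcs: set[tuple[int, int]] = set()
    for i, j, v in zip(mat.row, mat.col, mat.data):
        if v == 0:
            continue
        arcs.add((int(j), int(i)))
        if not directed:
            arcs.add((int(i), int(j)))
    return DirectedPattern(int(mat.shape[0]), frozenset(arcs))


def generate_erdos_renyi(n: int, m: int, seed: int) -> DirectedPattern:
    """Directed G(n, m): exactly ``m`` distinct arcs, uniform, no self-loops."""
    if n <= 0:
        raise ValueError("n must be positive")
    max_arcs = n * (n - 1)
    if not 0 <= m <= max_arcs:
        raise ValueError(f"m={m} out of range [0, {max_arcs}] for n={n}")
    rng = np.random.default_rng(seed)
    flat = rng.choice(max_arcs, size=m, replace=False)
    # decode index k -> ordered pair skipping the diagonal
    u = flat // (n - 1)
    r = flat % (n - 1)
    v = np.where(r >= u, r + 1, r)
    arcs = frozenset(zip(u.tolist(), v.tolist()))
    return DirectedPattern(n, arcs)


def generate_barabasi_albert(n: int, k: int, seed: int) -> DirectedPattern:
    """Preferential-attachment graph grown from a k-node seed clique.

    Each new vertex attaches to ``k`` distinct existing vertices chosen
    proportionally to degree (each seed node gets one phantom half-edge so
    the first attachment is well defined even for k=1).  The undirected
    result is symmetrized into a DirectedPattern.  Arc count is the
    deterministic ``2 * (k*(k-1)/2 + (n-k)*k)``.
    """
    if not 1 <= k < n:
        raise ValueError(f"require 1 <= k < n, got k={k}, n={n}")
    rng = np.random.default_rng(seed)
    edges: set[tuple[int, int]] = set()
    for i in range(k):
        for j in range(i + 1, k):
            edges.add((i, j))
    # degree-proportional sampling pool; seeded with one copy per clique node
    pool: list[int] = list(range(k))
    for i in range(k):
        for j in range(i + 1, k):
            pool.extend((i, j))
    for new in range(k, n):
        targets: set[int] = set()
        while len(targets) < k:
            targets.add(pool[rng.integers(len(pool))])
        for t in sorted(targets):
            edges.add((t, new))
            pool.extend((t, new))
    arcs = frozenset(
        pair for u, v in edges for pair in ((u, v), (v, u))
    )
    return DirectedPattern(n, arcs)


def generate_watts_strogatz(
    n: int, neighbors: int = 4, p: float = 0.2, seed: int = 0
) -> DirectedPattern:
    """Watts–Strogatz ring with rewiring, symmetrized to a pattern.

    ``neighbors`` must be even (ring lattice joins each node to its
    ``neighbors`` nearest neighbours); rewiring moves edges but never adds
    or removes them, so the undirected edge count is ``n * neighbors / 2``.
    """
    if neighbors % 2 != 0:
        raise ValueError("neighbors must be even")
    if neighbors >= n:
        raise ValueError("neighbors must be < n")
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must be in [0, 1]")
    g = nx.watts_strogatz_graph(n, neighbors, p, seed=int(seed))
    arcs = frozenset(
        pair for u, v in g.edges() for pair in ((u, v), (v, u))
    )
    return DirectedPattern(n, arcs)


def generate_from_config(config: dict | str) -> DirectedPattern:
    """Dispatch on a generator config ``{"family": ..., "n": ..., "seed": ...}``.

    Accepts a dict or a path to a JSON file.  Families: ``er`` (needs m),
    ``ba`` (needs k), ``ws`` (needs p, optional neighbors).
    """
    if isinstance(config, str):
        with open(config, "r", encoding="utf-8") as fh:
            config = json.load(fh)
    family = config["family"]
    n = int(config["n"])
    seed = int(config.get("seed", 0))
    if family == "er":
        return generate_erdos_renyi(n, int(config["m"]), seed)
    if family == "ba":
        return generate_barabasi_albert(n, int(config["k"]), seed)
    if family == "ws":
        return generate_watts_strogatz(
            n, int(config.get("neighbors", 4)), float(config["p"]), seed
        )
    raise ValueError(f"unknown family {family!r}")


def source_sccs(pattern: DirectedPattern) -> SCCDecomposition:
    """Strongly connected components with source flags.

    A component is a source iff it has in-degree 0 in the condensation.
    """
    g = pattern.to_networkx()
    comps = [frozenset(c) for c in nx.strongly_connected_components(g)]
    comps.sort(key=min)
    member = {}
    for ci, comp in enumerate(comps):
        for v in comp:
            member[v] = ci
    is_source = [True] * len(comps)
    for u, v in pattern.arcs:
        if member[u] != member[v]:
            is_source[member[v]] = False
    return SCCDecomposition(tuple(comps), tuple(is_source))
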