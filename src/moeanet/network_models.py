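"""Weighted benchmark networks: synthetic generators and GML/edge-list I/O.

All networks follow the weighted-adjacency convention of the reconstruction
problem: x_ij >= 1 on present edges, 0 otherwise, symmetric, zero diagonal.
Topologies come from networkx; edge weights are drawn independently and
applied symmetrically.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

__all__ = [
    "WeightedNetwork",
    "gen_er",
    "gen_ba",
    "gen_nw",
    "gen_ws",
    "assign_weights",
    "karate_club",
    "read_network",
    "write_network",
]


@dataclass
class WeightedNetwork:
    """Undirected weighted network stored as a dense adjacency matrix."""

    adjacency: np.ndarray
    node_labels: list[str] | None = field(default=None)

    def __post_init__(self) -> None:
        X = np.asarray(self.adjacency, dtype=float)
        if X.ndim != 2 or X.shape[0] != X.shape[1]:
            raise ValueError("adjacency must be a square matrix")
        if np.any(np.diag(X) != 0):
            raise ValueError("adjacency diagonal must be all zeros")
        if not np.allclose(X, X.T):
            raise ValueError("adjacency must be symmetric (undirected network)")
        nz = X[X > 0]
        if nz.size and nz.min() < 1.0 - 1e-12:
            raise ValueError("nonzero edge weights must be >= 1 (weighted-adjacency convention)")
        if np.any(X < 0):
            raise ValueError("edge weights must be nonnegative")
        self.adjacency = X

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def degrees(self) -> np.ndarray:
        return (self.adjacency > 0).sum(axis=1)

    @property
    def mean_degree(self) -> float:
        return float(self.degrees.mean())

    def edges(self):
        """Yield (i, j, weight) with i < j."""
        iu, ju = np.nonzero(np.triu(self.adjacency, k=1))
        for i, j in zip(iu, ju):
            yield int(i), int(j), float(self.adjacency[i, j])


def _binary_from_nx(g: nx.Graph, n: int) -> np.ndarray:
    X = np.zeros((n, n))
    for u, v in g.edges():
        if u == v:
            continue
        X[u, v] = X[v, u] = 1.0
    return X


def assign_weights(network: WeightedNetwork, low: float = 1.0, high: float = 3.0,
                   seed: int = 0) -> WeightedNetwork:
    """Give every edge an independent Uniform[low, high] weight, symmetrically.

    ``low`` must be >= 1 so the result respects the x_ij >= 1 convention.
    """
    if low < 1.0:
        raise ValueError(f"low must be >= 1 under the weighted-adjacency convention; got {low}")
    if high < low:
        raise ValueError("high must be >= low")
    rng = np.random.default_rng(seed)
    X = network.adjacency
    n = X.shape[0]
    out = np.zeros_like(X)
    iu, ju = np.nonzero(np.triu(X, k=1))
    w = rng.uniform(low, high, size=iu.size)
    out[iu, ju] = w
    out[ju, iu] = w
    return WeightedNetwork(out, node_labels=network.node_labels)


def gen_er(n: int, k_avg: float, seed: int = 0, low: float = 1.0, high: float = 3.0) -> WeightedNetwork:
    """Weighted Erdos-Renyi G(n, p) with p chosen so the mean degree is ``k_avg``."""
    if n < 2:
        raise ValueError("n must be >= 2")
    if not 0 < k_avg < n:
        raise ValueError(f"k_avg must lie in (0, n); got {k_avg}")
    p = k_avg / (n - 1)
    g = nx.fast_gnp_random_graph(n, p, seed=int(seed))
    net = WeightedNetwork(_binary_from_nx(g, n))
    return assign_weights(net, low, high, seed=_weight_seed(seed))


def gen_ba(n: int, m_attach: int, seed: int = 0, low: float = 1.0, high: float = 3.0) -> WeightedNetwork:
    """Weighted Barabasi-Albert scale-free network (preferential attachment)."""
    if not 1 <= m_attach < n:
        raise ValueError(f"m_attach must lie in [1, n); got {m_attach}")
    g = nx.barabasi_albert_graph(n, m_attach, seed=int(seed))
    net = WeightedNetwork(_binary_from_nx(g, n))
    return assign_weights(net, low, high, seed=_weight_seed(seed))


def gen_nw(n: int, k_ring: int, p_add: float, seed: int = 0, low: float = 1.0,
           high: float = 3.0) -> WeightedNetwork:
    """Weighted Newman-Watts small world: ring lattice plus random shortcuts."""
    _check_ring(n, k_ring)
    if not 0 <= p_add <= 1:
        raise ValueError("p_add must lie in [0, 1]")
    g = nx.newman_watts_strogatz_graph(n, k_ring, p_add, seed=int(seed))
    net = WeightedNetwork(_binary_from_nx(g, n))
    return assign_weights(net, low, high, seed=_weight_seed(seed))


def gen_ws(n: int, k_ring: int, p_rewire: float, seed: int = 0, low: float = 1.0,
           high: float = 3.0) -> WeightedNetwork:
    """Weighted Watts-Strogatz small world: ring lattice with rewired edges."""
    _check_ring(n, k_ring)
    if not 0 <= p_rewire <= 1:
        raise ValueError("p_rewire must lie in [0, 1]")
    g = nx.watts_strogatz_graph(n, k_ring, p_rewire, seed=int(seed))
    net = WeightedNetwork(_binary_from_nx(g, n))
    return assign_weights(net, low, high, seed=_weight_seed(seed))


def karate_club(seed: int = 0, low: float = 1.0, high: float = 3.0) -> WeightedNetwork:
    """Zachary karate-club benchmark (34 nodes, 78 edges) with random edge weights."""
    g = nx.karate_club_graph()
    net = WeightedNetwork(_binary_from_nx(g, g.number_of_nodes()))
    return assign_weights(net, low, high, seed=_weight_seed(seed))


def _check_ring(n: int, k_ring: int) -> None:
    if n < 3:
        raise ValueError("n must be >= 3 for ring-based models")
    if not 2 <= k_ring < n:
        raise ValueError(f"k_ring must lie in [2, n); got {k_ring}")


def _weight_seed(seed: int) -> np.random.SeedSequence:
    # decorrelate the weight stream from the topology stream
    return np.random.SeedSequence([int(seed), 1])


# ---------------------------------------------------------------------------
# file I/O


def _infer_format(path: str, fmt: str | None) -> str:
    if fmt is not None:
        return fmt
    p = str(path).lower()
    if p.endswith(".gml"):
        return "gml"
    return "edgelist"


def read_network(path, fmt: str | None = None) -> WeightedNetwork:
    """Read a network from GML or a 2-3 column delimited edge list.

    Missing edge weights default to 1.  GML node labels are preserved;
    nodes are relabeled to 0-based integer ids internally.
    """
    fmt = _infer_format(path, fmt)
    if fmt == "gml":
        return _read_gml(path)
    if fmt == "edgelist":
        return _read_edgelist(path)
    raise ValueError(f"unknown network format {fmt!r}")


def _read_gml(path) -> WeightedNetwork:
    try:
        g = nx.read_gml(path, label="id")
    except Exception as exc:  # networkx raises several parse-error types
        raise ValueError(f"failed to parse GML file {path}: {exc}") from exc
    nodes = sorted(g.nodes())
    index = {u: k for k, u in enumerate(nodes)}
    n = len(nodes)
    X = np.zeros((n, n))
    for u, v, data in g.edges(data=True):
        if u == v:
            continue
        w = float(data.get("weight", data.get("value", 1.0)))
        X[index[u], index[v]] = w
        X[index[v], index[u]] = w
    labels = [str(g.nodes[u].get("label", u)) for u in nodes]
    return WeightedNetwork(X, node_labels=labels)


def _read_edgelist(path) -> WeightedNetwork:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) not in (2, 3):
                raise ValueError(f"{path}:{lineno}: expected 2 or 3 columns, got {len(parts)}")
            try:
                u, v = int(parts[0]), int(parts[1])
                w = float(parts[2]) if len(parts) == 3 else 1.0
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
            rows.append((u, v, w))
    if not rows:
        raise ValueError(f"{path}: empty edge list")
    n = max(max(u, v) for u, v, _ in rows) + 1
    X = np.zeros((n, n))
    for u, v, w in rows:
        if u == v:
            continue
        X[u, v] = w
        X[v, u] = w
    return WeightedNetwork(X)


def write_network(network: WeightedNetwork, path, fmt: str | None = None) -> None:
    """Write GML or a weighted edge list; read(write(G)) reproduces the adjacency."""
    fmt = _infer_format(path, fmt)
    if fmt == "gml":
        g = nx.Graph()
        labels = network.node_labels
        for i in range(network.n_nodes):
            if labels is not None:
                g.add_node(i, label=labels[i])
            else:
                g.add_node(i)
        for i, j, w in network.edges():
            g.add_edge(i, j, weight=w)
        nx.write_gml(g, path)
    elif fmt == "edgelist":
        with open(path, "w") as fh:
            for i, j, w in network.edges():
                fh.write(f"{i}\t{j}\t{w!r}\n")
    else:
        raise ValueError(f"unknown network format {fmt!r}")
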