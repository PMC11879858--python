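"""Network substrates for contagion simulations.

Generators for isolated ego stars, classical random-graph models (restricted
to their giant component), and the degree-inverse neighbour-walk reduction
used to shrink a large empirical graph to a tractable connected sample.
All generators take an explicit :class:`numpy.random.Generator`; none touch
global RNG state.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable

import networkx as nx
import numpy as np
from scipy import stats

__all__ = [
    "Network",
    "DegreeSampler",
    "make_star",
    "sample_ego_degrees",
    "make_random_network",
    "reduce_by_neighbor_walk",
    "read_edgelist",
    "write_edgelist",
]


@dataclass
class Network:
    """Undirected simple graph with dense integer node indices.

    Wraps a :class:`networkx.Graph` whose nodes are relabelled to
    ``0..n_nodes-1``; keeps the original labels for round-tripping edge lists.
    """

    graph: nx.Graph
    labels: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.labels:
            self.labels = list(range(self.graph.number_of_nodes()))

    @classmethod
    def from_graph(cls, g: nx.Graph) -> "Network":
        g = nx.Graph(g)  # drop multi-edges if any
        g.remove_edges_from(nx.selfloop_edges(g))
        labels = list(g.nodes())
        mapping = {u: i for i, u in enumerate(labels)}
        return cls(graph=nx.relabel_nodes(g, mapping, copy=True), labels=labels)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    @property
    def degrees(self) -> np.ndarray:
        return np.array([self.graph.degree(i) for i in range(self.n_nodes)])

    def neighbors(self, i: int) -> list[int]:
        return list(self.graph.neighbors(i))

    def adjacency(self):
        """Sparse CSR adjacency indicator A_ij in {0,1}."""
        return nx.to_scipy_sparse_array(
            self.graph, nodelist=range(self.n_nodes), format="csr", dtype=np.int8
        )

    def adjacency_lists(self) -> list[np.ndarray]:
        return [np.array(self.neighbors(i), dtype=np.int64) for i in range(self.n_nodes)]

    def is_connected(self) -> bool:
        return self.n_nodes > 0 and nx.is_connected(self.graph)


@dataclass(frozen=True)
class DegreeSampler:
    """Zero-truncated binomial sampler for ego degrees.

    Degrees are Binomial(N, p) conditioned on being >= 1; truncation is done
    by rejection (redraw on zero), which realises the conditional law exactly.
    """

    N: int = 1000
    p: float = 0.004
    exclude_zero: bool = True

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        draws = rng.binomial(self.N, self.p, size=n)
        if self.exclude_zero:
            while True:
                zero = draws == 0
                if not zero.any():
                    break
                draws[zero] = rng.binomial(self.N, self.p, size=int(zero.sum()))
        return draws

    def pmf(self, k: np.ndarray | int) -> np.ndarray:
        """Probability mass of the (possibly truncated) degree distribution."""
        base = stats.binom.pmf(k, self.N, self.p)
        if not self.exclude_zero:
            return base
        p0 = stats.binom.pmf(0, self.N, self.p)
        out = base / (1.0 - p0)
        return np.where(np.asarray(k) >= 1, out, 0.0)

    def support(self, mass_cut: float = 1e-12) -> np.ndarray:
        """Degrees whose truncated pmf exceeds ``mass_cut``."""
        ks = np.arange(1 if self.exclude_zero else 0, self.N + 1)
        pm = self.pmf(ks)
        keep = pm > mass_cut
        # contiguous range up to the last kept value
        last = np.nonzero(keep)[0].max()
        first = np.nonzero(keep)[0].min()
        return ks[first : last + 1]


def make_star(k: int) -> Network:
    """Star network: one centre (node 0) of degree ``k`` and ``k`` leaves."""
    if k < 1:
        raise ValueError(f"star degree must be >= 1, got {k}")
    return Network.from_graph(nx.star_graph(k))


def sample_ego_degrees(
    n_egos: int, sampler: DegreeSampler, rng: np.random.Generator
) -> np.ndarray:
    if n_egos < 1:
        raise ValueError("n_egos must be >= 1")
    return sampler.sample(n_egos, rng)


def make_random_network(
    model: str,
    params: dict | None = None,
    rng: np.random.Generator | None = None,
) -> Network:
    """Giant component of one realisation of a random-graph model.

    Supported models: ``er`` (n, mean_degree), ``ba`` (n, m), ``ws``
    (n, k, p_rewire), ``sbm`` (sizes, p_matrix).
    """
    params = dict(params or {})
    if rng is None:
        rng = np.random.default_rng()
    seed = int(rng.integers(0, 2**31 - 1))
    model = model.lower()
    if model == "er":
        n = int(params.get("n", 1000))
        mean_degree = float(params.get("mean_degree", 4.0))
        p = mean_degree / (n - 1)
        g = nx.fast_gnp_random_graph(n, p, seed=seed)
    elif model == "ba":
        g = nx.barabasi_albert_graph(int(params.get("n", 1000)), int(params.get("m", 2)), seed=seed)
    elif model == "ws":
        g = nx.watts_strogatz_graph(
            int(params.get("n", 1000)),
            int(params.get("k", 4)),
            float(params.get("p_rewire", 0.1)),
            seed=seed,
        )
    elif model == "sbm":
        sizes = [int(s) for s in params["sizes"]]
        p_matrix = params["p_matrix"]
        g = nx.stochastic_block_model(sizes, p_matrix, seed=seed)
    else:
        raise ValueError(f"unknown network model {model!r}")
    giant = max(nx.connected_components(g), key=len)
    return Network.from_graph(g.subgraph(giant))


def reduce_by_neighbor_walk(
    big_net: Network,
    target_size: int,
    rng: np.random.Generator,
    start: int | None = None,
) -> Network:
    """Connected subnetwork grown by a degree-inverse neighbour walk.

    Starting from one uniformly random node, repeatedly select a neighbour of
    the current node with probability inversely proportional to the
    neighbour's degree; a newly selected node is added together with the
    connecting edge (so the result is a tree with ``target_size - 1`` edges).
    If the selected neighbour is already included, the walk moves there
    without adding anything and reselects from that node's neighbours.
    """
    if target_size < 1:
        raise ValueError("target_size must be >= 1")
    if target_size > big_net.n_nodes:
        raise ValueError(
            f"target_size {target_size} exceeds network size {big_net.n_nodes}"
        )
    adj = big_net.adjacency_lists()
    degs = big_net.degrees.astype(float)
    current = int(rng.integers(big_net.n_nodes)) if start is None else int(start)
    included = {current}
    edges: list[tuple[int, int]] = []
    while len(included) < target_size:
        nbs = adj[current]
        w = 1.0 / degs[nbs]
        nxt = int(nbs[rng.choice(len(nbs), p=w / w.sum())])
        if nxt not in included:
            included.add(nxt)
            edges.append((current, nxt))
        current = nxt
    g = nx.Graph()
    g.add_nodes_from(included)
    g.add_edges_from(edges)
    return Network.from_graph(g)


def _open_maybe_gzip(path: str | Path, mode: str) -> IO:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode + "t")
    return open(path, mode)


def read_edgelist(path: str | Path) -> Network:
    """Read a whitespace-separated ``u v`` edge list ('#' starts a comment)."""
    g = nx.Graph()
    with _open_maybe_gzip(path, "r") as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) < 2:
                raise ValueError(f"malformed edge-list line: {line!r}")
            g.add_edge(parts[0], parts[1])
    return Network.from_graph(g)


def write_edgelist(net: Network, path: str | Path) -> None:
    with _open_maybe_gzip(path, "w") as fh:
        for u, v in net.graph.edges():
            fh.write(f"{net.labels[u]} {net.labels[v]}\n")
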