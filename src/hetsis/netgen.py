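"""Network substrates: Erdős–Rényi, uncorrelated power-law, and edge-list IO.

Networks are simple undirected graphs over contiguous integer node labels
``0..n-1``, held as a symmetric 0/1 sparse adjacency matrix.  The power-law
generator is the uncorrelated configuration model: degrees are drawn from a
truncated discrete power law with the structural cutoff ``k_max = floor(sqrt(N))``,
which suppresses degree-degree correlations for exponents below 3, and the
stub-matched multigraph is then simplified (self-loops and multi-edges erased).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components

logger = logging.getLogger(__name__)

__all__ = [
    "Network",
    "generate_er",
    "generate_powerlaw",
    "sample_discrete_powerlaw",
    "giant_component",
    "read_edge_list",
    "write_edge_list",
]


@dataclass(frozen=True)
class Network:
    """Simple undirected graph with a sparse adjacency view.

    Attributes
    ----------
    adjacency : scipy.sparse.csr_array
        Symmetric 0/1 matrix with zero diagonal.
    meta : dict
        Provenance of the graph (generator name, parameters, seed).
    """

    adjacency: sp.csr_array
    meta: dict = field(default_factory=dict, compare=False)

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def degrees(self) -> np.ndarray:
        return np.asarray(self.adjacency.sum(axis=1)).ravel().astype(np.int64)

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.nnz // 2)

    def edges(self) -> np.ndarray:
        """Edge list as an (m, 2) array of sorted pairs i < j."""
        coo = sp.triu(self.adjacency, k=1).tocoo()
        e = np.column_stack([coo.row, coo.col]).astype(np.int64)
        order = np.lexsort((e[:, 1], e[:, 0]))
        return e[order]

    def is_connected(self) -> bool:
        n_comp, _ = connected_components(self.adjacency, directed=False)
        return n_comp == 1

    def validate(self) -> None:
        """Raise ``ValueError`` if the graph is not simple and undirected."""
        a = self.adjacency
        if a.shape[0] != a.shape[1]:
            raise ValueError("adjacency must be square")
        if a.diagonal().any():
            raise ValueError("self-loops present")
        if (a != a.T).nnz != 0:
            raise ValueError("adjacency not symmetric")
        if a.nnz and not np.all(a.data == 1):
            raise ValueError("adjacency entries must be 0/1")
        if self.degrees.sum() != 2 * self.n_edges:
            raise ValueError("degree sum inconsistent with edge count")

    @classmethod
    def from_edges(cls, n_nodes: int, edges, meta: dict | None = None) -> "Network":
        """Build from an iterable of (i, j) pairs; duplicates/reversals collapse."""
        edges = np.asarray(list(edges) if not isinstance(edges, np.ndarray) else edges,
                           dtype=np.int64).reshape(-1, 2)
        if len(edges):
            lo = edges.min(axis=1)
            hi = edges.max(axis=1)
            keep = lo != hi
            lo, hi = lo[keep], hi[keep]
            pairs = np.unique(np.column_stack([lo, hi]), axis=0)
        else:
            pairs = edges
        row = np.concatenate([pairs[:, 0], pairs[:, 1]])
        col = np.concatenate([pairs[:, 1], pairs[:, 0]])
        a = sp.csr_array(
            (np.ones(len(row), dtype=np.int8), (row, col)), shape=(n_nodes, n_nodes)
        )
        return cls(adjacency=a, meta=meta or {})

    @classmethod
    def from_networkx(cls, g: nx.Graph, meta: dict | None = None) -> "Network":
        n = g.number_of_nodes()
        a = nx.to_scipy_sparse_array(g, nodelist=range(n), dtype=np.int8, format="csr")
        a.setdiag(0)
        a.eliminate_zeros()
        a.data[:] = 1
        return cls(adjacency=sp.csr_array(a), meta=meta or {})


def generate_er(n_nodes: int, mean_degree: float, seed: int) -> Network:
    """G(N, p) graph with p chosen to hit a target mean degree.

    Parameters
    ----------
    n_nodes : int
        Number of nodes, at least 2.
    mean_degree : float
        Target mean degree; p = mean_degree / (n_nodes - 1).
    seed : int
        Seed for the graph sampler.
    """
    if n_nodes < 2:
        raise ValueError("n_nodes must be >= 2")
    p = mean_degree / (n_nodes - 1)
    if not 0 < p <= 1:
        raise ValueError(f"edge probability p={p} outside (0, 1]")
    g = nx.fast_gnp_random_graph(n_nodes, p, seed=int(seed))
    return Network.from_networkx(
        g, meta={"kind": "er", "n": n_nodes, "mean_degree": mean_degree, "seed": seed}
    )


def sample_discrete_powerlaw(
    n_samples: int, gamma: float, k_min: int, k_max: int, seed: int
) -> np.ndarray:
    """I.i.d. draws from P(k) ∝ k^(-gamma) on the integers [k_min, k_max].

    Sampling is by inverse CDF on the exactly normalized mass function, so
    moments match the truncated zeta values to Monte Carlo error.
    """
    if k_min > k_max:
        raise ValueError("k_min must not exceed k_max")
    if k_min < 1:
        raise ValueError("k_min must be >= 1")
    support = np.arange(k_min, k_max + 1, dtype=np.int64)
    pmf = support.astype(float) ** (-gamma)
    pmf /= pmf.sum()
    cdf = np.cumsum(pmf)
    rng = np.random.default_rng(seed)
    u = rng.random(n_samples)
    idx = np.searchsorted(cdf, u, side="right")
    return support[np.minimum(idx, len(support) - 1)]


def generate_powerlaw(n_nodes: int, gamma: float, k_min: int, seed: int) -> Network:
    """Uncorrelated configuration-model graph with P(k) ∝ k^(-gamma).

    Degrees are truncated to [k_min, floor(sqrt(N))] (structural cutoff).
    If the sampled degree sequence sums odd, the last entry is resampled
    until the sum is even.  Self-loops and multi-edges from stub matching
    are erased; the removed multiplicity is logged.
    """
    if gamma <= 2:
        raise ValueError("gamma must exceed 2")
    k_max = int(np.floor(np.sqrt(n_nodes)))
    if k_min > k_max:
        raise ValueError(f"empty degree support: k_min={k_min} > floor(sqrt(N))={k_max}")
    degrees = sample_discrete_powerlaw(n_nodes, gamma, k_min, k_max, seed)
    rng = np.random.default_rng(seed + 1)
    support = np.arange(k_min, k_max + 1, dtype=np.int64)
    pmf = support.astype(float) ** (-gamma)
    pmf /= pmf.sum()
    while degrees.sum() % 2 != 0:
        degrees[-1] = rng.choice(support, p=pmf)
    g = nx.configuration_model(degrees.tolist(), seed=int(seed))
    n_stub_edges = g.number_of_edges()
    g = nx.Graph(g)
    g.remove_edges_from(nx.selfloop_edges(g))
    removed = n_stub_edges - g.number_of_edges()
    if removed:
        logger.info(
            "configuration model: removed %d self-loop/multi-edge stubs "
            "(%.3g%% of edges)", removed, 100 * removed / n_stub_edges
        )
    return Network.from_networkx(
        g,
        meta={
            "kind": "powerlaw",
            "n": n_nodes,
            "gamma": gamma,
            "k_min": k_min,
            "k_max": k_max,
            "seed": seed,
            "removed_edges": removed,
        },
    )


def giant_component(net: Network) -> tuple[Network, np.ndarray]:
    """Largest connected component, nodes relabeled contiguously.

    Returns the induced subgraph and the old→new label map (an ``n_nodes``
    array with -1 for dropped nodes).  Ties between equal-size components
    break toward the component containing the smallest original label.
    """
    if net.n_nodes == 0:
        raise ValueError("empty graph")
    n_comp, labels = connected_components(net.adjacency, directed=False)
    counts = np.bincount(labels, minlength=n_comp)
    # scipy assigns component ids in order of first-seen node, so argmax's
    # first-match rule realizes the smallest-label tie-break
    target = int(np.argmax(counts))
    keep = np.flatnonzero(labels == target)
    mapping = np.full(net.n_nodes, -1, dtype=np.int64)
    mapping[keep] = np.arange(len(keep))
    sub = net.adjacency[np.ix_(keep, keep)]
    meta = dict(net.meta)
    meta["giant_component_of"] = net.n_nodes
    return Network(adjacency=sp.csr_array(sub), meta=meta), mapping


def read_edge_list(path, indexing: str = "auto") -> Network:
    """Read a whitespace-delimited two-column edge list.

    Lines beginning with '#' are ignored.  Duplicate and reversed pairs
    collapse to one undirected edge; self-loops are dropped with a logged
    count.  ``indexing`` is one of ``{"0-based", "1-based", "auto"}``; auto
    infers 1-based iff the minimum label is 1 and 0 never appears.
    """
    if indexing not in ("0-based", "1-based", "auto"):
        raise ValueError(f"unknown indexing mode {indexing!r}")
    pairs = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            tokens = stripped.split()
            if len(tokens) < 2:
                raise ValueError(f"{path}:{lineno}: expected two columns, got {stripped!r}")
            try:
                i, j = int(tokens[0]), int(tokens[1])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer token in {stripped!r}") from exc
            pairs.append((i, j))
    if not pairs:
        raise ValueError(f"{path}: no edges found")
    arr = np.asarray(pairs, dtype=np.int64)
    if indexing == "auto":
        indexing = "1-based" if (arr.min() == 1 and not (arr == 0).any()) else "0-based"
    if indexing == "1-based":
        if arr.min() < 1:
            raise ValueError("1-based edge list contains labels below 1")
        arr = arr - 1
    if arr.min() < 0:
        raise ValueError("negative node labels")
    n_loops = int((arr[:, 0] == arr[:, 1]).sum())
    if n_loops:
        logger.info("dropped %d self-loop line(s) from %s", n_loops, path)
    n_nodes = int(arr.max()) + 1
    return Network.from_edges(n_nodes, arr, meta={"kind": "file", "path": str(path)})


def write_edge_list(net: Network, path) -> None:
    """Write canonical 0-based sorted pairs, one edge per line."""
    with open(path, "w") as fh:
        fh.write(f"# nodes={net.n_nodes} edges={net.n_edges}\n")
        for i, j in net.edges():
            fh.write(f"{i} {j}\n")
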