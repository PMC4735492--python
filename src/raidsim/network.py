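"""Friendship-network construction, I/O, and characterization.

Networks are undirected, simple, connected graphs over contiguous integer
node ids ``0..N-1``.  Loaders remap arbitrary labels onto that range and keep
the mapping so that role annotations written against the original labels can
be reconciled.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
from scipy import stats

from .errors import FormatError, NetworkGenerationError, ParameterError

__all__ = [
    "SocialNetwork",
    "DegreeSummary",
    "generate_ws_network",
    "neighborhood",
    "top_degree_nodes",
    "ks_degree_comparison",
    "load_network",
    "save_network",
    "load_roles",
    "save_roles",
    "EDGE_LIST",
    "GRAPHML",
    "GML",
]

EDGE_LIST = "edgelist"
GRAPHML = "graphml"
GML = "gml"
_FORMATS = (EDGE_LIST, GRAPHML, GML)

#: default retry budget when a rewiring draw disconnects the graph
MAX_GENERATION_RETRIES = 100


class SocialNetwork:
    """A fixed, undirected, simple, connected friendship graph.

    Parameters
    ----------
    graph:
        An undirected :class:`networkx.Graph` whose nodes are the integers
        ``0..N-1``.  Validated on construction.
    label_map:
        Optional mapping from original (file) labels to internal ids, kept
        for provenance when the network was loaded from disk.
    """

    __slots__ = ("graph", "n", "label_map", "_adj", "_nbhd_cache", "_diameter")

    def __init__(self, graph: nx.Graph, label_map: dict | None = None):
        if graph.is_directed():
            raise FormatError("network must be undirected")
        if graph.is_multigraph():
            raise FormatError("network must be a simple graph (no parallel edges)")
        n = graph.number_of_nodes()
        if n < 3:
            raise FormatError(f"network must have at least 3 nodes, got {n}")
        expected = set(range(n))
        if set(graph.nodes) != expected:
            raise FormatError("node ids must be the contiguous integers 0..N-1")
        loops = list(nx.nodes_with_selfloops(graph))
        if loops:
            raise FormatError(f"self-loop at node {loops[0]}")
        if not nx.is_connected(graph):
            raise FormatError("network must be connected (single component)")
        self.graph = graph
        self.n = n
        self.label_map = dict(label_map) if label_map else {i: i for i in range(n)}
        self._adj = [
            np.array(sorted(graph.neighbors(v)), dtype=np.int64) for v in range(n)
        ]
        self._nbhd_cache: dict[tuple[int, int], np.ndarray] = {}
        self._diameter: int | None = None

    # -- basic accessors -------------------------------------------------

    def __len__(self) -> int:
        return self.n

    def __contains__(self, node: int) -> bool:
        return 0 <= int(node) < self.n

    @property
    def node_ids(self) -> range:
        return range(self.n)

    @property
    def edges(self) -> frozenset[tuple[int, int]]:
        """Edge set as a frozenset of sorted (u, v) pairs."""
        return frozenset(tuple(sorted(e)) for e in self.graph.edges)

    @property
    def num_edges(self) -> int:
        return self.graph.number_of_edges()

    def neighbors(self, node: int) -> np.ndarray:
        """Direct neighbors of ``node`` as a sorted integer array (read-only)."""
        self._check_node(node)
        return self._adj[node]

    def degrees(self) -> np.ndarray:
        return np.array([len(a) for a in self._adj], dtype=np.int64)

    def diameter(self) -> int:
        if self._diameter is None:
            self._diameter = nx.diameter(self.graph)
        return self._diameter

    def _check_node(self, node: int) -> None:
        if not (0 <= int(node) < self.n):
            raise KeyError(f"unknown node {node!r}")

    # -- distance neighborhoods (cached) ---------------------------------

    def neighborhood(self, node: int, r: int) -> np.ndarray:
        """All nodes at shortest-path distance in [1, r] from ``node``.

        Excludes ``node`` itself.  Results are cached per (node, r).
        """
        self._check_node(node)
        r = int(r)
        if r < 1:
            raise ParameterError(f"hop radius must be >= 1, got {r}")
        # beyond the diameter every node is reachable; collapse the cache key
        r_eff = min(r, self.n - 1)
        key = (int(node), r_eff)
        cached = self._nbhd_cache.get(key)
        if cached is not None:
            return cached
        visited = np.zeros(self.n, dtype=bool)
        visited[node] = True
        frontier = [int(node)]
        members: list[int] = []
        for _ in range(r_eff):
            nxt: list[int] = []
            for v in frontier:
                for w in self._adj[v]:
                    if not visited[w]:
                        visited[w] = True
                        nxt.append(int(w))
            if not nxt:
                break
            members.extend(nxt)
            frontier = nxt
        out = np.array(sorted(members), dtype=np.int64)
        out.setflags(write=False)
        self._nbhd_cache[key] = out
        return out


@dataclass(frozen=True)
class DegreeSummary:
    """Per-node degrees together with the empirical cumulative frequency."""

    degrees: np.ndarray
    #: sorted unique degree values
    values: np.ndarray = field(init=False)
    #: empirical CDF evaluated at ``values``; nondecreasing, ends at 1
    cumulative_frequency: np.ndarray = field(init=False)

    def __post_init__(self):
        values, counts = np.unique(np.asarray(self.degrees, dtype=np.int64), return_counts=True)
        cdf = np.cumsum(counts) / counts.sum()
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "cumulative_frequency", cdf)

    @classmethod
    def of(cls, net: SocialNetwork) -> "DegreeSummary":
        return cls(net.degrees())


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------


def generate_ws_network(
    N: int,
    neighbors: int,
    rewire_rate: float,
    seed: int,
    max_retries: int = MAX_GENERATION_RETRIES,
) -> SocialNetwork:
    """Generate a connected Watts-Strogatz small-world network.

    Starts from a ring lattice of ``neighbors`` neighbors per node and rewires
    each edge with probability ``rewire_rate``.  Rewiring preserves the edge
    count ``N * neighbors / 2``.  If a draw yields a disconnected graph the
    generation is retried with an advanced seed, up to ``max_retries`` times;
    the same ``(N, neighbors, rewire_rate, seed)`` always yields an identical
    graph.
    """
    N = int(N)
    neighbors = int(neighbors)
    if neighbors < 2 or neighbors % 2 != 0:
        raise ParameterError(f"neighbors must be an even count >= 2, got {neighbors}")
    if N <= neighbors:
        raise ParameterError(f"N must exceed neighbors ({N} <= {neighbors})")
    if not (0.0 <= rewire_rate <= 1.0):
        raise ParameterError(f"rewire_rate must be in [0, 1], got {rewire_rate}")
    if max_retries < 1:
        raise ParameterError("max_retries must be >= 1")
    for attempt in range(max_retries):
        g = nx.watts_strogatz_graph(N, neighbors, rewire_rate, seed=int(seed) + attempt)
        if nx.is_connected(g):
            return SocialNetwork(g)
    raise NetworkGenerationError(
        f"failed to generate a connected Watts-Strogatz graph "
        f"(N={N}, neighbors={neighbors}, rewire_rate={rewire_rate}, seed={seed}) "
        f"within {max_retries} attempts"
    )


# ---------------------------------------------------------------------------
# Characterization
# ---------------------------------------------------------------------------


def neighborhood(net: SocialNetwork, node: int, r: int) -> set[int]:
    """Nodes within shortest-path distance ``[1, r]`` of ``node`` (node excluded)."""
    return set(int(v) for v in net.neighborhood(node, r))


def top_degree_nodes(
    net: SocialNetwork, k: int, exclude: Iterable[int] = ()
) -> list[int]:
    """The ``k`` highest-degree nodes not in ``exclude``.

    Ties are broken by ascending node id, so the result is deterministic.
    """
    excluded = {int(v) for v in exclude}
    k = int(k)
    available = net.n - len(excluded)
    if k < 0:
        raise ParameterError(f"k must be >= 0, got {k}")
    if k > available:
        raise ParameterError(
            f"cannot select {k} nodes: only {available} nodes outside the exclusion set"
        )
    deg = net.degrees()
    candidates = [v for v in range(net.n) if v not in excluded]
    candidates.sort(key=lambda v: (-deg[v], v))
    return candidates[:k]


def ks_degree_comparison(
    net_a: SocialNetwork, net_b: SocialNetwork
) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov comparison of the two degree multisets.

    Returns ``(statistic, p_value)`` using the asymptotic two-sample p-value.
    """
    da = net_a.degrees()
    db = net_b.degrees()
    res = stats.ks_2samp(da, db, method="asymp")
    return float(res.statistic), float(min(res.pvalue, 1.0))


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def _check_format(fmt: str) -> str:
    fmt = fmt.lower().replace("-", "").replace("_", "")
    if fmt == "edgelist":
        return EDGE_LIST
    if fmt == "graphml":
        return GRAPHML
    if fmt == "gml":
        return GML
    raise ParameterError(f"unknown network format {fmt!r}; expected one of {_FORMATS}")


def _parse_edge_list(path: Path) -> nx.Graph:
    g = nx.Graph()
    seen: set[tuple[int, int]] = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) != 2:
                raise FormatError(
                    f"{path}:{lineno}: expected two whitespace-separated integers, got {raw.strip()!r}"
                )
            try:
                u, v = int(parts[0]), int(parts[1])
            except ValueError:
                raise FormatError(
                    f"{path}:{lineno}: non-integer node label in {raw.strip()!r}"
                ) from None
            if u == v:
                raise FormatError(f"{path}:{lineno}: self-loop '{u} {v}'")
            key = (u, v) if u < v else (v, u)
            if key in seen:
                raise FormatError(f"{path}:{lineno}: duplicate edge '{u} {v}'")
            seen.add(key)
            g.add_edge(u, v)
    return g


def _relabel_contiguous(g: nx.Graph) -> tuple[nx.Graph, dict]:
    """Map arbitrary node labels onto 0..N-1 (sorted order) and keep the mapping."""
    labels = list(g.nodes)
    try:
        labels.sort(key=lambda x: (0, int(x)))
    except (TypeError, ValueError):
        labels.sort(key=lambda x: (1, str(x)))
    mapping = {lab: i for i, lab in enumerate(labels)}
    return nx.relabel_nodes(g, mapping, copy=True), mapping


def load_network(path: str | Path, fmt: str | None = None) -> SocialNetwork:
    """Load an undirected network from edge-list, GraphML, or GML.

    Directed input is rejected.  Self-loops, duplicate edges, and
    disconnected graphs raise :class:`FormatError` naming the offending
    line or element.  Arbitrary labels are remapped onto ``0..N-1``; the
    mapping is kept on ``SocialNetwork.label_map`` (original -> internal).
    """
    path = Path(path)
    if fmt is None:
        fmt = {".graphml": GRAPHML, ".gml": GML}.get(path.suffix.lower(), EDGE_LIST)
    fmt = _check_format(fmt)
    if fmt == EDGE_LIST:
        g = _parse_edge_list(path)
    elif fmt == GRAPHML:
        try:
            g = nx.read_graphml(path)
        except Exception as exc:  # noqa: BLE001 - surface parser detail
            raise FormatError(f"{path}: GraphML parse failure: {exc}") from exc
        if g.is_directed():
            raise FormatError(f"{path}: directed GraphML is not supported")
    else:
        try:
            g = nx.read_gml(path, label="id")
        except Exception as exc:  # noqa: BLE001
            raise FormatError(f"{path}: GML parse failure: {exc}") from exc
        if g.is_directed():
            raise FormatError(f"{path}: directed GML is not supported")
    if g.is_multigraph():
        g = nx.Graph(g)
    loops = list(nx.nodes_with_selfloops(g))
    if loops:
        raise FormatError(f"{path}: self-loop at node {loops[0]!r}")
    g, mapping = _relabel_contiguous(g)
    g = nx.Graph(((u, v) for u, v in g.edges))  # drop attributes
    g.add_nodes_from(range(len(mapping)))
    try:
        return SocialNetwork(g, label_map=mapping)
    except FormatError as exc:
        raise FormatError(f"{path}: {exc}") from None


def save_network(net: SocialNetwork, path: str | Path, fmt: str | None = None) -> None:
    """Write a network so that ``load_network(save_network(net))`` round-trips."""
    path = Path(path)
    if fmt is None:
        fmt = {".graphml": GRAPHML, ".gml": GML}.get(path.suffix.lower(), EDGE_LIST)
    fmt = _check_format(fmt)
    if fmt == EDGE_LIST:
        with open(path, "w") as fh:
            fh.write(f"# undirected edge list, {net.n} nodes, {net.num_edges} edges\n")
            for u, v in sorted(net.edges):
                fh.write(f"{u} {v}\n")
    elif fmt == GRAPHML:
        nx.write_graphml(net.graph, path)
    else:
        nx.write_gml(net.graph, path)


# -- node role annotations (two-column CSV: node_id,role) -------------------

VALID_ROLES = ("leader", "regular", "saint", "devil")


def save_roles(roles: Mapping[int, str], path: str | Path) -> None:
    """Write node role annotations as a two-column CSV (node_id, role)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["node_id", "role"])
        for node in sorted(roles):
            writer.writerow([node, roles[node]])


def load_roles(path: str | Path) -> dict[int, str]:
    """Read node role annotations written by :func:`save_roles`."""
    path = Path(path)
    out: dict[int, str] = {}
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        for lineno, row in enumerate(reader, start=1):
            if not row or (lineno == 1 and row[0].strip().lower() == "node_id"):
                continue
            if len(row) != 2:
                raise FormatError(f"{path}:{lineno}: expected 'node_id,role', got {row!r}")
            try:
                node = int(row[0])
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-integer node id {row[0]!r}") from None
            role = row[1].strip().lower()
            if role not in VALID_ROLES:
                raise FormatError(
                    f"{path}:{lineno}: unknown role {role!r}; expected one of {VALID_ROLES}"
                )
            if node in out:
                raise FormatError(f"{path}:{lineno}: duplicate annotation for node {node}")
            out[node] = role
    return out
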