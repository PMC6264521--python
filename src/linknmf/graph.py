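"""Graph and attribute-table containers, file I/O, edge splits, summary statistics.

Networks are undirected, unweighted simple graphs held as a canonical edge set
of 0-based index pairs ``(i, j)`` with ``i < j`` plus an optional label map.
Node attributes are a non-negative ``n x m`` matrix, one row per node.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "Graph",
    "AttributeTable",
    "EdgeSplit",
    "NetworkSummary",
    "load_edge_list",
    "load_attribute_table",
    "write_attribute_table",
    "split_edges",
    "summary_stats",
]


def _canonical(i: int, j: int) -> tuple[int, int]:
    return (i, j) if i < j else (j, i)


@dataclass(frozen=True)
class Graph:
    """Undirected simple graph with a symmetric 0/1 adjacency matrix.

    Parameters
    ----------
    n_nodes : int
        Number of nodes; node indices are ``0 .. n_nodes-1``.
    edges : frozenset of (int, int)
        Unordered edges stored as pairs with ``i < j``. No self-loops.
    node_labels : tuple of str, optional
        Original labels in index order; defaults to stringified indices.
    """

    n_nodes: int
    edges: frozenset[tuple[int, int]]
    node_labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.n_nodes < 1:
            raise ValueError("graph must have at least one node")
        for i, j in self.edges:
            if i == j:
                raise ValueError(f"self-loop ({i},{i}) not allowed")
            if not (0 <= i < j < self.n_nodes):
                raise ValueError(f"edge ({i},{j}) out of range or not canonical")
        if not self.node_labels:
            object.__setattr__(
                self, "node_labels", tuple(str(i) for i in range(self.n_nodes))
            )
        elif len(self.node_labels) != self.n_nodes:
            raise ValueError("node_labels length must equal n_nodes")

    @classmethod
    def from_edges(
        cls,
        edge_iter,
        n_nodes: int | None = None,
        node_labels: tuple[str, ...] = (),
    ) -> "Graph":
        edges = frozenset(_canonical(int(i), int(j)) for i, j in edge_iter if i != j)
        if n_nodes is None:
            n_nodes = 1 + max((j for _, j in edges), default=0)
        return cls(n_nodes=n_nodes, edges=edges, node_labels=node_labels)

    @classmethod
    def from_adjacency(cls, A: np.ndarray) -> "Graph":
        A = np.asarray(A)
        if A.ndim != 2 or A.shape[0] != A.shape[1]:
            raise ValueError("adjacency must be square")
        if not np.array_equal(A, A.T):
            raise ValueError("adjacency must be symmetric")
        if not np.isin(A, (0, 1)).all():
            raise ValueError("adjacency entries must be 0/1")
        if np.diagonal(A).any():
            raise ValueError("adjacency diagonal must be zero")
        ii, jj = np.nonzero(np.triu(A, 1))
        return cls.from_edges(zip(ii.tolist(), jj.tolist()), n_nodes=A.shape[0])

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def adjacency(self, dtype=float) -> np.ndarray:
        """Dense symmetric 0/1 adjacency matrix (zero diagonal)."""
        A = np.zeros((self.n_nodes, self.n_nodes), dtype=dtype)
        if self.edges:
            idx = np.array(sorted(self.edges))
            A[idx[:, 0], idx[:, 1]] = 1
            A[idx[:, 1], idx[:, 0]] = 1
        return A

    def degrees(self) -> np.ndarray:
        return self.adjacency().sum(axis=1)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n_nodes))
        g.add_edges_from(self.edges)
        return g


@dataclass
class AttributeTable:
    """Non-negative node-by-attribute matrix Z.

    ``normalized`` is set once each column has been divided by its sum, the
    preprocessing step applied before attribute similarities are computed.
    """

    values: np.ndarray
    normalized: bool = False
    column_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("attribute table must be 2-dimensional")
        if (self.values < 0).any():
            i, j = np.argwhere(self.values < 0)[0]
            raise ValueError(f"negative attribute value at row {i}, column {j}")

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]

    @property
    def n_attrs(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class EdgeSplit:
    """Partition of an observed edge set into training and probe edges."""

    train_graph: Graph
    probe_edges: frozenset[tuple[int, int]]
    train_fraction: float
    seed: int

    def __post_init__(self) -> None:
        if self.train_graph.edges & self.probe_edges:
            raise ValueError("train and probe edge sets must be disjoint")


@dataclass(frozen=True)
class NetworkSummary:
    """Topology summary: N, E, average degree, mean distance, clustering."""

    n_nodes: int
    n_edges: int
    avg_degree: float
    mean_shortest_distance: float
    clustering_coefficient: float

    def to_tsv(self) -> str:
        return (
            "N\tE\tK\td\tC\n"
            f"{self.n_nodes}\t{self.n_edges}\t{self.avg_degree:.6g}\t"
            f"{self.mean_shortest_distance:.6g}\t{self.clustering_coefficient:.6g}\n"
        )


def load_edge_list(path, comment_char: str = "#") -> Graph:
    """Read an undirected edge list: two whitespace-separated labels per line.

    Labels map to dense 0-based indices in first-appearance order. Duplicate
    and reversed lines are deduplicated; self-loop lines are dropped with a
    warning. Raises ``ValueError`` on malformed lines or an empty edge set.
    """
    labels: dict[str, int] = {}
    edges: set[tuple[int, int]] = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split(comment_char, 1)[0].strip()
            if not line:
                continue
            tokens = line.split()
            if len(tokens) != 2:
                raise ValueError(
                    f"{path}: line {lineno}: expected 2 tokens, got {len(tokens)}"
                )
            u, v = tokens
            iu = labels.setdefault(u, len(labels))
            iv = labels.setdefault(v, len(labels))
            if iu == iv:
                logger.warning("%s: line %d: dropping self-loop %r", path, lineno, u)
                continue
            edges.add(_canonical(iu, iv))
    if not edges:
        raise ValueError(f"{path}: no edges found")
    return Graph(
        n_nodes=len(labels), edges=frozenset(edges), node_labels=tuple(labels)
    )


def load_attribute_table(path, header: bool | None = None) -> AttributeTable:
    """Read a TSV attribute table, one node per row, optional header row.

    When ``header`` is None the first row is treated as a header iff any of
    its fields fails to parse as a number.
    """
    with open(path) as fh:
        rows = [line.rstrip("\n").split("\t") for line in fh if line.strip()]
    if not rows:
        raise ValueError(f"{path}: empty attribute table")

    def _numeric(fields):
        try:
            return [float(x) for x in fields]
        except ValueError:
            return None

    column_names: tuple[str, ...] = ()
    first = _numeric(rows[0])
    if header is True or (header is None and first is None):
        column_names = tuple(rows[0])
        rows = rows[1:]
        first = None
    width = len(rows[0])
    data = []
    for ridx, fields in enumerate(rows):
        if len(fields) != width:
            raise ValueError(
                f"{path}: row {ridx}: ragged table ({len(fields)} != {width} columns)"
            )
        vals = _numeric(fields)
        if vals is None:
            raise ValueError(f"{path}: row {ridx}: non-numeric value")
        data.append(vals)
    values = np.array(data, dtype=float)
    if (values < 0).any():
        i, j = np.argwhere(values < 0)[0]
        raise ValueError(f"{path}: negative value at row {i}, column {j}")
    return AttributeTable(values=values, column_names=column_names)


def write_attribute_table(table: AttributeTable, path) -> None:
    with open(path, "w") as fh:
        if table.column_names:
            fh.write("\t".join(table.column_names) + "\n")
        for row in table.values:
            fh.write("\t".join(repr(float(x)) for x in row) + "\n")


def split_edges(graph: Graph, train_fraction: float, seed: int) -> EdgeSplit:
    """Uniform random partition of the edge set into train and probe parts.

    The training size is ``round(train_fraction * |E|)`` with half-up
    rounding; sampling is without replacement and driven solely by ``seed``.
    All nodes are kept in the training graph (isolates permitted).
    """
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must lie strictly between 0 and 1")
    if graph.n_edges < 2:
        raise ValueError("need at least 2 edges to split")
    n_train = int(math.floor(train_fraction * graph.n_edges + 0.5))
    rng = np.random.default_rng(seed)
    edge_list = sorted(graph.edges)
    order = rng.permutation(graph.n_edges)
    train = frozenset(edge_list[i] for i in order[:n_train])
    probe = frozenset(edge_list[i] for i in order[n_train:])
    train_graph = Graph(
        n_nodes=graph.n_nodes, edges=train, node_labels=graph.node_labels
    )
    return EdgeSplit(
        train_graph=train_graph,
        probe_edges=probe,
        train_fraction=train_fraction,
        seed=seed,
    )


def summary_stats(graph: Graph) -> NetworkSummary:
    """Topology summary: N, E, <K> = 2E/N, mean shortest distance, clustering.

    The mean distance averages shortest-path lengths over all reachable
    ordered pairs (self-pairs excluded); disconnected pairs are ignored.
    The clustering coefficient is the average local clustering, with nodes
    of degree < 2 contributing zero.
    """
    g = graph.to_networkx()
    n, e = graph.n_nodes, graph.n_edges
    total, pairs = 0, 0
    for _, dists in nx.all_pairs_shortest_path_length(g):
        total += sum(dists.values())
        pairs += len(dists) - 1  # drop the self-pair (distance 0)
    mean_d = total / pairs if pairs else 0.0
    clustering = float(np.mean(list(nx.clustering(g).values()))) if n else 0.0
    return NetworkSummary(
        n_nodes=n,
        n_edges=e,
        avg_degree=2 * e / n,
        mean_shortest_distance=mean_d,
        clustering_coefficient=clustering,
    )
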