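"""Synthetic attributed networks with community structure and homophily.

The generator plants a partition of the nodes into communities (edge
probability ``p_in`` within, ``p_out`` between) and gives every community a
disjoint block of characteristic binary attributes; each node copies its
community template with independent bit-flip noise. With ``p_in > p_out``
and small noise, attribute similarity is genuinely informative about link
presence — the homophily regime the joint factorization assumes.

A second generator thresholds a random non-negative Gram matrix to produce
near-low-rank graphs for factorization reconstruction tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .graph import AttributeTable, Graph

__all__ = ["SynthConfig", "generate_attributed_network", "generate_low_rank_graph"]


@dataclass
class SynthConfig:
    """Planted-partition scenario parameters.

    Defaults give a 200-node, 4-community network with strong communities
    (p_in = 0.25 vs p_out = 0.02), 40 binary attributes and 10% attribute
    noise — small enough for fast tests, strong enough signal for
    AUC-based checks.
    """

    n_nodes: int = 200
    n_communities: int = 4
    p_in: float = 0.25
    p_out: float = 0.02
    n_attrs: int = 40
    attr_noise: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_in", "p_out", "attr_noise"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.n_communities > self.n_nodes:
            raise ValueError("more communities than nodes")
        if self.n_attrs < self.n_communities:
            raise ValueError("need at least one attribute per community")


def _community_labels(n: int, c: int) -> np.ndarray:
    # sizes as equal as possible, remainder to the first communities
    base, rem = divmod(n, c)
    sizes = [base + (1 if i < rem else 0) for i in range(c)]
    return np.repeat(np.arange(c), sizes)


def generate_attributed_network(
    config: SynthConfig,
) -> tuple[Graph, AttributeTable, np.ndarray]:
    """Sample a planted-partition graph with homophilous binary attributes.

    Returns the graph, the node-by-attribute table, and community labels.
    Fully reproducible from ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    n, c, m = config.n_nodes, config.n_communities, config.n_attrs
    labels = _community_labels(n, c)

    same = labels[:, None] == labels[None, :]
    p = np.where(same, config.p_in, config.p_out)
    upper = np.triu(rng.random((n, n)) < p, k=1)
    A = upper | upper.T
    graph = Graph.from_adjacency(A.astype(int))

    block = -(-m // c)  # ceil(m / c): characteristic attributes per community
    templates = np.zeros((c, m), dtype=int)
    for ci in range(c):
        templates[ci, ci * block : min((ci + 1) * block, m)] = 1
    Z = templates[labels]
    flips = rng.random((n, m)) < config.attr_noise
    Z = np.where(flips, 1 - Z, Z).astype(float)
    return graph, AttributeTable(values=Z), labels


def generate_low_rank_graph(
    n: int, k: int, density_target: float, seed: int
) -> Graph:
    """Keep the top ``round(density_target * n_pairs)`` entries of the Gram
    matrix of a random non-negative n x k basis as edges.

    The resulting adjacency inherits near-rank-k structure (exactly nested
    neighbourhoods when k = 1). Raises if the target density yields no edges.
    """
    if k > n:
        raise ValueError("rank k cannot exceed n")
    if not 0 < density_target < 1:
        raise ValueError("density_target must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    B = rng.random((n, k))
    G = B @ B.T
    iu = np.triu_indices(n, k=1)
    vals = G[iu]
    n_keep = round(density_target * vals.size)
    if n_keep < 1:
        raise ValueError(f"density_target={density_target} produces an empty graph")
    keep = np.argsort(-vals, kind="stable")[:n_keep]
    edges = zip(iu[0][keep].tolist(), iu[1][keep].tolist())
    return Graph.from_edges(edges, n_nodes=n)
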