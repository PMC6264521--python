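"""Structural similarity indices for link prediction.

Seven classical indices over an undirected simple graph: the local
common-neighbour family (CN, Salton, Jaccard, resource allocation,
Adamic-Adar), the Katz index over all paths, and average commute time from
the pseudo-inverse Laplacian. Each returns a symmetric node-by-node score
matrix with zero diagonal; these serve both as standalone predictors and,
rescaled to [0, 1], as the internal auxiliary similarity fed to the joint
factorization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg

from .graph import Graph

__all__ = [
    "SimilarityMatrix",
    "common_neighbors",
    "salton",
    "jaccard",
    "resource_allocation",
    "adamic_adar",
    "katz",
    "average_commute_time",
    "structural_similarity",
    "STRUCTURAL_METHODS",
]


@dataclass
class SimilarityMatrix:
    """Symmetric node-by-node similarity scores.

    Attributes
    ----------
    values : ndarray of shape (n, n)
        Finite symmetric scores, zero diagonal.
    method : str
        Label of the producing index or metric.
    scaled : bool
        True after division by the global maximum (entries then in [0, 1]).
    """

    values: np.ndarray
    method: str
    scaled: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n, m = self.values.shape
        if n != m:
            raise ValueError("similarity matrix must be square")
        if not np.isfinite(self.values).all():
            raise ValueError("similarity matrix contains non-finite entries")
        if not np.allclose(self.values, self.values.T, atol=1e-9):
            raise ValueError("similarity matrix must be symmetric")

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]

    def rescaled(self) -> "SimilarityMatrix":
        """Divide by the global maximum so entries lie in [0, 1]."""
        m = self.values.max()
        vals = self.values / m if m > 0 else self.values.copy()
        return SimilarityMatrix(values=vals, method=self.method, scaled=True)


def _zero_diag(M: np.ndarray) -> np.ndarray:
    np.fill_diagonal(M, 0.0)
    return M


def common_neighbors(graph: Graph) -> SimilarityMatrix:
    """CN index: number of shared neighbours, ``S_xy = |G(x) n G(y)|``."""
    A = graph.adjacency()
    return SimilarityMatrix(_zero_diag(A @ A), method="CN")


def salton(graph: Graph) -> SimilarityMatrix:
    """Salton (cosine) index: ``CN / sqrt(k(x) k(y))``; 0 when a degree is 0."""
    A = graph.adjacency()
    cn = A @ A
    k = A.sum(axis=1)
    denom = np.sqrt(np.outer(k, k))
    with np.errstate(divide="ignore", invalid="ignore"):
        S = np.where(denom > 0, cn / denom, 0.0)
    return SimilarityMatrix(_zero_diag(S), method="Salton")


def jaccard(graph: Graph) -> SimilarityMatrix:
    """Jaccard index: ``CN / |G(x) u G(y)|``; 0 for an empty neighbour union."""
    A = graph.adjacency()
    cn = A @ A
    k = A.sum(axis=1)
    union = k[:, None] + k[None, :] - cn
    with np.errstate(divide="ignore", invalid="ignore"):
        S = np.where(union > 0, cn / union, 0.0)
    return SimilarityMatrix(_zero_diag(S), method="Jaccard")


def resource_allocation(graph: Graph) -> SimilarityMatrix:
    """RA index: sum over common neighbours z of ``1 / k(z)``."""
    A = graph.adjacency()
    k = A.sum(axis=1)
    w = np.where(k > 0, 1.0 / np.where(k > 0, k, 1.0), 0.0)
    return SimilarityMatrix(_zero_diag(A @ (w[:, None] * A)), method="RA")


def adamic_adar(graph: Graph) -> SimilarityMatrix:
    """AA index: sum over common neighbours z of ``1 / ln k(z)``.

    A common neighbour of a distinct pair has degree >= 2, so ln k(z) > 0;
    nodes of degree < 2 (which can never be common neighbours) get weight 0.
    """
    A = graph.adjacency()
    k = A.sum(axis=1)
    w = np.where(k >= 2, 1.0 / np.log(np.where(k >= 2, k, 2.0)), 0.0)
    return SimilarityMatrix(_zero_diag(A @ (w[:, None] * A)), method="AA")


def katz(graph: Graph, theta: float = 0.1) -> SimilarityMatrix:
    """Katz index: ``((I - theta A)^-1 - I)_xy``, summing all paths.

    Computed by a direct linear solve. Requires ``theta`` below the inverse
    spectral radius of A for the underlying series to converge.
    """
    A = graph.adjacency()
    n = graph.n_nodes
    if theta != 0:
        lam = float(np.max(np.abs(linalg.eigvalsh(A))))
        if theta * lam >= 1:
            raise ValueError(
                f"Katz diverges: theta={theta} >= 1/lambda_max={1 / lam:.6g}; "
                "use a smaller theta"
            )
    S = linalg.solve(np.eye(n) - theta * A, np.eye(n), assume_a="sym") - np.eye(n)
    return SimilarityMatrix(_zero_diag(S), method="Katz")


def average_commute_time(graph: Graph) -> SimilarityMatrix:
    """ACT index: ``1 / (l+_xx + l+_yy - 2 l+_xy)`` from the pseudo-inverse
    Laplacian ``L+``. Self-pairs and zero/non-finite denominators map to 0.
    """
    A = graph.adjacency()
    L = np.diag(A.sum(axis=1)) - A
    Lp = linalg.pinv(L)
    d = np.diagonal(Lp)
    denom = d[:, None] + d[None, :] - 2 * Lp
    with np.errstate(divide="ignore", invalid="ignore"):
        S = 1.0 / denom
    S[~np.isfinite(S)] = 0.0
    S[np.abs(denom) < 1e-12] = 0.0
    S = (S + S.T) / 2  # pinv round-off can break exact symmetry
    return SimilarityMatrix(_zero_diag(S), method="ACT")


STRUCTURAL_METHODS = {
    "CN": common_neighbors,
    "Salton": salton,
    "Jaccard": jaccard,
    "RA": resource_allocation,
    "AA": adamic_adar,
    "Katz": katz,
    "ACT": average_commute_time,
}


def structural_similarity(
    graph: Graph, method: str, scaled: bool = False
) -> SimilarityMatrix:
    """Dispatch to a named index; optionally max-rescale to [0, 1].

    ``scaled=True`` is used when the matrix enters the factorization, so its
    range is comparable to the 0/1 adjacency.
    """
    try:
        fn = STRUCTURAL_METHODS[method]
    except KeyError:
        raise ValueError(
            f"unknown similarity method {method!r}; "
            f"valid: {sorted(STRUCTURAL_METHODS)}"
        ) from None
    sim = fn(graph)
    return sim.rescaled() if scaled else sim
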