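"""Node-attribute preprocessing into an external auxiliary similarity matrix.

Attributes are first column-normalized (each attribute divided by its total
mass across nodes, so heterogeneous attribute scales become comparable), then
turned into a pairwise node similarity. Cosine is the default metric;
Euclidean-distance and Pearson variants are provided as alternatives.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .graph import AttributeTable
from .similarity import SimilarityMatrix

__all__ = [
    "normalize_columns",
    "cosine_similarity",
    "euclidean_similarity",
    "pearson_similarity",
    "attribute_similarity",
    "ATTRIBUTE_METRICS",
]


def normalize_columns(table: AttributeTable) -> AttributeTable:
    """Divide every column by its sum; all-zero columns are left unchanged."""
    if table.normalized:
        raise ValueError("attribute table is already normalized")
    Z = table.values.copy()
    sums = Z.sum(axis=0)
    nz = sums > 0
    Z[:, nz] /= sums[nz]
    return AttributeTable(values=Z, normalized=True, column_names=table.column_names)


def cosine_similarity(table: AttributeTable) -> SimilarityMatrix:
    """Cosine of attribute vectors: ``S_ij = <z_i, z_j> / (|z_i| |z_j|)``.

    All-zero rows get similarity 0 to everything, themselves included, so the
    output stays finite and non-negative.
    """
    Z = table.values
    norms = np.linalg.norm(Z, axis=1)
    safe = np.where(norms > 0, norms, 1.0)
    U = Z / safe[:, None]
    S = U @ U.T
    S[norms == 0, :] = 0.0
    S[:, norms == 0] = 0.0
    np.clip(S, 0.0, 1.0, out=S)  # clamp rounding spill past [0, 1]
    S = (S + S.T) / 2
    return SimilarityMatrix(values=S, method="cosine")


def euclidean_similarity(table: AttributeTable) -> SimilarityMatrix:
    """Bounded transform of Euclidean distance: ``S_ij = 1 / (1 + d_ij)``."""
    D = squareform(pdist(table.values, metric="euclidean"))
    return SimilarityMatrix(values=1.0 / (1.0 + D), method="euclidean")


def pearson_similarity(table: AttributeTable) -> SimilarityMatrix:
    """Row-wise Pearson correlation with negatives clipped to 0.

    Constant rows (zero variance) yield 0 against every row. Clipping keeps
    the matrix non-negative as the factorization requires.
    """
    Z = table.values
    centered = Z - Z.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1)
    safe = np.where(norms > 0, norms, 1.0)
    U = centered / safe[:, None]
    R = U @ U.T
    R[norms == 0, :] = 0.0
    R[:, norms == 0] = 0.0
    S = np.clip(R, 0.0, 1.0)
    S = (S + S.T) / 2
    return SimilarityMatrix(values=S, method="pearson")


ATTRIBUTE_METRICS = {
    "cosine": cosine_similarity,
    "euclidean": euclidean_similarity,
    "pearson": pearson_similarity,
}


def attribute_similarity(
    table: AttributeTable, metric: str = "cosine", normalize: bool = True
) -> SimilarityMatrix:
    """Full preprocessing pipeline: column-normalize, then pairwise similarity."""
    try:
        fn = ATTRIBUTE_METRICS[metric]
    except KeyError:
        raise ValueError(
            f"unknown attribute metric {metric!r}; valid: {sorted(ATTRIBUTE_METRICS)}"
        ) from None
    if normalize and not table.normalized:
        table = normalize_columns(table)
    return fn(table)
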