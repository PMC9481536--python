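"""Jaccard similarity profiles over binary drug-feature matrices.

For drugs A and B with binary feature vectors, J(A,B) = M11 / (M01 +
M10 + M11), where M11 counts items present in both and M01/M10 items
present in exactly one.  The resulting n x n matrix supplies the node
attributes of the multiplex DDI network: row i is drug i's similarity
profile against every drug.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_model import BinaryFeatureMatrix, DrugIndex, ValidationError


@dataclass(frozen=True)
class SimilarityMatrix:
    source: str
    drugs: DrugIndex
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValidationError("similarity matrix must be square")
        if v.shape[0] != len(self.drugs):
            raise ValidationError("similarity matrix size != number of drugs")
        if not np.allclose(v, v.T):
            raise ValidationError("similarity matrix must be symmetric")
        if v.min() < 0 or v.max() > 1:
            raise ValidationError("similarities must lie in [0, 1]")
        object.__setattr__(self, "values", v)


def jaccard(a: np.ndarray, b: np.ndarray) -> float:
    """Jaccard similarity of two binary vectors.

    Returns M11 / (M01 + M10 + M11); defined as 0.0 when both vectors
    are all-zero (no shared evidence, rather than vacuous identity).
    """
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise ValidationError(f"length mismatch: {a.shape} vs {b.shape}")
    if np.any((a != 0) & (a != 1)) or np.any((b != 0) & (b != 1)):
        raise ValidationError("inputs must be binary")
    m11 = int(np.sum((a == 1) & (b == 1)))
    union = int(np.sum((a == 1) | (b == 1)))
    return m11 / union if union else 0.0


def build_similarity_matrix(
    feature_matrix: BinaryFeatureMatrix, unit_diagonal: bool = True
) -> SimilarityMatrix:
    """All-pairs Jaccard over the rows of a binary feature matrix.

    Vectorized: intersections come from one integer matmul, unions from
    the row-sum identity |A ∪ B| = |A| + |B| - |A ∩ B|.  With
    ``unit_diagonal`` (default) the diagonal is forced to 1 even for
    drugs whose feature row is all zero, preserving self-similarity
    semantics for attribute use; off-diagonal 0/0 cells are 0.
    """
    x = feature_matrix.values.astype(np.int64)
    inter = x @ x.T
    row = x.sum(axis=1)
    union = row[:, None] + row[None, :] - inter
    with np.errstate(divide="ignore", invalid="ignore"):
        sim = np.where(union > 0, inter / np.maximum(union, 1), 0.0)
    if unit_diagonal:
        np.fill_diagonal(sim, 1.0)
    return SimilarityMatrix(feature_matrix.source, feature_matrix.drugs, sim)
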