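"""Stage-2 input construction: flatten drug tensors, fuse drug pairs.

A drug's (d x R) embedding matrix is flattened by concatenating its
per-event-type vectors in event-id order, F_i = [v_{i,1}, ..., v_{i,R}].
A pair is fused by one of the aggregation schemas:

  - ``a``: element-wise product F_i ⊙ F_j (length d·R) — the default,
    which scores best in the schema comparison;
  - ``b``: concatenation [F_i, F_j] (length 2·d·R);
  - ``d``: the same element-wise product, but historically computed as a
    multiply layer inside the classifier.  Numerically it is identical
    to ``a`` (reported accuracy differences between the two are training
    variance), so it is exposed as an alias.

Schema ``b`` is orientation-sensitive, so pairs are always fused in the
canonical i < j order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .embedding import EmbeddingTensor
from .io_model import EventEdgeList, ValidationError

SCHEMAS = ("a", "b", "d")


@dataclass(frozen=True)
class PairFeatureSet:
    """One pair-feature matrix per source, rows aligned to the edge list."""

    schema: str
    sources: tuple[str, ...]
    matrices: tuple[np.ndarray, ...]  # each (n_edges, width)
    labels: np.ndarray  # (n_edges,) event ids

    def __post_init__(self) -> None:
        widths = {m.shape for m in self.matrices}
        if len(widths) > 1:
            raise ValidationError(f"pair matrices disagree in shape: {widths}")

    @property
    def n_pairs(self) -> int:
        return self.matrices[0].shape[0]

    @property
    def width(self) -> int:
        return self.matrices[0].shape[1]

    def subset(self, indices: np.ndarray) -> "PairFeatureSet":
        return PairFeatureSet(
            self.schema,
            self.sources,
            tuple(m[indices] for m in self.matrices),
            self.labels[indices],
        )


def flatten_drug(tensor: EmbeddingTensor, i: int) -> np.ndarray:
    """F_i: concatenate drug i's per-layer vectors in event-id order."""
    if not 0 <= i < tensor.n_drugs:
        raise ValidationError(f"drug index {i} outside 0..{tensor.n_drugs - 1}")
    # (d, R) -> [v_{i,0}; v_{i,1}; ...]: transpose so layer blocks are contiguous
    return tensor.values[i].T.reshape(-1)


def fuse_pair(fi: np.ndarray, fj: np.ndarray, schema: str = "a") -> np.ndarray:
    """Fuse two flattened drug vectors into one pair feature vector."""
    if schema not in SCHEMAS:
        raise ValidationError(f"unknown schema {schema!r}; expected one of {SCHEMAS}")
    if fi.shape != fj.shape:
        raise ValidationError(f"length mismatch: {fi.shape} vs {fj.shape}")
    if schema in ("a", "d"):
        return fi * fj
    return np.concatenate([fi, fj])


def build_pair_features(
    tensors: list[EmbeddingTensor], edges: EventEdgeList, schema: str = "a"
) -> PairFeatureSet:
    """Per-source pair-feature matrices aligned to the edge list order."""
    if not tensors:
        raise ValidationError("need at least one embedding tensor")
    shapes = {t.values.shape for t in tensors}
    if len(shapes) > 1:
        raise ValidationError(f"tensors disagree in shape: {shapes}")
    pairs = edges.pairs()
    labels = edges.labels()
    matrices = []
    for t in tensors:
        flat = t.values.transpose(0, 2, 1).reshape(t.n_drugs, -1)  # (n, d*R)
        fi, fj = flat[pairs[:, 0]], flat[pairs[:, 1]]
        if schema in ("a", "d"):
            matrices.append(fi * fj)
        else:
            matrices.append(np.concatenate([fi, fj], axis=1))
    return PairFeatureSet(schema, tuple(t.source for t in tensors), tuple(matrices), labels)
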