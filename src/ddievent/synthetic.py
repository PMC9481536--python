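"""Seeded synthetic DDI datasets with planted structure.

The generator emulates the statistical shape the pipeline assumes:
drugs fall into latent classes; each feature source has one binary
prototype per class and a drug's bits are its class prototype corrupted
by independent bit flips (rate ``bit_flip_noise``); the event type of
an interacting pair is a deterministic function of the endpoint
classes, so both network topology and attributes carry signal; and
event sample counts follow a power-law profile, reproducing the heavy
right skew of real event-frequency distributions where the most common
event dwarfs the tail.

It does not emulate real chemistry: feature items are anonymous bits,
mechanism/action strings are placeholders, and drugs within one class
are exchangeable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations, combinations_with_replacement

import numpy as np

from .io_model import (
    BinaryFeatureMatrix,
    DrugIndex,
    EventCatalog,
    EventEdgeList,
    ValidationError,
)

DEFAULT_FEATURE_DIMS = {"structure": 120, "target": 90, "enzyme": 40, "pathway": 70}


@dataclass(frozen=True)
class SyntheticSpec:
    n_drugs: int = 400
    n_events: int = 8
    n_latent_classes: int = 4
    feature_dims: dict = field(default_factory=lambda: dict(DEFAULT_FEATURE_DIMS))
    bit_flip_noise: float = 0.1
    n_edges: int = 4000
    power_exponent: float = 2.0
    prototype_density: float = 0.3
    class_to_event_mode: str = "pair"
    seed: int = 0

    def __post_init__(self) -> None:
        k = self.n_latent_classes
        if self.n_events > k * (k + 1) // 2:
            raise ValidationError(
                f"{self.n_events} events need more than {k * (k + 1) // 2} "
                f"unordered class pairs; increase n_latent_classes"
            )
        if not 0 <= self.bit_flip_noise < 0.5:
            raise ValidationError("bit_flip_noise must be in [0, 0.5)")
        if self.class_to_event_mode != "pair":
            raise ValidationError("only the 'pair' class_to_event mode is supported")


def _event_counts(spec: SyntheticSpec) -> np.ndarray:
    """Power-law event-size profile, descending, summing to n_edges."""
    w = (np.arange(spec.n_events) + 1.0) ** (-spec.power_exponent)
    counts = np.maximum(np.round(w / w.sum() * spec.n_edges).astype(int), 2)
    counts[0] += spec.n_edges - counts.sum()  # absorb rounding in the head event
    return -np.sort(-counts)


def generate_dataset(
    spec: SyntheticSpec,
) -> tuple[dict[str, BinaryFeatureMatrix], EventEdgeList, EventCatalog, np.ndarray]:
    """Generate one planted dataset.

    Returns (feature matrices by source, edge list, event catalog,
    ground-truth class per drug).  Fully reproducible under the spec
    seed; all outputs pass the I/O-layer validations.
    """
    rng = np.random.default_rng(spec.seed)
    n, k_cls = spec.n_drugs, spec.n_latent_classes
    classes = rng.integers(0, k_cls, size=n)
    drugs = DrugIndex(tuple(f"D{idx:04d}" for idx in range(n)))

    features: dict[str, BinaryFeatureMatrix] = {}
    for source, m in spec.feature_dims.items():
        prototypes = (rng.random((k_cls, m)) < spec.prototype_density).astype(np.uint8)
        flips = rng.random((n, m)) < spec.bit_flip_noise
        bits = prototypes[classes] ^ flips
        items = tuple(f"{source}_item_{j:03d}" for j in range(m))
        features[source] = BinaryFeatureMatrix(source, drugs, items, bits)

    # event r <- r-th unordered class pair in a seeded shuffle; id order is
    # frequency order because the count profile is descending
    pair_pool = list(combinations_with_replacement(range(k_cls), 2))
    rng.shuffle(pair_pool)
    event_pairs = pair_pool[: spec.n_events]
    counts = _event_counts(spec)

    members = [np.flatnonzero(classes == c) for c in range(k_cls)]
    edges: list[tuple[int, int, int]] = []
    for r, (ca, cb) in enumerate(event_pairs):
        ma, mb = members[ca], members[cb]
        if ca == cb:
            cand = np.array(list(combinations(ma, 2)))
        else:
            cand = np.array([(i, j) for i in ma for j in mb])
        cand = np.sort(cand, axis=1)
        if counts[r] > len(cand):
            raise ValidationError(
                f"event {r} requests {counts[r]} edges but only {len(cand)} "
                f"class-pair combinations exist; lower n_edges or the skew"
            )
        pick = rng.choice(len(cand), size=counts[r], replace=False)
        edges.extend((int(i), int(j), r) for i, j in cand[pick])

    labels = tuple((f"mechanism_{r:02d}", f"action_{r:02d}") for r in range(spec.n_events))
    catalog = EventCatalog(labels, tuple(int(c) for c in counts))
    edge_list = EventEdgeList(tuple(edges), spec.n_events)
    return features, edge_list, catalog, classes


def generate_separable_pairs(
    n_pairs: int, input_dim: int, n_classes: int, seed: int = 0,
    separation: float = 6.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian class clusters with controllable inter-centroid distance.

    With the default separation the classes are linearly separable with
    margin; with ``separation=0`` all classes share one centroid and no
    classifier can beat chance.  Used as a classifier sanity benchmark.
    """
    if n_classes < 2:
        raise ValidationError("need at least 2 classes")
    rng = np.random.default_rng(seed)
    centroids = rng.normal(0.0, 1.0, size=(n_classes, input_dim))
    norms = np.linalg.norm(centroids, axis=1, keepdims=True)
    centroids = centroids / np.maximum(norms, 1e-12) * separation
    labels = rng.integers(0, n_classes, size=n_pairs)
    x = centroids[labels] + rng.normal(0.0, 1.0, size=(n_pairs, input_dim))
    return x, labels
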