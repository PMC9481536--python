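"""Attributed multiplex drug network assembly.

One node set (drugs), one undirected simple-graph layer per interaction
event class, and one attribute vector per node (a row of a similarity
matrix, or optionally a raw binary feature row).  Layers are unweighted;
nodes isolated in a layer stay addressable so every drug can receive a
per-layer embedding through the base/attribute pathway.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .io_model import EventEdgeList, ValidationError
from .similarity import SimilarityMatrix


@dataclass(frozen=True)
class AttributedHeteroNetwork:
    n_drugs: int
    n_layers: int
    layers: tuple[nx.Graph, ...]  # one graph per event id, nodes 0..n-1
    attributes: np.ndarray  # n x a

    def layer_edge_count(self, r: int) -> int:
        return self.layers[r].number_of_edges()

    def degree(self, r: int, node: int) -> int:
        return self.layers[r].degree[node]

    def adjacency(self, r: int) -> dict[int, np.ndarray]:
        """Neighbor index arrays per node for layer r (isolated nodes omitted)."""
        return {
            u: np.fromiter(self.layers[r].neighbors(u), dtype=np.int64)
            for u in self.layers[r].nodes
            if self.layers[r].degree[u] > 0
        }


def build_network(
    edges: EventEdgeList, attrs: SimilarityMatrix | np.ndarray
) -> AttributedHeteroNetwork:
    """Assemble the R-layer multiplex network with node attributes attached.

    The union of layer edge sets equals the input edge list; an empty
    edge list is rejected because an R = 0 network has no layers to walk.
    """
    if edges.n_edges == 0 or edges.n_events == 0:
        raise ValidationError("cannot build a network from an empty edge list")
    attr = attrs.values if isinstance(attrs, SimilarityMatrix) else np.asarray(attrs, dtype=np.float64)
    n = attr.shape[0]
    for i, j, _ in edges.edges:
        if i >= n or j >= n:
            raise ValidationError(
                f"edge index ({i},{j}) out of range for {n} attribute rows"
            )
    layers = []
    for r in range(edges.n_events):
        g = nx.Graph()
        g.add_nodes_from(range(n))
        g.add_edges_from((i, j) for i, j, rr in edges.edges if rr == r)
        layers.append(g)
    return AttributedHeteroNetwork(n, edges.n_events, tuple(layers), attr)
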