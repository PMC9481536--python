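"""Stage 1: multiplex network embedding with base + edge embeddings.

Every drug i gets one vector per event layer r:

    v[i, r] = x_i W_b + B_i + (agg_r(x)_i W_e^r) M_r

where x_i is the node-attribute vector, W_b (base transform) and the
free offsets B are shared across layers, W_e^r maps attributes into a
small per-layer edge space of size s, agg_r is a fixed neighbor-mean
propagation over the layer's graph (2 rounds by default; isolated nodes
keep their own attribute row), and M_r lifts the edge space back to the
output dimension d.  The parameters are trained by skip-gram with
negative sampling over uniform random walks confined to each layer, so
the vectors absorb both layer topology and attribute similarity.
Drugs isolated in a layer still receive a finite vector for that layer
through the attribute/base pathway; layers with no edges contribute no
skip-gram pairs.

Everything is plain NumPy with a single Adam loop; one master seed fans
out (via ``numpy.random.SeedSequence``) to the per-layer walk generators
and the trainer, making runs bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .heterograph import AttributedHeteroNetwork, build_network
from .io_model import DrugIndex, EventEdgeList, ValidationError
from .similarity import SimilarityMatrix


@dataclass(frozen=True)
class EmbeddingParams:
    """Hyperparameters of the walk + skip-gram embedding trainer.

    ``emb_dim`` defaults to 32, the dimension at which downstream
    accuracy peaks in the embedding-size sweep; the walk settings are
    conventional for networks of a few hundred nodes.
    """

    emb_dim: int = 32
    edge_dim: int = 8
    walks_per_node: int = 20
    walk_length: int = 10
    window: int = 5
    negatives: int = 5
    epochs: int = 5
    propagation_rounds: int = 2
    learning_rate: float = 0.01
    batch_size: int = 256
    seed: int = 0

    def __post_init__(self) -> None:
        if self.emb_dim < 1 or self.edge_dim < 1:
            raise ValidationError("embedding dimensions must be >= 1")
        if self.walk_length < 2:
            raise ValidationError("walk_length must be >= 2")
        if self.window < 1:
            raise ValidationError("window must be >= 1")


@dataclass(frozen=True)
class EmbeddingTensor:
    """Per-source drug representations, one d-vector per (drug, event layer)."""

    source: str
    values: np.ndarray  # (n, d, R)
    drugs: DrugIndex

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        if v.ndim != 3:
            raise ValidationError("embedding tensor must have shape (n, d, R)")
        if v.shape[0] != len(self.drugs):
            raise ValidationError("tensor first axis != number of drugs")
        if not np.all(np.isfinite(v)):
            raise ValidationError("embedding tensor contains non-finite values")
        object.__setattr__(self, "values", v)

    @property
    def n_drugs(self) -> int:
        return self.values.shape[0]

    @property
    def emb_dim(self) -> int:
        return self.values.shape[1]

    @property
    def n_layers(self) -> int:
        return self.values.shape[2]


def _layer_csr(net: AttributedHeteroNetwork, r: int) -> tuple[np.ndarray, np.ndarray]:
    """Compact adjacency (indptr, indices) for one layer."""
    g = net.layers[r]
    n = net.n_drugs
    indptr = np.zeros(n + 1, dtype=np.int64)
    degs = np.array([g.degree[u] for u in range(n)], dtype=np.int64)
    indptr[1:] = np.cumsum(degs)
    indices = np.empty(indptr[-1], dtype=np.int64)
    for u in range(n):
        if degs[u]:
            indices[indptr[u]: indptr[u + 1]] = np.fromiter(g.neighbors(u), dtype=np.int64)
    return indptr, indices


def generate_walks(
    net: AttributedHeteroNetwork,
    r: int,
    params: EmbeddingParams,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Uniform random walks confined to layer r.

    Starts ``walks_per_node`` walks of length ``walk_length`` from every
    node with degree >= 1 in the layer; isolated nodes contribute none.
    Returns an array of node-index sequences, shape (n_walks, walk_length).
    """
    if not 0 <= r < net.n_layers:
        raise ValidationError(f"layer {r} outside 0..{net.n_layers - 1}")
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([params.seed, r]))
    indptr, indices = _layer_csr(net, r)
    deg = np.diff(indptr)
    starts = np.flatnonzero(deg > 0)
    if starts.size == 0:
        return np.empty((0, params.walk_length), dtype=np.int64)
    cur = np.repeat(starts, params.walks_per_node)
    walks = np.empty((cur.size, params.walk_length), dtype=np.int64)
    walks[:, 0] = cur
    for step in range(1, params.walk_length):
        u = rng.random(cur.size)
        nxt = indices[indptr[cur] + (u * deg[cur]).astype(np.int64)]
        walks[:, step] = nxt
        cur = nxt
    return walks


def _skipgram_pairs(walks: np.ndarray, window: int) -> tuple[np.ndarray, np.ndarray]:
    """All (center, context) pairs within the window, both directions."""
    centers, contexts = [], []
    length = walks.shape[1]
    for delta in range(1, min(window, length - 1) + 1):
        a = walks[:, :-delta].ravel()
        b = walks[:, delta:].ravel()
        centers.append(a)
        contexts.append(b)
        centers.append(b)
        contexts.append(a)
    return np.concatenate(centers), np.concatenate(contexts)


def _propagate_attributes(
    net: AttributedHeteroNetwork, r: int, rounds: int
) -> np.ndarray:
    """Neighbor-mean diffusion of the attribute matrix over layer r.

    Isolated nodes keep their own attribute row at every round, so the
    result is defined for all drugs even in empty or sparse layers.
    """
    indptr, indices = _layer_csr(net, r)
    deg = np.diff(indptr)
    x = net.attributes.astype(np.float64)
    out = x
    connected = np.flatnonzero(deg > 0)
    for _ in range(rounds):
        nxt = out.copy()
        for u in connected:
            nxt[u] = out[indices[indptr[u]: indptr[u + 1]]].mean(axis=0)
        out = nxt
    return out


class _Adam:
    def __init__(self, shape: tuple[int, ...], lr: float):
        self.lr = lr
        self.m = np.zeros(shape)
        self.v = np.zeros(shape)
        self.t = 0
        self.b1, self.b2, self.eps = 0.9, 0.999, 1e-8

    def step(self, param: np.ndarray, grad: np.ndarray) -> None:
        self.t += 1
        self.m = self.b1 * self.m + (1 - self.b1) * grad
        self.v = self.b2 * self.v + (1 - self.b2) * grad * grad
        mhat = self.m / (1 - self.b1**self.t)
        vhat = self.v / (1 - self.b2**self.t)
        param -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def train_embedding(
    net: AttributedHeteroNetwork, params: EmbeddingParams, source: str = "attrs",
    drugs: DrugIndex | None = None,
) -> EmbeddingTensor:
    """Train the (n, d, R) embedding tensor for one attribute source.

    Skip-gram with negative sampling over per-layer walks; the layer
    vector of a node is the base part (attribute transform + free
    offset) plus the propagated edge part (see module docstring).
    """
    if all(net.layer_edge_count(r) == 0 for r in range(net.n_layers)):
        raise ValidationError("network has no edges in any layer")
    n, R = net.n_drugs, net.n_layers
    d, s = params.emb_dim, params.edge_dim
    x = net.attributes.astype(np.float64)
    a = x.shape[1]

    ss = np.random.SeedSequence([params.seed & 0x7FFFFFFF, 7919])
    walk_seeds, train_seed = ss.spawn(R), ss.spawn(1)[0]
    rng = np.random.default_rng(train_seed)

    scale = 1.0 / np.sqrt(a)
    w_base = rng.uniform(-scale, scale, size=(a, d))
    b_free = np.zeros((n, d))
    w_edge = rng.uniform(-scale, scale, size=(R, a, s))
    m_lift = rng.uniform(-1.0 / np.sqrt(s), 1.0 / np.sqrt(s), size=(R, s, d))
    ctx = np.zeros((n, d))

    agg = np.stack(
        [_propagate_attributes(net, r, params.propagation_rounds) for r in range(R)]
    )  # (R, n, a)

    opts = {
        "w_base": _Adam(w_base.shape, params.learning_rate),
        "b_free": _Adam(b_free.shape, params.learning_rate),
        "w_edge": _Adam(w_edge.shape, params.learning_rate),
        "m_lift": _Adam(m_lift.shape, params.learning_rate),
        "ctx": _Adam(ctx.shape, params.learning_rate),
    }

    layer_pairs: list[tuple[int, np.ndarray, np.ndarray, np.ndarray]] = []
    for r in range(R):
        walks = generate_walks(net, r, params, np.random.default_rng(walk_seeds[r]))
        if walks.shape[0] == 0:
            continue
        centers, contexts = _skipgram_pairs(walks, params.window)
        counts = np.bincount(walks.ravel(), minlength=n).astype(np.float64)
        noise = counts**0.75
        noise /= noise.sum()
        layer_pairs.append((r, centers, contexts, np.cumsum(noise)))

    k = params.negatives
    for _epoch in range(params.epochs):
        for r, centers, contexts, noise_cdf in layer_pairs:
            order = rng.permutation(centers.size)
            for lo in range(0, order.size, params.batch_size):
                sel = order[lo: lo + params.batch_size]
                ci, cj = centers[sel], contexts[sel]
                neg = np.searchsorted(noise_cdf, rng.random((sel.size, k)))

                xi = x[ci]
                ui = agg[r][ci] @ w_edge[r]  # (b, s)
                v = xi @ w_base + b_free[ci] + ui @ m_lift[r]  # (b, d)

                pos_t = ctx[cj]
                neg_t = ctx[neg]  # (b, k, d)
                g_pos = _sigmoid(np.einsum("bd,bd->b", v, pos_t)) - 1.0
                g_neg = _sigmoid(np.einsum("bd,bkd->bk", v, neg_t))
                if not np.all(np.isfinite(g_pos)):
                    raise ValidationError(
                        f"non-finite skip-gram loss in layer {r}; "
                        "lower the learning rate"
                    )

                inv_b = 1.0 / sel.size
                grad_v = (
                    g_pos[:, None] * pos_t + np.einsum("bk,bkd->bd", g_neg, neg_t)
                ) * inv_b
                grad_ctx = np.zeros_like(ctx)
                np.add.at(grad_ctx, cj, g_pos[:, None] * v * inv_b)
                np.add.at(
                    grad_ctx.reshape(n, d),
                    neg.ravel(),
                    (g_neg[..., None] * v[:, None, :] * inv_b).reshape(-1, d),
                )
                grad_b = np.zeros_like(b_free)
                np.add.at(grad_b, ci, grad_v)
                grad_wb = xi.T @ grad_v
                grad_m = ui.T @ grad_v
                grad_u = grad_v @ m_lift[r].T
                grad_we = agg[r][ci].T @ grad_u

                opts["ctx"].step(ctx, grad_ctx)
                opts["b_free"].step(b_free, grad_b)
                opts["w_base"].step(w_base, grad_wb)
                gm = np.zeros_like(m_lift)
                gm[r] = grad_m
                opts["m_lift"].step(m_lift, gm)
                ge = np.zeros_like(w_edge)
                ge[r] = grad_we
                opts["w_edge"].step(w_edge, ge)

    base = x @ w_base + b_free
    values = np.empty((n, d, R))
    for r in range(R):
        values[:, :, r] = base + (agg[r] @ w_edge[r]) @ m_lift[r]
    if drugs is None:
        drugs = DrugIndex(tuple(f"drug_{i}" for i in range(n)))
    return EmbeddingTensor(source, values, drugs)


def embed_all_sources(
    similarity_matrices: list[SimilarityMatrix],
    edges: EventEdgeList,
    params: EmbeddingParams,
) -> list[EmbeddingTensor]:
    """One embedding tensor per feature source.

    All sources share the same event layers; only the node attributes
    differ, so tensors are aligned and have identical shape (n, d, R).
    """
    if not similarity_matrices:
        raise ValidationError("need at least one similarity matrix")
    tensors = []
    for sim in similarity_matrices:
        net = build_network(edges, sim)
        tensors.append(train_embedding(net, params, source=sim.source, drugs=sim.drugs))
    return tensors
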