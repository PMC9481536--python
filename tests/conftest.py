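import numpy as np
import pytest

from ddievent import (
    EmbeddingParams,
    PredictorConfig,
    build_similarity_matrix,
    generate_dataset,
)
from ddievent.synthetic import SyntheticSpec


@pytest.fixture(scope="session")
def tiny_dataset():
    """Small planted dataset shared by the integration-style tests."""
    spec = SyntheticSpec(n_drugs=120, n_events=5, n_edges=500, seed=3)
    features, edges, catalog, classes = generate_dataset(spec)
    return spec, features, edges, catalog, classes


@pytest.fixture(scope="session")
def tiny_similarities(tiny_dataset):
    _, features, _, _, _ = tiny_dataset
    return [build_similarity_matrix(features[s]) for s in ("structure", "target")]


@pytest.fixture(scope="session")
def fast_embed_params():
    """Scaled-down walk/skip-gram settings for quick training in tests."""
    return EmbeddingParams(
        emb_dim=16,
        edge_dim=4,
        walks_per_node=5,
        walk_length=8,
        window=3,
        epochs=2,
        batch_size=2048,
        seed=1,
    )


@pytest.fixture(scope="session")
def fast_predictor_config():
    return PredictorConfig(hidden_sizes=(128, 64), max_epochs=30, seed=2)


@pytest.fixture(scope="session")
def tiny_tensors(tiny_similarities, tiny_dataset, fast_embed_params):
    from ddievent import embed_all_sources

    _, _, edges, _, _ = tiny_dataset
    return embed_all_sources(tiny_similarities, edges, fast_embed_params)
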