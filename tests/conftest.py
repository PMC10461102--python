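import numpy as np
import pytest

from multiplexcore import LayerNetwork, Parcellation


def make_parcellation(n: int, volumes=None, labels=None) -> Parcellation:
    if volumes is None:
        volumes = np.full(n, 1000.0)
    if labels is None:
        labels = tuple(f"Net{i % 7 + 1}" for i in range(n))
    return Parcellation(
        node_ids=tuple(range(n)),
        region_names=tuple(f"ROI_{i:03d}" for i in range(n)),
        network_labels=tuple(labels),
        volumes=np.asarray(volumes, dtype=float),
    )


def binary_layer(adjacency: np.ndarray, modality: str = "SC") -> LayerNetwork:
    adjacency = np.asarray(adjacency, dtype=float)
    return LayerNetwork(
        parcellation=make_parcellation(adjacency.shape[0]),
        weights=adjacency,
        modality=modality,
        is_binary=True,
    )


def random_connected_adjacency(rng: np.random.Generator, n: int, p: float = 0.15) -> np.ndarray:
    """Erdos-Renyi adjacency, resampled until connected."""
    from scipy.sparse.csgraph import connected_components

    while True:
        upper = np.triu(rng.random((n, n)) < p, 1).astype(float)
        adj = upper + upper.T
        if connected_components(adj > 0, directed=False)[0] == 1:
            return adj


@pytest.fixture
def parc4() -> Parcellation:
    return make_parcellation(4)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
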