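"""Categorically-coupled multiplex assembly and its supra-adjacency matrix.

A multiplex of L binary layers on N shared nodes is flattened into an
(L*N) x (L*N) supra-adjacency matrix: diagonal blocks are the layer
adjacencies, every off-diagonal block is w * I_N (each node linked to its
replicas in all other layers). The inter-layer weight w is chosen so the
total inter-layer connection weight balances the intra-layer edges.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .datamodel import LayerNetwork, ValidationError


def interlayer_weight(density: float, n_nodes: int) -> float:
    """Balance weight w = gamma * (N - 1) / 4 for a three-layer multiplex.

    Derived by equating the total number of inter-layer connections with
    the intra-layer edge count: w = 3 * gamma * C(N,2) / (6N).
    At gamma = 0.20, N = 100 this gives 4.95 (the "factor five" coupling).
    """
    if not (0 < density < 1):
        raise ValidationError("density must lie in (0, 1)")
    if n_nodes < 2:
        raise ValidationError("need at least 2 nodes")
    return density * (n_nodes - 1) / 4.0


@dataclass(frozen=True)
class MultiplexNetwork:
    """Ordered binary layers plus the assembled supra-adjacency."""

    layers: tuple[LayerNetwork, ...]
    interlayer_weight: float
    supra: np.ndarray

    @property
    def n_nodes(self) -> int:
        return self.layers[0].n_nodes

    @property
    def n_layers(self) -> int:
        return len(self.layers)


def build_supra(layers: list[LayerNetwork], w: float) -> MultiplexNetwork:
    """Assemble the supra-adjacency of categorically coupled binary layers."""
    if len(layers) < 2:
        raise ValidationError("a multiplex needs at least 2 layers")
    n = layers[0].n_nodes
    for k, layer in enumerate(layers):
        if layer.n_nodes != n:
            raise ValidationError(f"layer {k} has {layer.n_nodes} nodes, expected {n}")
        if not layer.is_binary:
            raise ValidationError(f"layer {k} ({layer.modality}) is not binary")
    if w < 0:
        raise ValidationError("inter-layer weight must be nonnegative")
    ell = len(layers)
    supra = np.kron(w * (np.ones((ell, ell)) - np.eye(ell)), np.eye(n))
    for a, layer in enumerate(layers):
        supra[a * n : (a + 1) * n, a * n : (a + 1) * n] = layer.weights
    return MultiplexNetwork(layers=tuple(layers), interlayer_weight=float(w), supra=supra)


def write_supra(mplex: MultiplexNetwork, path) -> None:
    """Export the supra-adjacency (headerless CSV) with a JSON sidecar."""
    path = Path(path)
    np.savetxt(path, mplex.supra, delimiter=",", fmt="%.12g")
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(
        json.dumps(
            {
                "layer_order": [lay.modality for lay in mplex.layers],
                "n_nodes": mplex.n_nodes,
                "n_layers": mplex.n_layers,
                "interlayer_weight": mplex.interlayer_weight,
                "densities": [lay.density for lay in mplex.layers],
            },
            indent=2,
        )
    )
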