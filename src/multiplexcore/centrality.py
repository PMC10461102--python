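"""Degree and eigenvector-type centralities for monoplex and multiplex nets.

Eigenvector centrality (EC) is the leading eigenvector of the adjacency,
computed by power iteration from a uniform start (all nodes begin equally
central). Its multiplex generalization, eigentensor centrality (ETC), is
the leading eigenvector of the supra-adjacency: the per-node-per-layer
components Theta_{i,alpha} are aggregated over layers with equal weight
(maximum-entropy contraction with the all-ones layer vector) to give the
per-node score theta_i.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.sparse.csgraph import connected_components

from .datamodel import ConvergenceError, LayerNetwork, ValidationError
from .multiplex import MultiplexNetwork

logger = logging.getLogger(__name__)


def degree_centrality(network: LayerNetwork) -> np.ndarray:
    """Degree k_i of each node (row sums of a binary adjacency)."""
    if not network.is_binary:
        raise ValidationError("degree centrality is defined on binary layers")
    return network.weights.sum(axis=1).astype(int)


def overlapping_degree(layers: list[LayerNetwork]) -> np.ndarray:
    """Overlapping degree o_i = sum over layers of the per-layer degree."""
    n = layers[0].n_nodes
    for layer in layers:
        if layer.n_nodes != n:
            raise ValidationError("layers must share the node space")
    return np.sum([degree_centrality(layer) for layer in layers], axis=0)


def power_iteration(
    matrix: np.ndarray, tol: float = 1e-5, max_iter: int = 10_000
) -> tuple[np.ndarray, float, int]:
    """Leading eigenpair of a symmetric nonnegative matrix.

    Starts from the uniform unit vector; each step multiplies by the
    matrix and renormalizes to unit Euclidean length; stops when the
    largest componentwise change of the normalized vector drops below
    ``tol``. Returns (unit eigenvector, Rayleigh-quotient eigenvalue,
    iterations used).

    Iteration runs on the shifted matrix A + I: for a nonnegative
    symmetric A the shift leaves the eigenvectors unchanged but makes the
    Perron eigenvalue strictly dominant, so bipartite-like spectra
    (lambda and -lambda of equal magnitude, e.g. a star graph) cannot
    trap the iteration in a two-cycle. The returned eigenvalue is the
    Rayleigh quotient on the unshifted matrix.
    """
    a = np.asarray(matrix, dtype=float)
    n = a.shape[0]
    shifted = a + np.eye(n)
    x = np.full(n, 1.0 / np.sqrt(n))
    for it in range(1, max_iter + 1):
        y = shifted @ x
        norm = np.linalg.norm(y)
        if norm == 0:
            raise ValidationError("matrix annihilated the start vector (no edges?)")
        y /= norm
        residual = np.max(np.abs(y - x))
        x = y
        if residual < tol:
            return x, float(x @ a @ x), it
    raise ConvergenceError(
        f"power iteration did not converge in {max_iter} iterations "
        f"(last residual {residual:.3g})"
    )


def _warn_if_disconnected(adjacency: np.ndarray, what: str) -> None:
    n_comp, labels = connected_components(adjacency > 0, directed=False)
    if n_comp > 1:
        sizes = np.bincount(labels)
        logger.warning(
            "%s is disconnected (%d components, sizes %s); centrality reflects "
            "the dominant component",
            what,
            n_comp,
            sizes.tolist(),
        )


def eigenvector_centrality(
    network: LayerNetwork, tol: float = 1e-5, max_iter: int = 10_000
) -> tuple[np.ndarray, float]:
    """Monoplex EC: leading eigenvector of the adjacency (unit norm)."""
    if network.edge_count == 0:
        raise ValidationError("eigenvector centrality needs at least one edge")
    _warn_if_disconnected(network.weights, "graph")
    x, lam, _ = power_iteration(network.weights, tol=tol, max_iter=max_iter)
    return x, lam


@dataclass(frozen=True)
class CentralityProfile:
    """Multiplex centralities from one supra-adjacency."""

    layer_degrees: np.ndarray          # L x N
    overlapping_degree: np.ndarray     # N
    eigentensor: np.ndarray            # L x N components Theta_{i,alpha}
    aggregated_etc: np.ndarray         # N, unit Euclidean norm
    leading_eigenvalue: float
    iterations_used: int


def eigentensor_centrality(
    mplex: MultiplexNetwork, tol: float = 1e-5, max_iter: int = 10_000
) -> CentralityProfile:
    """ETC of a categorically coupled multiplex via its supra-adjacency."""
    if mplex.interlayer_weight <= 0:
        raise ValidationError("inter-layer weight must be positive for ETC")
    if not np.any(mplex.supra):
        raise ValidationError("supra-adjacency has no nonzero entries")
    _warn_if_disconnected(mplex.supra, "supra graph")
    vec, lam, its = power_iteration(mplex.supra, tol=tol, max_iter=max_iter)
    ell, n = mplex.n_layers, mplex.n_nodes
    theta_layers = vec.reshape(ell, n)
    theta = theta_layers.sum(axis=0)
    theta = theta / np.linalg.norm(theta)
    degrees = np.array([degree_centrality(layer) for layer in mplex.layers])
    return CentralityProfile(
        layer_degrees=degrees,
        overlapping_degree=degrees.sum(axis=0),
        eigentensor=theta_layers,
        aggregated_etc=theta,
        leading_eigenvalue=lam,
        iterations_used=its,
    )


def etc_group_comparison(
    theta_a: np.ndarray, theta_b: np.ndarray, rel_threshold: float = 0.3
) -> dict[str, float]:
    """Nodewise comparison of two centrality profiles.

    Reports the fraction of nodes where group A exceeds group B and, among
    those, the fraction whose relative difference (denominated in the
    lower group's value) reaches ``rel_threshold``; symmetrically for B
    over A.
    """
    a = np.asarray(theta_a, dtype=float)
    b = np.asarray(theta_b, dtype=float)
    if a.shape != b.shape:
        raise ValidationError("profiles must have equal length")
    if np.any(a <= 0) or np.any(b <= 0):
        raise ValidationError("centrality profiles must be strictly positive")
    n = a.size
    a_over = a > b
    b_over = b > a
    frac_a = a_over.sum() / n
    frac_b = b_over.sum() / n
    big_a = ((a - b) / b)[a_over] >= rel_threshold
    big_b = ((b - a) / a)[b_over] >= rel_threshold
    return {
        "fraction_a_higher": float(frac_a),
        "fraction_a_higher_large": float(big_a.mean()) if a_over.any() else 0.0,
        "fraction_b_higher": float(frac_b),
        "fraction_b_higher_large": float(big_b.mean()) if b_over.any() else 0.0,
    }
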