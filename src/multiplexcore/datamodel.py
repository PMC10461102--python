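"""Shared domain types for multiplex connectome analysis.

All layers (structural, functional, metabolic) live on a single node space
defined by a :class:`Parcellation`; node order in the parcellation is the
single source of truth for every matrix in a run.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

MODALITIES = ("SC", "FC", "MC")


class ValidationError(ValueError):
    """Input violates a domain invariant."""


class FormatError(ValueError):
    """A file or table does not have the expected shape/columns."""


class SolverError(RuntimeError):
    """An iterative estimator failed to converge."""


class ConvergenceError(SolverError):
    """Power iteration exceeded its iteration budget."""


@dataclass(frozen=True, eq=False)
class Parcellation:
    """Node space shared by all connectivity layers.

    Parameters
    ----------
    node_ids : contiguous integer labels ``0..N-1`` (defines node order).
    region_names : one name per node.
    network_labels : functional-network label per node (opaque strings,
        e.g. the seven Schaefer/Yeo network names).
    volumes : region volumes in mm^3, strictly positive.
    """

    node_ids: tuple[int, ...]
    region_names: tuple[str, ...]
    network_labels: tuple[str, ...]
    volumes: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "volumes", np.asarray(self.volumes, dtype=float))
        n = len(self.node_ids)
        if n < 2:
            raise ValidationError("parcellation needs at least 2 nodes")
        if list(self.node_ids) != list(range(n)):
            raise FormatError("node_ids must be unique and contiguous 0..N-1")
        if not (len(self.region_names) == len(self.network_labels) == self.volumes.shape[0] == n):
            raise FormatError("parcellation columns have mismatched lengths")
        if not np.all(self.volumes > 0):
            bad = int(np.flatnonzero(self.volumes <= 0)[0])
            raise ValidationError(f"non-positive volume for node {bad}")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Parcellation):
            return NotImplemented
        return (
            self.node_ids == other.node_ids
            and self.region_names == other.region_names
            and self.network_labels == other.network_labels
            and np.array_equal(self.volumes, other.volumes)
        )

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    def networks(self) -> tuple[str, ...]:
        """Distinct network labels in first-appearance order."""
        seen: dict[str, None] = {}
        for lab in self.network_labels:
            seen.setdefault(lab)
        return tuple(seen)


def _check_square_symmetric(weights: np.ndarray, tol: float = 0.0) -> np.ndarray:
    w = np.asarray(weights, dtype=float)
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise FormatError(f"expected a square matrix, got shape {w.shape}")
    asym = np.abs(w - w.T).max() if w.size else 0.0
    if asym > tol:
        raise ValidationError(f"matrix is asymmetric (max |A-A'| = {asym:.3g})")
    return w


@dataclass(frozen=True)
class LayerNetwork:
    """One N x N connectivity layer (weighted or binary).

    ``density`` is the fraction of realized node pairs and is only defined
    for binary networks; weighted networks carry ``density=None``.
    """

    parcellation: Parcellation
    weights: np.ndarray
    modality: str
    is_binary: bool = False
    density: float | None = None

    def __post_init__(self) -> None:
        w = _check_square_symmetric(self.weights)
        object.__setattr__(self, "weights", w)
        n = self.parcellation.n_nodes
        if w.shape[0] != n:
            raise FormatError(f"matrix size {w.shape[0]} != parcellation size {n}")
        if self.modality not in MODALITIES:
            raise ValidationError(f"modality must be one of {MODALITIES}, got {self.modality!r}")
        if np.any(np.diag(w) != 0):
            raise ValidationError("layer adjacency must have a zero diagonal")
        if self.is_binary:
            if not np.isin(w, (0.0, 1.0)).all():
                raise ValidationError("binary layer has entries outside {0, 1}")
            m = int(np.count_nonzero(np.triu(w, 1)))
            dens = m / (n * (n - 1) / 2)
            if self.density is None:
                object.__setattr__(self, "density", dens)
            elif abs(self.density - dens) > 1e-12:
                raise ValidationError(
                    f"declared density {self.density} != realized {dens}"
                )

    @property
    def n_nodes(self) -> int:
        return self.parcellation.n_nodes

    @property
    def edge_count(self) -> int:
        return int(np.count_nonzero(np.triu(self.weights, 1)))

    def with_weights(self, weights: np.ndarray, **changes) -> "LayerNetwork":
        return replace(self, weights=weights, **changes)


@dataclass(frozen=True)
class SubjectObservations:
    """Per-subject raw observations on one parcellation.

    Any of the three blocks may be absent (``None``) if the corresponding
    modality is not analyzed.

    ``timeseries``: list of T_s x N arrays (ROI-averaged BOLD).
    ``uptake``: subjects x N array of positive tracer-uptake values.
    ``streamline_counts``: list of N x N symmetric nonnegative count matrices.
    """

    parcellation: Parcellation
    timeseries: tuple[np.ndarray, ...] | None = None
    uptake: np.ndarray | None = None
    streamline_counts: tuple[np.ndarray, ...] | None = None

    def __post_init__(self) -> None:
        n = self.parcellation.n_nodes
        if self.timeseries is not None:
            ts = tuple(np.asarray(t, dtype=float) for t in self.timeseries)
            for k, t in enumerate(ts):
                if t.ndim != 2 or t.shape[1] != n:
                    raise FormatError(f"time series {k}: expected T x {n}, got {t.shape}")
                if t.shape[0] < 2:
                    raise ValidationError(f"time series {k}: needs T >= 2, got T={t.shape[0]}")
            object.__setattr__(self, "timeseries", ts)
        if self.uptake is not None:
            u = np.asarray(self.uptake, dtype=float)
            if u.ndim != 2 or u.shape[1] != n:
                raise FormatError(f"uptake table: expected subjects x {n}, got {u.shape}")
            if not np.all(u > 0):
                raise ValidationError("uptake values must be strictly positive")
            object.__setattr__(self, "uptake", u)
        if self.streamline_counts is not None:
            cs = tuple(np.asarray(c, dtype=float) for c in self.streamline_counts)
            for k, c in enumerate(cs):
                _check_square_symmetric(c)
                if c.shape[0] != n:
                    raise FormatError(f"streamline matrix {k}: size {c.shape[0]} != {n}")
                if np.any(c < 0):
                    raise ValidationError(f"streamline matrix {k}: negative count")
            object.__setattr__(self, "streamline_counts", cs)

    @property
    def n_subjects(self) -> int:
        sizes = [
            len(x) if x is not None else 0
            for x in (self.timeseries, self.streamline_counts)
        ]
        if self.uptake is not None:
            sizes.append(self.uptake.shape[0])
        return max(sizes)


def default_density_grid() -> tuple[float, ...]:
    """Connectivity densities 10% to 50% in 1% steps (41 values)."""
    return tuple(np.round(np.arange(10, 51) / 100.0, 2))


def default_delta_grid() -> tuple[float, ...]:
    """Core-selection thresholds delta = 0.4 to 1.6 in 0.2 steps (7 values)."""
    return tuple(np.round(np.arange(2, 9) * 0.2, 1))


@dataclass(frozen=True)
class CoreConfig:
    """Grids and numerical settings for the coreness sweep."""

    density_grid: tuple[float, ...] = field(default_factory=default_density_grid)
    delta_grid: tuple[float, ...] = field(default_factory=default_delta_grid)
    top_fraction: float = 0.15
    power_iteration_tol: float = 1e-5
    max_iterations: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        dg, deltas = tuple(self.density_grid), tuple(self.delta_grid)
        object.__setattr__(self, "density_grid", dg)
        object.__setattr__(self, "delta_grid", deltas)
        if not dg or not deltas:
            raise ValidationError("density and delta grids must be non-empty")
        if any(b <= a for a, b in zip(dg, dg[1:])) or any(
            b <= a for a, b in zip(deltas, deltas[1:])
        ):
            raise ValidationError("grids must be strictly increasing")
        if not all(0 < g < 1 for g in dg):
            raise ValidationError("densities must lie in (0, 1)")
        if not (0 < self.top_fraction <= 1):
            raise ValidationError("top_fraction must lie in (0, 1]")
        if self.power_iteration_tol <= 0 or self.max_iterations <= 0:
            raise ValidationError("tolerance and iteration budget must be positive")

    @property
    def n_configurations(self) -> int:
        return len(self.density_grid) * len(self.delta_grid)
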