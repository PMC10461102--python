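"""Core-node selection and the coreness coefficient.

A node is in the core of one configuration (density gamma, threshold
delta) when it scores above mu + delta*sigma on BOTH a degree-type measure
(DC or overlapping degree) and an eigenvector-type measure (EC or
eigentensor centrality). The coreness coefficient C_i is the frequency of
core membership across the full (gamma, delta) grid, which makes the final
core robust to the arbitrary choices of binarization density and selection
threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Mapping

import numpy as np
import pandas as pd

from .datamodel import CoreConfig, Parcellation, ValidationError

logger = logging.getLogger(__name__)


def select_core(
    first_centrality: np.ndarray, second_centrality: np.ndarray, delta: float
) -> frozenset[int]:
    """Nodes strictly above mu + delta*sigma on both measures.

    Mean and standard deviation are taken over all N nodes per measure
    (population form, ddof=0); the inequality is strict, so a measure with
    zero variance admits no nodes.
    """
    c1 = np.asarray(first_centrality, dtype=float)
    c2 = np.asarray(second_centrality, dtype=float)
    if c1.shape != c2.shape or c1.ndim != 1 or c1.size == 0:
        raise ValidationError("centrality vectors must be equal-length and non-empty")
    if delta < 0:
        raise ValidationError("delta must be nonnegative")
    t1 = c1.mean() + delta * c1.std()
    t2 = c2.mean() + delta * c2.std()
    if c1.std() == 0 or c2.std() == 0:
        logger.info("zero-variance centrality at delta=%g; strict threshold applies", delta)
    return frozenset(np.flatnonzero((c1 > t1) & (c2 > t2)).tolist())


@dataclass(frozen=True)
class CoreResult:
    """Coreness over the configuration grid for one network source."""

    parcellation: Parcellation
    per_config_cores: Mapping[tuple[float, float], frozenset[int]]
    coreness: np.ndarray
    top_core: frozenset[int]
    config: CoreConfig
    source: str  # "SC" | "FC" | "MC" | "multiplex"


def coreness_coefficient(
    centrality_pairs: Callable[[float], tuple[np.ndarray, np.ndarray]],
    parcellation: Parcellation,
    config: CoreConfig,
    source: str,
) -> CoreResult:
    """Sweep the (density, delta) grid and count core memberships.

    ``centrality_pairs(gamma)`` must return the (degree-type,
    eigenvector-type) centrality vectors of the network built at density
    gamma; this function owns only the grid bookkeeping, so monoplex and
    multiplex sweeps share it.
    """
    n = parcellation.n_nodes
    counts = np.zeros(n)
    per_config: dict[tuple[float, float], frozenset[int]] = {}
    for gamma in config.density_grid:
        c_deg, c_eig = centrality_pairs(gamma)
        for delta in config.delta_grid:
            core = select_core(c_deg, c_eig, delta)
            per_config[(gamma, delta)] = core
            logger.debug("gamma=%g delta=%g core size %d", gamma, delta, len(core))
            for i in core:
                counts[i] += 1
    coreness = counts / config.n_configurations
    result = CoreResult(
        parcellation=parcellation,
        per_config_cores=per_config,
        coreness=coreness,
        top_core=frozenset(),
        config=config,
        source=source,
    )
    object.__setattr__(result, "top_core", top_fraction_core(result, config.top_fraction))
    return result


def top_fraction_core(result: CoreResult, fraction: float) -> frozenset[int]:
    """The round(fraction*N) nodes with the largest coreness.

    Boundary ties are broken in favor of the lower node id, which keeps
    the selection deterministic across platforms.
    """
    if not (0 < fraction <= 1):
        raise ValidationError("fraction must lie in (0, 1]")
    n = result.parcellation.n_nodes
    k = int(np.floor(fraction * n + 0.5))
    order = np.lexsort((np.arange(n), -result.coreness))
    return frozenset(order[:k].tolist())


@dataclass(frozen=True)
class CoreSimilarity:
    """Overlap of one core with a reference core: S_c = I / |reference|."""

    value: float
    intersection_count: int
    reference_core_size: int


def core_similarity(core_ref: frozenset[int], core_other: frozenset[int]) -> CoreSimilarity:
    """Fraction of the reference core shared with the other core."""
    if not core_ref:
        raise ValidationError("reference core must be non-empty")
    inter = len(set(core_ref) & set(core_other))
    return CoreSimilarity(
        value=inter / len(core_ref),
        intersection_count=inter,
        reference_core_size=len(core_ref),
    )


def network_membership_summary(
    core: frozenset[int], parcellation: Parcellation
) -> pd.Series:
    """Percentage of core nodes falling in each functional network.

    Covers every distinct label in the parcellation (zeros included);
    unrounded percentages sum to exactly 100.
    """
    if not core:
        raise ValidationError("core must be non-empty")
    if not set(core) <= set(parcellation.node_ids):
        raise ValidationError("core contains unknown node ids")
    labels = parcellation.network_labels
    nets = parcellation.networks()
    counts = {net: 0 for net in nets}
    for i in core:
        counts[labels[i]] += 1
    return pd.Series(
        {net: 100.0 * counts[net] / len(core) for net in nets}, name="percent_of_core"
    )
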