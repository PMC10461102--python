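"""End-to-end orchestration: layers -> multiplex -> centralities -> coreness.

The analysis itself is deterministic; randomness exists only in synthetic
data generation. Every run can be summarized by a :class:`RunManifest`
that, together with the input files, reproduces all outputs bit-for-bit.
"""

from __future__ import annotations

import datetime
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .centrality import (
    degree_centrality,
    eigentensor_centrality,
    eigenvector_centrality,
    etc_group_comparison,
    overlapping_degree,
)
from .core import (
    CoreResult,
    core_similarity,
    coreness_coefficient,
    network_membership_summary,
)
from .datamodel import CoreConfig, Parcellation, SubjectObservations, ValidationError
from .layers import PopulationConnectome, binarize_to_density, build_population_connectome
from .multiplex import build_supra, interlayer_weight

logger = logging.getLogger(__name__)

SOURCES = ("SC", "FC", "MC", "multiplex")


def _monoplex_pairs(connectome: PopulationConnectome, modality: str, config: CoreConfig):
    """Per-density (DC, EC) provider for one modality."""

    def pairs(gamma: float):
        if modality == "MC":
            if connectome.mc_matcher is None:
                raise ValidationError("no uptake data for MC")
            net = connectome.mc_matcher.support_at_density(gamma)
        else:
            weighted = connectome.sc_weighted if modality == "SC" else connectome.fc_weighted
            if weighted is None:
                raise ValidationError(f"no data for modality {modality}")
            net = binarize_to_density(weighted, gamma)
        dc = degree_centrality(net)
        ec, _ = eigenvector_centrality(
            net, tol=config.power_iteration_tol, max_iter=config.max_iterations
        )
        return dc.astype(float), ec

    return pairs


def run_monoplex(
    parcellation: Parcellation,
    obs: SubjectObservations,
    modality: str,
    config: CoreConfig,
) -> CoreResult:
    """Monoplex coreness sweep for one modality on the (DC, EC) pair."""
    if modality not in ("SC", "FC", "MC"):
        raise ValidationError(f"unknown modality {modality!r}")
    connectome = build_population_connectome(obs)
    return coreness_coefficient(
        _monoplex_pairs(connectome, modality, config), parcellation, config, modality
    )


def run_multiplex(
    parcellation: Parcellation,
    obs: SubjectObservations,
    config: CoreConfig,
) -> tuple[CoreResult, np.ndarray]:
    """Multiplex coreness sweep on the (ODC, ETC) pair.

    Returns the coreness result plus the eigentensor centrality averaged
    across the density grid (the profile used for group comparisons).
    """
    connectome = build_population_connectome(obs)
    n = parcellation.n_nodes
    theta_accum = np.zeros(n)
    n_gamma = 0

    def pairs(gamma: float):
        nonlocal n_gamma
        layers = connectome.binary_layers(gamma)
        w = interlayer_weight(gamma, n)
        mplex = build_supra(layers, w)
        profile = eigentensor_centrality(
            mplex, tol=config.power_iteration_tol, max_iter=config.max_iterations
        )
        theta_accum[:] += profile.aggregated_etc
        n_gamma += 1
        logger.debug("gamma=%g w=%g lambda1=%g", gamma, w, profile.leading_eigenvalue)
        return overlapping_degree(layers).astype(float), profile.aggregated_etc

    result = coreness_coefficient(pairs, parcellation, config, "multiplex")
    return result, theta_accum / n_gamma


def run_group_comparison(
    parcellation: Parcellation,
    obs_a: SubjectObservations,
    obs_b: SubjectObservations,
    config: CoreConfig,
    rel_threshold: float = 0.3,
) -> dict:
    """Per-source coreness in two groups, core similarity (reference =
    group A), ETC comparison on density-averaged profiles, and
    network-membership summaries."""
    report: dict = {"sources": {}, "config": _config_dict(config)}
    for source in SOURCES:
        if source == "multiplex":
            res_a, theta_a = run_multiplex(parcellation, obs_a, config)
            res_b, theta_b = run_multiplex(parcellation, obs_b, config)
            report["etc_comparison"] = etc_group_comparison(theta_a, theta_b, rel_threshold)
            report["theta_a"] = theta_a.tolist()
            report["theta_b"] = theta_b.tolist()
        else:
            res_a = run_monoplex(parcellation, obs_a, source, config)
            res_b = run_monoplex(parcellation, obs_b, source, config)
        sim = core_similarity(res_a.top_core, res_b.top_core)
        report["sources"][source] = {
            "core_similarity": sim.value,
            "intersection": sim.intersection_count,
            "core_a": sorted(res_a.top_core),
            "core_b": sorted(res_b.top_core),
            "membership_a": network_membership_summary(res_a.top_core, parcellation).to_dict(),
            "membership_b": network_membership_summary(res_b.top_core, parcellation).to_dict(),
        }
    return report


def _config_dict(config: CoreConfig) -> dict:
    return {
        "density_grid": list(config.density_grid),
        "delta_grid": list(config.delta_grid),
        "top_fraction": config.top_fraction,
        "power_iteration_tol": config.power_iteration_tol,
        "max_iterations": config.max_iterations,
        "seed": config.seed,
    }


@dataclass
class RunManifest:
    """Provenance record sufficient to reproduce a run from its inputs."""

    command: str
    config: CoreConfig
    input_paths: dict = field(default_factory=dict)
    output_paths: dict = field(default_factory=dict)
    seed: int = 0
    version: str = __version__
    timestamp: str = field(
        default_factory=lambda: datetime.datetime.now(datetime.timezone.utc).isoformat()
    )
    extra: dict = field(default_factory=dict)

    def write(self, path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "command": self.command,
                    "version": self.version,
                    "seed": self.seed,
                    "timestamp": self.timestamp,
                    "config": _config_dict(self.config),
                    "inputs": self.input_paths,
                    "outputs": self.output_paths,
                    **self.extra,
                },
                indent=2,
            )
        )
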