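"""Synthetic subject-level observations from a planted core-periphery model.

Emulates the statistical structure the analysis assumes: a shared set of
hub nodes that are densely connected within themselves and toward the
periphery, expressed independently in each connectivity layer. Time series
come from a stationary AR(1) Gaussian process whose stationary covariance
encodes the planted functional graph; uptake vectors come from a Gaussian
with sparse planted precision (then exponentiated to positive values);
streamline counts are Poisson with volume-proportional means on planted
structural edges.

All randomness flows from one root seed through named `SeedSequence`
child streams, so identical seeds give bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .datamodel import LayerNetwork, Parcellation, SubjectObservations, ValidationError

_NETWORK_NAMES = (
    "Visual",
    "Somatomotor",
    "DorsalAttention",
    "Salience",
    "Limbic",
    "Control",
    "DefaultMode",
)

_STREAMS = ("parcellation", "graph_SC", "graph_FC", "graph_MC", "timeseries", "uptake", "streamlines")


@dataclass(frozen=True)
class PlantedModel:
    """Parameters of the planted core-periphery generator.

    Block edge probabilities (hub-hub, hub-periphery, periphery-periphery)
    default to (0.8, 0.35, 0.08), giving hubs an expected degree of ~41
    against ~12 for periphery nodes at N=100. ``layer_probs`` optionally
    overrides the block probabilities per modality (used to attenuate
    FC/MC hubs in an "old" group while leaving SC untouched).
    """

    n_nodes: int = 100
    hub_set: tuple[int, ...] = tuple(range(15))
    p_hh: float = 0.8
    p_hp: float = 0.35
    p_pp: float = 0.08
    layer_probs: dict | None = None
    subjects: int = 30
    n_timepoints: int = 200
    ar_coefficient: float = 0.3
    noise_sd: float = 0.05
    fc_coupling_scale: float = 0.9   # c = scale / lambda_max(G), keeps Sigma PD
    uptake_coupling: float = 0.4     # off-diagonal precision weight on planted edges
    uptake_log_scale: float = 0.25   # log-scale of the exponentiated Gaussian
    uptake_level: float = 10.0       # multiplicative uptake scale (arbitrary units)
    sc_base_rate: float = 0.005      # streamlines per mm^3 of summed volume on an edge
    sc_offedge_strength: float = 0.02
    volume_range: tuple[float, float] = (500.0, 1500.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.p_hh > self.p_hp > self.p_pp >= 0):
            raise ValidationError("block probabilities must satisfy p_hh > p_hp > p_pp")
        if not set(self.hub_set) <= set(range(self.n_nodes)):
            raise ValidationError("hub_set must be a subset of the nodes")
        if not (0 <= self.ar_coefficient < 1):
            raise ValidationError("ar_coefficient must lie in [0, 1)")
        if self.n_timepoints < 3 or self.subjects < 3:
            raise ValidationError("need at least 3 timepoints and 3 subjects")

    def block_probs(self, modality: str) -> tuple[float, float, float]:
        if self.layer_probs and modality in self.layer_probs:
            return self.layer_probs[modality]
        return (self.p_hh, self.p_hp, self.p_pp)


def _streams(model: PlantedModel) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(model.seed).spawn(len(_STREAMS))
    return {name: np.random.default_rng(seq) for name, seq in zip(_STREAMS, children)}


def _sample_adjacency(
    model: PlantedModel, rng: np.random.Generator, modality: str
) -> np.ndarray:
    """Bernoulli block adjacency with hub/periphery edge probabilities."""
    n = model.n_nodes
    p_hh, p_hp, p_pp = model.block_probs(modality)
    is_hub = np.zeros(n, dtype=bool)
    is_hub[list(model.hub_set)] = True
    prob = np.where(
        is_hub[:, None] & is_hub[None, :],
        p_hh,
        np.where(is_hub[:, None] | is_hub[None, :], p_hp, p_pp),
    )
    upper = np.triu(rng.random((n, n)) < prob, 1).astype(float)
    return upper + upper.T


def make_parcellation(model: PlantedModel, rng: np.random.Generator | None = None) -> Parcellation:
    """Synthetic parcellation: cyclic functional-network labels and
    uniform-random region volumes in ``volume_range`` (mm^3)."""
    rng = rng or _streams(model)["parcellation"]
    n = model.n_nodes
    lo, hi = model.volume_range
    return Parcellation(
        node_ids=tuple(range(n)),
        region_names=tuple(f"ROI_{i:03d}" for i in range(n)),
        network_labels=tuple(_NETWORK_NAMES[i % len(_NETWORK_NAMES)] for i in range(n)),
        volumes=rng.uniform(lo, hi, size=n),
    )


def sample_layer_graph(
    model: PlantedModel,
    rng: np.random.Generator,
    parcellation: Parcellation,
    modality: str = "SC",
) -> LayerNetwork:
    """One planted binary layer as a validated network object."""
    return LayerNetwork(
        parcellation=parcellation,
        weights=_sample_adjacency(model, rng, modality),
        modality=modality,
        is_binary=True,
    )


def sample_fc_subjects(
    model: PlantedModel, rng: np.random.Generator, adjacency: np.ndarray
) -> tuple[np.ndarray, ...]:
    """Per-subject stationary AR(1) series with covariance I + c*G.

    c is set to ``fc_coupling_scale / lambda_max(G)`` so the stationary
    covariance stays positive definite; planted edges therefore carry
    population correlation c, absent edges zero. White observation noise
    of sd ``noise_sd`` is added on top.
    """
    n = model.n_nodes
    lam_max = np.linalg.eigvalsh(adjacency)[-1] if np.any(adjacency) else 0.0
    c = model.fc_coupling_scale / lam_max if lam_max > 0 else 0.0
    sigma = np.eye(n) + c * adjacency
    chol = np.linalg.cholesky(sigma)
    phi = model.ar_coefficient
    innov_scale = np.sqrt(1.0 - phi**2)
    t_len = model.n_timepoints
    out = []
    for _ in range(model.subjects):
        x = np.empty((t_len, n))
        x[0] = chol @ rng.standard_normal(n)
        for t in range(1, t_len):
            x[t] = phi * x[t - 1] + innov_scale * (chol @ rng.standard_normal(n))
        if model.noise_sd > 0:
            x = x + model.noise_sd * rng.standard_normal(x.shape)
        out.append(x)
    return tuple(out)


def sample_uptake_subjects(
    model: PlantedModel,
    rng: np.random.Generator,
    adjacency: np.ndarray,
    n_subjects: int | None = None,
) -> np.ndarray:
    """Subjects x N uptake table from a sparse-precision Gaussian.

    The precision matrix is P = I + rho*(D - G) with D the degree
    diagonal, which is diagonally dominant (hence PD) and has off-diagonal
    support exactly on the planted edges. Gaussian samples are
    exponentiated on a mild log-scale, keeping values strictly positive
    while approximately preserving pairwise correlations.
    """
    n = model.n_nodes
    s = n_subjects if n_subjects is not None else model.subjects
    rho = model.uptake_coupling
    degree = adjacency.sum(axis=1)
    precision = np.eye(n) + rho * (np.diag(degree) - adjacency)
    cov = np.linalg.inv(precision)
    chol = np.linalg.cholesky(cov)
    z = rng.standard_normal((s, n)) @ chol.T
    return model.uptake_level * np.exp(model.uptake_log_scale * z)


def sample_sc_subjects(
    model: PlantedModel,
    rng: np.random.Generator,
    adjacency: np.ndarray,
    volumes: np.ndarray,
) -> tuple[np.ndarray, ...]:
    """Per-subject streamline counts: Poisson with volume-scaled means.

    Mean count on (i, j) is base_rate * strength_ij * (vol_i + vol_j),
    with strength 1 on planted edges and ``sc_offedge_strength`` off them,
    so volume normalization downstream approximately recovers the planted
    edge strengths.
    """
    n = model.n_nodes
    strength = np.where(adjacency > 0, 1.0, model.sc_offedge_strength)
    np.fill_diagonal(strength, 0.0)
    mean = model.sc_base_rate * strength * (volumes[:, None] + volumes[None, :])
    iu = np.triu_indices(n, 1)
    out = []
    for _ in range(model.subjects):
        counts = np.zeros((n, n))
        counts[iu] = rng.poisson(mean[iu])
        out.append(counts + counts.T)
    return tuple(out)


def make_observations(
    model: PlantedModel,
) -> tuple[Parcellation, SubjectObservations, dict]:
    """Full synthetic dataset: parcellation, all three observation blocks,
    and a ground-truth record (hub set, per-layer planted graphs, seed)."""
    streams = _streams(model)
    parc = make_parcellation(model, streams["parcellation"])
    g_sc = _sample_adjacency(model, streams["graph_SC"], "SC")
    g_fc = _sample_adjacency(model, streams["graph_FC"], "FC")
    g_mc = _sample_adjacency(model, streams["graph_MC"], "MC")
    obs = SubjectObservations(
        parcellation=parc,
        timeseries=sample_fc_subjects(model, streams["timeseries"], g_fc),
        uptake=sample_uptake_subjects(model, streams["uptake"], g_mc),
        streamline_counts=sample_sc_subjects(model, streams["streamlines"], g_sc, parc.volumes),
    )
    truth = {
        "seed": model.seed,
        "hub_set": sorted(model.hub_set),
        "n_nodes": model.n_nodes,
        "subjects": model.subjects,
        "planted_edges": {
            "SC": np.triu(g_sc, 1).nonzero()[0].size,
            "FC": np.triu(g_fc, 1).nonzero()[0].size,
            "MC": np.triu(g_mc, 1).nonzero()[0].size,
        },
    }
    return parc, obs, truth


def attenuated(model: PlantedModel, p_hh: float = 0.6, p_hp: float = 0.30) -> PlantedModel:
    """An "old-group" variant: FC and MC hub probabilities weakened, SC
    untouched (structural cores age slower than functional/metabolic)."""
    overrides = dict(model.layer_probs or {})
    overrides["FC"] = (p_hh, p_hp, model.p_pp)
    overrides["MC"] = (p_hh, p_hp, model.p_pp)
    return replace(model, layer_probs=overrides, seed=model.seed + 1)


def make_group_pair(
    model_young: PlantedModel, model_old: PlantedModel | None = None
) -> tuple[
    tuple[Parcellation, SubjectObservations, dict],
    tuple[Parcellation, SubjectObservations, dict],
]:
    """Two independent groups on one shared parcellation.

    By default the old group is :func:`attenuated` from the young model.
    Both groups share the young model's parcellation (same node space and
    volumes); observations are drawn from each model's own seed streams.
    """
    if model_old is None:
        model_old = attenuated(model_young)
    if model_old.n_nodes != model_young.n_nodes:
        raise ValidationError("group models must share the node count")
    parc_young, obs_young, truth_young = make_observations(model_young)
    streams_old = _streams(model_old)
    g_sc = _sample_adjacency(model_old, streams_old["graph_SC"], "SC")
    g_fc = _sample_adjacency(model_old, streams_old["graph_FC"], "FC")
    g_mc = _sample_adjacency(model_old, streams_old["graph_MC"], "MC")
    obs_old = SubjectObservations(
        parcellation=parc_young,
        timeseries=sample_fc_subjects(model_old, streams_old["timeseries"], g_fc),
        uptake=sample_uptake_subjects(model_old, streams_old["uptake"], g_mc),
        streamline_counts=sample_sc_subjects(
            model_old, streams_old["streamlines"], g_sc, parc_young.volumes
        ),
    )
    truth_old = {
        "seed": model_old.seed,
        "hub_set": sorted(model_old.hub_set),
        "n_nodes": model_old.n_nodes,
        "subjects": model_old.subjects,
        "planted_edges": {
            "SC": np.triu(g_sc, 1).nonzero()[0].size,
            "FC": np.triu(g_fc, 1).nonzero()[0].size,
            "MC": np.triu(g_mc, 1).nonzero()[0].size,
        },
    }
    return (parc_young, obs_young, truth_young), (parc_young, obs_old, truth_old)
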