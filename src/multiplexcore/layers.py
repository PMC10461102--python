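"""Construction of weighted SC/FC/MC population layers and density-matched
binarization.

Structural (SC) and functional (FC) layers are built per subject and
averaged across the population; the metabolic (MC) layer is estimated at the
population level from across-subject covariation of tracer uptake via
sparse inverse covariance estimation (SICE). All layers are binarized to a
common connectivity density before entering the multiplex.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.covariance import graphical_lasso

from .datamodel import (
    LayerNetwork,
    Parcellation,
    SolverError,
    SubjectObservations,
    ValidationError,
)

__all__ = [
    "fc_from_timeseries",
    "sc_from_streamlines",
    "population_average",
    "proportional_scaling",
    "SICEDensityMatcher",
    "mc_via_sice",
    "binarize_to_density",
    "PopulationConnectome",
    "build_population_connectome",
]


def fc_from_timeseries(series: np.ndarray, parcellation: Parcellation) -> LayerNetwork:
    """Functional connectivity: Pearson correlation between ROI time series.

    The diagonal is zeroed; off-diagonal weights lie in [-1, 1].
    """
    ts = np.asarray(series, dtype=float)
    if ts.ndim != 2 or ts.shape[1] != parcellation.n_nodes:
        raise ValidationError(f"expected T x {parcellation.n_nodes} series, got {ts.shape}")
    if ts.shape[0] < 3:
        raise ValidationError("need at least 3 timepoints for correlation")
    sd = ts.std(axis=0)
    if np.any(sd == 0):
        bad = int(np.flatnonzero(sd == 0)[0])
        raise ValidationError(f"zero-variance time series for node {bad}")
    r = np.corrcoef(ts.T)
    np.fill_diagonal(r, 0.0)
    r = (r + r.T) / 2.0  # guard against last-bit asymmetry
    return LayerNetwork(parcellation=parcellation, weights=r, modality="FC")


def sc_from_streamlines(counts: np.ndarray, parcellation: Parcellation) -> LayerNetwork:
    """Structural connectivity: streamline counts normalized by the summed
    volumes of the two endpoint regions (streamline-density units)."""
    c = np.asarray(counts, dtype=float)
    if np.any(c < 0):
        raise ValidationError("streamline counts must be nonnegative")
    vols = parcellation.volumes
    denom = vols[:, None] + vols[None, :]
    w = c / denom
    np.fill_diagonal(w, 0.0)
    return LayerNetwork(parcellation=parcellation, weights=w, modality="SC")


def population_average(networks: list[LayerNetwork]) -> LayerNetwork:
    """Entrywise mean of weighted subject networks (shared modality)."""
    if not networks:
        raise ValidationError("need at least one network to average")
    modality = networks[0].modality
    parc = networks[0].parcellation
    for net in networks[1:]:
        if net.modality != modality:
            raise ValidationError(f"mixed modalities: {modality} vs {net.modality}")
        if net.parcellation is not parc and net.parcellation != parc:
            raise ValidationError("networks do not share a parcellation")
    mean = np.mean([net.weights for net in networks], axis=0)
    return LayerNetwork(parcellation=parc, weights=mean, modality=modality)


def proportional_scaling(raw_uptake: np.ndarray) -> np.ndarray:
    """Normalize a subject's regional uptake by the total uptake.

    Accepts a single length-N vector or a subjects x N table; each row of
    the output sums to one.
    """
    u = np.asarray(raw_uptake, dtype=float)
    if np.any(u <= 0):
        raise ValidationError("uptake values must be strictly positive")
    total = u.sum(axis=-1, keepdims=True)
    return u / total


def _triu_edge_count(n: int, density: float) -> int:
    return int(np.floor(density * (n * (n - 1) / 2) + 0.5))


class SICEDensityMatcher:
    """Sparse inverse covariance estimation with density-matched support.

    Holds the empirical correlation of the (column-standardized) uptake
    table and caches graphical-lasso fits along the L1 path, so that
    repeated density requests (e.g. a 41-point density sweep) reuse probed
    penalties. The achieved support density is non-increasing in the
    penalty, which is what the bisection exploits.
    """

    def __init__(
        self,
        uptake_table: np.ndarray,
        parcellation: Parcellation,
        *,
        penalty_bracket: tuple[float, float] = (1e-4, 1.0),
        max_bisections: int = 50,
        solver_tol: float = 1e-3,
        solver_max_iter: int = 200,
        support_tol: float = 1e-8,
    ) -> None:
        x = np.asarray(uptake_table, dtype=float)
        if x.ndim != 2 or x.shape[1] != parcellation.n_nodes:
            raise ValidationError(
                f"expected subjects x {parcellation.n_nodes} table, got {x.shape}"
            )
        if x.shape[0] < 3:
            raise ValidationError(f"SICE needs >= 3 subjects, got {x.shape[0]}")
        sd = x.std(axis=0)
        if np.any(sd == 0):
            bad = int(np.flatnonzero(sd == 0)[0])
            raise ValidationError(f"zero across-subject variance for node {bad}")
        z = (x - x.mean(axis=0)) / sd
        self.parcellation = parcellation
        self.emp_cov = np.corrcoef(z.T)
        self.penalty_bracket = penalty_bracket
        self.max_bisections = max_bisections
        self.solver_tol = solver_tol
        self.solver_max_iter = solver_max_iter
        self.support_tol = support_tol
        self._cache: dict[float, int] = {}  # penalty -> upper-triangle edge count
        self._supports: dict[float, np.ndarray] = {}
        self._failed: set[float] = set()

    def _fit(self, alpha: float) -> int:
        if alpha in self._cache:
            return self._cache[alpha]
        if alpha in self._failed:
            raise SolverError(f"graphical lasso failed at penalty {alpha:g}")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                _, precision = graphical_lasso(
                    self.emp_cov,
                    alpha=alpha,
                    mode="cd",
                    tol=self.solver_tol,
                    max_iter=self.solver_max_iter,
                )
            except (FloatingPointError, np.linalg.LinAlgError) as exc:
                self._failed.add(alpha)
                raise SolverError(f"graphical lasso failed at penalty {alpha:g}: {exc}") from exc
        n = self.parcellation.n_nodes
        iu = np.triu_indices(n, 1)
        support = np.abs(precision[iu]) > self.support_tol
        self._cache[alpha] = int(support.sum())
        adj = np.zeros((n, n))
        adj[iu] = support.astype(float)
        self._supports[alpha] = adj + adj.T
        return self._cache[alpha]

    def support_at_density(self, target_density: float) -> LayerNetwork:
        """Binary MC layer whose support density best matches the target.

        Bisects the penalty until the supported edge count equals the
        target exactly, or the bisection budget is spent; then prefers the
        closest probed density not exceeding the target.
        """
        if not (0 < target_density < 1):
            raise ValidationError("target density must lie in (0, 1)")
        n = self.parcellation.n_nodes
        target_m = _triu_edge_count(n, target_density)

        lo, hi = self.penalty_bracket  # density decreases as penalty grows
        # seed the bracket from the cache where possible
        for a, m in sorted(self._cache.items()):
            if m >= target_m:
                lo = max(lo, a)
            if m <= target_m:
                hi = min(hi, a)
                break
        # with fewer subjects than nodes the dense (small-penalty) end can be
        # ill-conditioned: raise the low bracket until the solver succeeds
        best_alpha = None
        while lo < hi:
            try:
                if self._fit(lo) == target_m:
                    best_alpha = lo
                break
            except SolverError:
                lo *= 4.0
        if lo >= hi and hi in self._failed:
            raise SolverError("graphical lasso failed over the whole penalty bracket")
        if self._fit(hi) == target_m:
            best_alpha = hi
        it = 0
        while best_alpha is None and it < self.max_bisections and (hi - lo) > 1e-12:
            mid = (lo + hi) / 2.0
            try:
                m = self._fit(mid)
            except SolverError:
                lo = mid  # ill-conditioned side: move toward stronger penalties
                it += 1
                continue
            if m == target_m:
                best_alpha = mid
            elif m > target_m:
                lo = mid
            else:
                hi = mid
            it += 1
        if best_alpha is None:
            # support path jumped over the target: closest density <= target,
            # falling back to closest overall if nothing is below it
            below = [(target_m - m, a) for a, m in self._cache.items() if m <= target_m]
            if below:
                _, best_alpha = min(below)
            else:
                _, best_alpha = min((abs(m - target_m), a) for a, m in self._cache.items())
        weights = self._supports[best_alpha]
        return LayerNetwork(
            parcellation=self.parcellation,
            weights=weights,
            modality="MC",
            is_binary=True,
        )


def mc_via_sice(
    uptake_table: np.ndarray, parcellation: Parcellation, target_density: float, **kwargs
) -> LayerNetwork:
    """One-shot convenience wrapper around :class:`SICEDensityMatcher`."""
    return SICEDensityMatcher(uptake_table, parcellation, **kwargs).support_at_density(
        target_density
    )


def binarize_to_density(network: LayerNetwork, density: float) -> LayerNetwork:
    """Keep exactly ``round(density * C(N,2))`` strongest edges.

    Edges are ranked by signed weight (most positive kept); ties at the
    cutoff are broken deterministically by lexicographic edge index.
    """
    if not (0 < density < 1):
        raise ValidationError("density must lie in (0, 1)")
    n = network.n_nodes
    w = network.weights
    iu, ju = np.triu_indices(n, 1)
    vals = w[iu, ju]
    if np.ptp(vals) == 0:
        warnings.warn(
            "all edge weights equal; binarization resolved by edge index",
            stacklevel=2,
        )
    m = _triu_edge_count(n, density)
    # sort by descending weight, then ascending (i, j)
    order = np.lexsort((ju, iu, -vals))
    keep = order[:m]
    adj = np.zeros((n, n))
    adj[iu[keep], ju[keep]] = 1.0
    adj = adj + adj.T
    return LayerNetwork(
        parcellation=network.parcellation,
        weights=adj,
        modality=network.modality,
        is_binary=True,
    )


@dataclass(frozen=True)
class PopulationConnectome:
    """Weighted SC/FC population layers plus a density-matched MC estimator."""

    parcellation: Parcellation
    sc_weighted: LayerNetwork | None
    fc_weighted: LayerNetwork | None
    mc_matcher: SICEDensityMatcher | None
    subject_count: int

    def binary_layers(self, density: float) -> list[LayerNetwork]:
        """SC, FC, MC binarized/estimated at one common density."""
        if self.sc_weighted is None or self.fc_weighted is None or self.mc_matcher is None:
            raise ValidationError("all three modalities are required for the multiplex")
        return [
            binarize_to_density(self.sc_weighted, density),
            binarize_to_density(self.fc_weighted, density),
            self.mc_matcher.support_at_density(density),
        ]


def build_population_connectome(
    obs: SubjectObservations, **sice_kwargs
) -> PopulationConnectome:
    """Assemble population-level weighted layers from subject observations."""
    parc = obs.parcellation
    sc = fc = matcher = None
    if obs.streamline_counts is not None:
        sc = population_average(
            [sc_from_streamlines(c, parc) for c in obs.streamline_counts]
        )
    if obs.timeseries is not None:
        fc = population_average([fc_from_timeseries(t, parc) for t in obs.timeseries])
    if obs.uptake is not None:
        scaled = proportional_scaling(obs.uptake)
        matcher = SICEDensityMatcher(scaled, parc, **sice_kwargs)
    return PopulationConnectome(
        parcellation=parc,
        sc_weighted=sc,
        fc_weighted=fc,
        mc_matcher=matcher,
        subject_count=obs.n_subjects,
    )
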