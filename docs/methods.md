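# Methods

## Problem and model

`multiplexcore` identifies *core* nodes in a multiplex brain network whose
three layers encode structural (SC), functional (FC) and metabolic (MC)
connectivity over one shared parcellation of N cortical regions. The core
of a network is a group of nodes with high centrality on essentially every
centrality measure; here core membership requires a node to score high
*jointly* on a degree-type and an eigenvector-type measure.

### Layer construction

- **SC** — per subject, edge weight = streamline count between two regions
  divided by the sum of the two region volumes (streamline-density units),
  then averaged entrywise across subjects.
- **FC** — per subject, the Pearson correlation between the ROI-averaged
  BOLD time series of the two regions, then averaged across subjects.
- **MC** — population-level: each subject contributes one vector of
  proportionally scaled tracer uptake (regional uptake / total uptake), and
  the layer is the off-diagonal support of an L1-penalized maximum-likelihood
  estimate of the inverse covariance across subjects (sparse inverse
  covariance estimation, SICE; `sklearn.covariance.graphical_lasso`
  underneath). SICE estimates where conditional dependencies are nonzero,
  which is exactly what a binary layer needs; edge magnitudes are never used.

Because the three modalities produce incomparable weight scales, every
layer is binarized to a common connectivity density γ: the
`round(γ·N(N−1)/2)` strongest edges are kept. FC edges are ranked by signed
correlation (most positive kept), the dominant resting-state convention,
which also keeps the supra-adjacency nonnegative so Perron–Frobenius
reasoning applies. Ties at the cutoff are broken by lexicographic edge
index for bit-reproducibility. For MC the density is matched by bisecting
the L1 penalty until the support has exactly the target edge count (early
exit on an exact hit); when the support path jumps past the target the
closest density not exceeding it is used, and the achieved density is
recorded on the layer. Penalty/support fits are cached per dataset, so a
41-point density sweep reuses previously probed penalties. With fewer
subjects than nodes the near-zero-penalty end of the path is
ill-conditioned; the bisection raises its dense-end bracket until the
solver succeeds rather than failing the run.

### Multiplex coupling

The L=3 binary layers are coupled *categorically*: each node is linked to
its replicas in all other layers with a uniform weight w, giving the
(L·N)×(L·N) supra-adjacency with layer adjacencies on the diagonal blocks
and w·I_N elsewhere. Ordinal coupling (adjacent layers only) is not
exposed — with three heterogeneous modalities there is no meaningful layer
ordering to prioritize. The coupling weight balances inter- against
intra-layer connectivity:

    w = 3 γ C(N,2) / (6N) = γ (N − 1) / 4,

so at γ = 0.20 and N = 100, w = 4.95 (≈5). w is kept real-valued, never
rounded.

### Centralities

- **DC / ODC** — monoplex degree k_i; multiplex overlapping degree
  o_i = Σ_α k_iα.
- **EC / ETC** — the leading eigenvector of the adjacency (monoplex) or of
  the supra-adjacency (multiplex). The supra eigenvector Θ_iα carries one
  component per node per layer; per-node eigentensor centrality is the
  equal-weight layer sum θ_i = Σ_α Θ_iα (a maximum-entropy aggregation:
  all layers equally important), renormalized to unit Euclidean length.

Both are computed by power iteration from the uniform start vector (all
nodes initially equally central), renormalizing to unit length each step
and stopping when the largest componentwise change of the normalized
vector falls below the tolerance (default 1e-5). Numerical notes:

- Iteration runs on the *shifted* matrix A + I. The shift leaves
  eigenvectors untouched but makes the Perron root strictly dominant, so
  bipartite-like spectra (±λ₁ of equal magnitude — e.g. a star graph)
  cannot trap the iteration in a two-cycle. The reported eigenvalue is the
  Rayleigh quotient on the unshifted matrix.
- The default iteration budget is 10,000 — generous for N ≤ 300 matrices;
  exhausting it signals a (near-)degenerate spectrum and raises an error
  carrying the last residual.
- Disconnected graphs are not an error: the iteration converges to the
  dominant component's eigenvector, nodes outside it get ≈0 centrality,
  and a warning logs the component sizes. At the densities analyzed
  (γ ≥ 0.10, with inter-layer coupling) the supra graph is essentially
  always connected.

### Core selection and the coreness coefficient

At one configuration (γ, δ) the core is

    { i : c1_i > μ₁ + δσ₁  and  c2_i > μ₂ + δσ₂ },

with (c1, c2) = (DC, EC) for a monoplex and (ODC, ETC) for the multiplex;
μ and σ are taken over all N nodes per measure. σ is the population
(divide-by-N) form; the threshold inequality is strict, so a zero-variance
measure yields an empty core rather than an error. Because both γ and δ
are arbitrary modeling choices, the analysis sweeps γ = 0.10…0.50 (step
0.01, 41 values) and δ = 0.4…1.6 (step 0.2, 7 values) and defines the
**coreness coefficient** C_i as the fraction of the 287 configurations in
which node i is in the core. The reported core is the top 15% of nodes by
C_i (`round(0.15·N)` nodes; boundary ties broken toward the lower node id,
a deterministic policy — no tie policy is canonical here).

Core overlap between two analyses is the asymmetric similarity
S_c = |core_ref ∩ core_other| / |core_ref| ∈ [0, 1] (the closed interval:
identical and disjoint cores attain the endpoints). Group contrasts also
report, per node, whether one group's density-averaged θ exceeds the
other's, and among those nodes the fraction whose relative difference —
denominated in the lower group's value — reaches 30%.

## Synthetic data generator

The generator plants one hub set (default 15 of 100 nodes) shared by all
three layers; each layer draws an independent Bernoulli graph with block
probabilities (p_hh, p_hp, p_pp) = (0.8, 0.35, 0.08) — hubs dense among
themselves and toward the periphery — giving expected degrees ≈41 (hubs)
vs ≈12 (periphery). Observations (defaults: 30 subjects, T = 200):

- **Time series** — stationary AR(1) Gaussian with autocorrelation 0.3
  (so FC estimation faces a realistic effective-sample-size reduction) and
  stationary covariance Σ = I + c·G_FC, with c = 0.9/λ_max(G_FC), the
  largest coupling that keeps Σ comfortably positive definite; white
  observation noise of sd 0.05 is added.
- **Uptake** — Gaussian with precision P = I + ρ(D − G_MC), ρ = 0.4: an
  attractive Gaussian graphical model, diagonally dominant hence always
  positive definite, with off-diagonal support exactly the planted graph.
  ρ = 0.4 makes chain-graph partial correlations ≈0.22–0.25, strong enough
  for SICE to recover a planted chain support reliably at 500 subjects.
  Samples are exponentiated on a mild log-scale (0.25) and scaled, keeping
  uptake strictly positive while approximately preserving correlations.
- **Streamline counts** — Poisson with mean
  base_rate · strength_ij · (vol_i + vol_j) (strength 1 on planted edges,
  0.02 off them; volumes uniform in [500, 1500] mm³), so the volume
  normalization in SC construction approximately inverts the volume factor.

All draws flow from a single root seed through named `SeedSequence` child
streams: the same seed reproduces every array bit-for-bit.

The "old group" variant attenuates FC/MC hub probabilities to
(0.6, 0.30) while leaving SC untouched, emulating structural cores that
are stable with age while functional/metabolic cores shift.

**What the generator does not emulate**: hemodynamic/metabolic signal
physics, motion and scanner artifacts, spatial autocorrelation between
neighboring parcels, subject-level covariates, and partial-volume effects.
Passing recovery tests therefore demonstrates that the pipeline's
statistics behave correctly on data with the assumed generative structure,
not that real PET-MR data satisfies those assumptions.

A known property of the uptake design: diagonal dominance scales a node's
precision diagonal with its degree, so planted *hub* edges carry weaker
partial correlations than periphery edges. MC support estimated at small
sample sizes consequently carries only a weak hub signal on its own — the
metabolic layer contributes to the multiplex core mainly through the
coupling with SC and FC, and MC-only core recovery is not a reliable
property at small N. This mirrors the practical situation in which the
population-level metabolic layer is the noisiest of the three.

## Problem sizes used in the shipped checks

The scientific checks run the full default study conditions — N = 100
nodes, 15 hubs, 30 subjects, the 41×7 configuration grid — with planted-hub
recovery averaged over 20 generator seeds; the eigensolver oracle check
uses 50 random connected instances with N ≤ 100 and L = 3; SICE support
recovery uses a 10-node chain with 500 subjects. Unit tests use smaller
instances (N ≤ 30) of the same constructions.

## Design choices where the design was open

- **SC volume normalization** divides by the *sum* of the two region
  volumes (alternatives: product, mean). The sum yields streamline-density
  units and is a common connectomics convention.
- **FC binarization** ranks signed correlations; negative edges are simply
  out-ranked rather than excluded or absolute-valued.
- **Eigenvector normalization** is unit Euclidean length with the
  nonnegative sign convention; every downstream quantity (rankings,
  z-thresholds, ratios) is invariant to this choice.
- **Convergence criterion** is the max componentwise change of the
  normalized vector, not eigenvalue change; with the shift this bounds the
  useful quantity (the vector) directly.
- **Relative difference** in group ETC comparisons uses the lower group's
  value as denominator.
- **MC per density** is re-estimated at every grid density through the
  shared penalty cache rather than fit once, keeping all three layers at
  exactly matched density per configuration.

## Limitations

- The coreness coefficient inherits the arbitrariness of its grids; the
  defaults cover the standard sparse-to-moderate density range and a broad
  δ band, but C_i values are only comparable between runs using the same
  grids.
- SICE assumes approximately Gaussian uptake after proportional scaling;
  heavy-tailed deviations would distort the estimated support.
- With very few subjects the dense end of the SICE path is unattainable
  (ill-conditioned), and the densest requested layers may fall back to the
  closest attainable density below the target.
- Degenerate spectra (exactly tied leading eigenvalues, e.g. perfectly
  symmetric graphs) make the leading eigenvector non-unique; the power
  iteration then converges to a start-vector-dependent representative.
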