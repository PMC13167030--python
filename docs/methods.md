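# Methods notes

## Model and assumptions

A shape is modeled as a metric measure space: a finite point cloud
S = {x_i} ⊂ R^D (D ∈ {2,3}) with the uniform probability measure and an
intrinsic distance d_S. Two default distance choices are supported:
ambient Euclidean distance (appropriate when shapes are star-like or
convex enough that chords do not cut through meaningful geometry) and
geodesic distance on a union-symmetrized k-nearest-neighbor graph
(appropriate for strongly non-convex surfaces; requires the graph to be
connected, and disconnection raises an error naming the component count
rather than silently producing infinite distances).

The stratified embedding assumes the ranking functional is informative:
points at geometrically distinct positions should receive distinct
scores. The default functional — the mean of the local distance
distribution — satisfies this for generic shapes but collapses on
strongly symmetric ones (see Limitations).

## Pipeline definitions and numerical choices

- **Local profiles.** Row i of the distance matrix, diagonal removed,
  sorted: length N−1. The global profile is the sorted strict upper
  triangle; each unordered pair counted once (the empirical quantile
  function is unchanged by the ordered/unordered convention because
  every distance has equal multiplicity either way).
- **Quantiles.** Linear interpolation between order statistics at
  fractional position (m−1)·q — the numpy default convention. The
  internal evaluator exploits that profile rows are pre-sorted; it
  agrees with `np.quantile` to 1 ulp (unit-tested) and snaps positions
  within 1e−12 of an integer so exact order-statistic levels reproduce
  entries bit for bit.
- **Ranks.** Mid-ranks with ties averaged, normalized as
  U = (rank − 0.5)/N. Values fall strictly inside (0,1), are invariant
  to point relabeling, and make bin assignment U ∈ ((b−1)/B, b/B]
  well-defined at both ends.
- **Quantile grid.** Midpoint levels q_j = (j−0.5)/Q, the midpoint rule
  for the q-integral; endpoint-inclusive grids would double-weight the
  extremes of the local distributions.
- **Empty bins.** When N < B (e.g. 26-point contours with the default
  B = 100) empty bin rows are filled by columnwise linear interpolation
  of nonempty rows against bin-center positions, with constant
  extrapolation at the ends. This keeps Φ̂ a discretization of a
  function on [0,1]² and keeps rows nondecreasing.
- **Distance.** D_p = ((1/(BQ)) Σ |ΔΦ̂|^p)^{1/p}. The 1/(BQ) weight
  makes values stable under grid refinement and makes D_p a true
  discretized L^p([0,1]²) norm, hence symmetric and triangle-inequality
  compliant by construction.
- **Scale normalization.** Optional division of the distance matrix by
  the median of its upper triangle (even counts: mean of the two central
  order statistics, which makes the operation idempotent). Degenerate
  all-zero matrices raise an error. The convention mirrors common
  practice for 2D contour data; for 3D mitotic-cell-style data size is
  biologically meaningful and normalization should stay off — the CLI's
  `normalize=auto` encodes exactly that (on for 2D, off for 3D).
- **p-values.** Add-one smoothing (1 + #{null ≥ obs})/(1 + P), ties
  counted as exceedances: valid finite-sample p-values, conservative on
  ties, with floor 1/(P+1).
- **SLB.** The N×N cost matrix of pairwise W_p^p between local profiles
  (equal lengths, so the elementwise sorted-vector formula is exact) is
  solved by exact linear assignment: with uniform equal-size marginals
  an optimal transport vertex is a permutation, so no entropic
  approximation is needed at desk scale. Unequal sizes are rejected;
  callers downsample to a common N first.
- **Unequal-length 1D Wasserstein.** Both empirical quantile functions
  are piecewise constant with breakpoints at i/m; |F₁⁻¹ − F₂⁻¹|^p is
  integrated exactly on the merged breakpoint grid.

## Parameters

| parameter | default | units | rationale |
|---|---|---|---|
| B (bins) | 100 | – | standard analysis setting; empty bins interpolated when N < B |
| Q (quantiles/bin) | 100 | – | standard analysis setting |
| p | 2 | – | Hilbertian distance → PSD Gaussian/Laplace kernels |
| metric | euclidean | – | robust default for cell contours/surfaces |
| k (geodesic) | 10 | neighbors | connectivity/locality compromise; flagged config choice, no principled default exists |
| kernel | laplace | – | heavier tails than Gaussian at equal bandwidth |
| γ | median heuristic | 1/distance (laplace), 1/distance² (gaussian) | scale-free default |
| permutations | 1000 | – | resolves p ≥ 1/1001 |
| downsampling | 200 points/shape (3D pipelines) | points | matches the surface-point preprocessing convention; 100 for GW-class baselines |

The periodic (von Mises type) covariate kernel is
exp(2γ(cos Δθ − 1)) — the Gaussian kernel on the chordal distance of the
circle embedding [cos θ, sin θ] — with γ set by the median of squared
chordal distances. Whether the factor 2 is absorbed into γ differs
between the periodic-Gaussian and von Mises writings of the same kernel;
this package fixes the periodic-Gaussian form with γ from squared
chordal distances, and results are insensitive to the convention up to a
bandwidth rescaling.

The `moments(k)` ranking functional orders points lexicographically by
their first k raw moments, then reports scores as lexicographic
mid-rank positions mapped through the empirical quantile function of the
first moment — a monotone rescaling that makes k = 1 reproduce the mean
ordering exactly while higher k breaks ties the mean cannot.

## Synthetic data: what it emulates and what it does not

The generator produces closed 2D contours (circle, ellipse, random
polygon with sorted uniform angles and radii in [0.5, 1], bilaterally
symmetric T outline) and 3D surfaces (area-uniform ellipsoid via
rejection sampling; dumbbell sampled from two spherical lobes and a
cylindrical neck proportionally to component areas). Sampling is uniform
by arc length (curves) or area (surfaces); isotropic Gaussian jitter
(default sd 0.02 on unit-scale shapes, i.e. 2% measurement noise) is
added afterwards so shape signal and noise remain separable; rigid
nuisance (Haar rotation, reflection with probability 1/2, translation)
can be layered per shape. All draws are seed-deterministic.

What it does **not** emulate: segmentation artifacts, correlated
boundary noise, intensity information, topological defects, or the
size/eccentricity covariation of real cell lines. Passing tests
therefore demonstrate correctness and statistical behavior of the
*method* under clean, controlled conditions — not performance on any
particular microscopy dataset.

The dumbbell's neck sampling ignores the sphere–cylinder intersection
(points may fall just inside a lobe); this is an idealized generator,
not a watertight surface sampler, and is irrelevant for its role as a
"two-lobed vs one-lobed" population contrast.

## Validation experiment sizes

The simulation studies use desk-scale settings chosen to estimate rates
stably: calibration uses 20 shapes per group × 64 points per shape ×
200 permutations × 200 trials; power uses the circle-vs-0.6-ellipse
contrast with 30 shapes per group (MMD) and covariate strength 0.6 with
60 pairs (HSIC), 100 trials each; consistency uses the noise-free unit
circle at N ∈ {50, 100, 200, 400} with 20 replicates and B = Q = 20;
runtime scaling times the default B = Q = 100 pipeline at
N ∈ {100, 200, 400, 800}. Rates and curves are recomputed, not stored:
`scripts/acceptance.py` reruns everything from a seed.

## Limitations

- On shapes with exact or near symmetries (the T-shape generator is the
  canonical case) the mean-rank functional assigns equal scores to
  geometrically distinct points, strata mix them, and stratified
  distances between such shapes are systematically overestimated. The
  `moments(k)` lexicographic ranking mitigates but does not resolve
  this; selecting a small data-adaptive k is open.
- B and Q have no data-driven selection rule; defaults follow common
  practice and the embedding is stable under refinement, but
  finite-sample bias/variance trade-offs are not quantified.
- The median-heuristic bandwidth is a convention, not an optimum; under
  low signal-to-noise a power-targeted bandwidth choice could do better.
- Full Gromov–Wasserstein is out of scope (exact GW is believed
  NP-hard); the SLB and global Wasserstein baselines bound it from
  below.
- The runtime slope reported by the scaling experiment reflects the
  mixed O(N² log N + N·Q) cost: at N ≲ Q the linear quantile-evaluation
  term flattens the curve, so measured slopes sit slightly below 2 on
  the 100–800 point range.
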