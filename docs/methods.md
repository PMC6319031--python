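# Methods

This note documents the models, parameters and numerical choices behind the
package, the design decisions taken where several constructions were
defensible, and what the synthetic experiments do and do not demonstrate.

## Curvilinear filterbank

**Impulse.**  The generating impulse is a trivariate Gaussian on warped
coordinates

    Γ(x, σ, c) ∝ Π_d (2π σ_d²)^{-1/2} exp(-X_d² / 2σ_d²),
    X₁ = x₁,  X₂ = x₂ + c₀x₁ + c₁x₁²,  X₃ = x₃ + c₂x₁³,

so σ sets the cross-section and elongation while c bends (c₁), shears (c₀)
and tilts (c₂) the support.  Value, gradient and Hessian are evaluated
analytically via the warp Jacobian; no finite differencing enters the
kernel construction.

**Scalar kernel.**  The filtering kernel is the second gauge derivative
`K = ω^t H(Γ) ω` with `ω = ∇Γ/|∇Γ|`, computed through the eigen-
factorization `H = QΛQ^t` with modulation coefficients
`γ_l = (∇Γ·q_l)²/|∇Γ|²`.  Where the gradient vanishes (relative norm below
1e-12, e.g. the kernel center) each `γ_l` takes its 1/3 limit, so `K`
degenerates to the mean principal curvature.  Eigenvalues are ordered by
ascending magnitude and eigenvector signs are fixed (largest-magnitude
component positive) so every decomposition is deterministic.  The truncated
discrete kernel retains a small DC residue (~2% of the peak on the default
11³ support); it is subtracted so the bank has exactly zero response to
constant images — without this, flat regions leak into the vesselness map.

**Tensor patch.**  From the convexity of `-log Γ`, per-voxel tensors
`T = Q Ψ Q^t` use the canonical semiaxes `ψ₁ = λ̃₁/√(λ̃₂λ̃₃)`,
`ψ₂ = λ̃₂/λ̃₃`, `ψ₃ = 1`, normalized to unit determinant and stored as the
six components of the matrix logarithm.  Warping can break convexity near
the support boundary; eigenvalues are floored at 1e-2 of the local maximum
magnitude (keeping the tensors SPD with bounded anisotropy) before the ψ
mapping.  Unit determinant is equivalent to a trace-free logarithm, which
survives every linear operation applied later (blending, interpolation).

**Steering.**  A kernel is steered by re-evaluating the analytic fields on
the back-rotated support grid; the cumulative rotation is tracked on the
kernel, tensors are conjugated (`R T R^t`), and the intrinsic orientation
basis — the impulse-weighted integral of the eigenbases, projected to the
nearest rotation by polar decomposition — maps exactly onto the target.
Interpolation-based resampling was tried first and rejected: the default
cross-section (σ = 0.7 voxel) is too sharp, and even cubic resampling lost
14% of the kernel in a rotate/rotate-back round trip, violating the
intended steering invariants.  Analytic steering is exact under
composition.

**Dictionary.**  The default bank holds 7 curvilinear kernels — straight
(c = 0), two bends (c₁ = ±0.1), two shears (c₀ = ±0.3), two tilts
(c₂ = ±0.02) — all at σ = (2.0, 0.7, 0.7) voxels on an 11³ support
(±2.5σ of the elongation), plus a tubular kernel for the saliency scan and
the degenerate pair.  The pseudo-impulsive kernel is the analytic Laplacian
of Gaussian at σ = 0.8 voxel (sharp-transition detector).  The flat kernel
is the σ→∞ limit on the fixed support — a near-uniform positive kernel
normalized to unit sum, i.e. a wide local average that responds to
homogeneous regions.  A signed LoG at large σ was tried and rejected: on a
truncated support it is all-negative, and applied to the image negative it
peaks at the vessels instead of the background, inverting the gate's role.
Note that no *linear* kernel can respond more strongly to a homogeneous
block than to noise of the same mean — equal means give equal expected
responses — so the background detector is validated against zero-mean
fluctuation instead.

## Per-scale synthesis

The image is downsampled (Gaussian prefilter at σ = 0.5/scale voxels,
pixel-area-aligned resampling, affine updated to preserve world
coordinates) at dyadic scales 1, 1/2, 1/4 by default, keeping the kernel
support fixed.  A tubular saliency map sums positive-part responses of the
tubular kernel steered over an icosphere at subdivision level 2 (162
vertices, 81 after antipodal deduplication — a second-derivative kernel
responds identically along ±d).  Seeds are voxels that are simultaneously
Laplacian sinks, local ridge maxima (all Hessian eigenvalues negative,
Gaussian-derivative Hessian at σ = 1 voxel) and above the 75th percentile
of the strictly positive saliency pool.  Their principal Hessian
directions, snapped to the nearest icosphere direction (quantization error
below the icosphere's own spacing), form the steering set Θ; snapping keeps
Θ compact (≤ 81) and lets steered kernels be cached across scales and
volumes.

The scalar map CVM_s sums positive-part responses of every dictionary
kernel steered along every Θ orientation (dense FFT convolution with a
cached image transform).  The tensor field blends, per voxel, the steered
patches of the up-to-three strongest-responding (kernel, orientation)
pairs, scattered over the 11³ patch neighbourhood with weight
(response × steered impulse × Hann window) and normalized by the
accumulated weight; blending more than one orientation matters at
bifurcations, where single-winner blending leaves the tensors anisotropic
along one branch and the geodesic stage then pays an artificial penalty to
turn the corner.  Voxels with no blend support receive the isotropic
identity; all tensors are re-centred to a trace-free logarithm (unit
determinant).  The boundary map (edge kernel on the image negative
`max(V) - V`) and background map (flat kernel on the same) are kept raw at
this stage.

## Multi-scale integration

Scales are accumulated coarse-to-fine with the upsample-and-max recursion:
`ĈVM_s = ĈVM_{s-1}↑ + max(α_s CVM_s·ε_s, ĈVM_{s-1}↑)`, with the final map
the sum of the per-scale accumulators and α_s = 1.  The gate
`ε_s = max(0, BDM_s · (1 - BGM_s))` is normalized before use: the
background map by a robust 2–95 percentile contrast stretch (the wide
average differs between thin vessels and surrounding tissue by only a few
percent, so a max normalization leaves it without dynamic range and a
noise-inflated maximum crushes it entirely), and the gate itself by its
95th positive percentile, clipped to [0, 1].  The gate therefore acts as a
soft background mask rather than a second multiplication of the vessel
contrast — with the literal raw products, faint but resolved vessels
inherit a squared dynamic range and drop below the background noise floor.
Tensors integrate as the accumulator-weighted Log-Euclidean average,
re-normalized to unit determinant; scaling the scalar map by a constant
leaves the tensor field unchanged.

## Geodesic connectivity

**Front propagation.**  Arrival energies solve the anisotropic Eikonal
problem with local cost `sqrt(d^t TF d) / speed`.  The solver is an
ordered-upwind scheme on the 26-neighbourhood: each update minimizes the
linearly interpolated arrival over the triangulated cube surface around the
voxel, using the closed-form minimizer along every surface edge (pairs of
neighbours sharing a cube face).  Accepted voxels that a later update
improves beyond 1e-9 are re-opened, which keeps the scheme convergent under
strong anisotropy.  On a 41³ grid with identity metric and unit speed the
arrival times match the Euclidean distance within 5.7% (the plain
26-neighbour Dijkstra bound is ≈10%).  Fronts are truncated by a radius
(30 mm default; unbounded for user-seeded endpoint mode), restricted to a
domain mask (vesselness above 1e-3 of maximum, dilated by 2 voxels) and by
an adaptive energy cap (a small multiple of the cost of crossing the whole
domain at the typical vessel speed); two-point updates are skipped in the
slow noise floor where first-order accuracy is irrelevant.

**Front speed.**  The propagation speed is the gamma-compressed normalized
vesselness, `speed = (CVM/max CVM)^0.7` (plus a 1e-6 relative floor).  The
compression is deliberate: the edge weight `F = ∫ F_AB dπ` with
`F_AB = (U_A+U_B) + |U_A-U_B|` makes path stretches through *fast* regions
nearly free, so under raw speeds — whose spread between thick and thin
vessels spans orders of magnitude — branch attachments drift toward thick
vessels and junctions displace by several millimetres.  γ = 0.7 narrows
the in-vessel speed spread enough for the length term to stay decisive
while preserving the cross-sectional profile that keeps geodesics on the
mid-line (stronger compression, or a saturating speed, measurably degrades
centerline accuracy).

**Pairwise connection.**  Every source pair whose truncated maps overlap is
screened by the meeting-point value of F_AB (vectorized over the masked
domain); the best ten candidates per node are back-traced, plus a spanning
structure of the screening graph so no component can end up bridged only by
one long redundant connection.  Back-tracing descends each source's *own*
arrival map from the meeting point down to that source (in the continuum
this is the same curve as descending F_AB, but the arrival map decreases
monotonically to zero at the source, so the discrete trace cannot stall),
with fixed 0.5-voxel steps, trilinear gradients and a discrete
steepest-descent fallback.  Traced polylines are resampled at 0.75 mm and
lightly smoothed before the Euclidean length and the integral of F_AB along
the path are computed.

**Adaptive refinement.**  The node set densifies by iterating: extract the
MST of the current graph; insert a source at the geodesic midpoint of every
MST edge whose midpoint lies at least μ = 3 mm from both endpoints; when
the midpoint duplicates an existing node, insert instead at the path point
farthest from all nodes (if any stretch is still uncovered beyond 2 mm);
additionally insert at points where an MST path separates from the corridor
of the other MST paths (with at least 2 mm of shared corridor) — the
geometric bifurcation lies at that separation point, not necessarily at a
graph node, and placing a source there lets the next sweep relocate the
junction onto it.  The loop runs the connectivity paradigm for the new
sources and stops when no insertion occurs (cap: 10 sweeps).

## Tree extraction

Kruskal's algorithm with the deterministic tie order (F, smaller id, larger
id) extracts the MST (per connected component).  Terminal branches shorter
than the leaf threshold (5 mm in the automatic mode; disabled in the seeded
mode, whose sources are known endpoints) are removed iteratively; an
optional geodesic threshold on F splits over-costly edges.  The root
defaults to the node with maximal vesselness; breadth-first traversal
assigns parents and depths.  ROI masks assign nodes by argmax membership
(ties to the lowest mask index; nodes in no mask are excluded as
background) and per-ROI MSTs form the forest.

## Synthetic data

The generator emulates space-filling vascular phantoms: recursive random
bifurcation (terminal count split near-evenly with random jitter, branching
angles 30–55°), 1 mm stepped trajectories with Gaussian heading noise
(0.06/mm), per-generation decaying branch length (22 mm × 0.85^g, minimum
7 mm) and radius (2 mm × 0.8^g, floor 0.8 mm), rasterized by per-radius
distance transforms, smoothed by a 0.5-voxel Gaussian (partial volume) and
degraded by additive Gaussian noise at three levels — 0.05, 0.15, 0.30 of
the unit foreground intensity.  Branch growth is self-avoiding: walkers are
repelled within 4 mm of previously grown centerlines (ignoring the shared
bifurcation neighbourhood) and the whole geometry is regrown from derived
random substreams when the achieved separation falls short, keeping
non-adjacent branches apart as in perfusion-driven phantoms.  All
randomness derives from one integer seed; identical seeds reproduce volumes
byte for byte.

What the generator does *not* emulate: intensity inhomogeneity and modality
-specific artifacts, vessel caliber variation along a branch, stenoses or
aneurysms, anastomoses (the trees are strictly acyclic), and truly kissing
vessels.  Passing the synthetic study therefore demonstrates the method's
behaviour under noise and branching complexity, not robustness to every
clinical artifact.

## Evaluation metrics

Centerlines are resampled at 0.5 mm; ε_S is the mean of bidirectional
nearest-neighbour distances and ε_H the mean of the two directed 95th
percentiles.  Branchpoint detection greedily matches true branchpoints to
reconstructed degree-≥3 nodes one-to-one by ascending distance within a
5 mm neighbourhood.  The tree edit distance is the Zhang–Shasha
ordered-tree algorithm with unit insert/delete costs and free relabeling
(nodes are unlabeled); child order is canonicalized by (subtree size,
branch azimuth) so isomorphic trees have distance zero, and the overlap
index is reported on the unit scale (1 = isomorphic).  The DIADEM-style
score weights true branchpoints by the number of terminals below them
(terminals weigh 1) and counts a node as matched when a reconstructed node
lies within the 5 mm tolerance *and* descends from the node matched to its
nearest matched critical ancestor; this is a simplified variant of the
original challenge metric (full path-length checks are reduced to
ancestor-connectivity), so scores are comparable within this implementation
only.

## Problem sizes and measured behaviour

The synthetic study runs at 64³ voxels (1 mm isotropic) with 10–20 terminal
branches per tree, five trees per noise level, in the endpoint-seeded mode;
one volume takes ~30–60 s on one CPU.  On clean volumes the reconstruction
recovers bifurcations to ~1–3 mm and centerlines to ~0.4–0.8 mm mean
symmetric error.  Across the noise levels the branchpoint detection rate
within 5 mm typically lands between 65% and 85% depending on the drawn
geometries (see `scripts/acceptance.py` for the exact cohort); the dominant
failure mode is not noise per se but tight branch geometry: when two non-adjacent branches approach to
about 4 mm, the smooth filterbank bridges the gap and the minimum spanning
tree can take the geodesic short-cut, detouring around a faint branch and
displacing its junction.  This is the kissing-vessel limitation inherent to
minimal-path reconstruction over a smoothed vesselness potential; the
over-connected graph retains the redundant true connections, but the MST
selection alone cannot disambiguate them without anatomical priors.

## Known limitations

- Kissing vessels produce geodesic short-cuts (above); anatomical or
  population priors would be needed to resolve them.
- Cyclic topologies (anastomoses) are outside the model: the output is a
  tree or forest by construction.
- The DIADEM-style score is a simplified variant; absolute values should
  not be compared against other implementations.
- The Eikonal solver is first-order; arrival errors up to ~6% of the
  distance translate into sub-voxel but non-zero geodesic jitter.
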