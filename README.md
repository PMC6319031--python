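# vesseltrees

Inference of vascular topology from 3D angiographic volumes.

Given a scalar angiography `V : R^3 -> R`, the package reconstructs the
*vectorial* topology of the vasculature — a geodesic minimum spanning tree
whose nodes sit on vessel mid-lines and whose edges are sub-voxel centerline
polylines — rather than a raster segmentation.  It is aimed at researchers
working on cerebrovascular image analysis who need connected, hierarchical
tree representations (junction locations, branching patterns, centerline
geometry) from noisy, fragmented vessel images.

## Method

The reconstruction has three stages:

1. **Steerable curvilinear filtering.**  A compact dictionary of Steerable
   Laplacian-of-Gaussian Swirls (SLoGS) — curvilinear trivariate Gaussians
   `Γ(x, σ, c)` differentiated twice along their gauge direction
   `K = ω^t H(Γ) ω`, with `ω = ∇Γ/|∇Γ|` — is steered along data-driven
   orientations and convolved with a multi-resolution pyramid of the image.
   Positive-part responses accumulate into a smoothly **connected vesselness
   map** (CVM), and each kernel's companion unit-determinant tensor patch
   (from the eigendecomposition of `H(-log Γ)`) is blended in the
   Log-Euclidean domain into an anisotropic **tensor field** (TF).  Two
   degenerate kernels gate the accumulation: a pseudo-impulsive edge
   detector (boundary map) and a flat background detector.

2. **Anisotropic geodesic connectivity.**  CVM and TF form a Riemannian
   potential: a front propagating from a source point `p` crosses voxel `x`
   along direction `d` at cost `sqrt(d^t TF(x) d) / speed(CVM(x))`.  Arrival
   maps `U_p` are computed by anisotropic fast marching; every pair of
   sources is joined through the minimizer of
   `F_AB = (U_A + U_B) + |U_A - U_B|`, back-traced into a geodesic path with
   Euclidean length `L` and integral geodesic length `F`.  Midpoint
   insertion on the running minimum spanning tree densifies the node set to
   a target spacing `μ`, yielding an over-connected geodesic graph `Π`.

3. **Tree extraction.**  The vascular tree `ζ` is the minimum spanning tree
   of `Π` under `F`; short terminal branches are pruned by `L`, a root is
   chosen (maximal vesselness by default) and the univocal parent-child
   hierarchy follows.  ROI masks split `Π` into a forest of per-territory
   trees.

The package also ships a synthetic vascular-tree generator (random
self-avoiding bifurcating trees rasterized into noisy volumes with exact
centerline/branchpoint ground truth) and a topology-aware evaluation suite:
symmetric centerline errors (ε_S, ε_H), branchpoint detection within a
spatial neighbourhood, the normalized tree-edit-distance overlap
`TED_ov = 1 - TED(ζ1, ζ2) / (TED(ζ1, ∅) + TED(ζ2, ∅))`, and a
spatially-aware DIADEM-style score.

## Worked example

```python
import numpy as np
from vesseltrees import (PipelineConfig, SyntheticTreeSpec, generate_tree,
                         run_pipeline, branchpoint_detection, centerline_errors)

spec = SyntheticTreeSpec(terminal_branches=12, volume_shape=(64, 64, 64),
                         noise_sigma=0.05, rng_seed=1)
truth, volume = generate_tree(spec)

# endpoint-seeded reconstruction (the terminal points are given as sources)
result = run_pipeline(volume, PipelineConfig(), seeds_mm=truth.endpoints)

rate, bp_eps_s, bp_eps_h = branchpoint_detection(result.tree, truth, 5.0)
eps_s, eps_h = centerline_errors(result.tree, truth)
print(f"branchpoints detected within 5 mm: {rate:.2f}")
print(f"centerline error eps_S = {eps_s:.2f} mm, eps_H = {eps_h:.2f} mm")
```

Output from the run above:

```
branchpoints detected within 5 mm: 1.00
centerline error eps_S = 0.47 mm, eps_H = 1.12 mm
```

All 11 bifurcations of this phantom are recovered within the 5 mm
neighbourhood and the reconstructed centerlines deviate from the true ones
by less than half the 1 mm voxel size on average.

A command-line interface mirrors the library:

```sh
vesseltrees simulate out/ --terminal-branches 12 --shape 64 --noise 0.05 --seed 1
vesseltrees run out/volume.nii.gz out/recon --seed 1
vesseltrees evaluate out/recon/tree.swc out/truth.swc
```

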