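# gpmrecon — freehand 3D ultrasound reconstruction by global patch matching

Freehand 3D ultrasound sweeps a tracked 2D probe by hand: every B-scan frame
carries a measured position and orientation, and the frames must be
compounded into a regular voxel volume. Because the hand motion is
irregular, large parts of the volume receive no data at all. `gpmrecon`
implements a two-stage reconstruction of that volume — for engineers and
researchers working on ultrasound compounding, and as a benchmarkable
reference for exemplar-based 3D hole filling.

**Stage 1 — robust bin-filling.** Each slice pixel `u_i` gets a *best
contribution distance* from a robust local response

    H_k(u_i) = α·MAD(u_i) + β·IQRAD(u_i),     k = 1..8,

where MAD is the absolute deviation of the center from the (lower) median
neighbor intensity, IQRAD the magnitude of the mean deviation over neighbors
inside the closed 25–75 % intensity band, and

    α = (3/4)(N+1)/(N+n+1),   β = 1 − α

with `N` the neighbor count and `n` the band count of the nested Chebyshev
disc of radius `k`. The minimizing class defines `d(u_i)`, the largest pixel
distance in that disc (mm). The pixel then contributes to every voxel center
`x` inside the ball of radius `d(u_i)` around its world position:

    V(x) = Σ_i I(u_i)/d(u_i, x)  /  Σ_i 1/d(u_i, x),

a convex, inverse-distance-weighted combination (the non-normalized variant
with denominator `Σ d` is available behind `eq11_literal`). Pixels landing
within half a voxel spacing of a center are direct hits and take precedence.

**Stage 2 — exemplar-based hole filling.** Remaining vacant regions are
filled greedily from their boundary (the *fill front*). Each front voxel `p`
carries the priority

    P(p) = C(p) · D(p) · G(p)

(confidence = summed confidence of known patch voxels over the patch size;
data = isophote strength in the front's tangent plane, `‖∇I × n_p‖/255`;
gradient = mean gradient magnitude over the known patch voxels). The
highest-priority 9×9×9 patch is compared on its known support against every
fully-known candidate patch in the volume by sum of absolute differences;
the vacant voxels are copied from the winner. Classical VNN
(nearest-neighbor), PNN (dilation-mean) and DW (distance-weighted) fillers
are included as baselines, scored by the mean absolute intensity difference
to ground truth over the carved region.

A synthetic module generates everything needed to exercise the pipeline:
textured phantoms, jittered linear/fan sweeps with pose sidecars, carved
vacancies (cube/cuboid/sphere/ellipsoid/tetrahedron), contiguous-frame
removal, and multiplicative speckle.

## Worked example

```python
import numpy as np
from gpmrecon import (default_phantom, simulate_sweep, RunConfig,
                      reconstruct, mean_abs_error)

truth = np.round(default_phantom((32, 32, 32), seed=7))
stack = simulate_sweep(truth, 8, jitter=(0.3, 0.3), seed=7)   # sparse sweep
cfg = RunConfig(grid_dims=(32, 32, 32), grid_spacing=1.0, search_window=12)
grid, log = reconstruct(cfg, slices=stack)
print("known after binning:", log["voxels_known_after_binning"])
print("hole-filled voxels :", log["voxels_hole_filled"])
print("fill iterations    :", log["hole_fill_iterations"])
print("mean abs error     :", round(mean_abs_error(grid.intensity, truth), 3))
```

prints

```
known after binning: 32013
hole-filled voxels : 755
fill iterations    : 12
mean abs error     : 25.307
```

Eight frames cover a 32³ volume only sparsely: bin-filling recovers 32 013
of 32 768 voxels from the posed pixels and their contribution balls, and the
patch-matching stage closes the remaining 755-voxel gaps in 12 patch copies.
The final number is the mean absolute intensity difference (gray levels,
0–255 scale) between the reconstruction and the phantom; it is dominated by
the interpolation error of the sparse sweep, not by the hole filler.

The same pipeline is scriptable from the shell:

```sh
gpm-synth --out data --dims 32 --n-frames 16 --jitter-mm 0.3 --seed 1
gpm-recon reconstruct --slices data/sweep.tif --poses data/sweep_poses.csv \
    --grid-spacing 1.0 --output recon.nii.gz
gpm-recon fill --volume data/phantom.nii.gz --mask data/mask_cube.nii.gz \
    --output filled.nii.gz        # standalone volume+mask mode
```

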