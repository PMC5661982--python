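# Methods

This note documents the models, numerical conventions, and design choices
behind `gpmrecon`, and what the synthetic benchmarks do and do not show.

## Geometry and conventions

A B-scan pixel `(u, v)` of frame `j` maps to the tracker (sensor) frame as
`(X_S + (u − N_U/2)·S_U,  Y_S − (N_V − v)·S_V,  Z_S)` with `N_U/2` a real
division, and onward to the world frame by the rigid transform `p ↦ R p + T`
(the homogeneous matrix carries the standard scalar 1 in its bottom-right
block). The voxel grid is voxel-centered: index `i` covers
`[origin + i·s − s/2, origin + i·s + s/2)`; nearest-voxel mapping rounds
half up; indices are 0-based and volumes are stored `array[ix, iy, iz]`.
Every tie-break in the package (patch search, nearest-neighbor fill,
priority argmax) resolves to the smallest linearized index with x fastest,
`lin = ix + nx·(iy + ny·iz)`, which makes all pipelines bit-deterministic.
Grids may be user-supplied or auto-fitted as the one-voxel-padded bounding
box of all transformed slice corners, with isotropic spacing defaulting to
the finest pixel spacing in the stack.

## Bin-filling

The robust response combines two deviation measures over nested Chebyshev
discs of radius k = 1..8 (center excluded, clipped at image borders):

* MAD uses the *lower* median for even neighbor counts — a fixed tie rule
  so results are exactly reproducible;
* IQRAD averages differences over the closed 25–75 % band of the neighbor
  intensity range and takes the absolute value of that mean. The printed
  form of the operator can be negative; since the response feeds an argmin
  of deviation magnitudes, the magnitude is the meaningful quantity. An
  empty band yields 0.
* The mixing weights are `α = (3/4)(N+1)/(N+n+1)` and `β = 1 − α`, which
  equals the closed form `((1/4)(N+1)+n)/(N+n+1)` identically; computing β
  as the complement keeps `α + β = 1` to machine precision.

The minimizing class (ties → smallest k) defines the contribution distance
`d(u_i)` as the largest Euclidean pixel distance in the chosen clipped
disc, converted to mm through the per-axis pixel spacing. Nested discs
(rather than annular rings) were chosen so that the eight responses are
comparable across k; this is stated here because either reading is
compatible with "indexed as eight classes".

Voxel accumulation: each pixel contributes `I/d` and `1/d` to every voxel
center within its ball. The default update `Σ(I/d)/Σ(1/d)` is a convex
combination of contributing intensities — consistent with weights
"inversely proportional to distance" — whereas the literal variant
`Σ(I/d)/Σ(d)` (flag `eq11_literal`) is not convex and is kept only for
comparison. Pixels within `direct_hit_fraction × spacing` (default 0.5) of
a voxel center are direct hits: the voxel keeps the running mean of its
direct hits, is excluded from ball updates, and measured data therefore
always outranks interpolation. The direct-hit rule also bounds the weights
(`d ≥ spacing/2` for all ball contributions), avoiding the blow-up of `1/d`
as `d → 0`.

Degenerate inputs: a constant image gives H ≡ 0, class 1 everywhere and a
constant fill; a voxel with no contribution stays vacant; a slice stack
that misses the grid entirely produces a warning and empty accumulators.

## Hole filling

Vacant regions are labeled by 6-connectivity. The fill front is the set of
vacant voxels with a known 6-neighbor; its unit normal is the gradient
(central differences, one-sided at the volume border) of the 3×3×3-smoothed
vacancy indicator, defaulting to +x when the gradient vanishes.

Priority is the product `P = C·D·G`:

* `C(p)` — summed confidence of known voxels in the (border-clipped) patch
  over the clipped patch size. Confidence starts at 1 for voxels known
  after bin-filling and 0 for vacant ones; filled voxels inherit the target
  center's confidence at selection time, so confidence decays with distance
  from measured data.
* `D(p) = max(‖∇I_p × n_p‖/α_norm, ε)` with `α_norm = 255` (8-bit range)
  and floor `ε = 10⁻³`. The cross product is the 3D generalization of the
  planar isophote term `|∇I^⊥·n|` (it reduces to it exactly in-plane): it
  is largest when intensity level sets run into the front. The floor keeps
  flat fronts from freezing under the multiplicative priority.
* `G(p)` — mean gradient magnitude over the known voxels of the patch.

Intensity gradients use known voxels only: central difference when both
axis neighbors are known (this also covers the vacant center itself),
one-sided when the center and one neighbor are known, zero otherwise;
out-of-bounds neighbors count as vacant. All priority terms are computed by
direct local summation (no running-sum filters), so a voxel's terms depend
bitwise only on its local patch content — this is what makes the local
priority update provably equal to a full recomputation.

The source region Φ is frozen at the pre-fill known mask: candidate patches
must lie fully inside the grid and contain no voxel of the original vacancy.
Freezing matters — allowing freshly filled voxels as source material creates
a feedback loop that replicates early errors. The search is global by
default; `search_window` restricts candidates to a cube around the target
for speed. SAD is evaluated over the target's known support (which does
include previously filled voxels); if no fully-known candidate exists, the
fallback compares candidates by maximal known overlap, then by SAD over
jointly known voxels normalized by their count. After the copy, only front
voxels within one patch width (9 voxels) of the filled center are
recomputed; the influence radius of a patch copy on any priority term is at
most half-width + 1 = 5 voxels, so the one-patch-width update region is
strictly conservative. Each iteration fills at least the selected front
voxel, so the vacant count strictly decreases and the loop terminates.

## Baselines and scoring

VNN copies the Euclidean-nearest known voxel (expanding-shell search with
the global tie rule); PNN performs direct-hit binning then repeated
6-neighbor mean dilation; DW interpolates by inverse distance within a
radius of 5 voxels, grown until a contributor exists (the radius is not
prescribed anywhere authoritative; 5 is fixed for reproducibility). All
three preserve known voxels bit-exactly. Reconstructions are scored by the
mean absolute intensity difference `V = (1/N) Σ |ν − ν′|`, evaluated over
the carved region in protocol reports (untouched voxels are identical by
construction; a whole-volume option exists).

## The synthetic phantom

`default_phantom` emulates the salient features of compounded clinical
ultrasound volumes rather than any specific dataset:

* **anatomy-scale structures** — a large bright body, a hypoechoic lobe, a
  fascia-like slab, and two full-length vessel-like tubes, each spanning a
  large fraction of the volume so that carved holes are small relative to
  the structures crossing them and boundary continuation is informative;
* **point-spread blur** (Gaussian, σ = 0.8 voxels) — compounded volumes
  never contain voxel-sharp edges;
* **stationary speckle texture** — a repeating random tile (period 8,
  ±15 % multiplicative) idealizing the statistical stationarity of fully
  developed speckle; texture repetition across the volume is precisely what
  global patch matching exploits;
* **a low-frequency additive bias field** (amplitude 12 gray levels)
  standing in for attenuation, time-gain compensation, and beam-profile
  modulation.

What this phantom does *not* model: physically realistic speckle statistics
(Rayleigh/Rician), beam-dependent resolution anisotropy, shadowing and
reverberation artifacts, or anatomy whose texture varies non-stationarily.
Multiplicative white speckle is available separately (`add_speckle`) but is
not part of the evaluation phantom: voxel-wise white noise is unpredictable
by construction, and under a mean-absolute-error score it penalizes any
texture-synthesizing method by ~√2 relative to smoothing methods regardless
of structural quality — it measures a different trade-off than the
benchmarks intend.

Sweeps sample frames by trilinear interpolation along a linear or fan
trajectory; with zero jitter and frame spacing equal to the voxel spacing
every pixel is a direct hit and binning reproduces the phantom bit-exactly,
which serves as the pipeline's identity fixture.

## Benchmark design and known limitations

The carved-shape suite (cube 20³, cuboid 15×50×20, sphere r = 10,
ellipsoid 10×12×8, tetrahedron; two seeded repetitions each) places each
hole at a seeded random admissible position of a per-case phantom at 64³.
The slice-removal protocol deletes k = 1..8 contiguous frames from a
100-frame jittered sweep at three seeded sites and averages the slab errors;
suite sizes (64³ volumes, 10 cases, 3 sites) are the package's chosen
benchmark scale. Protocol GPM runs use a search window of 16 voxels; the
exact-restoration fixture uses the global search.

Two properties of greedy 3D exemplar filling are worth stating plainly,
because the test suite documents both:

* Where hole content is predictable by continuation — straight or planar
  boundaries, smooth ramps, periodic texture with an intact period outside
  the hole — the filler is exact or near-exact (the planar-edge, ramp, and
  periodic-texture tests restore with zero error), and it preserves texture
  statistics that VNN/PNN/DW visibly destroy.
* At geometrically unique junctions of curved structures the best SAD
  match can still be poor, and a single 9³ copy commits several hundred
  voxels to the wrong structure ("edge creep"). Under a mean-absolute-error
  score at 64³ benchmark scale, those few catastrophic cases are heavy
  enough that conservative per-voxel interpolators can end up with a lower
  *mean* error across the suite even though the patch-matching filler wins
  about half of the individual cases. Passing or failing the mean-ordering
  benchmark at this scale therefore speaks to this specific trade-off, not
  to the visual or texture fidelity of the reconstruction, and results at
  desk scale should not be extrapolated to full-resolution clinical volumes,
  where holes are far smaller relative to the anatomy.

## Numerical choices

Tolerances: rotation orthonormality 1e-9; quaternion unit norm 1e-6
(normalized on read); the α + β identity is asserted at 1e-12; the
incremental-vs-full priority comparison at 1e-12 (exact local summation
makes it bitwise in practice). Patch dimensions must be odd; border patches
are clipped, never padded. The numba kernels are plain loop nests compiled
at first use; they introduce no floating-point reordering relative to the
reference implementations, which the kernel-vs-reference tests pin down.
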