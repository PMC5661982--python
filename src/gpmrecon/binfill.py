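"""Robust bin-filling of the voxel grid from posed slices.

Each slice pixel gets a *best contribution distance*: the largest distance
within the neighborhood class whose combined robust response

    H_k = alpha * MAD + beta * IQRAD,   k = 1..8

is smallest. MAD is the absolute difference between the center intensity and
the (lower) median neighbor intensity; IQRAD is the magnitude of the mean
difference over neighbors inside the 25-75% intensity band

    [I_min + 0.25 (I_max - I_min),  I_min + 0.75 (I_max - I_min)];

the weights

    alpha = (3/4)(N + 1) / (N + n + 1),    beta = 1 - alpha

depend on the neighbor count N and band count n (beta equals the printed
form ((1/4)(N+1) + n)/(N+n+1) identically). The neighborhood classes are
nested Chebyshev discs of radius k, center excluded, clipped at image
borders.

The pixel then contributes to every voxel center inside the spherical ball
of radius d(u_i) around its world position with weight inversely
proportional to the Euclidean distance. The default voxel update is the
normalized inverse-distance form

    V(x) = sum_i I(u_i)/d(u_i, x) / sum_i 1/d(u_i, x),

a convex combination of contributor intensities; ``eq11_literal=True``
divides by ``sum_i d(u_i, x)`` instead, reproducing the non-normalized
variant verbatim. Pixels landing within half a voxel spacing of a voxel
center are direct hits: the voxel keeps the running mean of its direct-hit
intensities and ball contributions never overwrite it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from . import _kernels
from .geometry import PosedSlice, VoxelGrid

__all__ = [
    "ContributionProfile",
    "mad",
    "iqrad",
    "combine_weights",
    "feature_response",
    "best_contribution",
    "contribution_distance_map",
    "accumulate",
    "finalize",
    "bin_fill",
]

MAX_CLASS = 8


def mad(patch_intensities, center_intensity: float) -> float:
    """Median absolute deviation of the center from its neighbors.

    Uses the lower median for even neighbor counts.
    """
    arr = np.sort(np.asarray(patch_intensities, dtype=float).ravel())
    if arr.size == 0:
        raise ValueError("patch must be non-empty")
    med = arr[(arr.size - 1) // 2]
    return abs(med - float(center_intensity))


def _iqrad_stats(patch_intensities, center_intensity: float) -> tuple[float, int]:
    arr = np.asarray(patch_intensities, dtype=float).ravel()
    if arr.size == 0:
        raise ValueError("patch must be non-empty")
    imin, imax = arr.min(), arr.max()
    lo = imin + 0.25 * (imax - imin)
    hi = imin + 0.75 * (imax - imin)
    band = arr[(arr >= lo) & (arr <= hi)]
    n = int(band.size)
    if n == 0:
        return 0.0, 0
    return abs(float(np.sum(band - float(center_intensity)))) / n, n


def iqrad(patch_intensities, center_intensity: float) -> float:
    """Inter-quartile-range absolute deviation.

    Magnitude of the mean difference between the center and the neighbors
    whose intensity lies in the closed 25-75% band of the neighbor range;
    0 when the band is empty.
    """
    return _iqrad_stats(patch_intensities, center_intensity)[0]


def combine_weights(N: int, n: int) -> tuple[float, float]:
    """MAD/IQRAD mixing weights (alpha, beta) with alpha + beta = 1."""
    if N < 1 or n < 0 or n > N:
        raise ValueError(f"invalid counts N={N}, n={n}")
    alpha = 0.75 * (N + 1) / (N + n + 1)
    return alpha, 1.0 - alpha


def _class_neighborhood(slc: PosedSlice, u: int, v: int, k: int):
    """Offsets and intensities of the border-clipped Chebyshev-k disc."""
    offs = []
    vals = []
    for dv in range(-k, k + 1):
        vv = v + dv
        if not 0 <= vv < slc.n_v:
            continue
        for du in range(-k, k + 1):
            if du == 0 and dv == 0:
                continue
            uu = u + du
            if not 0 <= uu < slc.n_u:
                continue
            offs.append((du, dv))
            vals.append(slc.pixels[vv, uu])
    return offs, np.asarray(vals, dtype=float)


def feature_response(slc: PosedSlice, pixel: tuple[int, int], k: int) -> float:
    """Combined robust response H_k at a pixel for distance class k."""
    if not 1 <= k <= MAX_CLASS:
        raise ValueError(f"distance class k={k} outside 1..{MAX_CLASS}")
    u, v = pixel
    _, vals = _class_neighborhood(slc, u, v, k)
    if vals.size == 0:
        raise ValueError(f"pixel {pixel} has no in-bounds neighbors")
    center = float(slc.pixels[v, u])
    m = mad(vals, center)
    iq, n = _iqrad_stats(vals, center)
    alpha, beta = combine_weights(int(vals.size), n)
    return alpha * m + beta * iq


@dataclass
class ContributionProfile:
    """Per-pixel robust responses and the chosen contribution distance."""

    pixel: tuple[int, int]
    H_k: np.ndarray            # responses for k = 1..8
    k_star: int                # argmin class (ties -> smallest k)
    d_ui: float                # best contribution distance, mm
    alpha: float
    beta: float
    N: int                     # neighbor count of the k* disc
    n: int                     # band count of the k* disc


def best_contribution(slc: PosedSlice, pixel: tuple[int, int]) -> ContributionProfile:
    """Choose the minimizing distance class and its contribution distance.

    d(u_i) is the largest Euclidean distance, in mm via the slice spacing,
    from the pixel to any member of the chosen (clipped) disc.
    """
    u, v = pixel
    hs = np.array([feature_response(slc, pixel, k) for k in range(1, MAX_CLASS + 1)])
    k_star = int(np.argmin(hs)) + 1  # np.argmin keeps the first minimum
    offs, vals = _class_neighborhood(slc, u, v, k_star)
    su, sv = slc.spacing
    d_ui = max(np.hypot(du * su, dv * sv) for du, dv in offs)
    center = float(slc.pixels[v, u])
    iq, n = _iqrad_stats(vals, center)
    alpha, beta = combine_weights(int(vals.size), n)
    return ContributionProfile(
        pixel=pixel, H_k=hs, k_star=k_star, d_ui=float(d_ui),
        alpha=alpha, beta=beta, N=int(vals.size), n=n,
    )


def contribution_distance_map(slc: PosedSlice, max_class: int = MAX_CLASS) -> np.ndarray:
    """Best-contribution distance d(u_i) for every pixel of a slice (mm)."""
    if slc.n_u * slc.n_v < 2:
        raise ValueError("slice too small: pixels have no neighbors")
    dmap, _, _ = _kernels.feature_maps(
        np.ascontiguousarray(slc.pixels, dtype=np.float64),
        float(slc.spacing[0]), float(slc.spacing[1]), int(max_class),
    )
    return dmap


def _ensure_accumulators(grid: VoxelGrid) -> None:
    if grid.numerator is None:
        shape = grid.dims
        grid.numerator = np.zeros(shape)
        grid.denominator = np.zeros(shape)
        grid.denominator_literal = np.zeros(shape)
        grid.hit_sum = np.zeros(shape)
        grid.hit_count = np.zeros(shape)
        grid.contrib_min = np.full(shape, np.inf)
        grid.contrib_max = np.full(shape, -np.inf)


def accumulate(grid: VoxelGrid, slices, dmaps=None,
               direct_hit_fraction: float = 0.5) -> VoxelGrid:
    """Scatter every pixel of every slice into the grid accumulators.

    ``dmaps`` may carry precomputed contribution-distance maps (one per
    slice) so repeated protocols do not recompute the robust features.
    """
    _ensure_accumulators(grid)
    touched = False
    for idx, slc in enumerate(slices):
        dmap = dmaps[idx] if dmaps is not None else contribution_distance_map(slc)
        ws = slc.world_positions().reshape(-1, 3)
        _kernels.accumulate_ball(
            np.ascontiguousarray(ws),
            np.ascontiguousarray(slc.pixels.ravel(), dtype=np.float64),
            np.ascontiguousarray(dmap.ravel(), dtype=np.float64),
            grid.origin[0], grid.origin[1], grid.origin[2],
            float(grid.spacing), float(direct_hit_fraction), *grid.dims,
            grid.numerator, grid.denominator, grid.denominator_literal,
            grid.hit_sum, grid.hit_count, grid.contrib_min, grid.contrib_max,
        )
        touched = True
    if touched and not np.any(grid.hit_count > 0) and not np.any(grid.denominator > 0):
        warnings.warn("no slice pixel intersects the grid; accumulators are empty")
    return grid


def finalize(grid: VoxelGrid, eq11_literal: bool = False) -> VoxelGrid:
    """Turn the accumulators into intensities and the known mask.

    Direct-hit voxels keep their direct-hit mean; other voxels with a
    nonzero denominator get the (normalized or literal) inverse-distance
    combination; the rest stay vacant.
    """
    _ensure_accumulators(grid)
    hits = grid.hit_count > 0
    den = grid.denominator_literal if eq11_literal else grid.denominator
    ball = (~hits) & (den > 0)
    grid.intensity = np.zeros(grid.dims)
    with np.errstate(invalid="ignore", divide="ignore"):
        grid.intensity[hits] = grid.hit_sum[hits] / grid.hit_count[hits]
        grid.intensity[ball] = grid.numerator[ball] / den[ball]
    grid.known_mask = hits | ball
    return grid


def bin_fill(grid: VoxelGrid, slices, eq11_literal: bool = False,
             dmaps=None, direct_hit_fraction: float = 0.5) -> VoxelGrid:
    """accumulate + finalize in one call."""
    accumulate(grid, slices, dmaps=dmaps, direct_hit_fraction=direct_hit_fraction)
    return finalize(grid, eq11_literal=eq11_literal)
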