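"""Comparator reconstruction methods and the evaluation protocols.

Three classical fill strategies serve as baselines against the patch-matching
hole filler:

* VNN (voxel nearest neighbor): each vacant voxel copies the Euclidean
  nearest known voxel.
* PNN (pixel nearest neighbor): direct-hit binning followed by iterative
  dilation, each vacant voxel taking the mean of its known 6-neighbors.
* DW (distance weighted): inverse-distance interpolation from known voxels
  within a radius, grown until a contributor exists.

Reconstruction quality is scored by the mean absolute intensity difference

    V = (1/N) sum_n |v_n - v'_n|

between reconstruction and ground truth, evaluated over the carved region
(untouched voxels are identical by construction; a whole-volume option
exists).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels, binfill, holefill
from .geometry import VoxelGrid
from .phantom import carve, shape_mask

__all__ = [
    "ReconstructionReport",
    "mean_abs_error",
    "vnn_fill",
    "pnn_fill",
    "dw_fill",
    "gpm_fill",
    "run_protocol",
    "run_slice_removal_protocol",
    "masked_grid",
]

DW_RADIUS = 5


def mean_abs_error(recon: np.ndarray, truth: np.ndarray,
                   mask: np.ndarray | None = None) -> float:
    """Mean absolute intensity difference over the mask (default: all)."""
    recon = np.asarray(recon, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if recon.shape != truth.shape:
        raise ValueError(f"shape mismatch {recon.shape} vs {truth.shape}")
    if mask is None:
        mask = np.ones(recon.shape, dtype=bool)
    elif mask.shape != recon.shape:
        raise ValueError("mask shape mismatch")
    if not mask.any():
        return 0.0
    return float(np.mean(np.abs(recon[mask] - truth[mask])))


def _require_known(grid: VoxelGrid) -> None:
    if not grid.known_mask.any():
        raise ValueError("grid has no known voxels to fill from")


def vnn_fill(grid: VoxelGrid) -> VoxelGrid:
    """Nearest-known-voxel fill (ties -> smallest linearized index)."""
    _require_known(grid)
    out = grid.copy()
    filled = out.intensity.copy()
    _kernels.vnn_search(grid.known_mask, grid.intensity, filled)
    out.intensity = np.where(grid.known_mask, grid.intensity, filled)
    out.known_mask = np.ones(grid.dims, dtype=bool)
    return out


def pnn_fill(grid: VoxelGrid, slices=None) -> VoxelGrid:
    """Direct-hit binning (when slices are given) + iterative 6-neighbor
    mean dilation until no vacancy remains."""
    out = grid.copy()
    if slices is not None:
        binfill._ensure_accumulators(out)
        for slc in slices:
            ws = slc.world_positions().reshape(-1, 3)
            # direct hits only: zero contribution distance
            _kernels.accumulate_ball(
                np.ascontiguousarray(ws),
                np.ascontiguousarray(slc.pixels.ravel(), dtype=np.float64),
                np.zeros(ws.shape[0]),
                out.origin[0], out.origin[1], out.origin[2],
                float(out.spacing), 0.5, *out.dims,
                out.numerator, out.denominator, out.denominator_literal,
                out.hit_sum, out.hit_count, out.contrib_min, out.contrib_max,
            )
        hits = out.hit_count > 0
        out.intensity = np.where(hits, 0.0, out.intensity)
        np.divide(out.hit_sum, out.hit_count, out=out.intensity, where=hits)
        out.known_mask = out.known_mask | hits
    _require_known(out)
    intensity = out.intensity.copy()
    known = out.known_mask.copy()
    while not known.all():
        s = np.zeros(out.dims)
        c = np.zeros(out.dims)
        for axis in range(3):
            for sign in (1, -1):
                shifted_known = np.roll(known, sign, axis=axis)
                shifted_val = np.roll(np.where(known, intensity, 0.0), sign, axis=axis)
                edge = [slice(None)] * 3
                edge[axis] = 0 if sign == 1 else -1
                shifted_known[tuple(edge)] = False
                shifted_val[tuple(edge)] = 0.0
                s += shifted_val
                c += shifted_known
        newly = (~known) & (c > 0)
        intensity[newly] = s[newly] / c[newly]
        known |= newly
    out.intensity = intensity
    out.known_mask = known
    return out


def dw_fill(grid: VoxelGrid, radius: int = DW_RADIUS) -> VoxelGrid:
    """Inverse-distance-weighted fill from known voxels within ``radius``
    voxels (grown by 1 until a contributor is found)."""
    _require_known(grid)
    out = grid.copy()
    filled = np.zeros(grid.dims)
    _kernels.dw_interp(grid.known_mask, grid.intensity, int(radius), filled)
    out.intensity = filled
    out.known_mask = np.ones(grid.dims, dtype=bool)
    return out


def gpm_fill(grid: VoxelGrid, **kwargs) -> VoxelGrid:
    """Patch-matching hole fill on a copy of the grid."""
    out = grid.copy()
    return holefill.hole_fill(out, **kwargs)


_METHODS = {
    "vnn": lambda g, kw: vnn_fill(g),
    "pnn": lambda g, kw: pnn_fill(g),
    "dw": lambda g, kw: dw_fill(g, radius=kw.get("dw_radius", DW_RADIUS)),
    "gpm": lambda g, kw: gpm_fill(
        g,
        patch_size=kw.get("patch_size", holefill.PATCH_SIZE),
        search_window=kw.get("search_window", 0),
        alpha_norm=kw.get("alpha_norm", holefill.ALPHA_NORM),
        data_floor=kw.get("data_floor", holefill.DATA_FLOOR),
    ),
}


@dataclass
class ReconstructionReport:
    """Per-method error statistics across the cases of a protocol."""

    method: str
    cases: list[str] = field(default_factory=list)
    errors: list[float] = field(default_factory=list)

    @property
    def min(self) -> float:
        return float(np.min(self.errors))

    @property
    def max(self) -> float:
        return float(np.max(self.errors))

    @property
    def mean(self) -> float:
        return float(np.mean(self.errors))

    @property
    def sd(self) -> float:
        return float(np.std(self.errors))

    def row(self) -> dict:
        return dict(method=self.method, n_cases=len(self.errors),
                    min=self.min, max=self.max, mean=self.mean, sd=self.sd)


def masked_grid(truth: np.ndarray, vacancy: np.ndarray,
                spacing: float = 1.0) -> VoxelGrid:
    """Grid whose known part is the truth volume outside the vacancy mask."""
    truth = np.asarray(truth, dtype=float)
    grid = VoxelGrid(truth.shape, spacing=spacing,
                     intensity=np.where(vacancy, 0.0, truth),
                     known_mask=~np.asarray(vacancy, dtype=bool))
    return grid


def reports_to_frame(reports: list[ReconstructionReport]):
    import pandas as pd

    rows = []
    for rep in reports:
        for case, err in zip(rep.cases, rep.errors):
            rows.append(dict(method=rep.method, case=case, error=err))
    summary = pd.DataFrame([rep.row() for rep in reports])
    return pd.DataFrame(rows), summary


def run_protocol(truth: np.ndarray, protocol: list[dict], methods: list[str],
                 method_params: dict | None = None,
                 whole_volume: bool = False) -> list[ReconstructionReport]:
    """Carve each case's vacancy from the truth, fill with each method, and
    score with the mean absolute error over the carved region.

    ``protocol`` is a list of case dicts: ``{"name": ..., "shape": ...,
    "center": ..., **shape params}`` as accepted by ``phantom.carve``.
    """
    method_params = method_params or {}
    unknown = [m for m in methods if m not in _METHODS]
    if unknown:
        raise ValueError(f"unknown methods: {unknown}")
    reports = [ReconstructionReport(m) for m in methods]
    for case in protocol:
        _, vacancy = carve(truth, case)
        grid = masked_grid(truth, vacancy)
        score_mask = None if whole_volume else vacancy
        for rep in reports:
            filled = _METHODS[rep.method](grid, method_params)
            assert np.array_equal(
                filled.intensity[grid.known_mask], grid.intensity[grid.known_mask]
            ), "baseline modified a known voxel"
            rep.cases.append(case.get("name", case["shape"]))
            rep.errors.append(
                mean_abs_error(filled.intensity, truth, score_mask))
    return reports


def run_slice_removal_protocol(truth: np.ndarray, slices, ks, methods,
                               seed: int = 0, method_params: dict | None = None,
                               spacing: float = 1.0, n_sites: int = 3):
    """Remove k contiguous frames from a sweep, re-bin, fill, and score.

    At each of ``n_sites`` seeded removal locations the deleted block grows
    in place from min(ks) to max(ks) frames; the error for each k is the
    mean, across sites, of the mean absolute difference to the truth over
    the z-slab spanned by the removed frames (small k may leave no vacancy
    at all, yet the slab still degrades). Returns
    ``{method: [error for each k]}``.
    """
    from .phantom import remove_slices

    method_params = method_params or {}
    rng = np.random.default_rng(seed)
    nz = truth.shape[2]
    n_frames = len(slices)
    dmaps = [binfill.contribution_distance_map(s) for s in slices]
    kmax = max(ks)
    lo, hi = n_frames // 4, 3 * n_frames // 4 - kmax
    starts = sorted(int(s) for s in
                    rng.choice(np.arange(lo, hi), size=n_sites, replace=False))
    per_site = {m: np.zeros((n_sites, len(list(ks)))) for m in methods}
    for si, start in enumerate(starts):
        for ki, k in enumerate(ks):
            reduced = remove_slices(slices, start, k)
            red_dmaps = dmaps[:start] + dmaps[start + k:]
            base = VoxelGrid(truth.shape, spacing=spacing)
            base = binfill.bin_fill(base, reduced, dmaps=red_dmaps)
            # z-slab spanned by the removed frames, in voxel indices
            zs = [slices[j].sensor_origin[2] for j in range(start, start + k)]
            z0 = max(0, int(np.floor(min(zs) / spacing)))
            z1 = min(nz - 1, int(np.ceil(max(zs) / spacing)))
            slab = np.zeros(truth.shape, dtype=bool)
            slab[:, :, z0:z1 + 1] = True
            for m in methods:
                filled = _METHODS[m](base, method_params)
                per_site[m][si, ki] = mean_abs_error(filled.intensity, truth, slab)
    return {m: list(per_site[m].mean(axis=0)) for m in methods}


def standard_hole_suite(dims=(64, 64, 64), seed: int = 0,
                        n_repeats: int = 2) -> list[dict]:
    """The carved-shape evaluation suite: cube 20^3, cuboid 15x50x20,
    sphere r=10, ellipsoid, tetrahedron, each carved at a seeded random
    admissible center of a per-case phantom (``phantom_seed`` field)."""
    rng = np.random.default_rng(seed)
    dims = tuple(dims)
    cases = []
    shapes = ["cube", "cuboid", "sphere", "ellipsoid", "tetrahedron"]
    idx = 0
    for rep in range(n_repeats):
        for kind in shapes:
            if kind == "cube":
                size = 20
                margin = np.array([11, 11, 11])
                spec = {"shape": "cube", "size": size}
            elif kind == "cuboid":
                spec = {"shape": "cuboid", "size": (15, 50, 20)}
                margin = np.array([9, 26, 11])
            elif kind == "sphere":
                spec = {"shape": "sphere", "radius": 10}
                margin = np.array([11, 11, 11])
            elif kind == "ellipsoid":
                spec = {"shape": "ellipsoid", "semi_axes": (10, 12, 8)}
                margin = np.array([11, 13, 9])
            else:
                spec = {"shape": "tetrahedron"}
                margin = None
            if margin is None:
                base = np.array([rng.integers(m, d - 1 - m)
                                 for d, m in zip(dims, (13, 13, 13))])
                verts = base + np.array(
                    [[-10, -10, -10], [12, -8, -6], [-4, 13, -8], [0, 0, 12]])
                spec["vertices"] = verts.tolist()
            else:
                spec["center"] = tuple(
                    int(rng.integers(m, d - 1 - m)) for d, m in zip(dims, margin))
            spec["name"] = f"{kind}_{rep}"
            spec["phantom_seed"] = int(rng.integers(0, 2**16))
            cases.append(spec)
            idx += 1
    return cases


def run_hole_suite(dims=(64, 64, 64), seed: int = 0, methods=("gpm", "dw", "vnn"),
                   method_params: dict | None = None, n_repeats: int = 2):
    """Run the standard carved-shape suite; each case gets its own phantom.

    Returns a list of ReconstructionReports (one per method).
    """
    from .phantom import default_phantom

    cases = standard_hole_suite(dims, seed, n_repeats)
    reports = [ReconstructionReport(m) for m in methods]
    for case in cases:
        case = dict(case)
        pseed = case.pop("phantom_seed")
        name = case.pop("name")
        truth = np.round(default_phantom(dims, seed=pseed))
        _, vacancy = carve(truth, case)
        grid = masked_grid(truth, vacancy)
        for rep in reports:
            filled = _METHODS[rep.method](grid, method_params or {})
            rep.cases.append(name)
            rep.errors.append(mean_abs_error(filled.intensity, truth, vacancy))
    return reports
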