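"""Exemplar-based 3D hole filling by global patch matching.

After bin-filling, vacant regions remain wherever no slice passed close
enough. They are filled greedily from their boundary (the *fill front*,
all vacant voxels 6-adjacent to a known voxel) inward. Each front voxel p
carries a priority

    P(p) = C(p) * D(p) * G(p)

where the confidence term C is the accumulated confidence of known voxels
in the patch around p divided by the patch size, the data term D measures
the isophote component lying in the front's tangent plane
(``|grad I x n_p| / alpha_norm``, floored so flat fronts keep a nonzero
priority), and the gradient term G is the mean gradient magnitude over the
known voxels of the patch. The highest-priority front voxel's patch is
compared, on its known support, with every fully-known candidate patch in
the search region (the whole volume by default) by sum of absolute
differences; vacant voxels of the target patch are copied from the winning
source patch and inherit the target's confidence. Only priorities near the
filled patch are recomputed between iterations.

All tie-breaks use the smallest linearized voxel index with x fastest.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from . import _kernels
from .geometry import VoxelGrid

__all__ = [
    "FillFront",
    "PatchSpec",
    "FillError",
    "label_vacant_regions",
    "extract_front",
    "confidence_term",
    "data_term",
    "gradient_term",
    "priority",
    "best_match",
    "copy_and_update",
    "hole_fill",
]

PATCH_SIZE = 9          # patch edge length (odd), i.e. half-width 4
ALPHA_NORM = 255.0      # 8-bit intensity range normalization of the data term
DATA_FLOOR = 1e-3       # keeps flat fronts from freezing the priority

_STRUCT6 = ndimage.generate_binary_structure(3, 1)


class FillError(RuntimeError):
    """Raised when no source patch can be found for a fill region."""


def _lin_index(p: tuple[int, int, int], dims: tuple[int, int, int]) -> int:
    return p[0] + dims[0] * (p[1] + dims[1] * p[2])


def label_vacant_regions(grid: VoxelGrid) -> tuple[np.ndarray, list[int]]:
    """6-connected components of vacant voxels; labels 1..L and their sizes."""
    labels, nlab = ndimage.label(~grid.known_mask, structure=_STRUCT6)
    sizes = [int(np.sum(labels == i)) for i in range(1, nlab + 1)]
    return labels, sizes


def _front_mask(known: np.ndarray) -> np.ndarray:
    has_known_neighbor = ndimage.binary_dilation(known, structure=_STRUCT6)
    return (~known) & has_known_neighbor


def _front_points(known: np.ndarray) -> np.ndarray:
    return np.argwhere(_front_mask(known)).astype(np.int64)


@dataclass
class FillFront:
    """Boundary voxels of the vacant regions with their priority terms."""

    voxels: list[tuple[int, int, int]] = field(default_factory=list)
    confidence: dict = field(default_factory=dict)
    data: dict = field(default_factory=dict)
    gradient: dict = field(default_factory=dict)
    priority: dict = field(default_factory=dict)
    normal: dict = field(default_factory=dict)


@dataclass
class PatchSpec:
    """A border-clipped cubic patch around a center voxel."""

    center: tuple[int, int, int]
    half_width: int
    lo: tuple[int, int, int]        # inclusive offset bounds, e.g. (-4,-4,-2)
    hi: tuple[int, int, int]
    known: np.ndarray               # patch-shaped known mask
    intensities: np.ndarray         # patch-shaped intensities (0 where vacant)

    @property
    def size(self) -> int:
        return self.known.size


def make_patch(grid: VoxelGrid, center: tuple[int, int, int],
               patch_size: int = PATCH_SIZE) -> PatchSpec:
    if patch_size % 2 != 1:
        raise ValueError("patch size must be odd")
    half = patch_size // 2
    c = np.asarray(center, dtype=int)
    dims = np.asarray(grid.dims)
    if np.any(c < 0) or np.any(c >= dims):
        raise ValueError(f"patch center {center} outside grid {grid.dims}")
    lo = np.maximum(-half, -c)
    hi = np.minimum(half, dims - 1 - c)
    sl = tuple(slice(c[a] + lo[a], c[a] + hi[a] + 1) for a in range(3))
    return PatchSpec(
        center=tuple(int(x) for x in c), half_width=half,
        lo=tuple(int(x) for x in lo), hi=tuple(int(x) for x in hi),
        known=grid.known_mask[sl].copy(),
        intensities=np.where(grid.known_mask[sl], grid.intensity[sl], 0.0),
    )


def front_normal(grid: VoxelGrid, p: tuple[int, int, int]) -> np.ndarray:
    """Unit normal of the fill front at p (gradient of the smoothed
    vacancy indicator; +x when the gradient vanishes)."""
    pts = np.asarray([p], dtype=np.int64)
    return _kernels.front_normals(grid.known_mask, pts)[0]


def confidence_term(grid: VoxelGrid, confidence_field: np.ndarray,
                    p: tuple[int, int, int], patch: PatchSpec | None = None) -> float:
    """C(p): summed confidence of known patch voxels over the patch size."""
    patch = patch or make_patch(grid, p)
    sl = tuple(slice(p[a] + patch.lo[a], p[a] + patch.hi[a] + 1) for a in range(3))
    known = grid.known_mask[sl]
    return float(np.sum(confidence_field[sl][known])) / known.size


def _masked_gradient(grid: VoxelGrid, q: tuple[int, int, int]) -> np.ndarray:
    g = np.zeros(3)
    known = grid.known_mask
    I = grid.intensity
    dims = grid.dims
    kc = known[q]
    for a in range(3):
        qp = list(q); qp[a] += 1
        qm = list(q); qm[a] -= 1
        kp = 0 <= qp[a] < dims[a] and known[tuple(qp)]
        km = 0 <= qm[a] < dims[a] and known[tuple(qm)]
        if kp and km:
            g[a] = 0.5 * (I[tuple(qp)] - I[tuple(qm)])
        elif kc and kp:
            g[a] = I[tuple(qp)] - I[q]
        elif kc and km:
            g[a] = I[q] - I[tuple(qm)]
    return g


def data_term(grid: VoxelGrid, p: tuple[int, int, int], n_p: np.ndarray,
              alpha_norm: float = ALPHA_NORM, floor: float = DATA_FLOOR) -> float:
    """D(p): isophote strength in the front's tangent plane.

    ``|grad I_p x n_p| / alpha_norm`` — the 3D generalization of the planar
    ``|grad I^perp . n|`` — floored at a small epsilon.
    """
    n_p = np.asarray(n_p, dtype=float)
    if abs(np.linalg.norm(n_p) - 1.0) > 1e-9:
        raise ValueError("front normal must be a unit vector")
    g = _masked_gradient(grid, tuple(p))
    return max(float(np.linalg.norm(np.cross(g, n_p))) / alpha_norm, floor)


def gradient_term(grid: VoxelGrid, p: tuple[int, int, int],
                  patch: PatchSpec | None = None) -> float:
    """G(p): mean gradient magnitude over the known voxels of the patch."""
    patch = patch or make_patch(grid, p)
    total = 0.0
    count = 0
    for dx in range(patch.lo[0], patch.hi[0] + 1):
        for dy in range(patch.lo[1], patch.hi[1] + 1):
            for dz in range(patch.lo[2], patch.hi[2] + 1):
                q = (p[0] + dx, p[1] + dy, p[2] + dz)
                if grid.known_mask[q]:
                    total += float(np.linalg.norm(_masked_gradient(grid, q)))
                    count += 1
    return total / count if count else 0.0


def priority(C: float, D: float, G: float) -> float:
    """Multiplicative fill priority P = C * D * G."""
    return C * D * G


def extract_front(grid: VoxelGrid, confidence_field: np.ndarray | None = None,
                  patch_size: int = PATCH_SIZE, alpha_norm: float = ALPHA_NORM,
                  data_floor: float = DATA_FLOOR) -> FillFront:
    """All vacant voxels with a known 6-neighbor, with their C/D/G/P terms."""
    if confidence_field is None:
        confidence_field = grid.known_mask.astype(float)
    pts = _front_points(grid.known_mask)
    front = FillFront()
    if pts.size == 0:
        return front
    C, D, G = _kernels.priority_terms(
        grid.intensity, grid.known_mask, confidence_field, pts,
        patch_size // 2, alpha_norm, data_floor,
    )
    normals = _kernels.front_normals(grid.known_mask, pts)
    for i, p in enumerate(map(tuple, pts)):
        front.voxels.append(p)
        front.confidence[p] = float(C[i])
        front.data[p] = float(D[i])
        front.gradient[p] = float(G[i])
        front.priority[p] = float(C[i] * D[i] * G[i])
        front.normal[p] = normals[i]
    return front


def _box_count(known: np.ndarray, lo, hi) -> np.ndarray:
    """Known-voxel count of the patch window [c+lo, c+hi] per center c.

    Computed from an integral image; only centers whose window is fully
    inside the array are meaningful to callers.
    """
    pad = np.zeros(tuple(s + 1 for s in known.shape), dtype=np.int64)
    pad[1:, 1:, 1:] = known.astype(np.int64)
    P = pad.cumsum(0).cumsum(1).cumsum(2)
    n = known.shape
    a = [np.clip(np.arange(n[i]) + lo[i], 0, n[i]) for i in range(3)]
    b = [np.clip(np.arange(n[i]) + hi[i] + 1, 0, n[i]) for i in range(3)]
    out = np.zeros(n, dtype=np.int64)
    for sx, ix in ((1, b[0]), (-1, a[0])):
        for sy, iy in ((1, b[1]), (-1, a[1])):
            for sz, iz in ((1, b[2]), (-1, a[2])):
                out += sx * sy * sz * P[np.ix_(ix, iy, iz)]
    return out


def best_match(grid: VoxelGrid, target: PatchSpec, search_window: int = 0,
               source_known: np.ndarray | None = None,
               ) -> tuple[tuple[int, int, int], float]:
    """Global (or windowed) minimum-SAD source patch for a target patch.

    Candidates share the target's (possibly clipped) shape, lie fully inside
    the grid, and contain no vacant voxel of the source region Phi = I - Omega
    (``source_known``; the fill loop freezes it at the pre-fill known mask so
    filled voxels never become source material). SAD runs over the target's
    known support, ties go to the smallest linearized index. When no
    fully-known candidate exists, candidates with maximal known overlap are
    compared by SAD over jointly known voxels normalized by their count.
    """
    if source_known is None:
        source_known = grid.known_mask
    known_off = np.argwhere(target.known)
    if known_off.size == 0:
        raise FillError(f"target patch at {target.center} has no known voxel")
    t_off = (known_off + np.asarray(target.lo)).astype(np.int64)
    t_val = target.intensities[target.known].astype(np.float64)

    dims = grid.dims
    lo, hi = target.lo, target.hi
    bounds = []
    for a in range(3):
        b0, b1 = -lo[a], dims[a] - 1 - hi[a]
        if search_window > 0:
            b0 = max(b0, target.center[a] - search_window)
            b1 = min(b1, target.center[a] + search_window)
        bounds.append((b0, b1))
    if any(b0 > b1 for b0, b1 in bounds):
        raise FillError(f"no candidate patch fits the grid for {target.center}")

    patch_voxels = int(np.prod([hi[a] - lo[a] + 1 for a in range(3)]))
    valid = _box_count(source_known, lo, hi) == patch_voxels
    (x0, x1), (y0, y1), (z0, z1) = bounds
    bx, by, bz, sad = _kernels.sad_scan_full(
        grid.intensity, valid, t_off, t_val, x0, x1, y0, y1, z0, z1)
    if bx >= 0:
        return (int(bx), int(by), int(bz)), float(sad)

    forbid = np.zeros(dims, dtype=bool)
    forbid[target.center] = True
    bx, by, bz, sad = _kernels.sad_scan_masked(
        grid.intensity, source_known, t_off, t_val, forbid,
        x0, x1, y0, y1, z0, z1)
    if bx < 0 and search_window > 0:
        # widen to the whole volume before giving up
        full = [(-lo[a], dims[a] - 1 - hi[a]) for a in range(3)]
        (x0, x1), (y0, y1), (z0, z1) = full
        bx, by, bz, sad = _kernels.sad_scan_masked(
            grid.intensity, source_known, t_off, t_val, forbid,
            x0, x1, y0, y1, z0, z1)
    if bx < 0:
        raise FillError(f"no source candidate for fill region at {target.center}")
    return (int(bx), int(by), int(bz)), float(sad)


def copy_and_update(grid: VoxelGrid, confidence_field: np.ndarray,
                    target_center: tuple[int, int, int],
                    source_center: tuple[int, int, int],
                    patch: PatchSpec) -> list[tuple[int, int, int]]:
    """Copy source intensities into the vacant target voxels.

    Newly filled voxels become known and inherit the target center's
    confidence at selection time. Returns the list of filled voxels.
    """
    filled = []
    tc = np.asarray(target_center)
    sc = np.asarray(source_center)
    cval = confidence_field[tuple(tc)]
    for dx in range(patch.lo[0], patch.hi[0] + 1):
        for dy in range(patch.lo[1], patch.hi[1] + 1):
            for dz in range(patch.lo[2], patch.hi[2] + 1):
                t = (tc[0] + dx, tc[1] + dy, tc[2] + dz)
                if grid.known_mask[t]:
                    continue
                s = (sc[0] + dx, sc[1] + dy, sc[2] + dz)
                grid.intensity[t] = grid.intensity[s]
                grid.known_mask[t] = True
                confidence_field[t] = cval
                filled.append((int(t[0]), int(t[1]), int(t[2])))
    return filled


def hole_fill(grid: VoxelGrid, patch_size: int = PATCH_SIZE,
              search_window: int = 0, alpha_norm: float = ALPHA_NORM,
              data_floor: float = DATA_FLOOR,
              confidence_field: np.ndarray | None = None,
              log: list | None = None, callback=None) -> VoxelGrid:
    """Fill every vacant voxel by greedy highest-priority patch copying.

    Deterministic for a fixed input; each iteration fills at least the
    front voxel it selects, so the vacant count strictly decreases and the
    loop terminates. ``callback(grid, confidence, state)`` runs after each
    iteration with the live priority table {voxel: (C, D, G, P)}; returning
    a truthy value stops the fill early.
    """
    known = grid.known_mask
    if not known.any():
        raise ValueError("cannot hole-fill an all-vacant grid")
    if known.all():
        return grid
    half = patch_size // 2
    conf = confidence_field if confidence_field is not None \
        else known.astype(float)
    source_known = known.copy()  # Phi = I - Omega, frozen before filling

    dims = grid.dims

    def _terms(pts: np.ndarray):
        return _kernels.priority_terms(
            grid.intensity, grid.known_mask, conf, pts, half,
            float(alpha_norm), float(data_floor))

    pts = _front_points(grid.known_mask)
    C, D, G = _terms(pts)
    state = {tuple(p): (C[i], D[i], G[i], C[i] * D[i] * G[i])
             for i, p in enumerate(pts)}
    n_iter = 0
    while state:
        # argmax priority, ties -> smallest linearized index
        p_best = None
        best_p = -np.inf
        best_lin = None
        for p, (_, _, _, P) in state.items():
            lin = _lin_index(p, dims)
            if P > best_p or (P == best_p and lin < best_lin):
                best_p = P
                best_lin = lin
                p_best = p
        cb = state[p_best][0]
        patch = make_patch(grid, p_best, patch_size)
        src, _sad = best_match(grid, patch, search_window=search_window,
                               source_known=source_known)
        conf[p_best] = cb  # newly filled voxels inherit C(p_best)
        copy_and_update(grid, conf, p_best, src, patch)
        n_iter += 1
        # local priority update: refresh front voxels within one patch width
        new_pts = _front_points(grid.known_mask)
        new_set = set(map(tuple, new_pts))
        for p in [p for p in state if p not in new_set]:
            del state[p]
        pb = np.asarray(p_best)
        near = [p for p in new_set
                if np.max(np.abs(np.asarray(p) - pb)) <= patch_size
                or p not in state]
        if near:
            arr = np.asarray(near, dtype=np.int64)
            C, D, G = _terms(arr)
            for i, p in enumerate(near):
                state[p] = (C[i], D[i], G[i], C[i] * D[i] * G[i])
        if callback is not None and callback(grid, conf, dict(state)):
            if log is not None:
                log.append({"hole_fill_iterations": n_iter})
            return grid
    if log is not None:
        log.append({"hole_fill_iterations": n_iter})
    assert grid.known_mask.all()
    return grid
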