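"""Synthetic phantoms, freehand sweeps, carved vacancies, and speckle.

This module generates everything the reconstruction pipeline consumes so the
package is testable end to end without external scan data: a textured
phantom volume standing in for a tissue-mimicking (PVA-cryogel-style)
phantom, a jittered linear or fan sweep of posed B-scan frames sampled from
it, carved vacant regions (cubes, cuboids, spheres, ellipsoids,
tetrahedra), contiguous-frame removal, and multiplicative speckle noise.

Everything is deterministic given its spec and seed. World coordinates of
phantoms are voxel-index coordinates (1 mm isotropic spacing, origin 0).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .geometry import PosedSlice, RigidPose

__all__ = [
    "PhantomSpec",
    "make_phantom",
    "default_phantom",
    "shape_mask",
    "carve",
    "simulate_sweep",
    "remove_slices",
    "add_speckle",
]


@dataclass
class PhantomSpec:
    """Recipe for a synthetic phantom volume.

    ``structures`` is a list of primitive dicts (see ``shape_mask``) each
    with an ``intensity``; ``texture`` selects the background field;
    ``speckle`` is the multiplicative noise scale applied last.
    """

    dims: tuple[int, int, int] = (64, 64, 64)
    structures: list = field(default_factory=list)
    texture: dict = field(default_factory=lambda: {"kind": "constant", "level": 100.0})
    speckle: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.dims = tuple(int(d) for d in self.dims)
        if any(d < 8 for d in self.dims):
            raise ValueError("phantom dims must be >= 8 per axis")
        for s in self.structures:
            if not 0 <= s.get("intensity", 0) <= 255:
                raise ValueError("structure intensities must lie in [0, 255]")
        if self.texture.get("kind") == "periodic":
            p = int(self.texture.get("period", 4))
            if any(d % p for d in self.dims):
                raise ValueError("period must divide the phantom dims")
        if self.speckle < 0:
            raise ValueError("speckle scale must be >= 0")


def shape_mask(spec: dict, dims: tuple[int, int, int]) -> np.ndarray:
    """Rasterize a primitive into a boolean mask; out-of-bounds shapes are
    a domain error.

    Specs: ``{"shape": "cube", "size": a, "center": c}``,
    ``{"shape": "cuboid", "size": (a, b, c), "center": c}``,
    ``{"shape": "sphere", "radius": r, "center": c}``,
    ``{"shape": "ellipsoid", "semi_axes": (a, b, c), "center": c}``,
    ``{"shape": "tetrahedron", "vertices": 4x3}``.
    Cubes/cuboids are axis-aligned index boxes starting at
    ``center - size//2`` so a cube of edge a covers exactly a^3 voxels.
    """
    dims = tuple(dims)
    kind = spec["shape"]
    mask = np.zeros(dims, dtype=bool)
    if kind in ("cube", "cuboid"):
        size = spec["size"]
        if np.isscalar(size):
            size = (size, size, size)
        c = np.asarray(spec["center"], dtype=int)
        lo = c - np.asarray(size, dtype=int) // 2
        hi = lo + np.asarray(size, dtype=int)
        if np.any(lo < 0) or np.any(hi > np.asarray(dims)):
            raise ValueError(f"{kind} at {tuple(c)} exceeds volume bounds")
        mask[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] = True
        return mask
    idx = np.indices(dims, dtype=float)
    if kind == "sphere":
        c = np.asarray(spec["center"], dtype=float)
        r = float(spec["radius"])
        if np.any(c - r < 0) or np.any(c + r > np.asarray(dims) - 1):
            raise ValueError(f"sphere at {tuple(c)} exceeds volume bounds")
        d2 = sum((idx[a] - c[a]) ** 2 for a in range(3))
        return d2 <= r * r
    if kind == "ellipsoid":
        c = np.asarray(spec["center"], dtype=float)
        ax = np.asarray(spec["semi_axes"], dtype=float)
        if np.any(c - ax < 0) or np.any(c + ax > np.asarray(dims) - 1):
            raise ValueError(f"ellipsoid at {tuple(c)} exceeds volume bounds")
        q = sum(((idx[a] - c[a]) / ax[a]) ** 2 for a in range(3))
        return q <= 1.0
    if kind == "tetrahedron":
        verts = np.asarray(spec["vertices"], dtype=float)
        if verts.shape != (4, 3):
            raise ValueError("tetrahedron needs 4 vertices")
        if np.any(verts < 0) or np.any(verts > np.asarray(dims) - 1):
            raise ValueError("tetrahedron vertices exceed volume bounds")
        # barycentric coordinates: p inside iff all coords in [0, 1]
        T = (verts[1:] - verts[0]).T  # 3x3
        pts = np.stack([idx[a].ravel() for a in range(3)], axis=0)
        lam = np.linalg.solve(T, pts - verts[0][:, None])
        inside = np.all(lam >= 0, axis=0) & (lam.sum(axis=0) <= 1.0)
        return inside.reshape(dims)
    raise ValueError(f"unknown shape kind: {kind}")


def make_phantom(spec: PhantomSpec) -> np.ndarray:
    """Deterministic phantom volume in [0, 255] for a given spec and seed."""
    rng = np.random.default_rng(spec.seed)
    kind = spec.texture.get("kind", "constant")
    if kind == "constant":
        vol = np.full(spec.dims, float(spec.texture.get("level", 100.0)))
    elif kind == "smooth":
        vol = np.full(spec.dims, float(spec.texture.get("level", 100.0)))
    elif kind == "periodic":
        p = int(spec.texture.get("period", 4))
        lo = float(spec.texture.get("low", 20.0))
        hi = float(spec.texture.get("high", 235.0))
        tile = rng.integers(int(lo), int(hi) + 1, size=(p, p, p)).astype(float)
        reps = tuple(d // p for d in spec.dims)
        vol = np.tile(tile, reps)
    else:
        raise ValueError(f"unknown texture kind: {kind}")
    for s in spec.structures:
        vol[shape_mask(s, spec.dims)] = float(s["intensity"])
    if kind == "smooth":
        amp = float(spec.texture.get("amplitude", 20.0))
        sigma = float(spec.texture.get("sigma", 2.0))
        noise = ndimage.gaussian_filter(rng.standard_normal(spec.dims), sigma)
        sd = noise.std()
        if sd > 0:
            vol = vol + amp * noise / sd
    if spec.speckle > 0:
        vol = vol * (1.0 + spec.speckle * rng.standard_normal(spec.dims))
    return np.clip(vol, 0.0, 255.0)


def default_phantom(dims=(64, 64, 64), seed: int = 0) -> np.ndarray:
    """Structure-dense study phantom emulating tissue-mimicking brain
    phantoms and in vivo scans.

    Many primitives of varied echogenicity (hypo- to hyperechoic) are placed
    at random so that anatomical edges occur at the scale of typical carved
    holes, over a background with spatially correlated texture — the
    compounded-speckle appearance of a reconstructed ultrasound volume.
    Deterministic per seed.
    """
    dims = tuple(dims)
    rng = np.random.default_rng(seed)
    n = min(dims)

    def _jitter(lo, hi):
        if hi <= lo:  # degenerate range at small volume sizes
            return int(lo)
        return int(rng.integers(lo, hi + 1))

    # anatomy-scale structures: every primitive spans a large fraction of
    # the volume so that carved holes are small relative to the structures
    # crossing them and boundary continuation is informative
    structures = []
    # ventricle-like large bright body
    r = _jitter(n // 3 - 2, n // 3 + 2)
    structures.append({
        "shape": "sphere", "radius": r,
        "center": tuple(_jitter(r, d - 1 - r) for d in dims),
        "intensity": 160.0})
    # hypoechoic lobe
    ax = tuple(_jitter(dims[a] // 4, dims[a] // 3) for a in range(3))
    structures.append({
        "shape": "ellipsoid", "semi_axes": ax,
        "center": tuple(_jitter(ax[a], dims[a] - 1 - ax[a]) for a in range(3)),
        "intensity": 40.0})
    # fascia-like slab spanning x and y
    th = _jitter(6, 9)
    structures.append({
        "shape": "cuboid", "size": (dims[0] - 2, dims[1] - 2, th),
        "center": (dims[0] // 2, dims[1] // 2,
                   _jitter(th, dims[2] - 1 - th)),
        "intensity": 120.0})
    # two vessel-like tubes through the whole volume
    for intensity in (200.0, 30.0):
        w = _jitter(5, 8)
        axis = int(rng.integers(0, 3))
        size = [w, w, w]
        size[axis] = dims[axis] - 2
        c = [0, 0, 0]
        for a in range(3):
            c[a] = dims[a] // 2 if a == axis else _jitter(w, dims[a] - 1 - w)
        structures.append({"shape": "cuboid", "size": tuple(size),
                           "center": tuple(c), "intensity": intensity})
    spec = PhantomSpec(
        dims=dims,
        structures=structures,
        texture={"kind": "constant", "level": 80.0},
        speckle=0.0,
        seed=seed + 1,
    )
    levels = make_phantom(spec)
    # point-spread-function blur: compounded ultrasound volumes never have
    # voxel-sharp edges
    levels = ndimage.gaussian_filter(levels, 0.8)
    # stationary speckle texture: fully developed speckle is statistically
    # stationary across the volume, idealized here as a repeating random
    # tile multiplying the echogenicity level field
    period = 8
    tile = 0.85 + 0.3 * rng.random((period, period, period))
    reps = tuple(int(np.ceil(d / period)) for d in dims)
    texture = np.tile(tile, reps)[: dims[0], : dims[1], : dims[2]]
    vol = levels * texture
    # smooth intensity modulation (attenuation / time-gain compensation /
    # beam-profile effects): a low-frequency additive bias field
    bias = ndimage.gaussian_filter(rng.standard_normal(dims), min(dims) / 6)
    sd = bias.std()
    if sd > 0:
        vol = vol + 12.0 * bias / sd
    return np.clip(vol, 0.0, 255.0)


def carve(volume: np.ndarray, spec: dict) -> tuple[np.ndarray, np.ndarray]:
    """Mark the voxels inside a primitive vacant.

    Returns (carved volume with vacant voxels zeroed, vacancy mask).
    """
    volume = np.asarray(volume, dtype=float)
    mask = shape_mask(spec, volume.shape)
    carved = np.where(mask, 0.0, volume)
    return carved, mask


def simulate_sweep(volume: np.ndarray, n_frames: int,
                   trajectory: str = "linear",
                   jitter: tuple[float, float] = (0.0, 0.0),
                   seed: int = 0,
                   spacing: tuple[float, float] = (1.0, 1.0)) -> list[PosedSlice]:
    """Sample a posed B-scan sweep from a phantom volume.

    ``trajectory`` is ``linear`` (translation along z across the volume) or
    ``fan`` (rotation about the x axis through the volume center, +-15 deg);
    ``jitter = (mm, degrees)`` perturbs each frame's pose. Frames are sampled
    by trilinear interpolation; a frame plane entirely outside the volume
    yields a blank frame with a warning.
    """
    from scipy.spatial.transform import Rotation

    volume = np.asarray(volume, dtype=float)
    nx, ny, nz = volume.shape
    if n_frames == 0:
        return []
    rng = np.random.default_rng(seed)
    n_u, n_v = nx, ny
    su, sv = spacing
    zs = np.linspace(0.0, nz - 1.0, n_frames) if n_frames > 1 else [(nz - 1) / 2.0]
    if trajectory == "fan":
        angles = np.linspace(-15.0, 15.0, n_frames)
    elif trajectory != "linear":
        raise ValueError(f"unknown trajectory: {trajectory}")
    center = np.array([(nx - 1) / 2.0, (ny - 1) / 2.0, (nz - 1) / 2.0])
    slices = []
    uu, vv = np.meshgrid(np.arange(n_u, dtype=float), np.arange(n_v, dtype=float))
    for j in range(n_frames):
        # sensor origin chosen so pixel (u, v) sits at (u*su, v*sv, z_j)
        origin = (n_u / 2.0 * su, n_v * sv, float(zs[j]))
        R = np.eye(3)
        T = np.zeros(3)
        if trajectory == "fan":
            rot = Rotation.from_euler("x", angles[j], degrees=True)
            R = rot.as_matrix()
            T = center - R @ center
        if jitter[0] > 0 or jitter[1] > 0:
            drot = Rotation.from_rotvec(
                np.deg2rad(jitter[1]) * rng.standard_normal(3))
            R = drot.as_matrix() @ R
            T = T + jitter[0] * rng.standard_normal(3)
            T = T + center - drot.as_matrix() @ center  # jitter about the center
        pose = RigidPose(R=R, T=T)
        sensor = np.stack(
            [origin[0] + (uu - n_u / 2.0) * su,
             origin[1] - (n_v - vv) * sv,
             np.full_like(uu, origin[2])], axis=-1)
        world = pose.apply(sensor.reshape(-1, 3))
        coords = world.T  # phantom world == voxel coords
        pix = ndimage.map_coordinates(volume, coords, order=1,
                                      mode="constant", cval=0.0)
        pix = pix.reshape(n_v, n_u)
        outside = np.any(coords < -0.5, axis=0) | np.any(
            coords > (np.array([nx, ny, nz])[:, None] - 0.5), axis=0)
        if outside.all():
            warnings.warn(f"frame {j} lies entirely outside the volume")
        slices.append(PosedSlice(np.clip(pix, 0.0, 255.0), frame_index=j,
                                 spacing=(su, sv), sensor_origin=origin,
                                 pose=pose))
    return slices


def remove_slices(stack: list[PosedSlice], start: int, k: int) -> list[PosedSlice]:
    """Drop frames [start, start + k) from a sweep (1 <= k <= 8)."""
    if not 1 <= k <= 8:
        raise ValueError("k must be in 1..8")
    if start < 0 or start + k > len(stack):
        raise ValueError(f"removal range [{start}, {start + k}) outside stack "
                         f"of {len(stack)} frames")
    return stack[:start] + stack[start + k:]


def add_speckle(data, scale: float, seed: int = 0):
    """Multiplicative Gaussian speckle: I' = clip(I * (1 + scale * eta)).

    Accepts a volume array or a list of PosedSlices.
    """
    if scale < 0:
        raise ValueError("speckle scale must be >= 0")
    rng = np.random.default_rng(seed)
    if isinstance(data, np.ndarray):
        return np.clip(data * (1.0 + scale * rng.standard_normal(data.shape)),
                       0.0, 255.0)
    out = []
    for s in data:
        noisy = np.clip(
            s.pixels * (1.0 + scale * rng.standard_normal(s.pixels.shape)),
            0.0, 255.0)
        out.append(PosedSlice(noisy, frame_index=s.frame_index,
                              spacing=s.spacing, sensor_origin=s.sensor_origin,
                              pose=s.pose))
    return out
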