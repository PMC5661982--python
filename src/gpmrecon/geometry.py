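"""Posed B-scan slices, the reconstruction voxel grid, and coordinate transforms.

A freehand acquisition produces a sequence of 2D grayscale B-scans, each
tagged by a tracker with a rigid pose (position + orientation) and a pixel
spacing. Three coordinate frames are involved:

* the slice frame ``O'-UV`` (pixel indices ``u`` along width, ``v`` along
  height),
* the sensor frame ``O_S - X_S Y_S Z_S`` of the tracking device, and
* the world frame ``O-XYZ`` of the reconstruction volume.

A pixel ``(u, v)`` of slice ``j`` maps into the sensor frame as

    X = X_Sj + (u - N_jU / 2) * S_jU
    Y = Y_Sj - (N_jV - v)     * S_jV
    Z = Z_Sj

(``N_jU/2`` is real division) and then into the world frame by the rigid
transform ``p -> R p + T``.

The voxel grid uses a voxel-center convention: voxel index ``i`` on an axis
covers the world interval ``[origin + i*s - s/2, origin + i*s + s/2)`` where
``s`` is the voxel spacing; nearest-voxel mapping rounds half up. Indices are
0-based and volumes are stored as ``array[ix, iy, iz]``.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PosedSlice",
    "RigidPose",
    "VoxelGrid",
    "FormatError",
    "pixel_to_sensor",
    "sensor_to_world",
    "world_to_voxel",
    "quaternion_to_matrix",
    "read_slice_stack",
    "read_volume",
    "write_volume",
    "fit_grid_to_slices",
]

_ORTHO_TOL = 1e-9


class FormatError(ValueError):
    """Raised for malformed slice stacks, pose sidecars, or volume files."""


def _check_rotation(R: np.ndarray, tol: float = _ORTHO_TOL) -> np.ndarray:
    R = np.asarray(R, dtype=float)
    if R.shape != (3, 3):
        raise ValueError(f"rotation must be 3x3, got {R.shape}")
    if not np.allclose(R.T @ R, np.eye(3), atol=tol):
        raise ValueError("rotation matrix is not orthonormal")
    if np.linalg.det(R) < 0:
        raise ValueError("rotation matrix has determinant -1 (improper)")
    return R


def quaternion_to_matrix(q: Sequence[float], tol: float = 1e-6) -> np.ndarray:
    """Convert a unit quaternion ``(w, x, y, z)`` to a rotation matrix.

    Quaternions within ``tol`` of unit norm are normalized; anything further
    off is rejected, since tracker logs should contain unit quaternions.
    """
    q = np.asarray(q, dtype=float)
    if q.shape != (4,):
        raise ValueError("quaternion must have 4 components (w, x, y, z)")
    norm = float(np.linalg.norm(q))
    if abs(norm - 1.0) > tol:
        raise FormatError(f"non-unit quaternion (norm {norm:.6g})")
    w, x, y, z = q / norm
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


@dataclass
class RigidPose:
    """Rigid transform from the sensor frame to the world frame.

    The homogeneous form is ``[[R, T], [0, r]]`` with ``r = 1`` (the scalar
    block is never assigned a value by tracker conventions, so the standard
    homogeneous 1 is used); the transform is applied as ``R p + T``.
    """

    R: np.ndarray = field(default_factory=lambda: np.eye(3))
    T: np.ndarray = field(default_factory=lambda: np.zeros(3))
    r: float = 1.0

    def __post_init__(self) -> None:
        self.R = _check_rotation(self.R)
        self.T = np.asarray(self.T, dtype=float).reshape(3)
        if self.r == 0:
            raise ValueError("homogeneous scalar r must be nonzero")

    def apply(self, p: np.ndarray) -> np.ndarray:
        p = np.asarray(p, dtype=float)
        return p @ self.R.T + self.T


@dataclass
class PosedSlice:
    """One 2D B-scan with its pose metadata.

    ``pixels[v, u]`` holds intensities on a 0-255 scale; ``spacing`` is
    (S_U, S_V) in mm/pixel; ``sensor_origin`` is the slice position
    (X_S, Y_S, Z_S) in the sensor frame; ``pose`` carries the slice's
    sensor-to-world rigid transform.
    """

    pixels: np.ndarray
    frame_index: int = 0
    spacing: tuple[float, float] = (1.0, 1.0)
    sensor_origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    pose: RigidPose = field(default_factory=RigidPose)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2 or min(self.pixels.shape) < 1:
            raise ValueError("pixels must be a non-empty 2D array")
        if not np.all(np.isfinite(self.pixels)) or np.any(self.pixels < 0):
            raise ValueError("intensities must be finite and >= 0")
        if self.spacing[0] <= 0 or self.spacing[1] <= 0:
            raise ValueError("pixel spacings must be positive")

    @property
    def n_u(self) -> int:
        return self.pixels.shape[1]

    @property
    def n_v(self) -> int:
        return self.pixels.shape[0]

    def world_positions(self) -> np.ndarray:
        """World coordinates of every pixel center, shape (n_v, n_u, 3)."""
        u = np.arange(self.n_u, dtype=float)
        v = np.arange(self.n_v, dtype=float)
        uu, vv = np.meshgrid(u, v)
        su, sv = self.spacing
        ox, oy, oz = self.sensor_origin
        sensor = np.stack(
            [
                ox + (uu - self.n_u / 2.0) * su,
                oy - (self.n_v - vv) * sv,
                np.full_like(uu, oz),
            ],
            axis=-1,
        )
        return self.pose.apply(sensor.reshape(-1, 3)).reshape(self.n_v, self.n_u, 3)


def pixel_to_sensor(slc: PosedSlice, u: float, v: float) -> np.ndarray:
    """Sensor-frame position (mm) of pixel ``(u, v)`` of a posed slice."""
    if not (0 <= u < slc.n_u) or not (0 <= v < slc.n_v):
        raise IndexError(f"pixel ({u}, {v}) outside slice {slc.n_u}x{slc.n_v}")
    su, sv = slc.spacing
    ox, oy, oz = slc.sensor_origin
    return np.array(
        [ox + (u - slc.n_u / 2.0) * su, oy - (slc.n_v - v) * sv, oz]
    )


def sensor_to_world(pose: RigidPose, p: np.ndarray) -> np.ndarray:
    """Apply the rigid sensor-to-world transform ``R p + T``."""
    p = np.asarray(p, dtype=float)
    if not np.all(np.isfinite(p)):
        raise ValueError("point must be finite")
    return pose.apply(p)


@dataclass
class VoxelGrid:
    """The 3D reconstruction lattice.

    ``intensity`` and ``known_mask`` are ``(nx, ny, nz)`` arrays; vacant
    voxels have ``known_mask == False``. The bin-filling accumulators
    (numerator/denominator sums, direct-hit sums/counts) live here so that
    accumulation over many slices can be incremental.
    """

    dims: tuple[int, int, int]
    spacing: float = 1.0
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    intensity: np.ndarray | None = None
    known_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.dims = tuple(int(d) for d in self.dims)
        if any(d < 1 for d in self.dims):
            raise ValueError("grid dims must be >= 1 on each axis")
        if self.spacing <= 0:
            raise ValueError("voxel spacing must be positive")
        self.origin = tuple(float(o) for o in self.origin)
        if self.intensity is None:
            self.intensity = np.zeros(self.dims, dtype=float)
        else:
            self.intensity = np.asarray(self.intensity, dtype=float)
            if self.intensity.shape != self.dims:
                raise ValueError("intensity shape does not match dims")
        if self.known_mask is None:
            self.known_mask = np.zeros(self.dims, dtype=bool)
        else:
            self.known_mask = np.asarray(self.known_mask, dtype=bool)
            if self.known_mask.shape != self.dims:
                raise ValueError("known_mask shape does not match dims")
        # bin-filling accumulators (allocated lazily by accumulate())
        self.numerator: np.ndarray | None = None
        self.denominator: np.ndarray | None = None
        self.denominator_literal: np.ndarray | None = None
        self.hit_sum: np.ndarray | None = None
        self.hit_count: np.ndarray | None = None
        self.contrib_min: np.ndarray | None = None
        self.contrib_max: np.ndarray | None = None

    def copy(self) -> "VoxelGrid":
        g = VoxelGrid(
            self.dims, self.spacing, self.origin,
            self.intensity.copy(), self.known_mask.copy(),
        )
        for name in ("numerator", "denominator", "denominator_literal",
                     "hit_sum", "hit_count", "contrib_min", "contrib_max"):
            a = getattr(self, name)
            setattr(g, name, None if a is None else a.copy())
        return g

    def voxel_centers_axis(self, axis: int) -> np.ndarray:
        return self.origin[axis] + np.arange(self.dims[axis]) * self.spacing


def world_to_voxel(grid: VoxelGrid, p: np.ndarray) -> tuple[tuple[int, int, int], bool]:
    """Nearest-voxel index for a world point, with an inside-bounds flag.

    Rounds half up under the voxel-center convention; out-of-bounds points
    get the same arithmetic with ``inside == False``.
    """
    p = np.asarray(p, dtype=float)
    idx = np.floor((p - np.asarray(grid.origin)) / grid.spacing + 0.5).astype(int)
    inside = bool(np.all(idx >= 0) and np.all(idx < np.asarray(grid.dims)))
    return (int(idx[0]), int(idx[1]), int(idx[2])), inside


def fit_grid_to_slices(
    slices: Sequence[PosedSlice], spacing: float | None = None, pad: int = 1
) -> VoxelGrid:
    """Auto-fit a grid as the padded bounding box of all slice corners.

    Spacing defaults to the finest pixel spacing across the stack so that
    slice detail is not lost in the lattice.
    """
    if not slices:
        raise ValueError("cannot fit a grid to an empty slice stack")
    if spacing is None:
        spacing = min(min(s.spacing) for s in slices)
    corners = []
    for s in slices:
        for u in (0, s.n_u - 1):
            for v in (0, s.n_v - 1):
                corners.append(sensor_to_world(s.pose, pixel_to_sensor(s, u, v)))
    corners = np.asarray(corners)
    lo = corners.min(axis=0) - pad * spacing
    hi = corners.max(axis=0) + pad * spacing
    dims = tuple(int(np.ceil((hi[i] - lo[i]) / spacing)) + 1 for i in range(3))
    return VoxelGrid(dims, spacing=spacing, origin=tuple(lo))


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_POSE_COLUMNS = ["frame", "x", "y", "z", "qw", "qx", "qy", "qz", "su", "sv"]


def _read_pose_table(pose_path: str | Path) -> list[dict]:
    pose_path = Path(pose_path)
    if pose_path.suffix.lower() == ".json":
        with open(pose_path) as fh:
            rows = json.load(fh)
        if not isinstance(rows, list):
            raise FormatError("JSON pose sidecar must be a list of frame records")
        return rows
    df = pd.read_csv(pose_path)
    missing = [c for c in _POSE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"pose CSV missing columns: {missing}")
    return df.to_dict("records")


def _pose_from_record(rec: dict, frame: int) -> tuple[RigidPose, tuple, tuple]:
    try:
        origin = (float(rec["x"]), float(rec["y"]), float(rec["z"]))
        spacing = (float(rec["su"]), float(rec["sv"]))
        if "rotation" in rec:
            R = np.asarray(rec["rotation"], dtype=float).reshape(3, 3)
            R = _check_rotation(R, tol=1e-6)
        else:
            R = quaternion_to_matrix(
                [rec["qw"], rec["qx"], rec["qy"], rec["qz"]]
            )
    except (KeyError, ValueError, FormatError) as exc:
        raise FormatError(f"frame {frame}: unparseable pose ({exc})") from exc
    return RigidPose(R=R), origin, spacing


def _load_frames(image_path: str | Path) -> list[np.ndarray]:
    image_path = Path(image_path)
    if image_path.is_dir():
        import imageio.v3 as iio

        files = sorted(
            p for p in image_path.iterdir()
            if p.suffix.lower() in {".png", ".tif", ".tiff"}
        )
        if not files:
            raise FormatError(f"no PNG/TIFF frames in {image_path}")
        return [np.asarray(iio.imread(p), dtype=float) for p in files]
    suffix = "".join(image_path.suffixes).lower()
    if suffix.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        data = np.asanyarray(nib.load(str(image_path)).dataobj).astype(float)
        if data.ndim != 3:
            raise FormatError("NIfTI slice stack must be 3D (frames on axis 2)")
        return [data[:, :, j].T for j in range(data.shape[2])]
    if image_path.suffix.lower() in {".tif", ".tiff"}:
        import tifffile

        data = np.asarray(tifffile.imread(str(image_path)), dtype=float)
        if data.ndim == 2:
            data = data[None]
        return [frame for frame in data]
    raise FormatError(f"unsupported slice stack format: {image_path}")


def read_slice_stack(image_path: str | Path, pose_path: str | Path) -> list[PosedSlice]:
    """Read a stack of B-scan frames plus its pose sidecar into PosedSlices.

    Frames and pose rows are matched by ``frame`` index; a count mismatch is
    a format error naming the discrepancy.
    """
    frames = _load_frames(image_path)
    records = _read_pose_table(pose_path)
    if len(records) != len(frames):
        raise FormatError(
            f"pose sidecar has {len(records)} rows for {len(frames)} frames"
        )
    records = sorted(records, key=lambda r: int(r["frame"]))
    slices = []
    for rec, pix in zip(records, frames):
        frame = int(rec["frame"])
        pose, origin, spacing = _pose_from_record(rec, frame)
        slices.append(
            PosedSlice(pix, frame_index=frame, spacing=spacing,
                       sensor_origin=origin, pose=pose)
        )
    return slices


def write_pose_csv(slices: Sequence[PosedSlice], path: str | Path) -> None:
    """Write a pose sidecar CSV for a slice stack (quaternion wxyz form)."""
    from scipy.spatial.transform import Rotation

    rows = []
    for s in slices:
        qx, qy, qz, qw = Rotation.from_matrix(s.pose.R).as_quat()
        rows.append(
            dict(frame=s.frame_index, x=s.sensor_origin[0], y=s.sensor_origin[1],
                 z=s.sensor_origin[2], qw=qw, qx=qx, qy=qy, qz=qz,
                 su=s.spacing[0], sv=s.spacing[1])
        )
    pd.DataFrame(rows, columns=_POSE_COLUMNS).to_csv(path, index=False)


def write_volume(grid: VoxelGrid, path: str | Path, dtype: str = "float32") -> None:
    """Write a grid as NIfTI (.nii/.nii.gz) or MetaImage (.mha/.mhd).

    ``dtype`` selects ``uint8`` or ``float32`` storage. Spacing and origin go
    into the header; the write/read round trip is lossless for integer data.
    """
    path = Path(path)
    if dtype not in {"uint8", "float32"}:
        raise ValueError("dtype must be 'uint8' or 'float32'")
    data = grid.intensity.astype(dtype)
    name = path.name.lower()
    if name.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        affine = np.diag([grid.spacing] * 3 + [1.0])
        affine[:3, 3] = grid.origin
        nib.save(nib.Nifti1Image(data, affine), str(path))
    elif name.endswith((".mha", ".mhd")):
        import SimpleITK as sitk

        img = sitk.GetImageFromArray(np.ascontiguousarray(data.T))
        img.SetSpacing((grid.spacing,) * 3)
        img.SetOrigin(grid.origin)
        sitk.WriteImage(img, str(path))
    else:
        raise FormatError(f"unsupported volume format: {path}")


def read_volume(path: str | Path) -> VoxelGrid:
    """Read a NIfTI or MetaImage volume back into a fully-known VoxelGrid."""
    path = Path(path)
    name = path.name.lower()
    if name.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj).astype(float)
        affine = img.affine
        spacing = float(affine[0, 0])
        origin = tuple(affine[:3, 3])
    elif name.endswith((".mha", ".mhd")):
        import SimpleITK as sitk

        img = sitk.ReadImage(str(path))
        data = sitk.GetArrayFromImage(img).T.astype(float)
        spacing = float(img.GetSpacing()[0])
        origin = tuple(img.GetOrigin())
    else:
        raise FormatError(f"unsupported volume format: {path}")
    grid = VoxelGrid(data.shape, spacing=spacing, origin=origin,
                     intensity=data, known_mask=np.ones(data.shape, bool))
    return grid
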