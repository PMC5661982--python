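"""End-to-end orchestration: read -> geometry -> bin-filling -> hole-filling
-> write, plus the evaluation protocol driver.

The run configuration is validated up front (unknown keys rejected) and a
structured run log records voxel counts and parameters. The reconstruction
itself contains no randomness; ``seed`` only governs synthetic fixtures and
protocol case placement.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, fields
from pathlib import Path

import numpy as np

from . import baselines, binfill, holefill
from .geometry import VoxelGrid, fit_grid_to_slices, read_slice_stack, \
    read_volume, write_volume

logger = logging.getLogger("gpmrecon")

__all__ = ["RunConfig", "reconstruct", "fill_volume", "evaluate"]


@dataclass
class RunConfig:
    """Validated configuration for a reconstruction or evaluation run."""

    # inputs
    slices: str | None = None          # slice stack (dir, TIFF, NIfTI)
    poses: str | None = None           # pose sidecar (CSV/JSON)
    volume: str | None = None          # dense volume for fill/evaluate mode
    mask: str | None = None            # vacancy mask volume for fill mode
    # grid geometry overrides (auto-fitted when absent)
    grid_spacing: float | None = None
    grid_dims: tuple | None = None
    grid_origin: tuple | None = None
    # bin-filling
    max_class: int = 8
    eq11_literal: bool = False
    direct_hit_fraction: float = 0.5
    # hole-filling
    patch_size: int = holefill.PATCH_SIZE
    search_window: int = 0
    alpha_norm: float = holefill.ALPHA_NORM
    data_floor: float = holefill.DATA_FLOOR
    dw_radius: int = baselines.DW_RADIUS
    # evaluation
    protocol: list | None = None
    methods: tuple = ("gpm",)
    # outputs / misc
    output: str | None = None
    output_dtype: str = "float32"
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.patch_size % 2 != 1 or self.patch_size < 3:
            raise ValueError("patch_size must be an odd integer >= 3")
        if not 0 < self.direct_hit_fraction <= 1:
            raise ValueError("direct_hit_fraction must be in (0, 1]")
        if self.alpha_norm <= 0 or self.data_floor < 0:
            raise ValueError("alpha_norm must be > 0 and data_floor >= 0")
        unknown = [m for m in self.methods if m not in baselines._METHODS]
        if unknown:
            raise ValueError(f"unknown method names: {unknown}")

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        valid = {f.name for f in fields(cls)}
        unknown = set(d) - valid
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix.lower() in {".yaml", ".yml"}:
            import yaml

            return cls.from_dict(yaml.safe_load(text) or {})
        return cls.from_dict(json.loads(text))

    def method_params(self) -> dict:
        return dict(patch_size=self.patch_size, search_window=self.search_window,
                    alpha_norm=self.alpha_norm, data_floor=self.data_floor,
                    dw_radius=self.dw_radius)


def _setup_logging(config: RunConfig) -> None:
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), 20))


def reconstruct(config: RunConfig, slices=None) -> tuple[VoxelGrid, dict]:
    """Full pipeline from posed slices to a fully-known volume.

    ``slices`` may be passed directly (e.g. synthetic sweeps); otherwise the
    configured stack and pose sidecar are read. Returns the filled grid and
    a run log with voxel counts and parameters.
    """
    _setup_logging(config)
    if slices is None:
        if not config.slices or not config.poses:
            raise ValueError("reconstruct needs slice stack + pose sidecar paths")
        slices = read_slice_stack(config.slices, config.poses)
    if not slices:
        raise ValueError("empty slice stack")
    if config.grid_dims is not None:
        grid = VoxelGrid(tuple(config.grid_dims),
                         spacing=config.grid_spacing or 1.0,
                         origin=tuple(config.grid_origin or (0.0, 0.0, 0.0)))
    else:
        grid = fit_grid_to_slices(slices, spacing=config.grid_spacing)
    logger.info("grid %s spacing %.3g origin %s", grid.dims, grid.spacing,
                grid.origin)
    binfill.bin_fill(grid, slices, eq11_literal=config.eq11_literal,
                     direct_hit_fraction=config.direct_hit_fraction)
    known_after_binning = int(grid.known_mask.sum())
    fill_log: list = []
    holefill.hole_fill(grid, patch_size=config.patch_size,
                       search_window=config.search_window,
                       alpha_norm=config.alpha_norm,
                       data_floor=config.data_floor, log=fill_log)
    total = int(np.prod(grid.dims))
    log = {
        "n_slices": len(slices),
        "grid_dims": list(grid.dims),
        "grid_spacing": grid.spacing,
        "voxels_total": total,
        "voxels_known_after_binning": known_after_binning,
        "voxels_hole_filled": total - known_after_binning,
        "hole_fill_iterations": fill_log[0]["hole_fill_iterations"] if fill_log else 0,
        "parameters": {k: v for k, v in asdict(config).items()
                       if k in {"max_class", "eq11_literal", "direct_hit_fraction",
                                "patch_size", "search_window", "alpha_norm",
                                "data_floor"}},
    }
    logger.info("bin-filling known %d/%d; hole-filling filled %d voxels in %d "
                "iterations", known_after_binning, total,
                log["voxels_hole_filled"], log["hole_fill_iterations"])
    if config.output:
        write_volume(grid, config.output, dtype=config.output_dtype)
    return grid, log


def fill_volume(config: RunConfig) -> tuple[VoxelGrid, dict]:
    """Standalone hole-filling: dense volume + vacancy mask in, filled out."""
    _setup_logging(config)
    if not config.volume or not config.mask:
        raise ValueError("fill mode needs volume and mask paths")
    vol = read_volume(config.volume)
    mask = read_volume(config.mask)
    vacancy = mask.intensity > 0
    grid = baselines.masked_grid(vol.intensity, vacancy, spacing=vol.spacing)
    grid.origin = vol.origin
    fill_log: list = []
    holefill.hole_fill(grid, patch_size=config.patch_size,
                       search_window=config.search_window,
                       alpha_norm=config.alpha_norm,
                       data_floor=config.data_floor, log=fill_log)
    log = {"voxels_filled": int(vacancy.sum()),
           "hole_fill_iterations": fill_log[0]["hole_fill_iterations"]}
    if config.output:
        write_volume(grid, config.output, dtype=config.output_dtype)
    return grid, log


def evaluate(config: RunConfig, truth: np.ndarray | None = None):
    """Run the carve/fill/score protocol and return (cases, summary) frames."""
    _setup_logging(config)
    if truth is None:
        if not config.volume:
            raise ValueError("evaluate needs a truth volume (path or array)")
        truth = read_volume(config.volume).intensity
    if not config.protocol:
        raise ValueError("evaluate needs a protocol (list of carve cases)")
    reports = baselines.run_protocol(truth, config.protocol,
                                     list(config.methods),
                                     method_params=config.method_params())
    cases, summary = baselines.reports_to_frame(reports)
    if config.output:
        cases.to_csv(config.output, index=False)
        summary.to_csv(str(config.output) + ".summary.csv", index=False)
    return cases, summary
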