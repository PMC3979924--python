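"""ROI sampling and z sum-projection.

The scoring statistic is defined on thin sub-volumes (200 x 200 x 24 um^3 by
default) collapsed to 2-D by summing 13 slices at 2 um intervals along z.
ROIs are drawn uniformly at random (with replacement, overlap permitted)
from the allowed region; origins are snapped to the voxel grid and logged
for audit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .io import ImageVolume, RunConfig

log = logging.getLogger("axonquant")


@dataclass
class ROI:
    """An axis-aligned analysis sub-volume of a parent volume."""
    index: int
    origin_um: tuple[float, float, float]        # (z, y, x)
    size_um: tuple[float, float, float]          # (z, y, x) physical dimensions
    origin_vox: tuple[int, int, int]
    size_vox: tuple[int, int, int]               # z counts planes (inclusive span)
    parent: ImageVolume

    def content(self) -> np.ndarray:
        z0, y0, x0 = self.origin_vox
        nz, ny, nx = self.size_vox
        return self.parent.data[z0:z0 + nz, y0:y0 + ny, x0:x0 + nx]


@dataclass
class ProjectedImage:
    """A 2-D sum projection of an ROI."""
    data: np.ndarray                             # float64 (y, x)
    pixel_spacing_um: tuple[float, float]        # (dy, dx)
    n_slices: int
    slice_interval_um: float
    roi_index: int


def _roi_grid_size(volume: ImageVolume, config: RunConfig) -> tuple[int, int, int]:
    dz, dy, dx = volume.spacing
    nz = int(round(config.roi_thickness_um / dz)) + 1        # inclusive plane span
    ny = int(round(config.roi_edge_um / dy))
    nx = int(round(config.roi_edge_um / dx))
    return nz, ny, nx


def sample_rois(
    volume: ImageVolume,
    config: RunConfig,
    region: dict[str, tuple[float, float]] | None = None,
    seed: int | np.random.Generator | None = None,
) -> list[ROI]:
    """Draw ``config.roi_count`` ROIs uniformly at random within a region.

    ``region`` optionally restricts the sampling window per axis with
    ``{"x": (lo_um, hi_um), ...}`` bands (e.g. an offset band distal to the
    repair site); ROIs must fit entirely inside their band.  Sampling is
    with replacement, reproducible for a fixed seed.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(
        config.seed if seed is None else seed
    )
    nz, ny, nx = _roi_grid_size(volume, config)
    size_vox = (nz, ny, nx)
    shape = volume.data.shape
    if any(s < r for s, r in zip(shape, size_vox)):
        need = tuple(size_vox)
        raise ValueError(
            f"volume shape {shape} cannot contain one ROI of {need} voxels "
            f"({config.roi_edge_um} x {config.roi_edge_um} x {config.roi_thickness_um} um)"
        )
    region = region or {}
    spans = []
    for ax, name in enumerate("zyx"):
        d = volume.spacing[ax]
        lo_vox, hi_vox = 0, shape[ax] - size_vox[ax]        # inclusive origin range
        if name in region and region[name] is not None:
            lo_um, hi_um = region[name]
            lo_vox = max(lo_vox, int(np.ceil(lo_um / d - 1e-9)))
            roi_extent = (size_vox[ax] - 1) * d if ax == 0 else size_vox[ax] * d
            hi_vox = min(hi_vox, int(np.floor((hi_um - roi_extent) / d + 1e-9)))
        if hi_vox < lo_vox:
            raise ValueError(
                f"region too small on axis {name}: ROI needs "
                f"{size_vox[ax]} voxels but the band {region.get(name)} um allows none "
                f"(volume extent {(shape[ax] - 1) * d:.1f} um)"
            )
        spans.append((lo_vox, hi_vox))
    n_positions = int(np.prod([hi - lo + 1 for lo, hi in spans]))
    if n_positions == 1:
        log.warning(
            "region admits exactly one ROI position; returning %d identical copies",
            config.roi_count,
        )
    rois = []
    for i in range(config.roi_count):
        origin_vox = tuple(int(rng.integers(lo, hi + 1)) for lo, hi in spans)
        origin_um = tuple(o * d for o, d in zip(origin_vox, volume.spacing))
        size_um = (config.roi_thickness_um, config.roi_edge_um, config.roi_edge_um)
        rois.append(ROI(i, origin_um, size_um, origin_vox, size_vox, volume))
    log.info("sampled %d ROIs of %s voxels from %d candidate positions",
             len(rois), size_vox, n_positions)
    return rois


def sum_project(
    roi: ROI,
    n_slices: int | None = None,
    interval_um: float | None = None,
) -> ProjectedImage:
    """Collapse an ROI to 2-D by summing slices at fixed z intervals.

    If the native z spacing differs from the requested interval the slices
    are linearly interpolated in z first (logged).  The output is held in a
    wide float type; rescaling happens only at binarization.
    """
    dz, dy, dx = roi.parent.spacing
    nz = roi.size_vox[0]
    if n_slices is None and interval_um is None:
        n_slices, interval_um = nz, dz
    n_slices = int(n_slices if n_slices is not None else nz)
    interval_um = float(interval_um if interval_um is not None else dz)
    if interval_um <= 0 or n_slices < 1:
        raise ValueError("need a positive slice interval and at least one slice")
    span = (n_slices - 1) * interval_um
    thickness = (nz - 1) * dz
    if span > thickness + 1e-9:
        raise ValueError(
            f"{n_slices} slices at {interval_um} um span {span} um, exceeding the "
            f"ROI thickness {thickness} um"
        )
    content = roi.content().astype(np.float64)
    positions = np.arange(n_slices) * interval_um
    idx_f = positions / dz
    if np.allclose(idx_f, np.round(idx_f)):
        planes = content[np.round(idx_f).astype(int)]
    else:
        log.info("native z spacing %.3g um != interval %.3g um: interpolating", dz, interval_um)
        idx0 = np.clip(np.floor(idx_f).astype(int), 0, nz - 2)
        w = idx_f - idx0
        planes = (1 - w)[:, None, None] * content[idx0] + w[:, None, None] * content[idx0 + 1]
    return ProjectedImage(
        data=planes.sum(axis=0),
        pixel_spacing_um=(dy, dx),
        n_slices=n_slices,
        slice_interval_um=interval_um,
        roi_index=roi.index,
    )
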