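"""Volume I/O, run configuration and logging.

All image data is held as a 3-D array in ``(z, y, x)`` order with physical
voxel spacing in micrometres.  Multi-page grayscale TIFF is the single
supported on-disk format (the de-facto confocal export); voxel spacing is
persisted in the TIFF resolution tags plus a plain-text sidecar so that a
round trip through disk is lossless.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np
import tifffile
import yaml

log = logging.getLogger("axonquant")

#: Default voxel spacing (z, y, x) in um.  The lateral value is 200/512 um so
#: that one 200 um analysis window is exactly 512 px wide; the axial value
#: matches the 2 um slice interval of the projection protocol.
DEFAULT_SPACING = (2.0, 200.0 / 512.0, 200.0 / 512.0)


@dataclass
class ImageVolume:
    """A 3-D grayscale intensity volume with voxel spacing in um.

    Parameters
    ----------
    data:
        Intensity array, shape ``(nz, ny, nx)``, non-negative.
    spacing:
        Voxel spacing ``(dz, dy, dx)`` in micrometres, all positive.
    metadata:
        Free-form provenance (source path, or scene spec + seed).
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = DEFAULT_SPACING
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3 or self.data.size == 0:
            raise ValueError(
                f"volume must be a non-empty 3-D (z, y, x) array, got shape {self.data.shape}"
            )
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"voxel spacing must be positive on all axes, got {self.spacing}")
        if self.data.size and float(self.data.min()) < 0:
            raise ValueError("intensities must be non-negative")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def extent_um(self) -> tuple[float, float, float]:
        """Physical extent per axis: (n - 1) * spacing (plane-to-plane)."""
        return tuple((n - 1) * s for n, s in zip(self.data.shape, self.spacing))

    def bit_depth(self) -> int:
        return self.data.dtype.itemsize * 8


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Parameters of the scoring pipeline.

    Defaults follow the published analysis protocol: 200x200x24 um^3 regions
    of interest, 13 z-slices summed at 2 um intervals, 32 regions per volume,
    Otsu binarization, and the three long-fragment criteria
    (eccentricity > 0.99, major axis > 200 px, filled area > 2000 px).
    """

    roi_edge_um: float = 200.0
    roi_thickness_um: float = 24.0
    slices_per_projection: int = 13
    slice_interval_um: float = 2.0
    roi_count: int = 32
    #: sampling band distal to the repair site, in mm.  Localising the repair
    #: site is a manual step, so the band is always interpreted relative to a
    #: caller-supplied origin (see :func:`axonquant.projection.sample_rois`).
    offset_band_mm: tuple[float, float] = (1.0, 2.0)
    binarization: str = "otsu"          # "otsu" | "fixed"
    fixed_threshold: float | None = None
    eccentricity_threshold: float = 0.99
    major_axis_threshold_px: float = 200.0
    filled_area_threshold_px: float = 2000.0
    connectivity: int = 8               # 4 | 8 (pixel neighbourhood)
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        span = (self.slices_per_projection - 1) * self.slice_interval_um
        if not np.isclose(span, self.roi_thickness_um):
            raise ValueError(
                "inconsistent projection geometry: "
                f"{self.slices_per_projection} slices at {self.slice_interval_um} um span "
                f"{span} um, but ROI thickness is {self.roi_thickness_um} um"
            )
        if self.roi_edge_um <= 0 or self.roi_thickness_um <= 0:
            raise ValueError("ROI dimensions must be positive")
        if self.roi_count < 1:
            raise ValueError("roi_count must be >= 1")
        if self.binarization not in ("otsu", "fixed"):
            raise ValueError(f"unknown binarization method {self.binarization!r}")
        if self.binarization == "fixed" and self.fixed_threshold is None:
            raise ValueError("binarization='fixed' requires fixed_threshold")
        if self.eccentricity_threshold <= 0 or not self.eccentricity_threshold < 1:
            raise ValueError("eccentricity threshold must lie in (0, 1)")
        if self.major_axis_threshold_px <= 0 or self.filled_area_threshold_px <= 0:
            raise ValueError("classification thresholds must be positive")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")

    def as_dict(self) -> dict:
        return asdict(self)

    def echo(self) -> None:
        """Log every effective parameter once (config audit line)."""
        log.info("run config: %s", json.dumps(self.as_dict(), default=str))

    def replace(self, **kw) -> "RunConfig":
        return replace(self, **kw)


def load_config(path: str | Path | None = None, **overrides) -> RunConfig:
    """Build a :class:`RunConfig` from a YAML file and/or keyword overrides.

    An empty/absent file yields the protocol defaults.  Every field is
    validated and the effective configuration is echoed to the log.
    """
    values: dict = {}
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, dict):
            raise ValueError(f"config file {path} must contain a mapping")
        values.update(loaded)
    values.update(overrides)
    known = RunConfig.__dataclass_fields__
    unknown = set(values) - set(known)
    if unknown:
        raise ValueError(f"unknown config fields: {sorted(unknown)}")
    for tup in ("offset_band_mm",):
        if tup in values and values[tup] is not None:
            values[tup] = tuple(values[tup])
    cfg = RunConfig(**values)
    cfg.echo()
    return cfg


# ---------------------------------------------------------------------------
# TIFF round trip
# ---------------------------------------------------------------------------

def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".meta.txt")


def write_volume(volume: ImageVolume, path: str | Path) -> Path:
    """Write a volume as a multi-page grayscale TIFF plus a metadata sidecar.

    Lossless for integer data.  Spacing is stored in the TIFF resolution
    tags (x/y) and ImageJ-style ``spacing`` metadata (z), and repeated in a
    plain-text key/value sidecar together with any provenance metadata.
    """
    path = Path(path)
    dz, dy, dx = volume.spacing
    data = volume.data
    if data.dtype.kind == "f":
        data = data.astype(np.float32)
    tifffile.imwrite(
        path,
        data,
        imagej=data.dtype in (np.dtype(np.uint8), np.dtype(np.uint16), np.dtype(np.float32)),
        resolution=(1.0 / dx, 1.0 / dy),
        metadata={"spacing": dz, "unit": "um", "axes": "ZYX"},
    )
    lines = [
        f"spacing_z_um={dz!r}",
        f"spacing_y_um={dy!r}",
        f"spacing_x_um={dx!r}",
    ]
    for key, val in volume.metadata.items():
        lines.append(f"{key}={json.dumps(val, default=str)}")
    _sidecar_path(path).write_text("\n".join(lines) + "\n")
    log.info("wrote volume %s shape=%s dtype=%s spacing=%s", path, data.shape, data.dtype, volume.spacing)
    return path


def read_volume(path: str | Path) -> ImageVolume:
    """Read a multi-page grayscale TIFF volume.

    Spacing is recovered from the sidecar when present, else from the TIFF
    tags; if neither carries it, the documented default spacing is assumed
    with a logged warning.  Multi-channel (RGB) input is rejected.
    """
    path = Path(path)
    try:
        with tifffile.TiffFile(path) as tf:
            data = tf.asarray()
            ij = tf.imagej_metadata or {}
            page = tf.pages[0]
            xres = page.tags.get("XResolution")
            yres = page.tags.get("YResolution")
    except Exception as exc:  # noqa: BLE001 - annotate path on any reader failure
        raise OSError(f"could not read TIFF volume {path}: {exc}") from exc
    if data.ndim == 2:
        data = data[None]
    if data.ndim != 3:
        raise ValueError(
            f"{path}: expected a single-channel z-stack, got shape {data.shape}; "
            "select one channel before analysis"
        )
    spacing = None
    sidecar = _sidecar_path(path)
    meta: dict = {"source": str(path)}
    if sidecar.exists():
        kv = {}
        for line in sidecar.read_text().splitlines():
            if "=" in line:
                k, v = line.split("=", 1)
                kv[k] = v
        try:
            spacing = (float(kv["spacing_z_um"]),
                       float(kv["spacing_y_um"]),
                       float(kv["spacing_x_um"]))
        except (KeyError, ValueError, SyntaxError):
            spacing = None
        for k, v in kv.items():
            if not k.startswith("spacing_"):
                try:
                    meta[k] = json.loads(v)
                except (json.JSONDecodeError, ValueError):
                    meta[k] = v
    if spacing is None:
        dz = ij.get("spacing")
        if dz and xres and yres:
            def _per_px(tag):
                num, den = tag.value
                return den / num if num else None
            dx = _per_px(xres)
            dy = _per_px(yres)
            if dx and dy:
                spacing = (float(dz), float(dy), float(dx))
    if spacing is None:
        spacing = DEFAULT_SPACING
        log.warning("%s: no voxel spacing found; assuming default %s um", path, spacing)
    return ImageVolume(data=data, spacing=spacing, metadata=meta)
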