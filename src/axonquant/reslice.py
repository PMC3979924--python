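"""Virtual cross-sectioning and rectangular-region intensity profiles.

Tissue clearing permits reconstructing transverse cross sections of a nerve
computationally instead of physically sectioning it: the nerve is mounted
with its axis along one volume axis (x by convention here) and a plane
orthogonal to that axis is extracted at any position.  Depth (z) and
lateral (x) intensity profiles over rectangular regions expose the
depth-attenuation and radial-staining structure of the volume.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import ImageVolume


@dataclass
class CrossSection:
    """A transverse (z-y) plane extracted at a position along the nerve axis."""
    data: np.ndarray                       # 2-D intensity, axes = remaining volume axes
    position_um: float
    pixel_spacing_um: tuple[float, float]  # spacing of the two section axes (anisotropic)
    axis: int                              # volume axis orthogonal to the section


@dataclass
class IntensityProfile:
    """Mean intensity per coordinate along one axis over a rectangle."""
    axis: str                              # "z" | "x"
    coordinates_um: np.ndarray
    mean_intensity: np.ndarray
    rectangle: tuple                       # the averaging window, voxel slices


def transverse_reslice(
    volume: ImageVolume,
    position_um: float,
    axis: int = 2,
    interpolation: str = "nearest",
) -> CrossSection:
    """Extract the plane orthogonal to the nerve axis at a given position.

    With nearest interpolation, on-grid positions reproduce the stored
    voxel plane exactly; linear interpolation blends the two neighbouring
    planes.  Spacing of the remaining axes is carried (possibly
    anisotropic) so displays can set the aspect ratio correctly.
    """
    d = volume.spacing[axis]
    extent = (volume.data.shape[axis] - 1) * d
    if not 0.0 <= position_um <= extent + 1e-9:
        raise ValueError(
            f"position {position_um} um outside the volume extent [0, {extent}] um on axis {axis}"
        )
    idx_f = position_um / d
    if interpolation == "nearest":
        plane = np.take(volume.data, int(round(idx_f)), axis=axis)
    elif interpolation == "linear":
        i0 = int(np.floor(idx_f))
        i0 = min(i0, volume.data.shape[axis] - 2) if volume.data.shape[axis] > 1 else 0
        w = idx_f - i0
        a = np.take(volume.data, i0, axis=axis).astype(np.float64)
        b = np.take(volume.data, min(i0 + 1, volume.data.shape[axis] - 1), axis=axis)
        plane = (1 - w) * a + w * b.astype(np.float64)
    else:
        raise ValueError(f"unknown interpolation {interpolation!r}")
    other = [ax for ax in range(3) if ax != axis]
    return CrossSection(
        data=np.asarray(plane),
        position_um=float(position_um),
        pixel_spacing_um=(volume.spacing[other[0]], volume.spacing[other[1]]),
        axis=axis,
    )


def reslice_series(
    volume: ImageVolume,
    start_um: float,
    stop_um: float,
    step_um: float,
    axis: int = 2,
    interpolation: str = "nearest",
) -> list[CrossSection]:
    """Evenly spaced cross sections; count = floor((stop - start)/step) + 1."""
    if step_um <= 0:
        raise ValueError("step must be positive")
    n = int(np.floor((stop_um - start_um) / step_um + 1e-9)) + 1
    if n < 1:
        raise ValueError("empty reslice range")
    return [
        transverse_reslice(volume, start_um + k * step_um, axis, interpolation)
        for k in range(n)
    ]


def depth_intensity_profile(
    volume: ImageVolume,
    rectangle: dict[str, tuple[float, float]],
    axis: str = "z",
) -> IntensityProfile:
    """Mean intensity along z (depth) or x over a rectangular region.

    ``rectangle`` gives ``(lo_um, hi_um)`` bands for the two non-profile
    axes (half-open in voxel space); the profile axis spans the full
    volume.  A zero-area rectangle is an error.
    """
    if axis not in ("z", "x"):
        raise ValueError("profile axis must be 'z' or 'x'")
    ax_index = {"z": 0, "y": 1, "x": 2}
    prof_ax = ax_index[axis]
    slices: list[slice] = [slice(None)] * 3
    for name, ax in ax_index.items():
        if ax == prof_ax:
            continue
        if name not in rectangle:
            continue
        lo_um, hi_um = rectangle[name]
        d = volume.spacing[ax]
        lo = max(0, int(np.ceil(lo_um / d - 1e-9)))
        hi = min(volume.data.shape[ax], int(np.floor(hi_um / d + 1e-9)) + 1)
        if hi <= lo:
            raise ValueError(f"rectangle is degenerate on axis {name}: {rectangle[name]} um")
        slices[ax] = slice(lo, hi)
    sub = volume.data[tuple(slices)].astype(np.float64)
    reduce_axes = tuple(ax for ax in range(3) if ax != prof_ax)
    mean = sub.mean(axis=reduce_axes)
    coords = np.arange(volume.data.shape[prof_ax]) * volume.spacing[prof_ax]
    return IntensityProfile(axis=axis, coordinates_um=coords, mean_intensity=mean,
                            rectangle=tuple(slices))


def fit_attenuation_length(profile: IntensityProfile) -> float:
    """Recover the exponential depth-attenuation length constant (um).

    Log-linear least squares on the positive samples of a depth profile:
    ``mean(z) ~ exp(-z / L)`` gives slope ``-1/L``.
    """
    pos = profile.mean_intensity > 0
    if pos.sum() < 2:
        raise ValueError("profile has fewer than two positive samples")
    slope, _ = np.polyfit(profile.coordinates_um[pos],
                          np.log(profile.mean_intensity[pos]), 1)
    if slope >= 0:
        raise ValueError("profile is non-decreasing; no attenuation to fit")
    return -1.0 / slope
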