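"""Basement-membrane detection from SHG and digital epithelial flattening.

The trachea is curved, so a single z plane cuts obliquely through the
epithelium.  Collagen in the basement membrane / subepithelium produces a
strong second-harmonic (SHG) signal; we locate, for every lateral column,
the shallowest sustained SHG response (seen from the lumen) and then shift
each column along z so that this surface lands on one reference plane.
Downstream, "apical" and "nuclear position" are then simple functions of z.

Surface model: for column (y, x) we take the largest z index at which the
SHG signal exceeds an adaptive (Otsu) threshold for at least ``persistence``
consecutive voxels going into the tissue, refine the crossing to sub-voxel
precision by linear interpolation, median-filter and Gaussian-smooth the
resulting depth map, and inpaint columns with no crossing from their
nearest valid neighbors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .stack_io import LabelVolume, MultiChannelStack


class SurfaceError(ValueError):
    """Raised when the basement membrane cannot be detected."""


@dataclass
class DetectionParams:
    """Settings for basement-membrane detection.

    persistence
        Number of consecutive supra-threshold voxels (going from the
        membrane into the tissue) required to accept a crossing; guards
        against speckle in the fibrous collagen signal.
    median_size, gaussian_sigma
        Lateral smoothing of the depth map; the membrane is smooth at
        cell scale, so a 5x5 median plus sigma = 2 px Gaussian is gentle.
    threshold
        Absolute SHG threshold; ``None`` selects Otsu's threshold over
        the whole SHG volume.
    max_invalid_fraction
        Detection fails when more than this fraction of columns has no
        sustained crossing (e.g. cartilage shadows over the whole field).
    """

    persistence: int = 3
    median_size: int = 5
    gaussian_sigma: float = 2.0
    threshold: float | None = None
    max_invalid_fraction: float = 0.5


@dataclass
class SurfaceMap:
    """Basement-membrane depth per lateral position, in voxel units."""

    z_surface: np.ndarray  # (ny, nx) float, sub-voxel depth
    valid_mask: np.ndarray  # (ny, nx) bool, True where detection succeeded
    smoothing_params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.z_surface = np.asarray(self.z_surface, dtype=np.float64)
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        if self.z_surface.shape != self.valid_mask.shape:
            raise SurfaceError("geometry error: surface/mask shape mismatch")
        if not np.all(np.isfinite(self.z_surface[self.valid_mask])):
            raise SurfaceError("surface contains non-finite values on valid mask")

    @property
    def shape(self) -> tuple[int, int]:
        return self.z_surface.shape

    def roughness(self) -> float:
        """SD of the surface depth over valid columns."""
        return float(np.std(self.z_surface[self.valid_mask]))


def detect_basement_membrane(
    stack: MultiChannelStack, params: DetectionParams | None = None
) -> SurfaceMap:
    """Locate the basement membrane surface in the SHG channel.

    Returns a :class:`SurfaceMap` whose ``z_surface`` holds, per (y, x),
    the sub-voxel z of the shallowest sustained SHG response seen from the
    lumen side (canonical orientation: lumen at high z).

    Raises
    ------
    SurfaceError
        If the SHG channel has no dynamic range ("surface not detectable")
        or more than ``max_invalid_fraction`` of columns has no crossing.
    """
    params = params or DetectionParams()
    shg = stack.shg
    nz, ny, nx = shg.shape
    if shg.max() <= shg.min():
        raise SurfaceError("surface not detectable: SHG channel has no dynamic range")

    thresh = params.threshold if params.threshold is not None else float(threshold_otsu(shg))
    binary = shg > thresh

    # sustained[z] := binary[z] & binary[z-1] & ... over `persistence` voxels
    # going down into the tissue (towards smaller z).
    w = max(1, int(params.persistence))
    sustained = _sustained_down(binary, w)

    # topmost z (largest index) where a sustained run starts
    any_run = sustained.any(axis=0)
    # argmax of reversed z gives the first True from the lumen side
    z_top = (nz - 1) - np.argmax(sustained[::-1], axis=0)
    z_top = z_top.astype(np.float64)
    z_top[~any_run] = np.nan

    invalid_fraction = 1.0 - any_run.mean()
    if invalid_fraction > params.max_invalid_fraction:
        raise SurfaceError(
            f"surface not detectable: {invalid_fraction:.0%} of columns have no "
            f"sustained SHG crossing"
        )

    z_sub = _subvoxel_refine(shg, z_top, any_run, thresh)

    # inpaint invalid columns from nearest valid neighbor, then smooth
    if not any_run.all():
        _, (iy, ix) = ndimage.distance_transform_edt(~any_run, return_indices=True)
        z_sub = z_sub[iy, ix]
    z_smooth = ndimage.median_filter(z_sub, size=params.median_size, mode="nearest")
    z_smooth = ndimage.gaussian_filter(z_smooth, sigma=params.gaussian_sigma, mode="nearest")
    z_smooth = np.clip(z_smooth, 0.0, nz - 1.0)

    return SurfaceMap(
        z_surface=z_smooth,
        valid_mask=any_run,
        smoothing_params={
            "threshold": thresh,
            "persistence": w,
            "median_size": params.median_size,
            "gaussian_sigma": params.gaussian_sigma,
        },
    )


def _sustained_down(binary: np.ndarray, w: int) -> np.ndarray:
    """binary AND-ed over a window of w voxels extending toward smaller z."""
    out = binary.copy()
    for k in range(1, w):
        shifted = np.zeros_like(binary)
        shifted[k:] = binary[:-k]
        out &= shifted
    return out


def _subvoxel_refine(
    shg: np.ndarray, z_top: np.ndarray, valid: np.ndarray, thresh: float
) -> np.ndarray:
    """Half-maximum edge localization around the detected crossing.

    The detection threshold (Otsu) separates signal from background but
    sits nowhere near the edge midpoint when class sizes are unbalanced,
    so the surface position is refined against the local half-max level:
    midway between the background just above the membrane (z_top + 1) and
    the full band intensity just below it (z_top - 1).
    """
    nz = shg.shape[0]
    z_int = np.where(valid, z_top, 1).astype(int)
    iy, ix = np.indices(valid.shape)
    at = shg[z_int, iy, ix]
    above = shg[np.minimum(z_int + 1, nz - 1), iy, ix]
    deep = shg[np.maximum(z_int - 1, 0), iy, ix]
    deep = np.maximum(deep, at)  # band interior never below the edge voxel
    level = 0.5 * (deep + above)

    with np.errstate(divide="ignore", invalid="ignore"):
        frac_up = (level - above) / (at - above)  # crossing in [z_top, z_top+1]
        frac_down = (level - at) / (deep - at)  # crossing in [z_top-1, z_top]
    frac_up = np.clip(np.where(np.isfinite(frac_up), frac_up, 1.0), 0.0, 1.0)
    frac_down = np.clip(np.where(np.isfinite(frac_down), frac_down, 0.0), 0.0, 1.0)
    refined = np.where(at >= level, (z_int + 1) - frac_up, z_int - frac_down)
    refined = np.where(z_int + 1 > nz - 1, z_int.astype(float), refined)
    return np.where(valid, refined, np.nan)


def flatten_stack(
    stack: MultiChannelStack,
    surface: SurfaceMap,
    reference_z: float = 10,
    integer_shift: bool = False,
) -> MultiChannelStack:
    """Resample every channel along z so the membrane lies at ``reference_z``.

    Column (y, x) of each channel is shifted by ``z_surface(y, x) -
    reference_z`` with linear interpolation (or the nearest integer shift
    when ``integer_shift`` is set, which permutes rather than blends
    intensities).  Voxels shifted in from outside the volume are zero.

    Raises
    ------
    SurfaceError
        "geometry error" when the surface's lateral shape does not match.
    """
    nz, ny, nx = stack.shape
    if surface.shape != (ny, nx):
        raise SurfaceError(
            f"geometry error: surface shape {surface.shape} != lateral {(ny, nx)}"
        )
    shift = surface.z_surface - float(reference_z)
    if integer_shift:
        shift = np.round(shift)

    zz, yy, xx = np.meshgrid(
        np.arange(nz), np.arange(ny), np.arange(nx), indexing="ij"
    )
    src_z = zz + shift[None, :, :]
    coords = np.stack([src_z, yy, xx]).reshape(3, -1)

    order = 0 if integer_shift else 1
    flattened = {}
    for name, vol in stack.channels().items():
        out = ndimage.map_coordinates(
            vol, coords, order=order, mode="constant", cval=0.0, prefilter=False
        ).reshape(nz, ny, nx)
        flattened[name] = out
    result = stack.with_channels(**flattened)
    result.metadata["flattened"] = {
        "reference_z": float(reference_z),
        "integer_shift": bool(integer_shift),
    }
    return result


def flatten_labels(
    labels: LabelVolume, surface: SurfaceMap, reference_z: float = 10
) -> LabelVolume:
    """Apply the same flattening to a label volume, with nearest-voxel
    (integer) shifts so label identities are never blended."""
    nz, ny, nx = labels.shape
    if surface.shape != (ny, nx):
        raise SurfaceError(
            f"geometry error: surface shape {surface.shape} != lateral {(ny, nx)}"
        )
    shift = np.round(surface.z_surface - float(reference_z)).astype(int)
    zz, yy, xx = np.meshgrid(np.arange(nz), np.arange(ny), np.arange(nx), indexing="ij")
    src_z = zz + shift[None, :, :]
    valid = (src_z >= 0) & (src_z < nz)
    out = np.zeros_like(labels.labels)
    out[valid] = labels.labels[src_z[valid], yy[valid], xx[valid]]
    return LabelVolume(labels=out, type_of=dict(labels.type_of))
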