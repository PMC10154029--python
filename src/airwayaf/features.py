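"""Optical redox ratio and per-cell morphometric features.

The optical redox ratio FAD / (NAD(P)H + FAD) is a scattering- and
mitochondrial-abundance-robust proxy for cellular metabolic state.  For
each segmented cell in a flattened stack we compute 12 descriptors:

==================  =========================================================
fad, nadh           mean channel intensity over the cell mask (detector units)
ratio               mean per-voxel redox ratio over the cell's defined voxels
nuclear_position    nucleus centroid height above the basement-membrane
                    plane, in micrometres
x_length            largest lateral extent: maximum Feret (caliper) diameter
                    of the XY projection, micrometres
y_length            smallest lateral extent: minimum Feret diameter of the
                    XY projection, micrometres
z_length            axial extent (max z - min z + 1 voxels), micrometres
aspect_xy           x_length / y_length  (>= 1 by construction)
aspect_yz           y_length / z_length
sd_top, sd_bottom   SD of per-voxel ratio strictly above / at-or-below the
                    cell's mid-height plane
sd_ratio            sd_top / sd_bottom (NaN when sd_bottom == 0)
==================  =========================================================

The cell masks are inputs (drawn from post-fixation staining in real data,
or synthetic ground truth); this module does not segment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import ConvexHull, QhullError
from scipy.stats import ttest_rel

from .stack_io import LabelVolume, MultiChannelStack

logger = logging.getLogger(__name__)

#: CSV column order for feature tables
FEATURE_COLUMNS = [
    "fad",
    "nadh",
    "ratio",
    "nuclear_position",
    "x_length",
    "y_length",
    "z_length",
    "aspect_xy",
    "aspect_yz",
    "sd_top",
    "sd_bottom",
    "sd_ratio",
]
TABLE_COLUMNS = ["cell_id", "cell_type"] + FEATURE_COLUMNS

#: smallest cell accepted by the feature extractor, voxels
MIN_CELL_VOXELS = 50
#: smallest region accepted as a nucleus, voxels
MIN_NUCLEUS_VOXELS = 30


class FeatureError(ValueError):
    pass


# ---------------------------------------------------------------------------
# redox ratio volume
# ---------------------------------------------------------------------------

@dataclass
class RatioVolume:
    """Per-voxel FAD / (NAD(P)H + FAD) with a defined-voxel mask.

    Voxels whose total autofluorescence falls below the denominator floor
    carry NaN and are excluded from every downstream statistic.
    """

    ratio: np.ndarray
    defined_mask: np.ndarray
    floor: float = 0.0

    def __post_init__(self) -> None:
        vals = self.ratio[self.defined_mask]
        if vals.size and (np.nanmin(vals) < 0 or np.nanmax(vals) > 1):
            raise FeatureError("ratio outside [0, 1] on defined mask")


def default_ratio_floor(stack: MultiChannelStack, fraction: float = 0.01) -> float:
    """Denominator floor: ``fraction`` of the joint channel dynamic range.

    Suppresses noise-dominated voxels (nuclei, voids, background) where the
    ratio of two near-zero numbers is meaningless.
    """
    joint_max = float(max(stack.nadph.max(), stack.fad.max()))
    joint_min = float(min(stack.nadph.min(), stack.fad.min()))
    return max(fraction * (joint_max - joint_min), np.finfo(float).tiny)


def compute_ratio_volume(stack: MultiChannelStack, floor: float | None = None) -> RatioVolume:
    """Compute the optical redox ratio wherever FAD + NAD(P)H >= ``floor``.

    Raises
    ------
    FeatureError
        "invalid floor" for a non-positive floor.
    """
    if floor is None:
        floor = default_ratio_floor(stack)
    if floor <= 0:
        raise FeatureError(f"invalid floor: {floor}")
    total = stack.fad + stack.nadph
    defined = total >= floor
    ratio = np.full(stack.shape, np.nan)
    np.divide(stack.fad, total, out=ratio, where=defined)
    return RatioVolume(ratio=ratio, defined_mask=defined, floor=float(floor))


# ---------------------------------------------------------------------------
# nucleus estimation
# ---------------------------------------------------------------------------

@dataclass
class NucleusEstimate:
    """The largest connected low-autofluorescence region inside a cell.

    Nuclei carry almost no NAD(P)H/FAD fluorophores, so they image as dark
    holes in the cytoplasmic signal.
    """

    centroid: tuple[float, float, float]  # (z, y, x) voxels
    voxels: np.ndarray  # (n, 3) int voxel indices
    mean_af: float


def _mask_bbox(mask: np.ndarray, pad: int = 1) -> tuple[slice, slice, slice]:
    """Bounding-box slices of a boolean mask, padded and clipped."""
    idx = np.nonzero(mask)
    return tuple(
        slice(max(int(a.min()) - pad, 0), min(int(a.max()) + pad + 1, n))
        for a, n in zip(idx, mask.shape)
    )


def estimate_nucleus(
    stack_flat: MultiChannelStack,
    cell_mask: np.ndarray,
    quantile: float = 0.2,
    min_voxels: int = MIN_NUCLEUS_VOXELS,
) -> NucleusEstimate:
    """Find the nucleus as the largest dark region inside the cell.

    Voxels with total autofluorescence strictly below the cell's
    ``quantile``-quantile form candidate regions; the largest connected
    component of at least ``min_voxels`` is returned.

    Raises
    ------
    FeatureError
        "nucleus not found" when no qualifying region exists (e.g. a cell
        of uniform intensity).
    """
    if not cell_mask.any():
        raise FeatureError("nucleus not found: empty cell mask")
    box = _mask_bbox(cell_mask)
    mask = cell_mask[box]
    total = stack_flat.nadph[box] + stack_flat.fad[box]
    cell_vals = total[mask]
    thresh = np.quantile(cell_vals, quantile)
    low = mask & (total < thresh)
    labeled, n = ndimage.label(low)
    if n == 0:
        raise FeatureError("nucleus not found: no low-autofluorescence region")
    sizes = ndimage.sum_labels(np.ones_like(labeled), labeled, index=np.arange(1, n + 1))
    best = int(np.argmax(sizes)) + 1
    if sizes[best - 1] < min_voxels:
        raise FeatureError(
            f"nucleus not found: largest dark region has {int(sizes[best - 1])} voxels "
            f"(< {min_voxels})"
        )
    voxels_local = np.argwhere(labeled == best)
    # darkness-weighted centroid: voxels just under the threshold (dim
    # cytoplasm annexed to the dark region) get near-zero weight, so the
    # centroid tracks the truly dark nuclear core
    weights = np.maximum(thresh - total[tuple(voxels_local.T)], 0.0)
    if weights.sum() > 0:
        centroid_local = np.average(voxels_local, axis=0, weights=weights)
    else:
        centroid_local = voxels_local.mean(axis=0)
    offset = np.array([s.start for s in box])
    mean_af = float(total[labeled == best].mean())
    return NucleusEstimate(
        centroid=tuple(centroid_local + offset),
        voxels=voxels_local + offset,
        mean_af=mean_af,
    )


# ---------------------------------------------------------------------------
# Feret diameters
# ---------------------------------------------------------------------------

def feret_diameters_2d(points: np.ndarray) -> tuple[float, float]:
    """Maximum and minimum Feret (caliper) diameters of a 2D point set.

    The maximum Feret diameter is the largest pairwise distance (computed
    on the convex hull); the minimum is the smallest width over all hull
    edge orientations (rotating calipers).  Distances are between point
    coordinates; callers measuring digitized shapes should add one pixel
    to correct for the finite pixel footprint (a run of k pixels spans k
    pixel widths, while its center-to-center distance is k - 1).
    Degenerate sets (single point or collinear) get a width of zero.
    """
    points = np.asarray(points, dtype=float)
    if len(points) == 1:
        return 0.0, 0.0
    try:
        hull = ConvexHull(points)
        hull_pts = points[hull.vertices]
    except QhullError:  # collinear
        d = np.linalg.norm(points[:, None] - points[None, :], axis=-1)
        return float(d.max()), 0.0
    diff = hull_pts[:, None, :] - hull_pts[None, :, :]
    max_feret = float(np.sqrt((diff**2).sum(-1)).max())

    # min width: for each hull edge, spread of projections on its normal
    edges = np.roll(hull_pts, -1, axis=0) - hull_pts
    lengths = np.linalg.norm(edges, axis=1)
    normals = np.stack([-edges[:, 1], edges[:, 0]], axis=1) / lengths[:, None]
    proj = hull_pts @ normals.T  # (n_pts, n_edges)
    widths = proj.max(axis=0) - proj.min(axis=0)
    min_feret = float(widths.min())
    return max_feret, min_feret


def max_feret_bruteforce(points: np.ndarray) -> float:
    """O(n^2) maximum pairwise distance; independent oracle for tests."""
    points = np.asarray(points, dtype=float)
    d = np.linalg.norm(points[:, None] - points[None, :], axis=-1)
    return float(d.max())


# ---------------------------------------------------------------------------
# per-cell feature extraction
# ---------------------------------------------------------------------------

@dataclass
class FeatureVector:
    """The 12 per-cell descriptors plus provenance."""

    cell_id: int
    cell_type: str | None
    fad: float
    nadh: float
    ratio: float
    nuclear_position: float
    x_length: float
    y_length: float
    z_length: float
    aspect_xy: float
    aspect_yz: float
    sd_top: float
    sd_bottom: float
    sd_ratio: float

    def as_dict(self) -> dict:
        return {
            "cell_id": self.cell_id,
            "cell_type": self.cell_type,
            **{k: getattr(self, k) for k in FEATURE_COLUMNS},
        }


def extract_features(
    stack_flat: MultiChannelStack,
    ratio_vol: RatioVolume,
    cell_mask: np.ndarray,
    nucleus: NucleusEstimate | None,
    cell_id: int = 0,
    cell_type: str | None = None,
    reference_z: float = 0.0,
    min_voxels: int = MIN_CELL_VOXELS,
) -> FeatureVector:
    """Compute the 12 descriptors for one cell of a flattened stack.

    The stack must be flattened so that the basement membrane lies at
    ``reference_z``; nuclear position is measured from that plane in
    micrometres.  ``nucleus=None`` yields NaN nuclear position (imputed
    downstream).

    Raises
    ------
    FeatureError
        "cell too small" below ``min_voxels``.
    """
    n_vox = int(cell_mask.sum())
    if n_vox < min_voxels:
        raise FeatureError(f"cell too small: {n_vox} voxels < {min_voxels}")
    dx, dy, dz = stack_flat.voxel_size

    box = _mask_bbox(cell_mask)
    mask = cell_mask[box]
    z_off = box[0].start
    fad_mean = float(stack_flat.fad[box][mask].mean())
    nadh_mean = float(stack_flat.nadph[box][mask].mean())

    defined = mask & ratio_vol.defined_mask[box]
    ratio_box = ratio_vol.ratio[box]
    cell_ratio = float(ratio_box[defined].mean()) if defined.any() else np.nan

    zs, ys, xs = np.nonzero(mask)
    zs = zs + z_off
    ys = ys + box[1].start
    xs = xs + box[2].start
    # lateral Feret diameters on the XY projection, in physical units,
    # plus one pixel for the finite pixel footprint (cf. z extent below);
    # coordinates are taken relative to the mask's own corner so the
    # result is bit-identical under lateral translation
    proj = np.unique(
        np.stack([(ys - ys.min()) * dy, (xs - xs.min()) * dx], axis=1), axis=0
    )
    px = 0.5 * (dx + dy)
    max_f, min_f = feret_diameters_2d(proj)
    x_length = max_f + px
    y_length = min(min_f + px, x_length)
    z_length = float(zs.max() - zs.min() + 1) * dz

    aspect_xy = x_length / y_length
    aspect_yz = y_length / z_length

    if nucleus is not None:
        nuclear_position = (nucleus.centroid[0] - reference_z) * dz
    else:
        nuclear_position = np.nan

    mid_z = 0.5 * (zs.max() + zs.min())
    z_planes = np.arange(box[0].start, box[0].stop)[:, None, None]
    top = defined & (z_planes > mid_z)
    bottom = defined & (z_planes <= mid_z)
    sd_top = float(np.std(ratio_box[top])) if top.any() else np.nan
    sd_bottom = float(np.std(ratio_box[bottom])) if bottom.any() else np.nan
    sd_ratio = sd_top / sd_bottom if (sd_bottom and sd_bottom > 0) else np.nan

    return FeatureVector(
        cell_id=cell_id,
        cell_type=cell_type,
        fad=fad_mean,
        nadh=nadh_mean,
        ratio=cell_ratio,
        nuclear_position=float(nuclear_position),
        x_length=float(x_length),
        y_length=float(y_length),
        z_length=float(z_length),
        aspect_xy=float(aspect_xy),
        aspect_yz=float(aspect_yz),
        sd_top=sd_top,
        sd_bottom=sd_bottom,
        sd_ratio=sd_ratio,
    )


def build_feature_table(
    stack_flat: MultiChannelStack,
    ratio_vol: RatioVolume,
    labels: LabelVolume,
    reference_z: float = 0.0,
    min_voxels: int = MIN_CELL_VOXELS,
    nucleus_quantile: float = 0.2,
) -> pd.DataFrame:
    """One feature row per cell surviving the size filter, ordered by label.

    Cells whose nucleus cannot be found keep a NaN nuclear position; cells
    below the size filter are logged and dropped.  An empty label volume
    yields an empty table with the full header.
    """
    rows = []
    for label in labels.ids():
        mask = labels.mask(int(label))
        try:
            nucleus = estimate_nucleus(stack_flat, mask, quantile=nucleus_quantile)
        except FeatureError:
            nucleus = None
        try:
            fv = extract_features(
                stack_flat,
                ratio_vol,
                mask,
                nucleus,
                cell_id=int(label),
                cell_type=labels.type_of.get(int(label)),
                reference_z=reference_z,
                min_voxels=min_voxels,
            )
        except FeatureError as exc:
            logger.info("dropping cell %d: %s", label, exc)
            continue
        rows.append(fv.as_dict())
    return pd.DataFrame(rows, columns=TABLE_COLUMNS)


# ---------------------------------------------------------------------------
# paired perturbation comparison
# ---------------------------------------------------------------------------

def paired_ratio_change(
    before: dict[int, float] | pd.Series,
    after: dict[int, float] | pd.Series,
) -> dict:
    """Per-cell paired comparison of redox ratios across a perturbation.

    Returns mean delta (after - before), the paired t statistic and its
    two-sided p value.  With zero variance in the deltas the t test is
    undefined and reported as NaN.

    Raises
    ------
    FeatureError
        "pairing error" when the two conditions cover different cells.
    """
    before = pd.Series(dict(before) if not isinstance(before, pd.Series) else before)
    after = pd.Series(dict(after) if not isinstance(after, pd.Series) else after)
    if set(before.index) != set(after.index) or len(before) == 0:
        raise FeatureError("pairing error: cell ids differ between conditions")
    after = after.loc[before.index]
    delta = after - before
    if len(delta) < 2 or np.allclose(delta.std(ddof=1), 0.0):
        # zero variance in the deltas: t undefined, report NaN
        t_stat, p_value = np.nan, np.nan
    else:
        t_stat, p_value = ttest_rel(after.values, before.values)
    return {
        "n": int(len(delta)),
        "mean_delta": float(delta.mean()),
        "t_statistic": float(t_stat) if np.isfinite(np.float64(t_stat)) else np.nan,
        "p_value": float(p_value) if np.isfinite(np.float64(p_value)) else np.nan,
    }
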