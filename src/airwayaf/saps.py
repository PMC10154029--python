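"""Detection, quantification and tracking of secretory-cell voids (SAPs).

Cholinergic stimulation makes airway secretory cells internalize luminal
content through secretory-cell-associated antigen passages (SAPs), which
image as non-fluorescent spherical "voids" distinct from the (also dark)
nucleus.  Operationally: within a cell, connected low-autofluorescence
components other than the nucleus that are large and round enough are
called as voids.  The fraction of secretory cells carrying at least one
void is the headline physiology readout (≈9% at baseline, rising steeply
after methacholine), and greedy nearest-centroid linking across
time-lapse frames turns per-frame calls into uptake/secretion events.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.stats import beta
from skimage.measure import marching_cubes, mesh_surface_area

from .features import NucleusEstimate, _mask_bbox
from .stack_io import MultiChannelStack


class SapError(ValueError):
    pass


@dataclass
class VoidParams:
    """Operational void criteria (the reference analysis was by eye; these
    thresholds are this module's deterministic stand-in).

    low_af_quantile
        Same dark-region rule as nucleus detection: voxels below this
        quantile of the cell's total autofluorescence are candidates.
    min_volume_um3
        Smallest accepted void volume.
    min_sphericity
        Sphericity floor; rejects cracks and shading artifacts.
    """

    low_af_quantile: float = 0.2
    min_volume_um3: float = 0.5
    min_sphericity: float = 0.5
    max_boundary_fraction: float = 0.3
    require_membrane_shell: bool = False
    fitc_sd_threshold: float = 2.0


@dataclass
class VoidCall:
    """One detected intracellular non-fluorescent region (SAP candidate)."""

    cell_id: int
    voxels: np.ndarray  # (n, 3) voxel indices
    volume_um3: float
    sphericity: float
    centroid: tuple[float, float, float]  # (z, y, x) voxels
    apical_offset_um: float  # centroid height above the cell's mid-height
    frame: int = 0
    dextran_positive: bool | None = None


@dataclass
class VoidTrack:
    """A void linked across time-lapse frames."""

    track_id: int
    calls: list[VoidCall] = field(default_factory=list)
    events: list[str] = field(default_factory=list)

    @property
    def frames(self) -> list[int]:
        return [c.frame for c in self.calls]


def sphericity_of_mask(mask: np.ndarray, voxel_size: tuple[float, float, float]) -> float:
    """Sphericity pi^(1/3) (6V)^(2/3) / A of a voxel mask.

    V is the voxel volume; A is the surface area of the marching-cubes
    isosurface of the (padded) mask, evaluated with anisotropic spacing.
    1 for a perfect sphere, smaller for anything else.
    """
    dx, dy, dz = voxel_size
    volume = float(mask.sum()) * dx * dy * dz
    if volume == 0:
        return 0.0
    padded = np.pad(mask.astype(np.float64), 1)
    try:
        verts, faces, _, _ = marching_cubes(padded, level=0.5, spacing=(dz, dy, dx))
        area = float(mesh_surface_area(verts, faces))
    except (ValueError, RuntimeError):
        return 0.0
    if area == 0:
        return 0.0
    return float(np.pi ** (1 / 3) * (6 * volume) ** (2 / 3) / area)


def detect_voids(
    stack_flat: MultiChannelStack,
    cell_mask: np.ndarray,
    nucleus: NucleusEstimate | None,
    cell_id: int = 0,
    params: VoidParams | None = None,
    frame: int = 0,
) -> list[VoidCall]:
    """Detect non-fluorescent void candidates inside one cell.

    Connected components of low total autofluorescence (below the cell's
    ``low_af_quantile`` quantile) that do not belong to the nucleus and
    pass the volume and sphericity gates are returned.  An empty list is
    a valid result.  No call ever intersects the nucleus voxel set.

    When the stack carries a ``fitc`` channel, calls are annotated
    ``dextran_positive`` if their mean FITC exceeds the cell background
    by ``fitc_sd_threshold`` standard deviations (annotation only).
    """
    params = params or VoidParams()
    if not cell_mask.any():
        return []
    dx, dy, dz = stack_flat.voxel_size
    box = _mask_bbox(cell_mask)
    mask = cell_mask[box]
    offset = np.array([s.start for s in box])
    total = stack_flat.nadph[box] + stack_flat.fad[box]
    thresh = np.quantile(total[mask], params.low_af_quantile)
    low = mask & (total < thresh)

    nucleus_local = np.zeros_like(mask)
    if nucleus is not None:
        nv = np.asarray(nucleus.voxels) - offset
        inside = np.all((nv >= 0) & (nv < np.array(mask.shape)), axis=1)
        nucleus_local[tuple(nv[inside].T)] = True

    zs = np.nonzero(mask)[0]
    mid_z = 0.5 * (zs.max() + zs.min()) + offset[0]

    labeled, n = ndimage.label(low)
    calls: list[VoidCall] = []
    for comp in range(1, n + 1):
        comp_mask = labeled == comp
        if (comp_mask & nucleus_local).any():
            continue  # the nucleus (or a region touching it) is not a void
        # a SAP is an intracellular structure: dark fringes hugging the
        # cell border (e.g. resampling artifacts at the apical surface)
        # have most of their voxels in contact with the exterior and are
        # not voids, while a genuine void clipped by the border only
        # touches it over a small cap
        contact = comp_mask & ndimage.binary_dilation(~mask)
        if contact.sum() > params.max_boundary_fraction * comp_mask.sum():
            continue
        volume = float(comp_mask.sum()) * dx * dy * dz
        if volume < params.min_volume_um3:
            continue
        sph = sphericity_of_mask(comp_mask, stack_flat.voxel_size)
        if sph < params.min_sphericity:
            continue
        comp_vox = np.argwhere(comp_mask) + offset
        centroid = tuple(comp_vox.mean(axis=0))
        call = VoidCall(
            cell_id=cell_id,
            voxels=comp_vox,
            volume_um3=volume,
            sphericity=sph,
            centroid=centroid,
            apical_offset_um=float((centroid[0] - mid_z) * dz),
            frame=frame,
        )
        if "fitc" in stack_flat.extra:
            fitc = stack_flat.extra["fitc"][box]
            bg_vals = fitc[mask & ~comp_mask]
            call.dextran_positive = bool(
                fitc[comp_mask].mean()
                > bg_vals.mean() + params.fitc_sd_threshold * bg_vals.std()
            )
        calls.append(call)
    return calls


def sap_fraction(
    cell_ids: list[int], calls: list[VoidCall], confidence: float = 0.95
) -> dict:
    """Fraction of cells with at least one void, with an exact binomial CI.

    The Clopper-Pearson interval is used; the fraction is monotone
    nondecreasing in the set of calls.

    Raises
    ------
    SapError
        "no cells" for an empty cell set.
    """
    if not cell_ids:
        raise SapError("no cells")
    with_void = {c.cell_id for c in calls} & set(cell_ids)
    k, n = len(with_void), len(cell_ids)
    alpha = 1 - confidence
    lo = 0.0 if k == 0 else float(beta.ppf(alpha / 2, k, n - k + 1))
    hi = 1.0 if k == n else float(beta.ppf(1 - alpha / 2, k + 1, n - k))
    return {
        "n_cells": n,
        "n_with_void": k,
        "fraction": k / n,
        "ci_low": lo,
        "ci_high": hi,
        "confidence": confidence,
    }


def track_voids(
    frame_calls: list[list[VoidCall]],
    gating_radius_um: float = 2.0,
    voxel_size: tuple[float, float, float] = (0.25, 0.25, 0.5),
) -> list[VoidTrack]:
    """Greedy nearest-centroid linking of void calls across frames.

    A call within ``gating_radius_um`` of an open track's last centroid
    extends that track; otherwise it opens a new track (an "uptake"
    event when it appears after the first frame).  Tracks without a
    continuation close with a "disappearance" (secretion) event.

    Raises
    ------
    SapError
        "temporal order error" if the per-frame lists are not in strictly
        increasing frame order.
    """
    frames = [calls[0].frame for calls in frame_calls if calls]
    if any(b <= a for a, b in zip(frames, frames[1:])):
        raise SapError("temporal order error: frames must be strictly increasing")
    dx, dy, dz = voxel_size
    scale = np.array([dz, dy, dx])

    tracks: list[VoidTrack] = []
    open_tracks: list[VoidTrack] = []
    first_frame = frame_calls[0][0].frame if frame_calls and frame_calls[0] else 0

    for i, calls in enumerate(frame_calls):
        frame = calls[0].frame if calls else (frames[0] + i if frames else i)
        unmatched = list(calls)
        survivors: list[VoidTrack] = []
        # greedy: repeatedly link the globally closest (track, call) pair
        pairs = []
        for t in open_tracks:
            last = np.array(t.calls[-1].centroid) * scale
            for c in unmatched:
                d = float(np.linalg.norm(np.array(c.centroid) * scale - last))
                if d <= gating_radius_um:
                    pairs.append((d, t, c))
        pairs.sort(key=lambda p: p[0])
        used_tracks, used_calls = set(), set()
        for d, t, c in pairs:
            if id(t) in used_tracks or id(c) in used_calls:
                continue
            t.calls.append(c)
            used_tracks.add(id(t))
            used_calls.add(id(c))
            survivors.append(t)
        for t in open_tracks:
            if id(t) not in used_tracks:
                t.events.append(f"disappearance@{frame}")
                # closed: secretion or loss
        for c in calls:
            if id(c) not in used_calls:
                t = VoidTrack(track_id=len(tracks), calls=[c])
                if c.frame > first_frame:
                    t.events.append(f"uptake@{c.frame}")
                tracks.append(t)
                survivors.append(t)
        open_tracks = survivors
    return tracks


def calls_to_frame(calls: list[VoidCall]) -> pd.DataFrame:
    """Serialize void calls to the CSV schema."""
    rows = [
        {
            "cell_id": c.cell_id,
            "frame": c.frame,
            "z": c.centroid[0],
            "y": c.centroid[1],
            "x": c.centroid[2],
            "volume_um3": c.volume_um3,
            "sphericity": c.sphericity,
            "apical_offset_um": c.apical_offset_um,
            "dextran_positive": c.dextran_positive,
        }
        for c in calls
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "cell_id", "frame", "z", "y", "x", "volume_um3",
            "sphericity", "apical_offset_um", "dextran_positive",
        ],
    )


def tracks_to_frame(tracks: list[VoidTrack]) -> pd.DataFrame:
    """Serialize void tracks to the CSV schema."""
    rows = [
        {
            "track_id": t.track_id,
            "frames": ";".join(str(f) for f in t.frames),
            "event": ";".join(t.events) if t.events else "",
        }
        for t in tracks
    ]
    return pd.DataFrame(rows, columns=["track_id", "frames", "event"])
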