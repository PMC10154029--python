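"""Synthetic airway-epithelium scenes and feature tables with ground truth.

Every other module in this package is testable without any real data: this
module renders 3D multichannel stacks emulating a two-photon acquisition of
a curved tracheal epithelium — a fibrous collagen (SHG) band at the
basement membrane, seven cell types as ellipsoids with type-specific
intensity and shape distributions, dark ellipsoidal nuclei, apical FAD
puncta in ionocytes, a locally doubled layer for hillocks, and injectable
dark spherical voids in secretory cells — together with the exact label
volume, surface, per-cell feature table and void list used to render.

Numeric per-type feature means are invented, constrained by the known
qualitative orderings: the redox ratio ranks ciliated > basal > secretory;
neuroendocrine cells have the dimmest NAD(P)H and FAD of all types; the
three rare types (ionocyte, tuft, neuroendocrine) have nearly identical
ratios and are separable only through morphology; basal cells sit lowest
on the membrane.  A loader can override the means from a per-cell
reference CSV when one is available.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .celltyper import CELL_TYPES
from .features import TABLE_COLUMNS
from .flatten import SurfaceMap
from .stack_io import LabelVolume, MultiChannelStack


class GeneratorError(ValueError):
    pass


#: per-type counts analyzed in the reference dataset (206 cells total)
REFERENCE_COUNTS = {
    "basal": 30,
    "ciliated": 32,
    "secretory": 32,
    "hillock": 30,
    "ionocyte": 21,
    "tuft": 30,
    "neuroendocrine": 31,
}

#: features drawn directly; aspect_xy, aspect_yz, sd_ratio are derived
SAMPLED_FEATURES = [
    "fad",
    "nadh",
    "ratio",
    "nuclear_position",
    "x_length",
    "y_length",
    "z_length",
    "sd_top",
    "sd_bottom",
]

#: sampling bounds per feature (truncated-normal support)
_FEATURE_BOUNDS = {
    "fad": (1e-6, np.inf),
    "nadh": (1e-6, np.inf),
    "ratio": (0.0, 1.0),
    "nuclear_position": (0.0, np.inf),
    "x_length": (0.5, np.inf),
    "y_length": (0.5, np.inf),
    "z_length": (0.5, np.inf),
    "sd_top": (1e-4, np.inf),
    "sd_bottom": (1e-4, np.inf),
}


@dataclass
class CellTypeParams:
    """Feature distribution and rendering recipe for one cell type.

    ``means``/``sds`` cover the nine directly sampled features (lengths
    in micrometres, intensities in detector units); aspect ratios and the
    SD ratio are recomputed from the sampled values so the defining
    identities hold exactly on every emitted row.
    """

    name: str
    means: dict[str, float]
    sds: dict[str, float]
    # rendering
    nucleus_radius_fraction: float = 0.55
    nucleus_intensity_scale: float = 0.15
    apical_fad_gradient: float = 0.2  # fractional apical FAD increase base->apex
    apical_puncta: bool = False  # ionocyte: bright FAD dots at the apex
    layered: bool = False  # hillock: cells alternate between two layers
    polygonal: bool = False  # hillock: squarish lateral cross-section
    void_probability: float = 0.0  # secretory: chance of one dark void
    void_radius_um: float = 1.5

    def __post_init__(self) -> None:
        if any(sd < 0 for sd in self.sds.values()):
            raise GeneratorError(f"{self.name}: negative feature SD")
        if self.means["fad"] <= 0 or self.means["nadh"] <= 0:
            raise GeneratorError(f"{self.name}: intensity means must be positive")


def default_type_params() -> dict[str, CellTypeParams]:
    """Parameters for the seven airway epithelial cell types.

    Satisfies the qualitative constraints described in the module
    docstring; absolute values are synthetic defaults in detector units
    and micrometres.
    """
    # (fad, nadh, ratio, nuclear_position, x_len, y_len, z_len, sd_top, sd_bottom)
    table = {
        # ciliated and secretory share their morphology (both tall columnar
        # luminal cells) and are separated almost entirely by their
        # autofluorescence, as in real airway epithelium
        #                 fad  nadh ratio  npos   x     y     z   sdt   sdb
        "basal":          (80,  90, 0.47,  3.0,  7.0,  5.0,  6.0, 0.05, 0.05),
        "ciliated":       (120, 60, 0.66, 10.0,  8.0,  5.5, 16.0, 0.08, 0.05),
        "secretory":      (60, 140, 0.30,  7.0,  8.0,  5.5, 16.0, 0.06, 0.05),
        "hillock":        (90,  80, 0.53,  6.0, 10.0,  8.0,  8.0, 0.05, 0.06),
        "ionocyte":       (55,  85, 0.40, 10.0,  6.0,  3.0, 14.0, 0.10, 0.04),
        "tuft":           (62,  85, 0.42, 11.0,  9.0,  4.0, 15.0, 0.06, 0.05),
        "neuroendocrine": (30,  45, 0.40,  5.0,  7.0,  4.0, 12.0, 0.04, 0.05),
    }
    rel_sd = {
        "fad": 0.08, "nadh": 0.08, "ratio": None, "nuclear_position": None,
        "x_length": 0.08, "y_length": 0.08, "z_length": 0.08,
        "sd_top": None, "sd_bottom": None,
    }
    abs_sd = {"ratio": 0.02, "nuclear_position": 1.0, "sd_top": 0.01, "sd_bottom": 0.01}

    params: dict[str, CellTypeParams] = {}
    for name, vals in table.items():
        means = dict(zip(SAMPLED_FEATURES, map(float, vals)))
        sds = {
            feat: (abs_sd[feat] if rel_sd[feat] is None else rel_sd[feat] * means[feat])
            for feat in SAMPLED_FEATURES
        }
        params[name] = CellTypeParams(
            name=name,
            means=means,
            sds=sds,
            apical_fad_gradient={"ciliated": 0.8, "ionocyte": 0.45, "tuft": 0.3}.get(name, 0.15),
            apical_puncta=(name == "ionocyte"),
            layered=(name == "hillock"),
            polygonal=(name == "hillock"),
            void_probability=BASELINE_VOID_PROBABILITY if name == "secretory" else 0.0,
        )
    return params


def load_type_params_from_table(table: pd.DataFrame) -> dict[str, CellTypeParams]:
    """Override the default per-type means/SDs from a per-cell feature CSV.

    The table needs a ``cell_type`` column plus the 12 feature columns;
    empirical per-type means and SDs of the nine sampled features replace
    the invented defaults, rendering recipes are kept.
    """
    params = default_type_params()
    for name, group in table.groupby("cell_type"):
        if name not in params:
            continue
        p = params[name]
        means = dict(p.means)
        sds = dict(p.sds)
        for feat in SAMPLED_FEATURES:
            if feat in group.columns:
                means[feat] = float(group[feat].mean())
                sds[feat] = float(group[feat].std(ddof=1)) if len(group) > 1 else 0.0
        params[name] = replace(p, means=means, sds=sds)
    return params


# ---------------------------------------------------------------------------
# feature-table sampling
# ---------------------------------------------------------------------------

def _trunc_normal(rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float, size: int) -> np.ndarray:
    if sd == 0:
        return np.full(size, np.clip(mean, lo, hi))
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def _normalize_counts(n_per_type: dict[str, int] | None) -> dict[str, int]:
    counts = dict(REFERENCE_COUNTS) if n_per_type is None else dict(n_per_type)
    unknown = set(counts) - set(CELL_TYPES)
    if unknown:
        raise GeneratorError(f"unknown cell types {sorted(unknown)}")
    if any(v < 0 for v in counts.values()):
        raise GeneratorError("invalid count: negative cells requested")
    return counts


def sample_feature_table(
    params: dict[str, CellTypeParams] | None = None,
    n_per_type: dict[str, int] | None = None,
    seed: int = 0,
    separation: float = 1.0,
) -> pd.DataFrame:
    """Draw a per-cell feature table from the per-type distributions.

    Each of the nine base features is a truncated normal with the type's
    mean and SD; aspect ratios and the SD ratio are recomputed from the
    sampled values, and the x/y length pair is ordered so x >= y.
    ``separation`` scales every type mean's offset from the grand mean
    (1 = defaults; 0 = all types identical), providing a difficulty dial
    for classifier studies.  Deterministic per seed.
    """
    params = params or default_type_params()
    counts = _normalize_counts(n_per_type)
    rng = np.random.default_rng(seed)

    grand = {
        feat: float(np.mean([p.means[feat] for p in params.values()]))
        for feat in SAMPLED_FEATURES
    }

    frames = []
    next_id = 1
    for name in CELL_TYPES:
        n = counts.get(name, 0)
        if n == 0:
            continue
        p = params[name]
        cols = {}
        for feat in SAMPLED_FEATURES:
            lo, hi = _FEATURE_BOUNDS[feat]
            mean = grand[feat] + separation * (p.means[feat] - grand[feat])
            cols[feat] = _trunc_normal(rng, mean, p.sds[feat], lo, hi, n)
        x_len = np.maximum(cols["x_length"], cols["y_length"])
        y_len = np.minimum(cols["x_length"], cols["y_length"])
        df = pd.DataFrame(
            {
                "cell_id": np.arange(next_id, next_id + n),
                "cell_type": name,
                "fad": cols["fad"],
                "nadh": cols["nadh"],
                "ratio": cols["ratio"],
                "nuclear_position": cols["nuclear_position"],
                "x_length": x_len,
                "y_length": y_len,
                "z_length": cols["z_length"],
                "aspect_xy": x_len / y_len,
                "aspect_yz": y_len / cols["z_length"],
                "sd_top": cols["sd_top"],
                "sd_bottom": cols["sd_bottom"],
                "sd_ratio": cols["sd_top"] / cols["sd_bottom"],
            }
        )
        next_id += n
        frames.append(df)
    if not frames:
        return pd.DataFrame(columns=TABLE_COLUMNS)
    return pd.concat(frames, ignore_index=True)[TABLE_COLUMNS]


# ---------------------------------------------------------------------------
# scene rendering
# ---------------------------------------------------------------------------

@dataclass
class SceneGeometry:
    """Spatial and noise parameters of a rendered scene.

    The default voxel size (0.5, 0.5, 1.0) um is a deliberately coarse
    sampling that keeps scenes compact while leaving every cell tens of
    voxels across; the curved epithelium is modeled as a 1D sinusoid
    along x (a proxy for tracheal curvature).
    """

    shape: tuple[int, int, int] = (40, 256, 256)  # (nz, ny, nx)
    voxel_size: tuple[float, float, float] = (0.5, 0.5, 1.0)  # (dx, dy, dz) um
    base_z: float = 10.0  # mean membrane depth, voxels
    curvature_amplitude: float = 4.0  # voxels
    curvature_period: float = 128.0  # voxels along x
    shg_intensity: float = 60.0
    shg_band_voxels: int = 4
    background: float = 2.0
    read_noise_sd: float = 2.0
    poisson_noise: bool = True


@dataclass
class SyntheticScene:
    """A rendered stack plus every piece of ground truth used to render it."""

    stack: MultiChannelStack
    labels: LabelVolume
    surface_truth: SurfaceMap
    feature_truth: pd.DataFrame
    void_truth: pd.DataFrame  # cell_id, z, y, x, radius_um, volume_um3
    seed: int
    params: dict[str, CellTypeParams] = field(repr=False, default=None)
    n_per_type: dict[str, int] = field(default=None)
    geometry: SceneGeometry = field(default=None)


def _fiber_texture(rng: np.random.Generator, ny: int, nx: int, n_fibers: int = 400) -> np.ndarray:
    """Sum of randomly oriented line segments, lightly smoothed: a cheap
    stand-in for the fibrous collagen texture seen in SHG."""
    from scipy.ndimage import gaussian_filter
    from skimage.draw import line

    img = np.zeros((ny, nx))
    for _ in range(n_fibers):
        y0, x0 = rng.integers(0, ny), rng.integers(0, nx)
        angle = rng.uniform(0, np.pi)
        length = rng.integers(10, 40)
        y1 = int(np.clip(y0 + length * np.sin(angle), 0, ny - 1))
        x1 = int(np.clip(x0 + length * np.cos(angle), 0, nx - 1))
        rr, cc = line(int(y0), int(x0), y1, x1)
        img[rr, cc] += rng.uniform(0.5, 1.5)
    img = gaussian_filter(img, 1.0)
    # rescale into [0.75, 1.25] so every column clears an Otsu threshold
    lo, hi = img.min(), img.max()
    if hi > lo:
        img = 0.75 + 0.5 * (img - lo) / (hi - lo)
    else:
        img = np.ones_like(img)
    return img


def _surface(geom: SceneGeometry) -> np.ndarray:
    nz, ny, nx = geom.shape
    x = np.arange(nx)
    z_line = geom.base_z + geom.curvature_amplitude * np.sin(2 * np.pi * x / geom.curvature_period)
    return np.broadcast_to(z_line, (ny, nx)).astype(float).copy()


def _render_shg(geom: SceneGeometry, z_surface: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    nz, ny, nx = geom.shape
    fiber = _fiber_texture(rng, ny, nx)
    z_idx = np.arange(nz)[:, None, None]
    # voxel z covers [z-0.5, z+0.5]; band occupies [z_s - t, z_s]
    top = z_surface[None]
    bottom = top - geom.shg_band_voxels
    coverage = np.clip(np.minimum(z_idx + 0.5, top) - np.maximum(z_idx - 0.5, bottom), 0, 1)
    return geom.shg_intensity * fiber[None] * coverage


def _max_pairwise(points: np.ndarray) -> float:
    """Exact max pairwise distance of a 2D point set (via its hull)."""
    from scipy.spatial import ConvexHull, QhullError

    if len(points) < 2:
        return 0.0
    try:
        pts = points[ConvexHull(points).vertices]
    except QhullError:
        pts = points
    d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
    return float(d.max())


def _grid_slots(geom: SceneGeometry, pitch: int, rng: np.random.Generator) -> list[tuple[int, int]]:
    nz, ny, nx = geom.shape
    margin = pitch // 2 + 1
    ys = np.arange(margin, ny - margin, pitch)
    xs = np.arange(margin, nx - margin, pitch)
    slots = [(int(y), int(x)) for y in ys for x in xs]
    rng.shuffle(slots)
    return slots


def _ellipsoid_mask(
    shape: tuple[int, int, int],
    center: tuple[float, float, float],
    semi: tuple[float, float, float],
    power: float = 2.0,
) -> tuple[np.ndarray, tuple[slice, slice, slice]]:
    """Boolean mask of a (super)ellipsoid within its bounding box."""
    cz, cy, cx = center
    sz, sy, sx = semi
    z0, z1 = max(0, int(np.floor(cz - sz))), min(shape[0], int(np.ceil(cz + sz)) + 1)
    y0, y1 = max(0, int(np.floor(cy - sy))), min(shape[1], int(np.ceil(cy + sy)) + 1)
    x0, x1 = max(0, int(np.floor(cx - sx))), min(shape[2], int(np.ceil(cx + sx)) + 1)
    if z0 >= z1 or y0 >= y1 or x0 >= x1:
        return np.zeros((0, 0, 0), bool), (slice(0, 0), slice(0, 0), slice(0, 0))
    zz, yy, xx = np.meshgrid(
        np.arange(z0, z1), np.arange(y0, y1), np.arange(x0, x1), indexing="ij"
    )
    p = power
    dist = (
        np.abs((zz - cz) / sz) ** 2
        + np.abs((yy - cy) / sy) ** p
        + np.abs((xx - cx) / sx) ** p
    )
    return dist <= 1.0, (slice(z0, z1), slice(y0, y1), slice(x0, x1))


def render_scene(
    params: dict[str, CellTypeParams] | None = None,
    n_per_type: dict[str, int] | None = None,
    geometry: SceneGeometry | None = None,
    seed: int = 0,
    intensity_scale: tuple[float, float] = (1.0, 1.0),
    void_probability_override: float | None = None,
) -> SyntheticScene:
    """Render a full synthetic multichannel scene with ground truth.

    Cells are placed on a shuffled non-overlapping lateral grid sitting on
    the curved membrane surface, rendered with their type's intensities
    (dark nuclei, apical FAD gradients, ionocyte puncta, secretory voids),
    then Poisson shot noise and Gaussian read noise are applied.  The
    returned scene carries the exact surface, labels, per-cell features
    and void list.

    ``intensity_scale`` (nadph_scale, fad_scale) and
    ``void_probability_override`` exist so perturbation presets can
    re-render the same scene (same seed, same placement) under altered
    physiology.

    Raises
    ------
    GeneratorError
        "placement failure" when the field cannot hold the requested cells.
    """
    params = params or default_type_params()
    counts = _normalize_counts(n_per_type)
    geom = geometry or SceneGeometry()
    rng = np.random.default_rng(seed)
    nz, ny, nx = geom.shape
    dx, dy, dz = geom.voxel_size
    nadph_scale, fad_scale = intensity_scale

    z_surface = _surface(geom)
    shg_clean = _render_shg(geom, z_surface, rng)

    # lateral pitch from the widest type present
    widest_um = max(
        (params[t].means["x_length"] for t, n in counts.items() if n > 0), default=8.0
    )
    pitch = int(np.ceil(widest_um * 1.15 / dx)) + 2
    slots = _grid_slots(geom, pitch, rng)
    n_cells = sum(counts.values())
    if n_cells > len(slots):
        raise GeneratorError(
            f"placement failure: {n_cells} cells requested, {len(slots)} grid slots "
            f"available at pitch {pitch}"
        )

    nadph_clean = np.full(geom.shape, geom.background, dtype=np.float64)
    fad_clean = np.full(geom.shape, geom.background, dtype=np.float64)
    labels = np.zeros(geom.shape, dtype=np.int32)
    type_of: dict[int, str] = {}
    truth_rows = []
    void_rows = []

    cell_id = 0
    for name in CELL_TYPES:
        p = params.get(name)
        for i in range(counts.get(name, 0)):
            cell_id += 1
            cy, cx = slots[cell_id - 1]
            base = float(z_surface[cy, cx])

            x_len = max(float(_trunc_normal(rng, p.means["x_length"], p.sds["x_length"], 1.0, np.inf, 1)[0]), 2 * dx)
            y_len = max(float(_trunc_normal(rng, p.means["y_length"], p.sds["y_length"], 1.0, np.inf, 1)[0]), 2 * dy)
            x_len, y_len = max(x_len, y_len), min(x_len, y_len)
            z_len = max(float(_trunc_normal(rng, p.means["z_length"], p.sds["z_length"], 1.0, np.inf, 1)[0]), 2 * dz)
            sx, sy, sz = x_len / 2 / dx, y_len / 2 / dy, z_len / 2 / dz

            layer_lift = sz if (p.layered and i % 2 == 1) else 0.0
            cz = base + sz + layer_lift
            if cz + sz > nz - 1:  # clamp tall cells into the volume
                cz = nz - 1 - sz
            power = 4.0 if p.polygonal else 2.0
            mask, box = _ellipsoid_mask(geom.shape, (cz, cy, cx), (sz, sy, sx), power)
            mask &= labels[box] == 0
            if mask.sum() < 8:
                continue
            labels[box][mask] = cell_id
            type_of[cell_id] = name

            nadph_cell = nadph_scale * float(
                _trunc_normal(rng, p.means["nadh"], p.sds["nadh"], 1e-3, np.inf, 1)[0]
            )
            fad_cell = fad_scale * float(
                _trunc_normal(rng, p.means["fad"], p.sds["fad"], 1e-3, np.inf, 1)[0]
            )
            zz_box = np.arange(box[0].start, box[0].stop)[:, None, None]
            apical_frac = np.clip((zz_box - (cz - sz)) / (2 * sz), 0, 1)
            fad_field = fad_cell * (1 + p.apical_fad_gradient * (apical_frac - 0.5))
            nadph_box = nadph_clean[box]
            fad_box = fad_clean[box]
            nadph_box[mask] = nadph_cell
            fad_box[mask] = np.broadcast_to(fad_field, mask.shape)[mask]

            # a void (if any) is placed just below the apex; decided before
            # the nucleus so the nucleus can be kept clear of it
            v_prob = (
                void_probability_override
                if (void_probability_override is not None and name == "secretory")
                else p.void_probability
            )
            has_void = bool(rng.uniform() < v_prob)
            v_cz = cz + sz - p.void_radius_um / dz - 1.5

            # nucleus: dark ellipsoid at the sampled nuclear height
            n_pos = float(
                _trunc_normal(rng, p.means["nuclear_position"], p.sds["nuclear_position"], 0.0, np.inf, 1)[0]
            )
            nuc_cz = np.clip(base + n_pos / dz, cz - sz * 0.45, cz + sz * 0.45)
            if has_void:
                # keep the nucleus top >= 2 voxels below the void bottom
                nuc_top_max = v_cz - p.void_radius_um / dz - 2
                nuc_cz = min(nuc_cz, nuc_top_max - 0.55 * sz)
            nuc_semi = (
                max(p.nucleus_radius_fraction * sz, 1.2),
                max(p.nucleus_radius_fraction * sy, 1.2),
                max(p.nucleus_radius_fraction * sx, 1.2),
            )
            nuc_mask, nuc_box = _ellipsoid_mask(geom.shape, (nuc_cz, cy, cx), nuc_semi)
            nuc_mask &= labels[nuc_box] == cell_id
            nadph_clean[nuc_box][nuc_mask] *= p.nucleus_intensity_scale
            fad_clean[nuc_box][nuc_mask] *= p.nucleus_intensity_scale * 0.9
            if nuc_mask.any():  # digitized nucleus centroid, truth for nuclear position
                nuc_cz = float(np.nonzero(nuc_mask)[0].mean() + nuc_box[0].start)

            # ionocyte apical FAD puncta
            if p.apical_puncta:
                for _ in range(int(rng.integers(2, 4))):
                    off_y = rng.uniform(-0.4, 0.4) * sy
                    off_x = rng.uniform(-0.4, 0.4) * sx
                    pm, pbox = _ellipsoid_mask(
                        geom.shape,
                        (cz + 0.7 * sz, cy + off_y, cx + off_x),
                        (1.2, 1.5, 1.5),
                    )
                    pm &= labels[pbox] == cell_id
                    fad_clean[pbox][pm] = fad_cell * 3.0

            # secretory void: one dark sphere just below the apex
            if has_void:
                r_um = p.void_radius_um
                v_semi = (r_um / dz, r_um / dy, r_um / dx)
                v_cy = float(cy)
                vm, vbox = _ellipsoid_mask(geom.shape, (v_cz, v_cy, cx), v_semi)
                vm &= labels[vbox] == cell_id
                if vm.sum() >= 4:
                    nadph_clean[vbox][vm] = geom.background * 0.2
                    fad_clean[vbox][vm] = geom.background * 0.2
                    void_rows.append(
                        {
                            "cell_id": cell_id,
                            "z": float(v_cz),
                            "y": float(v_cy),
                            "x": float(cx),
                            "radius_um": r_um,
                            "volume_um3": 4 / 3 * np.pi * r_um**3,
                        }
                    )

            # geometric truth uses the digitized extents of the rendered
            # mask (max pairwise distance of the lateral projection for the
            # long axis, bounding-box span for the short one, plus the
            # one-voxel footprint), so it refers to the object that actually
            # exists in the volume; sampled analytic lengths kept alongside
            mz, my, mx = np.nonzero(mask)
            z_span = (mz.max() - mz.min() + 1) * dz
            proj = np.unique(np.stack([my * dy, mx * dx], axis=1), axis=0)
            x_d = _max_pairwise(proj) + 0.5 * (dx + dy)
            spans = ((my.max() - my.min() + 1) * dy, (mx.max() - mx.min() + 1) * dx)
            y_d = min(min(spans), x_d)
            truth_rows.append(
                {
                    "cell_id": cell_id,
                    "cell_type": name,
                    "nadph_base": nadph_cell,
                    "fad_base": fad_cell,
                    "nuclear_position": (nuc_cz - base) * dz,
                    "x_length": x_d,
                    "y_length": y_d,
                    "z_length": z_span,
                    "aspect_xy": x_d / y_d,
                    "aspect_yz": y_d / z_span,
                    "x_length_sampled": x_len,
                    "y_length_sampled": y_len,
                    "z_length_sampled": z_len,
                    "center_z": cz,
                    "center_y": float(cy),
                    "center_x": float(cx),
                }
            )

    # per-cell intensity/ratio truth measured on the clean volumes, with the
    # same denominator-floor convention the ratio extractor uses (1% of range)
    total_clean = nadph_clean + fad_clean
    floor = 0.01 * max(nadph_clean.max(), fad_clean.max())
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio_clean = np.where(total_clean >= floor, fad_clean / total_clean, np.nan)
    for row in truth_rows:
        m = labels == row["cell_id"]
        row["fad"] = float(fad_clean[m].mean())
        row["nadh"] = float(nadph_clean[m].mean())
        row["ratio"] = float(np.nanmean(ratio_clean[m]))
        zs = np.nonzero(m)[0]
        mid = 0.5 * (zs.max() + zs.min())
        z_idx = np.arange(nz)[:, None, None]
        top = m & (z_idx > mid)
        bot = m & (z_idx <= mid)
        row["sd_top"] = float(np.nanstd(ratio_clean[top])) if top.any() else np.nan
        row["sd_bottom"] = float(np.nanstd(ratio_clean[bot])) if bot.any() else np.nan
        row["sd_ratio"] = (
            row["sd_top"] / row["sd_bottom"] if row["sd_bottom"] else np.nan
        )

    # detector noise
    if geom.poisson_noise:
        nadph = rng.poisson(nadph_clean).astype(np.float64)
        fad = rng.poisson(fad_clean).astype(np.float64)
        shg = rng.poisson(shg_clean).astype(np.float64)
    else:
        nadph, fad, shg = nadph_clean.copy(), fad_clean.copy(), shg_clean.copy()
    if geom.read_noise_sd > 0:
        nadph = np.clip(nadph + rng.normal(0, geom.read_noise_sd, geom.shape), 0, None)
        fad = np.clip(fad + rng.normal(0, geom.read_noise_sd, geom.shape), 0, None)
        shg = np.clip(shg + rng.normal(0, geom.read_noise_sd, geom.shape), 0, None)

    stack = MultiChannelStack(
        nadph=nadph,
        fad=fad,
        shg=shg,
        voxel_size=geom.voxel_size,
        metadata={"synthetic": True, "seed": seed},
    )
    feature_truth = pd.DataFrame(truth_rows)
    if not feature_truth.empty:
        ordered = TABLE_COLUMNS + [
            c for c in feature_truth.columns if c not in TABLE_COLUMNS
        ]
        feature_truth = feature_truth[ordered]
    void_truth = pd.DataFrame(
        void_rows, columns=["cell_id", "z", "y", "x", "radius_um", "volume_um3"]
    )
    surface_truth = SurfaceMap(
        z_surface=z_surface,
        valid_mask=np.ones((ny, nx), bool),
        smoothing_params={"analytic": True},
    )
    return SyntheticScene(
        stack=stack,
        labels=LabelVolume(labels=labels, type_of=type_of),
        surface_truth=surface_truth,
        feature_truth=feature_truth,
        void_truth=void_truth,
        seed=seed,
        params=params,
        n_per_type=counts,
        geometry=geom,
    )


# ---------------------------------------------------------------------------
# perturbation presets
# ---------------------------------------------------------------------------

#: (nadph scale, fad scale, secretory void probability or None)
PERTURBATION_PRESETS = {
    # complex I/III inhibition: NAD(P)H accumulates, redox ratio falls
    "rotenone_antimycin": (1.6, 1.0, None),
    # uncoupling: NAD(P)H is oxidized away, redox ratio rises
    "fccp": (0.6, 1.0, None),
    # cholinergic stimulus: both channels shift and secretory cells form
    # dark voids at high incidence (0.78 vs 0.09 at baseline)
    "methacholine": (1.2, 0.9, 0.78),
}

#: baseline incidence of secretory-cell voids (before stimulation)
BASELINE_VOID_PROBABILITY = 0.09
#: incidence after cholinergic (methacholine) stimulation
STIMULATED_VOID_PROBABILITY = 0.78


def apply_perturbation(scene: SyntheticScene, preset: str) -> SyntheticScene:
    """Re-render a scene under a pharmacologic perturbation preset.

    The same seed, geometry and placement are reused so the output is a
    paired observation of the identical cells under altered physiology.

    Raises
    ------
    GeneratorError
        "invalid preset" for unknown preset names.
    """
    if preset not in PERTURBATION_PRESETS:
        raise GeneratorError(
            f"invalid preset {preset!r}; choose from {sorted(PERTURBATION_PRESETS)}"
        )
    nadph_scale, fad_scale, void_prob = PERTURBATION_PRESETS[preset]
    return render_scene(
        params=copy.deepcopy(scene.params),
        n_per_type=scene.n_per_type,
        geometry=scene.geometry,
        seed=scene.seed,
        intensity_scale=(nadph_scale, fad_scale),
        void_probability_override=void_prob,
    )
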