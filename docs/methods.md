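# Methods

This note documents the models, algorithms and parameter choices behind
`airwayaf`, what the synthetic-data generator does and does not emulate,
and the limitations a user should know about.

## Geometry and conventions

Volumes are `(z, y, x)` arrays with 0-based voxel indices. After loading,
z always increases from tissue (basement-membrane side) toward the lumen;
stacks declared in the opposite orientation are flipped. The default
voxel size when a file carries no geometry is (0.25, 0.25, 0.5) µm: the
axial step matches a typical two-photon z-stack, and the lateral pitch is
an estimate for a 25× lens at 2× zoom with a 1024×1024 scan — it must be
overridden when the true pitch is known, since every length feature
scales with it. Intensities are kept in detector units as floats; no
normalization is applied at load time.

## Basement-membrane detection and flattening

Collagen under the epithelium produces a strong second-harmonic (SHG)
signal, while the epithelium itself produces essentially none. The
surface model is, per lateral column:

1. binarize the SHG volume at a global Otsu threshold (overridable with
   an absolute value);
2. scanning from the lumen, accept the first crossing that persists for
   ≥ 3 consecutive voxels going into the tissue (persistence suppresses
   speckle from isolated fibers);
3. refine the crossing to sub-voxel precision against the local
   *half-maximum* level, midway between the background just above the
   crossing and the band interior just below it. Otsu is good at
   separating the classes but sits far from the edge midpoint when class
   sizes are unbalanced, so interpolating against Otsu itself biases the
   surface by several tenths of a voxel; half-max localization is the
   standard remedy;
4. median-filter (5×5) then Gaussian-smooth (σ = 2 px) the depth map —
   the membrane is smooth at cell scale;
5. inpaint columns with no sustained crossing (cartilage shadows, local
   dropouts) from their nearest valid neighbor, and flag them invalid.
   If more than half the columns are invalid the surface is declared
   undetectable.

Flattening shifts each column in z by `z_surface − reference_z`, linear
interpolation by default. Linear interpolation blends neighboring
voxels; an integer-shift mode is provided that permutes voxels instead,
preserving per-column intensity sums exactly and making flattening
idempotent to machine precision. On rendered scenes the recovered
surface has RMSE ≲ 0.2 voxels against the analytic truth for curvature
amplitudes up to 10 voxels, and re-detecting the surface after
flattening gives sub-voxel roughness.

Label volumes are always flattened with integer shifts so label
identities are never blended.

## Redox ratio and per-cell features

The ratio volume is `fad / (fad + nadph)` wherever the denominator
reaches a floor ε, by default 1% of the joint channel dynamic range;
voxels below the floor (nuclei, voids, background) are NaN and excluded
from every statistic. The floor suppresses ratio noise where both
channels are near zero. Scale invariance (multiplying both channels by
c > 0 changes nothing) holds exactly on the defined mask.

The nucleus of a cell is the largest connected region of total
autofluorescence (NAD(P)H + FAD) strictly below the cell's 0.2 quantile,
subject to a 30-voxel minimum — nuclei carry almost no fluorophores and
image as dark holes. The reported centroid is darkness-weighted
(weight = threshold − AF): the quantile rule inevitably annexes a fringe
of dim cytoplasm to the dark component, and those near-threshold voxels
would otherwise drag the centroid; weighting by how far below threshold
a voxel sits makes the centroid track the dark nuclear core. A cell of
uniform intensity has no sub-threshold voxels and raises "nucleus not
found".

The 12 descriptors per cell: mean FAD, mean NADH, mean per-voxel ratio
(mean of voxel ratios, not ratio of means — consistent with the SD
features, which are also per-voxel), nuclear position ((centroid z −
reference z)·dz, µm), X length (maximum Feret/caliper diameter of the XY
projection), Y length (minimum Feret width via rotating calipers over
the convex hull), Z length (voxel-plane span), aspect ratios X/Y and
Y/Z, and the SD of the ratio strictly above / at-or-below the cell's
mid-height plane plus their quotient. "Lengths" are Feret diameters
rather than bounding-box sides so that obliquely oriented or polygonal
cells are measured by their true extents. One pixel is added to the
lateral calipers and one plane to the z span for the finite voxel
footprint (a run of k pixels spans k pixel widths; its center-to-center
distance is k − 1); with that convention a digitized ellipsoid with
semi-axes (5, 2, 4) µm measures (10, 4, 8) µm within one voxel, and the
error vanishes as the voxel size does. Feret computations use
mask-corner-relative coordinates, which makes the features bit-identical
under lateral translation. The mid-height split for the SD features is
the deterministic reading of "cell top / cell bottom"; an alternative
split at the nucleus would inherit nucleus-detection noise.

Cells below 50 voxels are dropped (logged); a failed nucleus gives a NaN
nuclear position, median-imputed at classification time.

Paired perturbation comparisons use a two-sided paired t-test on
per-cell ratio differences; with zero variance (identical conditions)
the statistic is undefined and reported as NaN.

## Classification

The feature table is classified with three models: k-nearest neighbors
(k = 3), multinomial logistic regression (L2, up to 1000 iterations),
and gradient-boosted trees (XGBoost; 200 trees, depth 3, learning rate
0.1, fixed seed, gain importances normalized to sum to 1). Distance- and
margin-based models receive z-scored features; trees consume raw
features and are invariant to monotone per-feature scaling (verified by
test). Splits are stratified 75/25 with round-half-up test size — 206
cells give 154 train / 52 test — falling back to unstratified with a
warning when a class has fewer than 2 members. Accuracy and the
multiclass Matthews Correlation Coefficient come from scikit-learn; the
confusion matrix is reported in the fixed vocabulary order (basal,
ciliated, secretory, hillock, ionocyte, tuft, neuroendocrine).

Because single-split accuracy on 52 cells is quantized in steps of ~2%
and depends on the split seed, headline performance is always reported
as the mean over repeated stratified splits
(`repeated_split_performance`).

UMAP uses random_state 42, spread 3, min_dist 0.1, n_neighbors 15 on
z-scored, median-imputed features; a fixed random_state makes the
embedding bitwise reproducible.

## Void (SAP) detection and tracking

Secretory-cell-associated antigen passages image as non-fluorescent,
roughly spherical intracellular voids distinct from the nucleus. The
detector reuses the nucleus rule's dark-voxel threshold (0.2 quantile of
the cell's total AF) and calls every connected dark component that

- does not intersect or touch the nucleus component (the largest dark
  region is the nucleus; a dark region merged with it cannot be
  separated and is not called),
- has volume ≥ 0.5 µm³,
- has sphericity π^⅓(6V)^⅔ / A ≥ 0.5, with the surface area A measured
  on the marching-cubes isosurface of the component at the stack's
  anisotropic voxel spacing (rejects cracks and shading sheets), and
- has at most 30% of its voxels in contact with the cell exterior: a
  genuine void clipped by the cell border touches it over a small cap,
  whereas the one-voxel dark fringes that interpolation leaves along the
  apical surface after flattening hug the border with most of their
  voxels.

The original void criterion was human judgment; these thresholds are
this package's deterministic operationalization and are all
configurable. On rendered scenes with r ≥ 1 µm injected voids at the
acquisition voxel size, detection precision and recall are ≥ 0.9 (1.0 in
the shipped benchmarks). The volume gate is expressed in µm³, so at
coarse voxel sizes (≥ 0.25 µm³/voxel) it admits very small components;
void analyses should run at acquisition resolution.

The fraction of cells with ≥ 1 void carries an exact (Clopper–Pearson)
binomial CI. Tracking across frames is greedy nearest-centroid linking
within a gating radius (default 2 µm): closest pairs link first, calls
with no track within the gate open new tracks ("uptake" when after the
first frame), unmatched tracks close ("disappearance"/secretion). When a
FITC channel exists, a void is annotated dextran-positive if its mean
FITC exceeds the cell background by 2 SD — an annotation, never a
detection gate. A membrane-shell filter is not implemented beyond the
annotation hook: membrane-boundedness is not decidable from
autofluorescence alone.

## The synthetic generator

The generator emulates, with full ground truth: a curved epithelial
sheet (1D sinusoid along x — a tractable proxy for tracheal curvature;
default amplitude 4 voxels, period 128), a fibrous SHG band (4 voxels
thick, random line-segment texture rescaled to 0.75–1.25 of the band
intensity, partial-volume rendering at the band top), and seven cell
types as non-overlapping (super)ellipsoids seated on the membrane, with
dark nuclei, apical FAD gradients, ionocyte apical FAD puncta, a locally
doubled layer of squarish cells for hillocks, and optional dark
spherical voids in secretory cells. Poisson shot noise plus Gaussian
read noise (σ = 2) model the detector. Every output is a pure function
of (parameters, seed).

Numeric per-type feature means are **invented**: the qualitative
structure is constrained — ciliated > basal > secretory in redox ratio;
neuroendocrine dimmest in both channels; the three rare types within
0.05 of each other in ratio (they cannot be separated by ratio alone);
basal cells lowest on the membrane; ciliated and secretory sharing their
morphology so that the common columnar types are separated almost
entirely by autofluorescence — but the absolute values are synthetic
defaults. `load_type_params_from_table` replaces them with empirical
per-type means/SDs from any per-cell feature CSV. Sampled tables draw
each base feature from a truncated normal and recompute the aspect and
SD-ratio identities exactly; a `separation` dial scales all between-type
mean differences for difficulty studies.

Scene ground truth records what was actually rendered: digitized mask
extents (hull max-pairwise distance and bounding-box width, one-voxel
footprint) rather than the sampled analytic lengths, and the digitized
nucleus centroid. At the default coarse scene voxels (0.5, 0.5, 1.0) µm
the difference between analytic and digitized lengths reaches ~16% for
the smallest cells, which is a property of voxelization, not of the
extractor; the sampled values are kept in `*_sampled` columns.

Perturbation presets re-render the same scene (same seed, same
placement) under scaled physiology, giving genuinely paired
observations: rotenone+antimycin scales NAD(P)H ×1.6 (ratio falls), FCCP
×0.6 (ratio rises), methacholine scales NAD(P)H ×1.2 / FAD ×0.9 and
raises the secretory void incidence from the 0.09 baseline to 0.78.

What the generator does **not** emulate: optical PSF blur and axial
elongation, depth-dependent attenuation, autofluorescence spectral
bleed-through, cell crowding/contact (cells are isolated on a grid),
cilia, immune cells, and real biological variance structure
(within-type feature correlations are zero by construction). Passing
tests on generated scenes therefore demonstrate the correctness of the
geometry, statistics and bookkeeping — not that classification accuracy
or detection rates will transfer to real tissue, where the types overlap
more and segmentation masks are imperfect. Classifier scores on the
default generator should be read as an upper bound.

## Problem sizes in the shipped checks

The test suite and `scripts/acceptance.py` use: 40×256×256 scenes (up to
10-voxel curvature) for surface recovery; 206-cell tables at the
reference composition with 20–50 repeated splits for classification;
100 secretory cells at (0.25, 0.25, 0.5) µm voxels for void recovery at
the 0.09 and 0.78 incidences; and a 17-cell mixed scene for the paired
perturbation checks. These sizes keep a full run to a few minutes on one
CPU while leaving every estimate's sampling error well inside the
asserted tolerances.

## Known limitations

- Surface detection assumes the SHG band is the shallowest sustained
  signal; strong luminal debris with SHG contrast would fool it.
- Flattening translates columns independently; it does not unroll the
  cylinder, so lateral distances on strongly curved fields remain
  slightly distorted, and no depth-attenuation correction is applied.
- X/Y lengths assume approximately isotropic lateral sampling (dx ≈ dy);
  the Feret correction uses their mean.
- Cell masks are inputs (from staining-derived boundaries or synthetic
  truth); the package does not segment cells from autofluorescence.
- The exact train/test split of any external reference dataset is
  unknowable from summary numbers alone, so comparisons are made on
  split-averaged performance, not on a single split.
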