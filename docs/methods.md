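# Methods

This note documents the models, numerical choices and synthetic test
substrate behind `cytotome`, in the spirit of a package's own methods
appendix: what is computed, under which assumptions, and what the tests do
and do not establish.

## Cell-size grading

Somata in a nuclear-stain image are graded by which morphological openings
they survive. The model assumption is purely geometric: a foreground
component survives opening with a disk/ball structural element (SE) of
radius r iff it can contain that SE. With SE radii (6, 10, 14) px at
0.65 µm/px, the survival bands correspond to soma radii of roughly
< 4 µm (noise), 4–6.5 µm (small), 6.5–9 µm (medium) and > 9 µm (large)
cross-sections. No instance segmentation is attempted — adhered cells are
graded as the patch they form, which is the price of whole-brain
throughput.

Numerical choices:

* **Openings via distance transforms.** Erosion by the Euclidean SE
  {o : |o| ≤ r} equals thresholding the Euclidean distance transform at r;
  dilation is the complementary threshold. This is pixel-identical to
  explicit SE-shift morphology (the test oracle) and O(n) in image size.
  Outside the image counts as background, so the operation is
  anti-extensive at borders too.
* **Sequential cascade.** Each opening round re-opens the previous round's
  output. For ideal Euclidean disks, opening the original mask per radius
  would be equivalent, but *digital* disks are not exactly unions of
  smaller digital-disk translates, so only the sequential composition
  guarantees the nesting O₆ ⊇ O₁₀ ⊇ O₁₄ that grade banding requires.
  Near the survival threshold (component radius within ~2 px of an SE
  radius) the digital band edges are approximate; the phantoms therefore
  use soma radii at least 2 px away from SE radii.
* **Adaptive threshold.** Foreground = pixel > local mean (101 px window,
  reflected borders) + offset (2% of the dynamic range by default). Both
  are configurable; isolated threshold noise is absorbed into grade 0 by
  the first opening.
* **Top-hat before binarization** (disk SE radius 20 px, slightly larger
  than the largest soma) flattens smooth background. On synthetic volumes
  with flat background it is a no-op and may be skipped
  (`grade_slices(..., tophat_radius_px=None)`).
* **Enhancement.** Mean projection of per-grade indicators over 8 adjacent
  slices; each RGB channel is rescaled so its 99th percentile of positive
  values maps to 1 (grade abundances differ by orders of magnitude).
* The 3D variant binarizes slice-wise in the three orthogonal plane
  families, averages the three masks, Gaussian-smooths, re-thresholds at
  0.5, and opens with ball SEs.

## Cortical coordinate system

The cortex between the layer-I/II interface and the GM/WM interface is
modelled as a Laplace domain: laminae are isopotentials, columns are
gradient streamlines. This assumes the mask is a single handle-free,
cavity-free 26-connected component (checked by `validate_mask`, which
counts components, cavities and the boundary-surface Euler characteristic
χ∂ = 2(V − E + F − C) of the cubical complex; genus = components +
cavities − χ∂/2). Layer I is assumed already removed from the mask, as
in-vitro sulcal banks nearly touch and layer I boundaries are unreliable.

* **Discretization.** 6-neighbour stencil on the isotropic 12 µm analysis
  grid. Dirichlet values at labelled boundary voxels are imposed *at the
  shared voxel face* by ghost reflection (u_ghost = 2g − u_P), placing the
  effective interface half a voxel outside the outermost cortex voxels —
  exactly where the streamline tracer terminates, and second-order accurate
  for flat interfaces. Unlabelled background neighbours act as homogeneous
  Neumann walls.
* **Solver.** The resulting SPD system is solved by Jacobi-preconditioned
  conjugate gradients (direct sparse solve below 4000 unknowns); `tol`
  (default 10⁻³) bounds the final max-norm stencil residual. The discrete
  maximum principle keeps interior values inside the boundary range.
* **Accuracy.** Against the closed-form annulus solution
  u(r) = u_in·(1/r − 1/r_out)/(1/r_in − 1/r_out), the radially binned
  profile agrees to ~0.2% of range on a 96³ grid (bins of one voxel width;
  nominal radii apply because of the face-centred interfaces). Per-voxel
  errors at staircase boundary voxels reach ~2% — an irreducible
  half-voxel boundary-position ambiguity times the local gradient, not
  solver error — and the per-voxel L1 error decreases monotonically under
  grid refinement (64³ → 96³ → 128³).
* **Streamlines.** Fixed-step Euler integration (step = 0.5 voxel) of the
  trilinearly interpolated unit gradient, traced from every cortex voxel
  both downhill (to the outer interface) and uphill; a streamline
  terminates when its nearest voxel leaves the cortex, which for
  axis-aligned geometry stops exactly at the interface face. Depth =
  L_outer / (L_outer + L_inner); thickness = L_outer + L_inner; each
  crossing overshoots by at most one step in oblique geometry. Runaway
  paths beyond 4× the grid extent are flagged truncated and their voxels
  inherit depth from the nearest traced voxel. RK4 was considered and not
  adopted: at step 0.5 voxel the Euler error is far below the voxelization
  error of the field itself.
* **Mid-surface and radial units.** The midpoint of each streamline
  (reached by marching |L_out − L_in|/2 from the seed toward the longer
  side) is snapped to its nearest cortex voxel; unique midpoint voxels get
  contiguous IDs in lexicographic (z, y, x) order, and every cortex voxel
  maps to its streamline's midpoint ID. Radial units are the k nearest
  mid-surface voxels of each centre by *Euclidean distance in physical
  space* (ties broken lexicographically). Across a near-touching sulcus,
  Euclidean KNN can in principle group banks that are geodesically far
  apart; the sulcus phantom exists to quantify this, and a geodesic option
  is a possible extension, not implemented.

## Laminar signals, clustering, tomograms

* Cube densities divide per-grade pixel counts by *all* pixels of the
  12 µm cube (partial edge cubes by their actual member count); laminate
  bins are half-open with the last closed at 1, and a cube's depth is the
  solved depth at its analysis-grid voxel. Laminates left empty by thin
  cortex are imputed from the nearest populated laminate and flagged.
* PCA is column-centred; the retained component count is the smallest m
  whose cumulative explained variance reaches the configured fraction
  (0.95), and scores are z-normalized per component — giving each retained
  direction equal weight in the distance and making β scale-free.
* The MRF is a Potts model over a symmetrized 6-nearest-neighbour graph of
  unit centres, β = 1.0 on z-scored scores, optimized by ICM with
  sequential (unit-ID-ordered) label updates and centroid re-estimation
  between sweeps; both steps lower the energy, so the per-sweep energy
  trace is non-increasing (asserted at runtime). ICM is greedy and only
  locally optimal — the K-means initialization is what anchors it near a
  good solution. Empty clusters are permitted and reported.
* Tomogram maps average cube densities per unit within nine equal depth
  intervals spanning [0.05, 0.95]; depths outside that range are trimmed
  (boundary laminae are dominated by interface voxelization). Montage
  brightness is normalized per (grade, interval) panel by default, or per
  grade on request. Mesh faces for PLY/VTK export are a cosmetic
  triangulation of 26-adjacent surface voxels; the per-vertex scalars are
  the data.

## Synthetic phantoms: what they emulate, and what they do not

Phantoms define geometry on the analysis grid and an expected volume
fraction per size class at every point: region laminar profile
(cells/mm³, per depth bin) × soma volume, optionally modulated laterally
(barrel grids). Two output modes:

* **`graded`** draws each 3 µm render voxel's grade i.i.d. from the local
  class fractions — an idealized, already-graded volume with binomial
  counting noise (~64 px per 12 µm cube). It isolates the coordinate,
  feature and clustering stages from grading imperfections.
* **`intensity`** places somata by an inhomogeneous Poisson process and
  renders them as filled balls (intensity 200 on background 20, Gaussian
  noise SD 10, optional smooth ramp). The rendered fidelity phantom
  (isotropic 0.75 µm/px, class radii 6/9/15 µm = 8/12/20 px) exercises the
  real grading path; recovered per-class laminar density curves correlate
  with truth at r ≥ 0.8 despite the known 2D-method bias that off-equator
  slices of large somata band into smaller grades.

Study conditions fixed in the canned phantoms (chosen once, at design
time): slabs ~24 analysis cubes (~290 µm) thick — a desk-scale stand-in
for real cortex, thick enough for 20 laminates at one cube per laminate;
three-region profiles with a mid-depth small-cell peak (granular-like), a
deep large-pyramid excess (agranular-like) and an intermediate mix; barrel
pitch 96 µm with contrast 0.5 at mid depth; the smooth control varies over
a wavelength of twice the lateral extent, chosen from the explicit
criterion that disk-mean attenuation 2·J₁(qR)/(qR) at the largest unit
size (k = 1000, R ≈ 18 cubes) stays ≥ 0.95, i.e. the control is smooth
*relative to every unit size swept*.

What passing phantom tests do **not** show about real data: no optics
(PSF, depth attenuation, stitching seams), no vasculature shadows or
staining gradients beyond a linear ramp, somata are perfect balls with a
single intensity, and region boundaries are crisp. The phantoms validate
the machinery — geometry handling, counting, recovery under sampling
noise — not robustness to acquisition artifacts.

## Degenerate inputs and tie-breaks

Zero-gradient (saddle) voxels are flagged singular and their streamlines
terminate in place (depth then imputed). k larger than the surface is
clamped with a warning. Masks failing topology checks are reported;
`repair_mask` fixes components and cavities only — handles require
anatomical judgement. All randomness flows from explicit seeds
(`numpy.random.default_rng`; scikit-learn `random_state`), and repeated
runs are bitwise identical.

## Problem sizes used in the shipped tests

Laplace accuracy uses shells up to 128³; end-to-end parcel recovery runs
ten seeds of a (26, 20, 72)-cube slab (~2200 radial units); the
radial-unit-size sweep uses a (22, 50, 50) barrel slab and a (22, 96, 96)
smooth slab with k ∈ {10, 50, 200, 1000}; the rendered fidelity phantom is
(14, 26, 26) cubes at 0.75 µm (~34M voxels). These sizes were chosen as the
smallest at which each property is comfortably out of the noise.

## Known limitations

* Euclidean (not geodesic) KNN radial units can bridge near-touching
  sulcal banks at large k.
* Depth is pure streamline arc-length fraction; no equivolumetric
  correction for curvature-induced laminar thickness changes.
* The 2D grading path underestimates large-cell density (slice-geometry
  bias); the 3D ball-SE path avoids this but needs isotropic data.
* ICM finds local optima of the Potts energy; β, K and the adjacency
  degree are fixed choices, not model-selected.
* Imputation of empty laminates copies the nearest populated laminate,
  which flattens genuine gradients in very thin cortex.
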