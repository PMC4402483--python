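# Methods

## Model and procedure

2D singular spectrum analysis decomposes an image additively without a
prior noise model. The trajectory matrix stacks vectorized moving-window
contents as columns; its SVD is optimal in the sense that the leading
partial sums are the best low-rank approximations, and a grouped partial
sum is mapped back to image space by averaging all matrix cells that read
the same pixel. Because the embedding is linear and the back-projection is
a per-pixel mean, reconstruction is exactly additive: the components of
any partition of the eigentriples sum to the original image on every pixel
covered by at least one window placement.

Fields that satisfy linear recurrences — products of polynomials,
exponentials and sinusoids — have finite rank under this embedding (a
constant or separable exponential is rank 1, a sinusoid rank 2), which is
what makes frequency-based grouping work: smooth expression trends load a
few leading low-frequency components, a periodic stripe pattern loads an
oscillatory pair, and noise spreads thinly over the tail.

Two embedding variants extend the rectangular method:

* **Circular** — window anchor positions advance modulo the image size on
  a periodic axis, so placements wrap across the seam. We wrap the *anchor
  grid* per circular axis (each wrapped placement reads pixels through the
  modulus); an alternative reading would also enlarge the anchor set on
  the non-circular axis, but anchor wrapping reproduces the printed
  worked-example matrix exactly and keeps K = rows x (cols - L2 + 1) for a
  row-circular image.
* **Shaped** — the support mask and/or the window is an arbitrary pixel
  set; a placement is admissible iff every window offset (after wrapping
  on circular axes) lands on a supported pixel (full containment).

Pixel values are vectorized row-major within the window and anchors are
enumerated row-major over the image; this order is fixed by the worked
example and must not be changed, since trajectory matrices of the two
orders differ by a row/column permutation (harmless for sigmas, fatal for
cross-implementation comparisons).

## Embryo workflow

Per-nucleus data are mapped to a regular grid before SSA:

1. **Major axis** by PCA of nuclear coordinates. The sign is fixed so the
   first nonzero component of the axis is positive; collinear clouds are
   accepted (their first principal direction is well defined), only fully
   coincident points are rejected.
2. **Cylindrical projection**: axial position along the axis rescaled to
   [0, 100] percent egg length (%EL); angular position is the azimuth
   about the axis in a deterministic frame, degrees in [0, 360). No local
   radius correction is applied — the azimuth of an ellipsoid point and of
   its cylinder projection coincide, and arc-length distortion only
   matters for metric (not topological) statements about the DV axis; this
   is a known simplification.
3. **Gridding**: Delaunay triangulation + linear interpolation of
   (axial, angular) points onto a regular grid, with all points replicated
   at angular +-360 degrees so the interpolant is seam-free; grid nodes
   outside the convex hull of the replicated points are masked out
   (convex-hull masking is deterministic; alpha shapes were rejected for
   that reason). Exact duplicate (axial, angular) pairs are nudged by 1e-9
   before triangulating (logged). Only a central axial band is gridded
   (clip defaults below) to avoid the pole distortion of the
   ellipsoid-to-cylinder transformation.
4. **Back-interpolation** of smooth reconstructions onto nuclear centres
   (bilinear on the periodic grid); residual = original per-nucleus value
   minus the back-interpolated smooth component.

Linear interpolation reproduces constant and linear fields exactly, which
is the fidelity contract the tests enforce (away from hull-boundary
nodes).

## Parameter defaults

| parameter | default | units | rationale |
|---|---|---|---|
| axial grid step | 0.5 | %EL | standard resolution for stripe-region analyses |
| angular step | 1.8 (200 rows) | degrees | matches the axial step at the mean embryo radius; never stated by upstream practice, chosen once |
| clip left/right | 20 / 5 | %EL | focuses the stripe region for gap/pair-rule embryos; presets carry 15/15 and 25/15 variants |
| window | 10 x 25 (DV x AP) | pixels | oscillation axis (AP, columns) gets the longer side; presets: 10x25, 10x40, 10x30, 10x15 |
| max components | 50 | – | decompositions are inspected to ~26 components in practice |
| rank tolerance | 1e-10 (relative) | – | singular values below it are numerically zero |
| f_trend | 2 | cycles/image | trend = axial frequency at or below this |
| f_lo..f_hi | 4..12 | cycles/image | stripe band; a 7-stripe pattern sits near 7 |
| s_min | 0.1% | share of total energy | below it a component is noise |
| tau | 0.3 | – | phase-correlation threshold; conservative against noise-only correlation (null simulations in the tests) |
| min stripe area | 8 | pixels | drops thresholding specks |
| straight tolerance | 2 columns (~1 %EL at step 0.5) | axial units | flatness bound for the "straight" class |
| dominance ratio | 2 | – | quadratic/cubic dominance for C vs S |
| solver seed | 42 | – | any randomized solver start is seeded |

Component indices are 1-based at the API surface (component 1 is the
leading eigentriple) and 0-based internally.

Component labelling automates what is otherwise a visual-inspection step;
the frequency rule (trend / stripe band / noise gate) is this package's
codification and its band edges should be reviewed per dataset. In
particular, a sharp expression boundary spreads over components whose
axial frequency falls *between* the trend cutoff and the stripe band
(label `unassigned`); grouping remains analyst-controlled, and the
stripe-removal routine accepts explicit index sets for exactly this
reason.

The crosstalk verdict is the sign of the normalized zero-lag inner product
of the two channels' stripe reconstructions on their common support
(mean-removed): above +tau in phase (undercorrection), below -tau
antiphase (overcorrection), otherwise none. Reconstructions, not
eigenvectors, are compared, so the two channels may use different windows.
If either channel yields no stripe-labelled component the verdict is
"none" — the detector cannot fire without stripes on both sides, which is
also what controls its type-I error on crosstalk-free data.

Stripe shape classification fits the per-row axial midpoint of a stripe
with Legendre polynomials on the stripe's own row span (circular rows are
unrolled around the largest gap before fitting): flat centerlines are
"straight", a dominant quadratic is a C (sign gives direction), a dominant
cubic an S. The thresholds codify qualitative shape classes; the
straight/weak-S boundary is not sharply defined in practice and both
thresholds are exposed rather than asserted.

## Numerical choices

* **SVD route.** Dense LAPACK up to 5e7 trajectory cells; beyond that, a
  seeded iterative solver on a matrix-free operator that gathers image
  values through the cell-to-pixel index map in chunks. The switchover is
  deliberately high: Lanczos iteration converges poorly on the
  near-degenerate noise spectra these matrices have, while dense SVD of a
  (window-size x placements) matrix is cheap because the window side is
  small.
* **Sign convention.** Each left singular vector is flipped so its
  largest-magnitude element is positive; reconstructions are invariant,
  but persisted eigentriples become reproducible. Equal singular values
  keep the solver's stable output order; tests avoid degenerate spectra
  except where either order is accepted.
* **Singular values.** We store sigma_i; squared values are used wherever
  energy shares are reported. Component energy shares are normalized by
  the squared Frobenius norm of the trajectory matrix (the sum over *all*
  components), so shares do not depend on the truncation depth.
* **No-data.** Masked-out or never-covered pixels carry NaN, never zero —
  zero is a meaningful intensity.
* **Degenerate inputs.** All-zero images decompose to an empty eigentriple
  list; a window with no admissible placement, non-finite values under the
  mask, out-of-range component indices, and overlapping trend/stripe
  groups raise immediately with the offending sizes or indices named.

## Synthetic embryo generator

The generator is the single source of ground truth for the test suite. It
emulates: a prolate-ellipsoidal nuclear shell (default 6000 nuclei,
semi-axes 250 x 95 x 95 um) on a deterministic Fibonacci lattice; an
anterior-high logistic gap-gene profile (boundary at 47 %EL, width 4 %EL);
a 7-stripe raised-sinusoid pair-rule profile with an optional row-dependent
phase bend (quadratic for C-shaped stripes, cubic for S); signed linear
crosstalk alpha x pair-rule added to the gap channel (alpha < 0 emulates
overcorrection, alpha > 0 undercorrection); and intensity-dependent
Gaussian noise, sd = eta |signal| + eta0, independent across nuclei.
Fixed seeds give bit-identical output.

It does **not** emulate: non-sinusoidal stripe profiles with unequal
widths/intensities, nuclear packing irregularities beyond optional jitter,
asymmetric ("belly") embryo geometry, staining/registration artefacts, or
microscope PSF blur. Passing recovery tests therefore demonstrate the
correctness and calibration of the algorithms under the stated statistical
structure — not performance bounds on real embryos, where stripe
irregularity and geometry will loosen the frequency separation.

Recovery studies run at a desk scale chosen once for the suite: 1500
nuclei, 1 %EL x 6 degree grids, 8 x 20 windows, 12 components, crosstalk
|alpha| = 0.2 against noise floor 0.02 (stripe signal-to-noise 5). The
noise-only calibration of the component labeller uses 100 x 151 grids with
the default-shape 10 x 25 window, which preserves the label rule's
geometry (row gate passes only the zero bin; same stripe-band fraction) at
half the default row count.

## Known limitations

* The circular variant wraps anchors per axis; fully-circular 2D wrapping
  of both anchor grid and window has not been cross-validated against an
  independent implementation.
* Convex-hull masking admits hull-boundary grid nodes whose interpolation
  stencil is one-sided; constant/linear reproduction there is exact, but
  curvature bias at the hull edge is untested.
* The frequency rule assumes stripes are near-transverse (low row
  frequency); strongly oblique periodic artefacts would be labelled
  `unassigned`.
* Stripe boundaries are pixel-resolution polylines (no sub-pixel zero
  crossing); at step 0.5 %EL this bounds boundary accuracy at ~0.5 %EL.
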