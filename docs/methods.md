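# Methods

## Model and assumptions

The pipeline is an unsupervised saliency detector specialized to PET hot
spots. Its core assumption is that tumor tissue occupies a small fraction
of the slice and has internal intensity statistics that differ sharply
from the slice-wide average, because tracer uptake is much higher there.
Under that assumption the problem factorizes into *recognition* (which
regions are anomalous) and *delineation* (their pixel extent), and both
can be done at superpixel granularity:

1. a piecewise linear stretch amplifies the hot band;
2. SLIC partitions the slice into N coherent regions;
3. each region becomes a fixed-length M-vector (pad/truncate to the mean
   length), giving an M×N matrix S;
4. the eigenvectors of the superpixel covariance span the principal modes
   of region-level intensity variation; the top K modes carrying ≥ 95% of
   the variance define a coordinate system in which
5. each superpixel's L1 distance from the average superpixel is a
   saliency score; and
6. an exact binary k-means on the 1-D scores separates tumor from normal,
   after which
7. opening, contour tracing and a distance heatmap produce the pixel-level
   products.

Everything downstream of SLIC is linear algebra on an M×N matrix with
N ≈ 600–700 and M ≈ 100, which is why the method is fast.

## Parameters

| parameter | default | units | notes |
|---|---|---|---|
| stretch threshold | 110 | intensity | start of the hot band |
| stretch base | 200 | intensity | image of the threshold |
| stretch slope | 55/145 | — | makes 255 a fixed point |
| branch mode | `stretch_high` | — | see "Stretch branches" below |
| target superpixels | 700 | count | actual N reported per run |
| compactness | 10 | intensity (0–255 scale) | spatial-regularity weight |
| SLIC iterations | 10 | count | |
| variance fraction | 0.95 | — | selects K |
| min separation | 0 (off) | pooled σ of D | optional no-tumor guard |
| morphology radius | 1 | px | Euclidean disk opening |

All intensities are carried as floats in [0, 255]; quantization (round
half to even) happens only when a file is written, so the non-integer
stretch output is never double-rounded.

### Stretch branches

The transfer function has two plausible readings that differ in which side
of the threshold is stretched. Applying the identity *above* 110 and the
linear map below it is non-monotone (it lifts the background above the
mid-tones), while the constants algebraically anchor the opposite reading:
with the stretch applied at and above the threshold, 110 → 200 and
255 → 55/145·145 + 200 = 255 exactly. The default is therefore
`stretch_high`; the literal variant remains available as `as_printed` and
both are under test.

### Covariance normalization

The covariance uses the formulation's 1/(N+1) scale rather than the
conventional 1/(N−1). Every quantity consumed downstream — eigenvector
directions, cumulative variance fractions, hence K, hence the distances up
to a common positive factor — is invariant to positive rescaling of the
covariance, so the choice is immaterial; a test asserts that K is
unchanged under any positive rescaling of the spectrum.

## Numerical choices

- Eigenpairs come from an SVD of the centered matrix rather than forming
  and decomposing the M×M covariance: better conditioned, and naturally
  bounded by rank ≤ min(M, N). The explicit `eigendecompose` operation
  (used for cross-checking) validates symmetry, clamps small negative
  eigenvalues to zero, and fixes each eigenvector's sign by making its
  largest-magnitude entry positive, so the decomposition is deterministic.
- K is the smallest count whose cumulative variance fraction reaches the
  target (with a 1e-12 guard against float round-off at the boundary). A
  zero total variance (constant image) raises a degenerate-input error:
  segmentation is undefined when every superpixel equals the average.
- The 1-D k=2 objective is solved exactly: sort the distances, evaluate
  all N−1 interval splits with prefix sums, take the minimum. This is the
  global optimum of the k-means objective (optimal 1-D clusters are
  intervals), removes all seed sensitivity, and is O(N log N). A constant
  distance vector raises a degenerate-input error. Ties in the distances
  are handled by stable sorting; any split achieving the optimal cost is
  an equally valid clustering, and tests compare objective values, not
  label patterns.
- Superpixel equalization is deliberately order-stable: within a
  superpixel, pixels are enumerated in raster-scan order; padding repeats
  the final raster value (never a foreign intensity) and truncation keeps
  the first M values. Mean length M rounds half away from zero.
- The SLIC backend (scikit-image) rescales intensities to [0, 1] by the
  image's own range before weighing them against spatial distance; the
  wrapper divides the compactness by that range so the parameter stays
  defined on the canonical 0–255 intensity scale. A post-pass guarantees
  the partition invariants regardless of backend behavior: every label is
  one 4-connected component (orphan fragments are merged into the largest
  4-adjacent superpixel), labels are consecutive and non-empty, and sizes
  sum to the pixel count.
- Morphological cleanup is opening (erosion then dilation) with a
  Euclidean disk. Note the radius-1 disk is the 4-neighborhood diamond,
  which cannot reproduce sharp convex corners: opening a large square
  clips its 4 corner pixels. This is the expected geometry, not an
  artifact, and the tests encode it.
- Contours are traced on the pixel-edge lattice ("crack" boundaries):
  vertices are pixel corners and every step is a unit edge, so a filled
  r×c rectangle has perimeter exactly 2(r+c) steps. Diagonally touching
  pixels are kept on a single loop by a consistent turn rule at
  checkerboard junctions; only outer boundaries (positive signed area)
  are returned, one per 8-connected component, ordered by topmost-then-
  leftmost vertex.
- The heatmap is published on the raw distance scale with its limits in a
  sidecar file; a min–max normalized rendering is used only for the
  color image. Distances are not calibrated probabilities and are never
  presented as such in data products.

## The phantom generator

Phantoms emulate the features of a single FDG-PET slice that the method
exploits: a low background (level 40) with a gentle smooth ripple, 1–2
focal moderate-uptake blobs (level 100, radius 10–20 px) standing in for
physiologic organ uptake, and 1–3 tumor disks (level 230, radius 6–14 px),
blurred by a Gaussian PSF (σ 1.5 px) and degraded by additive Gaussian
noise (σ 5); a Poisson noise option scales variance with the local mean,
closer to PET count statistics. Ground truth is the union of the
*unblurred* tumor disks; evaluation absorbs blur-induced boundary softness
through the overlap threshold rather than by eroding the truth.

The generator does **not** emulate sinogram-level physics (attenuation,
scatter, reconstruction artifacts, spatially correlated noise), partial-
volume heterogeneity inside lesions, or anatomy with diffuse uptake
gradients. Passing the phantom suite therefore demonstrates that the
implementation realizes the method faithfully and that the method recovers
compact hot lesions over realistic contrast and noise — not that it is
clinically validated.

Two phantom behaviors are informative about the method itself:

- *Noise inflates K.* On the study phantoms the 95% rule selects anywhere
  from ~4 to tens of components depending on how much of the variance is
  noise; on smooth clinical slices the same rule selects 2–3. The distance
  score degrades gracefully (noise components add a nearly common offset),
  but K should not be interpreted as a physical dimensionality.
- *A binary split cannot rank three uptake classes.* When a slice contains
  background, a moderate-uptake organ, and a small lesion, the k=2
  objective can be minimized by grouping the organ's superpixels with the
  lesion's — many moderately salient points outweigh a few extreme ones.
  The recovery suite shows exactly this: lesion *detection* is robust
  (every truth lesion overlaps the mask), while mean Dice is dragged down
  on small-lesion phantoms by absorbed organ superpixels. This is a
  property of the binary clustering itself (the split is verified
  globally optimal against brute force), and the `min_separation` guard
  does not address it; a k=3 extension would, but is out of scope.

## Problem sizes

The default test and reproduction runs use 256×256 phantoms (N ≈ 620,
M ≈ 100), a 233×328 slice for the clinical-scale accounting, 20 phantoms
for the recovery suite, and 200 random vectors of length ≤ 50 for the
clustering-optimality check; these sizes exercise every code path at the
method's intended operating point while keeping a full run in seconds.

## Known limitations

- 2-D single-frame inputs only; no DICOM series, SUV calibration, or 3-D
  volumes.
- Exactly one tumor/normal split (k = 2); multi-class uptake and
  multi-lesion grading are out of scope, with the consequences described
  above.
- The stretch constants are tuned for the [0, 255] convention; other
  modalities or bit depths need re-parameterization (inputs can be
  min–max rescaled on load).
- On a tumor-free slice the method will, by construction, still nominate
  its most salient superpixels unless the `min_separation` guard is
  enabled; the guard's threshold (in pooled-σ units of the distance
  vector) is a heuristic, disabled by default.
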