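# Methods

## Topological features of binarized tissue

A grayscale image binarized at threshold `t` (foreground = intensity ≤ t)
is treated as a 2-D cubical complex.  We compute:

- **b0**: the number of 8-connected foreground components;
- **b1**: the number of holes, counted as 4-connected background components
  that do not touch the image border (implemented by padding with a
  one-pixel background frame, labeling the background, and subtracting the
  single frame-connected component).

The 8-connected-foreground / 4-connected-background pairing is the standard
digital-topology dual.  It is the unique pairing under which the Euler
number `b0 − b1` is computable locally by 2×2 bit-quad counting (Gray's
formula `E8 = (Q1 − Q3 − 2QD)/4`), which the test suite exploits as an
independent oracle alongside a hand-written BFS flood fill.  Background
regions open to the border are deliberately not holes: a hole is an
enclosed lumen, not a concavity.

The binarization direction (dark = foreground) follows H&E staining:
hematoxylin-dense structures (nuclei, chromatin) are dark, so sweeping the
threshold upward grows the foreground from the most cell-dense structures
outward.  The sweep default is `0, 5, 10, …, 245, 250, 255` (52 thresholds);
a coarser sweep (step 15, 19 thresholds) is used where runtime matters more
than curve resolution, and every sweep ends at 255 so the final binary image
is all-foreground (`b0 = 1, b1 = 0` identically, a built-in sanity check).

Betti numbers per threshold are plain counts, not persistence diagrams:
the per-threshold curve is the feature, and no pairing of birth/death
events is needed.  Counts are raw, not area-normalized.

### Multiscale concatenation

Each image is block-average downsampled (integer factors only, round-half-up)
to a declared scale set — e.g. 1024²/512²/256²/128² for 1600×1200-class
material after patching, 768²/384²/192²/96² for 768² images — and the
Betti curves at each scale are concatenated (`2 × |sweep| × |scales|`
features, names like `HI_s384_t135_b1`).  Block averaging is deterministic
and interpolation-free; merging blocks acts as a crude coarse-graining
under which small components fuse or vanish, so different scales probe
different granularity of the tissue.

## Texture baseline

The comparison features are the six standard radiomics families — 18
first-order, 23 GLCM, 16 GLRLM, 16 GLSZM, 14 GLDM, 5 NGTDM = 92 per scale —
implemented directly against the IBSI-consistent definitions, with the
whole image as the region of interest.  Settings follow common radiomics
defaults: fixed bin width 25 intensity units; distance 1; the four 2-D
directions for GLCM/GLRLM with feature values averaged over directions;
symmetric GLCM; GLDM with dependence tolerance α = 0 (the center pixel
counts itself as dependent, so dependence ≥ 1).  Degenerate inputs are
well defined by convention: on a constant image, variance-normalized
quantities return fixed values (GLCM Correlation = 1, first-order Skewness
and Kurtosis = 0) instead of dividing by zero.

Because discretization and direction conventions vary between radiomics
implementations, these features are contract-reproducible (stable names,
exact family counts, documented conventions) rather than bit-identical to
any particular external toolkit.

## Classification pipeline

- **Standardization** (optional, flag 0/1): per-feature z-score with
  training-split mean and population SD, applied unchanged to validation
  and test; zero-variance features map to 0.
- **Feature selection** (optional, flag 0/1): one-way ANOVA F statistic per
  feature on the training split; keep the top `floor(0.2 d)`; ties broken
  by column order; NaN scores (zero within-class variance) rank last.
- **Classifiers**: ids 0–7 = perceptron, logistic regression, kNN (k = 5),
  linear SVM, RBF SVM, decision tree, random forest (100 trees), gradient
  tree boosting (xgboost, 100 trees).  Hyperparameters are pinned in
  `algorithm_defaults.yaml` so "defaults" cannot drift with library
  upgrades.  Two pins deviate from upstream: LogisticRegression
  `max_iter = 1000` (the historical default of 100 does not converge on
  several-hundred-column standardized tables) and SVC `max_iter = 100000`
  (libsvm does not reliably terminate on unstandardized features spanning
  ten orders of magnitude, and half the search grid runs without
  standardization; the bound is far above what standardized data needs).
- **Search**: every combination of the two flags, every non-empty subset of
  the scale set, and the eight algorithms, in a fixed order (flags
  ascending, subsets by bitmask over scales sorted descending by
  resolution, algorithm id ascending) — 480 configurations for four scales.
  Candidates are scored on the validation split; results are sorted by
  validation accuracy with enumeration order as tiebreak, all tied-best
  configurations are reported, and the first of them is evaluated once on
  the test split (accuracy = confusion-matrix trace / total).
- **Leakage control**: splits are drawn at the parent-image level before
  any patch extraction, so all patches of an image share its split; all
  preprocessing statistics come from the training split only.

Patch extraction (for small datasets) samples top-left corners uniformly
with replacement — overlap permitted, since no disjointness rule is implied
by uniform sampling — and flips each patch vertically/horizontally with
probability 1/2.  Flips are applied to all three splits: Betti curves are
exactly flip-invariant, so this perturbs only the texture baseline.
Evaluation is at the patch level; no image-level vote is taken.

Randomness policy: one master seed per study, forked deterministically into
independent streams for splitting, patch corners/flips, and the stochastic
classifiers; the whole search is bit-reproducible for a fixed seed.

## Synthetic data generator

The generator renders histology-like RGB images from per-class recipes:
dark solid disks ("blobs" ≈ nuclei / dense chromatin) and dark rings with
bright lumina ("rings" ≈ alveoli, glands, vessels) on a bright background,
with Gaussian pixel noise and a cosmetic H&E-like tint (purple foreground,
pink background channel multipliers) so grayscale conversion behaves as on
real stains.  Shapes are placed by rejection sampling with a 2-pixel
clearance and never overlap, so a noiseless render's topology is known
exactly: `b0 = blobs + rings`, `b1 = rings` at any threshold between the
foreground and background intensities.  Intensity defaults are foreground
60, background 220, noise SD 5 — a wide gap, as in well-stained, well-lit
microscopy.

Presets: `private-mimic` (5 classes with class sizes 20/20/23/19/12 = 94
images at 1600×1200, class recipes ranging from air-space-rich "normal" to
blob-dominated "invasive") and `public-mimic` (3 classes at 768×768, 100
per class by default).  A third recipe family, `topology_contrast`, draws
exactly the same number of dark shapes per class with matched rasterized
areas (rings of outer radius 14–18 at width 4 cover 296–396 px; blobs of
radius 10–11 cover 317–377 px) so the classes differ essentially only in
their hole counts while their intensity histograms overlap heavily.

What the generator does **not** emulate: chromatin texture, stain and
illumination variability, overlapping or touching cell clusters, tissue
folds, or any disease morphology beyond component/hole statistics.  Tests
passing on synthetic data therefore validate the machinery (topology
computation, leakage-free search, recovery of planted signal), not
clinical performance on real slides.

## Validation experiments and problem sizes

- **Oracle equivalence**: 1000 random binary images up to 64×64; the
  package's (b0, b1) equal the BFS flood-fill oracle's and satisfy the
  bit-quad Euler identity on every image.
- **Invariance**: Betti curves are exactly equal under horizontal/vertical
  flips and 90° rotation on 100 random smoothed-noise grayscale images.
- **End-to-end recovery**: the public-mimic preset (300 images, 768², four
  scales, sweep step 15) through the full 480-configuration search reaches
  test accuracy ≥ 0.95 for each of three seeds.  The coarser sweep keeps a
  full repetition under two minutes on one CPU without changing the
  conclusion; step 5 behaves the same, only slower.
- **Method contrast**: on topology-contrast data (3 classes × 30 images at
  384², 54/18/18 split) the best homology configuration beats the best
  first-order-only configuration by ≥ 0.1 validation accuracy (mean over
  five seeds; observed margins are ≈ 0.3–0.5).  This comparison runs at the
  native scale only: block-average downsampling converts boundary length
  into intermediate-intensity pixels, and since equal-area rings have about
  twice the perimeter of disks, a downsampled histogram *does* leak the
  topology — an instructive observation, but it would test the
  downsampler, not the histogram features, so the contrast experiment
  excludes it.

## Known limitations

- Betti numbers are global counts; spatial arrangement of components is
  invisible to them (two images with the same component/hole counts in
  different configurations are indistinguishable).
- The hole definition requires closed lumina at the pixel level: a
  one-pixel break in a ring merges its hole into the background.  Real
  tissue boundaries are noisier than the generator's.
- Texture features are convention-reproducible, not bit-identical to any
  specific radiomics toolkit version.
- The exhaustive search's validation split is the sole arbiter of model
  choice; with small validation sets, ties are common and the enumeration
  order tiebreak is a convention, not a statistical statement.
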