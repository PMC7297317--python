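# Methods

This note documents the models, parameter choices and numerical conventions
behind `dermabcd`, and what the synthetic experiments do and do not show.

## Threshold selection

A 256-bin histogram is treated as a probability distribution p_i = n_i/N.
For a candidate threshold k the dark ("lesion") class covers levels
[0, k−1] and the bright ("skin") class [k, 255]; this pair of ranges is used
consistently for the class probabilities, means, variances and the
dispersion sequences. Candidates with an empty class score −∞; ties break
toward the smallest k, so results are deterministic.

Three objectives are maximized over k:

- **otsu** — σ²_B with weights (P_L, P_S). The identity
  σ²_B(k) + σ²_W(k) = σ² holds at every candidate, so maximizing σ²_B is
  the same as minimizing σ²_W; the test suite asserts the identity to 1e−6
  relative.
- **otsu2** — weights (D_L, D_S), where D is the population standard
  deviation of the class's mass sequence {i·p_i}, divided by N. The
  divisor is constant in k, so any fixed positive normalization yields the
  same argmax; dividing by N keeps D dimensionally a "normalized standard
  deviation". Classes with fewer than one level get D = 0.
- **otsu2prime** — weights (D_L·P_L, D_S·P_S).

For the two weighted variants the duality with the within-class form need
not hold, so the between-class form is the one optimized, mirroring the
classic formulation. All three selectors are verified against an exhaustive
scan that re-evaluates the objective from raw pixel lists.

## Segmentation pipeline

`segment()` chains: saliency → threshold → trimap → KNN matting →
composite.

**Saliency.** The stage's job is coarse lesion localization. The default
detector (`contrast`) scores each pixel by its CIELab distance from the
median border color, damped by a Gaussian center prior — a strong prior for
dermoscopy, where the lesion sits centrally on skin-colored surround. A
spectral-residual detector (`spectral`) is available as an alternative; in
our experiments it responds most strongly to thin high-frequency structures
(hair strokes), which is the opposite of what this stage needs on hairy
images, hence it is not the default.

**Threshold region.** The salient support (classic Otsu cut of the 8-bit
saliency map) is dilated by 16 px (at 256 px frames; scaled linearly) before
the luma histogram is taken. Without the margin a tight support can contain
*only* lesion pixels, and a two-class threshold selector then splits the
lesion against its own darkest artifacts instead of against skin. The
selector (default otsu2) can alternatively be applied to the saliency map
itself (`threshold_on="saliency_map"`).

**Post-processing.** A 2 px (scaled) morphological opening removes
hair-width structures from the binary mask, then the largest connected
component is kept and holes filled. Luma uses ITU-R BT.601 weights.

**Trimap and matting.** Foreground = mask eroded by a disk (default radius
5 px at 256, scaled), background = complement of the dilated mask, unknown
= the ring between. Matting solves the KNN-affinity Laplacian over pixel
features (CIELab scaled to [0,1] per channel, spatial coordinates weighted
0.1), K = 10 neighbors, affinity 1 − d/√dim. Seed pixels are eliminated
from the linear system, so their alphas are exact by construction; a soft
penalty mode (`lam`) exists but a finite penalty cannot bound the seed
residual below degree/λ, which is why elimination is the default. The final
mask is α ≥ 0.5. The lesion is assumed darker than skin (`lesion_dark`
flag otherwise).

## Asymmetry features

Lesions are split across the *mask centroid* (an `image` center option
exists); splitting at the centroid makes the half-comparison measure lesion
shape rather than placement. The centre row/column goes to the first half
and the second half is zero-padded to match.

Keypoint similarity uses `skimage.feature.SIFT` (128-d descriptors) on the
grayscale lesion, exhaustive 2-NN matching (`scipy.spatial.distance.cdist`)
and Lowe's ratio test at 0.7. Matching is run in both directions and the
minimum of the two counts is the feature, making it invariant to swapping
the halves. Halves are compared as-is; a `mirror` option flips the second
half first. Featureless halves (or halves with a single keypoint, where the
ratio test is undefined) score 0.

Projection profiles are computed on the lesion's square bounding canvas
(side = the larger bounding-box side, content centred) so the row and
column profiles have equal length and the correlation is invariant to
translation within the frame. The correlation is standard Pearson; a
zero-variance profile raises. Moments are *central* (about the centroid) —
the zero-skewness anchor for symmetric shapes only holds about the mean.
The scalar skewness feature is the mean of |skewness_H| and |skewness_V|;
both raw values are retained in reports.

## Color variegation

sRGB↔CIELab conversions use the D65 white point (scikit-image). The palette
is k-means (k = 7) with seeded random initialization, 10 restarts, best SSE
kept, iterated to assignment stability (`tol=0`): the palette must be a
k-means fixed point (each centroid the mean of its members), which the
suite asserts.

Classification is palette-based: the darkest palette color is dropped as
background if L < 1 (a surviving matting background is near-black but
rarely exactly [0,0,0]); every other palette color with cluster proportion
≥ 5% is tested — channel-wise range membership for black / dark brown /
light brown, Minkowski p=3 distance < T = 50 for white / red / blue-gray.
Because the black and dark-brown ranges overlap, each palette color
contributes to at most one shade: the nearest (range midpoint or reference
point) wins. A `per_pixel` mode implements the literal any-pixel range
reading for comparison; it is noisier, and the 5% gate then applies only to
the distance-based shades. The shipped range/reference table
(`dermabcd/data/suspicious_colors.json`) is an editable JSON file with
channel order L, a, b; the blue-gray reference has a strongly negative a
and is used as shipped.

## Diameter

The maximum Feret diameter is the largest pairwise distance between
boundary pixel centres, computed on the convex hull of the boundary (with
an O(n²) fallback for degenerate point sets) and verified against the
brute-force all-pairs oracle. The pixel-centre convention means a single
pixel has diameter 0; `pixel_extent=True` adds one pixel width. Calibration
defaults to 29.7 px/mm for 256 px frames and rescales linearly with frame
size; no ruler detection is attempted.

## CART classifier

Gini impurity, candidate thresholds at midpoints of consecutive sorted
unique values, impurity ties broken by (lowest feature index, lowest
threshold), routing `feature ≤ threshold → left`, no pruning and no depth
cap: growth stops only at purity or at identical feature vectors with
conflicting labels, in which case the leaf takes the majority label and is
flagged `impure`. Trees serialize to nested-dict JSON. The evaluation
protocol is a seeded stratified 80:20 split reporting overall accuracy and
per-class correct counts.

## Synthetic generator

Fixtures emulate the geometry and photometry that the measures consume: a
star-convex lesion r(θ) = r₀(1 + α Σ a_k sin(kθ+φ_k)) (α = 0 is a circle),
painted by per-pixel sampling of a CIELab fill palette with Gaussian Lab
noise (default sd 2), on a light-skin background (L,a,b ≈ 72, 12, 16), with
optional dark 1–3 px Bézier "hairs". Ground truth — label (α ≤ 0.05 is
symmetric), suspicious-color count (fills classified by the same
range/reference rule, no clustering), diameter (max pairwise distance on
the continuous boundary) — comes from the continuous spec, so rasterization
error is bounded and testable.

What the generator does **not** emulate: pigment networks and dermoscopic
texture, smooth lesion borders with halo gradients, specular highlights,
rulers, vignetting, or realistic inter-patient skin-tone variation.
Passing the synthetic-recovery experiments therefore demonstrates that the
implementation measures what it claims on controlled inputs — not that the
measured accuracies transfer to clinical dermoscopy.

## Experiment sizes and determinism

The packaged experiments use sizes chosen to exercise the full pipeline at
desk scale: threshold-oracle equivalence on 20 seeded 64×64 two-Gaussian
mixtures; Feret and moment oracles on ≤ 128×128 blobs; color recovery on 20
fixtures painted with 1–4 suspicious shades at equal fractions; classifier
recovery on one 100-fixture set (128 px canvas, α = 0 vs α ∈ [0.3, 0.5])
with 20 seeded stratified splits; pipeline ordering on 20 hairy 256 px
fixtures. All randomness flows through explicit integer seeds
(`numpy.random.default_rng`); identical seeds give byte-identical fixtures
and identical reports.

## Known limitations

- The spectral-residual saliency option underperforms the contrast detector
  whenever thin dark artifacts dominate the high-frequency content.
- KNN matting solves a sparse system per image; very large frames (≫ 512²)
  get slow and memory-hungry.
- The keypoint-similarity feature is weakly informative on low-texture
  synthetic lesions (few keypoints); label recovery there is carried mostly
  by the correlation and skewness features.
- The suspicious-color ranges are an empirical contract inherited from a
  specific dermoscopy corpus; other acquisition setups likely need a
  re-derived table (the JSON config exists for exactly that).
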