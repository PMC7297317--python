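# dermabcd

Automated **ABCD-rule** feature extraction for dermoscopic skin-lesion
images: **A**symmetry, **C**olor variegation and **D**iameter, computed
objectively from a photograph instead of by visual judgment. The package is
aimed at researchers building computer-aided melanoma screening tools and at
anyone who needs reproducible shape/color/size measurements of a segmented
blob on a contrasting background.

## What it computes

**Segmentation.** Lesions are extracted by a pipeline of saliency detection
→ histogram thresholding → trimap construction → KNN alpha matting. The
thresholding step offers classic Otsu plus two dispersion-weighted variants.
Classic Otsu picks the gray level k* maximizing the between-class variance

    σ²_B(k) = P_L(k)·(μ_L−μ_T)² + P_S(k)·(μ_S−μ_T)²

with class probabilities P_L, P_S. The *Otsu-II* variant replaces P_L, P_S
by dispersion weights D_L, D_S — normalized standard deviations of the class
mass sequences {i·p_i} — making the threshold less biased toward the class
with the larger spread; *Otsu-II′* uses the products D·P. Segmentations are
scored with the Dice overlap 2|A∩G|/(|A|+|G|).

**Asymmetry** is a 3-component feature vector:

1. *Keypoint-match similarity* — the lesion is split across its centroid
   into left/right and top/bottom halves; 128-d scale-invariant descriptors
   are matched between opposite halves by exhaustive 2-NN search with
   Lowe's ratio test (0.7), and the total match count v_s + h_s is reported
   (high = self-similar = symmetric).
2. *Projection-profile correlation* — Pearson correlation between row-sum
   and column-sum profiles of the mask; a circle scores exactly 1.
3. *Skewness* — standardized third central moments M₃₀/√M₂₀³ and
   M₀₃/√M₀₂³, zero for shapes symmetric about their centroid axes.

A CART decision tree (Gini splits, grown to purity) classifies the vector
as *symmetric* / *asymmetric*, with a stratified 80:20 evaluation protocol.

**Color variegation.** Lesion pixels are clustered in CIELab with k-means
(k = 7); each dominant color covering ≥ 5% of the lesion is tested against
six melanoma-suspicious shades — black / dark brown / light brown by
empirical CIELab ranges, white / red / blue-gray by Minkowski (p = 3)
distance below T = 50, half the p=3 distance between CIELab white and black.
The suspicious-color count 0–6 is reported.

**Diameter.** Maximum Feret (caliper) diameter of the mask — the largest
boundary point-pair distance, computed on the convex hull — converted to
millimetres with a 29.7 px/mm calibration (256×256 frames). The clinical
landmark is 6 mm.

Because dermoscopy datasets and dermatologist labels cannot be shipped, the
package includes a first-class synthetic generator (`dermabcd.synthgen`)
that renders blob-like lesions with controllable shape asymmetry, CIELab
fill palettes, noise and hair-like strokes, with all ground truth derived
from the continuous specification.

## Worked example

```python
from PIL import Image
from dermabcd import LesionSpec, render_lesion

fx = render_lesion(LesionSpec(
    canvas_size=256, shape="blob", radius=60, asymmetry=0.35, seed=7,
    fill=(((30.0, 15.0, 25.0), 0.5), ((60.0, 25.0, 40.0), 0.5)),  # dark + light brown
))
Image.fromarray(fx.rgb).save("demo_lesion.png")
# ground truth: label=asymmetric, suspicious colors=2, diameter=138.3 px
```

```
$ abcd extract demo_lesion.png --seed 0 --json demo_report.json
ABCD feature report
     similarity=0 correlation=0.6836 skewness=0.0009
  C  suspicious colors: 2 (dark_brown, light_brown)
  D  max Feret diameter: 138.1 px = 4.65 mm
```

The report recovers the generator's ground truth: both painted suspicious
browns are found (count 2), the measured diameter (138.1 px) is within a
pixel of the analytic boundary's 138.3 px, and the low projection
correlation (0.68, against 1.0 for a circle) reflects the injected shape
asymmetry. Train a tree on generator features (`abcd synth`, `abcd train`)
and pass `--model tree.json` to also print the symmetric/asymmetric label.

The same pipeline is available as sklearn-compatible estimators
(`OtsuThresholder`, `LesionSegmenter`, `AsymmetryFeatureExtractor`,
`CartAsymmetryClassifier`) that compose with `sklearn.pipeline.Pipeline`.

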