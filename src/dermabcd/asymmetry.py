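"""Shape-asymmetry features of an extracted lesion.

Three measurements summarize how lopsided a lesion silhouette is, and together
form the feature vector a decision tree classifies as symmetric/asymmetric:

1. *Keypoint-match similarity* — the lesion cut-out is split across its
   centroid into left/right and top/bottom halves; scale-invariant keypoints
   (128-d descriptors) are matched between opposite halves by exhaustive
   2-nearest-neighbor descriptor search with Lowe's ratio test (0.7).  The
   total count ``v_s + h_s`` is high for self-similar (symmetric) lesions.
2. *Projection-profile correlation* — Pearson correlation between the row-sum
   and column-sum profiles of the lesion mask on a square canvas; a circle
   scores exactly 1, asymmetry drives it down.
3. *Projection skewness* — third standardized central moments of the mask,
   ``M30 / sqrt(M20^3)`` horizontally and ``M03 / sqrt(M02^3)`` vertically;
   both vanish for shapes symmetric about their centroid axes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist
from skimage.feature import SIFT

from .segmentation import LesionImage
from .thresholding import rgb_to_luma

__all__ = [
    "HalfPair",
    "ProjectionProfile",
    "MomentSet",
    "AsymmetryFeatureVector",
    "split_halves",
    "sift_similarity",
    "total_similarity",
    "projection_profiles",
    "profile_correlation",
    "central_moments",
    "projection_skewness",
    "asymmetry_features",
]


@dataclass(frozen=True)
class HalfPair:
    """Two equally-shaped sub-images obtained by splitting a lesion in half."""

    first: np.ndarray
    second: np.ndarray
    axis: str  # "vertical" (left|right) or "horizontal" (top|bottom)

    def __post_init__(self) -> None:
        if self.first.shape != self.second.shape:
            raise ValueError("halves must have identical dimensions")


@dataclass(frozen=True)
class ProjectionProfile:
    """Row-wise (horizontal) and column-wise (vertical) foreground counts."""

    horizontal: np.ndarray  # H[i], one entry per row
    vertical: np.ndarray  # V[j], one entry per column

    @property
    def area(self) -> int:
        return int(self.horizontal.sum())


@dataclass(frozen=True)
class MomentSet:
    """Raw and central moments M_pq for p + q <= 3 of a binary mask.

    x is the column coordinate, y the row coordinate; central moments are
    taken about the foreground centroid with f = binary membership.
    """

    raw: dict
    central: dict
    centroid: tuple  # (x_bar, y_bar)

    @property
    def area(self) -> float:
        return self.central[(0, 0)]


@dataclass(frozen=True)
class AsymmetryFeatureVector:
    """The three classifier-facing measurements plus raw per-axis skewness."""

    sift_similarity: int
    projection_correlation: float
    skewness_summary: float
    skewness_h: float
    skewness_v: float
    v_s: int = 0
    h_s: int = 0

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.sift_similarity, self.projection_correlation, self.skewness_summary]
        )


def _lesion_parts(lesion) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(lesion, LesionImage):
        return np.asarray(lesion.rgb), np.asarray(lesion.mask).astype(bool)
    mask = np.asarray(lesion).astype(bool)
    return mask.astype(np.uint8) * 255, mask


def split_halves(lesion, center: str = "centroid") -> tuple[HalfPair, HalfPair]:
    """Split a lesion across its centre into (left|right) and (top|bottom) halves.

    ``center`` is ``"centroid"`` (the lesion-mask centroid; default — makes the
    comparison measure lesion shape rather than placement) or ``"image"`` (the
    frame centre).  The centre row/column goes to the first half; the second
    half is zero-padded so the pair shapes match.
    """
    img, mask = _lesion_parts(lesion)
    if not mask.any():
        raise ValueError("cannot split an empty lesion")
    if center == "centroid":
        ys, xs = np.nonzero(mask)
        cy, cx = int(round(ys.mean())), int(round(xs.mean()))
    elif center == "image":
        cy, cx = (mask.shape[0] - 1) // 2, (mask.shape[1] - 1) // 2
    else:
        raise ValueError(f"unknown split center {center!r}")

    gray = rgb_to_luma(img) if img.ndim == 3 else img
    gray = gray * mask

    def _pad_to(arr, shape):
        out = np.zeros(shape, dtype=arr.dtype)
        out[: arr.shape[0], : arr.shape[1]] = arr
        return out

    left, right = gray[:, : cx + 1], gray[:, cx + 1:]
    tgt = (gray.shape[0], max(left.shape[1], right.shape[1]))
    vertical = HalfPair(_pad_to(left, tgt), _pad_to(right, tgt), axis="vertical")

    top, bottom = gray[: cy + 1, :], gray[cy + 1:, :]
    tgt = (max(top.shape[0], bottom.shape[0]), gray.shape[1])
    horizontal = HalfPair(_pad_to(top, tgt), _pad_to(bottom, tgt), axis="horizontal")
    return vertical, horizontal


def _descriptors(gray: np.ndarray) -> np.ndarray:
    """128-d keypoint descriptors; empty array when nothing is detectable."""
    img = np.asarray(gray, dtype=np.float64)
    if img.ndim == 3:
        img = rgb_to_luma(img).astype(np.float64)
    if min(img.shape) < 16 or img.max() == img.min():
        return np.empty((0, 128))
    det = SIFT()
    try:
        det.detect_and_extract(img)
    except (RuntimeError, ValueError):
        return np.empty((0, 128))
    return np.asarray(det.descriptors, dtype=np.float64)


def _ratio_matches(d1: np.ndarray, d2: np.ndarray, ratio: float) -> int:
    """Exhaustive 2-NN descriptor matching with Lowe's ratio test."""
    if len(d1) == 0 or len(d2) < 2:
        return 0
    dist = cdist(d1, d2)
    part = np.partition(dist, 1, axis=1)[:, :2]
    with np.errstate(divide="ignore", invalid="ignore"):
        ok = part[:, 0] < ratio * part[:, 1]
    return int(np.count_nonzero(ok))


def sift_similarity(pair: HalfPair, ratio: float = 0.7, mirror: bool = False) -> int:
    """Keypoint-match count between the two halves.

    Matching runs exhaustively in both directions and the symmetrized count
    (the minimum of the two directional counts) is returned, so swapping the
    halves cannot change the feature.  ``mirror`` flips the second half
    before matching (the descriptors themselves are not mirror-invariant).
    """
    second = pair.second
    if mirror:
        second = second[:, ::-1] if pair.axis == "vertical" else second[::-1, :]
    d1, d2 = _descriptors(pair.first), _descriptors(second)
    return min(_ratio_matches(d1, d2, ratio), _ratio_matches(d2, d1, ratio))


def total_similarity(lesion, ratio: float = 0.7, mirror: bool = False,
                     center: str = "centroid") -> int:
    """Total keypoint similarity v_s + h_s over the two half pairs."""
    vertical, horizontal = split_halves(lesion, center=center)
    return (sift_similarity(vertical, ratio, mirror)
            + sift_similarity(horizontal, ratio, mirror))


def projection_profiles(mask: np.ndarray) -> ProjectionProfile:
    """Foreground counts per row (horizontal profile) and per column (vertical)."""
    mask = np.asarray(mask).astype(bool)
    if mask.ndim != 2:
        raise ValueError("projection profiles require a 2-D mask")
    return ProjectionProfile(
        horizontal=mask.sum(axis=1).astype(np.int64),
        vertical=mask.sum(axis=0).astype(np.int64),
    )


def profile_correlation(h1, h2) -> float:
    """Pearson correlation of two equal-length projection profiles."""
    h1 = np.asarray(h1, dtype=np.float64)
    h2 = np.asarray(h2, dtype=np.float64)
    if h1.shape != h2.shape:
        raise ValueError("profiles must have equal length")
    c1, c2 = h1 - h1.mean(), h2 - h2.mean()
    denom = np.sqrt((c1 * c1).sum() * (c2 * c2).sum())
    if denom == 0:
        raise ValueError("zero-variance profile: shape is degenerate")
    return float(np.clip((c1 * c2).sum() / denom, -1.0, 1.0))


def _square_canvas(mask: np.ndarray) -> np.ndarray:
    """Crop the mask to its bounding box and pad to a centred square canvas."""
    ys, xs = np.nonzero(mask)
    crop = mask[ys.min(): ys.max() + 1, xs.min(): xs.max() + 1]
    side = max(crop.shape)
    out = np.zeros((side, side), dtype=bool)
    oy, ox = (side - crop.shape[0]) // 2, (side - crop.shape[1]) // 2
    out[oy: oy + crop.shape[0], ox: ox + crop.shape[1]] = crop
    return out


def central_moments(mask: np.ndarray) -> MomentSet:
    """Raw and central moments up to order 3 of a binary mask (f = membership)."""
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise ValueError("moments of an empty mask are undefined")
    ys, xs = np.nonzero(mask)
    x = xs.astype(np.float64)
    y = ys.astype(np.float64)
    raw = {(p, q): float((x**p * y**q).sum()) for p in range(4) for q in range(4)
           if p + q <= 3}
    xb, yb = raw[(1, 0)] / raw[(0, 0)], raw[(0, 1)] / raw[(0, 0)]
    dx, dy = x - xb, y - yb
    central = {(p, q): float((dx**p * dy**q).sum()) for p in range(4) for q in range(4)
               if p + q <= 3}
    return MomentSet(raw=raw, central=central, centroid=(xb, yb))


def projection_skewness(moments: MomentSet) -> tuple[float, float]:
    """Standardized third central moments (horizontal, vertical).

    skewness_H = M30 / sqrt(M20^3) is positive when mass trails to the right
    of the centroid; skewness_V = M03 / sqrt(M02^3) likewise downward.
    """
    m20, m02 = moments.central[(2, 0)], moments.central[(0, 2)]
    if m20 <= 0 or m02 <= 0:
        raise ValueError("zero second moment: mask is a line or point")
    return (moments.central[(3, 0)] / np.sqrt(m20**3),
            moments.central[(0, 3)] / np.sqrt(m02**3))


def asymmetry_features(lesion, ratio: float = 0.7, mirror: bool = False,
                       center: str = "centroid") -> AsymmetryFeatureVector:
    """Assemble the 3-component asymmetry feature vector of a lesion.

    The skewness summary scalar is the mean of |skewness_H| and |skewness_V|;
    both raw values are retained on the result for inspection.
    """
    _, mask = _lesion_parts(lesion)
    if not mask.any():
        raise ValueError("cannot measure asymmetry of an empty lesion")
    vertical, horizontal = split_halves(lesion, center=center)
    v_s = sift_similarity(vertical, ratio, mirror)
    h_s = sift_similarity(horizontal, ratio, mirror)

    canvas = _square_canvas(mask)
    prof = projection_profiles(canvas)
    corr = profile_correlation(prof.horizontal, prof.vertical)
    sk_h, sk_v = projection_skewness(central_moments(mask))
    return AsymmetryFeatureVector(
        sift_similarity=v_s + h_s,
        projection_correlation=corr,
        skewness_summary=float((abs(sk_h) + abs(sk_v)) / 2.0),
        skewness_h=float(sk_h),
        skewness_v=float(sk_v),
        v_s=v_s,
        h_s=h_s,
    )
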