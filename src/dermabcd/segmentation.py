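"""Lesion segmentation pipeline: saliency, thresholding, trimap, matting.

The pipeline localizes the lesion coarsely with a saliency detector,
binarizes the salient region with one of the Otsu-family threshold selectors,
converts the binary mask into a trimap (certain foreground / certain
background / unknown border band) by erosion and dilation, refines the border
band with KNN alpha matting, and composites the final lesion cut-out.
Dice overlap against a ground-truth mask evaluates the result.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.ndimage import (
    binary_dilation,
    binary_erosion,
    binary_fill_holes,
    gaussian_filter,
    label,
    uniform_filter,
)
from skimage.color import rgb2lab
from skimage.morphology import disk
from skimage.transform import resize
from sklearn.neighbors import NearestNeighbors

from .thresholding import (
    apply_threshold,
    compute_histogram,
    otsu2_threshold,
    otsu2prime_threshold,
    otsu_threshold,
    rgb_to_luma,
)

__all__ = [
    "BACKGROUND",
    "UNKNOWN",
    "FOREGROUND",
    "Trimap",
    "AlphaMatte",
    "LesionImage",
    "SegmentConfig",
    "PipelineStageError",
    "detect_saliency",
    "generate_trimap",
    "knn_matte",
    "compose_lesion",
    "segment",
    "dice_coefficient",
]

# On-disk trimap encoding.
BACKGROUND, UNKNOWN, FOREGROUND = 0, 128, 255

_THRESHOLDERS = {
    "otsu": otsu_threshold,
    "otsu2": otsu2_threshold,
    "otsu2prime": otsu2prime_threshold,
}


class PipelineStageError(RuntimeError):
    """A segmentation stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"segmentation stage '{stage}' failed: {cause}")
        self.stage = stage
        self.__cause__ = cause


@dataclass(frozen=True)
class Trimap:
    """Three-label map: certain background, unknown band, certain foreground."""

    labels: np.ndarray  # uint8 grid over {0, 128, 255}

    @property
    def foreground(self) -> np.ndarray:
        return self.labels == FOREGROUND

    @property
    def background(self) -> np.ndarray:
        return self.labels == BACKGROUND

    @property
    def unknown(self) -> np.ndarray:
        return self.labels == UNKNOWN


@dataclass(frozen=True)
class AlphaMatte:
    """Per-pixel foreground opacity in [0, 1]."""

    alpha: np.ndarray


@dataclass(frozen=True)
class LesionImage:
    """Lesion cut-out: RGB zeroed outside the mask, plus the binary support."""

    rgb: np.ndarray
    mask: np.ndarray


def detect_saliency(rgb_image: np.ndarray, method: str = "spectral") -> np.ndarray:
    """Per-pixel salience in [0, 1]; higher where the image is 'interesting'.

    ``spectral`` is the spectral-residual detector: suppress the smooth part
    of the log-amplitude spectrum, transform back and smooth.  ``contrast``
    scores each pixel by its CIELab distance from the median border color,
    damped by a Gaussian center prior — a strong prior for dermoscopy, where
    the lesion sits near the frame center on skin-colored surround.
    """
    rgb_image = np.asarray(rgb_image)
    if rgb_image.ndim != 3 or rgb_image.shape[-1] < 3:
        raise ValueError("saliency detection expects a 3-channel image")
    if np.ptp(rgb_image[..., :3].reshape(-1, 3), axis=0).max() == 0:
        return np.full(rgb_image.shape[:2], 0.5)  # no contrast anywhere
    if method == "spectral":
        sal = _spectral_residual(rgb_to_luma(rgb_image).astype(np.float64))
    elif method == "contrast":
        sal = _border_contrast(rgb_image)
    else:
        raise ValueError(f"unknown saliency method {method!r}")
    lo, hi = sal.min(), sal.max()
    if hi - lo < 1e-12:
        return np.full(sal.shape, 0.5)
    return (sal - lo) / (hi - lo)


def _spectral_residual(gray: np.ndarray, work_size: int = 64) -> np.ndarray:
    small = resize(gray, (work_size, work_size), anti_aliasing=True)
    spectrum = np.fft.fft2(small)
    log_amp = np.log(np.abs(spectrum) + 1e-12)
    residual = log_amp - uniform_filter(log_amp, size=3)
    sal = np.abs(np.fft.ifft2(np.exp(residual + 1j * np.angle(spectrum)))) ** 2
    sal = gaussian_filter(sal, sigma=3)
    return resize(sal, gray.shape, anti_aliasing=True)


def _border_contrast(rgb: np.ndarray, border_frac: float = 0.05) -> np.ndarray:
    lab = rgb2lab(np.asarray(rgb)[..., :3] / 255.0 if rgb.dtype == np.uint8 else rgb)
    h, w = lab.shape[:2]
    b = max(1, int(round(border_frac * min(h, w))))
    border = np.concatenate(
        [lab[:b].reshape(-1, 3), lab[-b:].reshape(-1, 3),
         lab[:, :b].reshape(-1, 3), lab[:, -b:].reshape(-1, 3)]
    )
    ref = np.median(border, axis=0)
    dist = np.linalg.norm(lab - ref, axis=-1)
    yy, xx = np.mgrid[0:h, 0:w]
    prior = np.exp(-(((yy - (h - 1) / 2) / (0.5 * h)) ** 2 +
                     ((xx - (w - 1) / 2) / (0.5 * w)) ** 2))
    return gaussian_filter(dist * prior, sigma=0.02 * min(h, w))


def generate_trimap(mask: np.ndarray, erode_radius: float, dilate_radius: float) -> Trimap:
    """Trimap from a binary mask: eroded core = foreground, complement of the
    dilated mask = background, the ring in between = unknown."""
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise ValueError("trimap requires a non-empty mask")
    core = binary_erosion(mask, structure=disk(erode_radius)) if erode_radius > 0 else mask
    if not core.any():
        raise ValueError(
            f"erosion with radius {erode_radius} removed the entire mask; "
            "use a smaller erode radius"
        )
    halo = binary_dilation(mask, structure=disk(dilate_radius)) if dilate_radius > 0 else mask
    labels = np.full(mask.shape, BACKGROUND, dtype=np.uint8)
    labels[halo] = UNKNOWN
    labels[core] = FOREGROUND
    return Trimap(labels=labels)


def knn_matte(
    rgb_image: np.ndarray,
    trimap: Trimap,
    k: int = 10,
    lam: float | None = None,
    spatial_weight: float = 0.1,
) -> AlphaMatte:
    """Solve for the alpha matte with KNN-affinity Laplacian propagation.

    Each pixel gets a feature vector (CIELab color scaled to [0, 1] per
    channel, spatial coordinates scaled by ``spatial_weight``); affinities
    ``1 - d/d_max`` link each pixel to its ``k`` nearest feature-space
    neighbors.  Trimap seeds are enforced exactly (eliminated from the
    Laplacian system); pass a finite ``lam`` to use a soft seed penalty of
    that weight instead.
    """
    rgb_image = np.asarray(rgb_image)
    tri = trimap.labels
    if rgb_image.shape[:2] != tri.shape:
        raise ValueError("image and trimap shapes differ")
    fg, bg, unk = trimap.foreground, trimap.background, trimap.unknown
    if not fg.any() or not bg.any():
        raise ValueError("trimap must contain both foreground and background seeds")
    if not unk.any():
        return AlphaMatte(alpha=fg.astype(np.float64))

    h, w = tri.shape
    lab = rgb2lab(rgb_image[..., :3] / 255.0 if rgb_image.dtype == np.uint8 else rgb_image)
    yy, xx = np.mgrid[0:h, 0:w]
    feats = np.column_stack([
        (lab[..., 0] / 100.0).ravel(),
        ((lab[..., 1] + 128.0) / 255.0).ravel(),
        ((lab[..., 2] + 128.0) / 255.0).ravel(),
        spatial_weight * (yy / max(h - 1, 1)).ravel(),
        spatial_weight * (xx / max(w - 1, 1)).ravel(),
    ])
    n = feats.shape[0]
    nn = NearestNeighbors(n_neighbors=min(k + 1, n)).fit(feats)
    dist, idx = nn.kneighbors(feats)
    dist, idx = dist[:, 1:], idx[:, 1:]  # drop self-match
    d_max = np.sqrt(feats.shape[1])
    aff = np.clip(1.0 - dist / d_max, 0.0, None)

    rows = np.repeat(np.arange(n), idx.shape[1])
    A = sparse.coo_matrix((aff.ravel(), (rows, idx.ravel())), shape=(n, n))
    A = (A + A.T) * 0.5
    A = A.tocsr()
    L = sparse.diags(np.asarray(A.sum(axis=1)).ravel()) - A

    seed_val = np.where(fg.ravel(), 1.0, 0.0)
    seeded = (fg | bg).ravel()
    if lam is not None:
        # Soft penalty: (L + lam*C) alpha = lam * c
        C = sparse.diags(seeded.astype(np.float64))
        alpha = sparse.linalg.spsolve((L + lam * C).tocsc(), lam * seeded * seed_val)
    else:
        free = ~seeded
        L_csr = L.tocsr()
        Luu = L_csr[free][:, free] + 1e-8 * sparse.eye(int(free.sum()))
        Luk = L_csr[free][:, seeded]
        rhs = -Luk @ seed_val[seeded]
        alpha = seed_val.copy()
        alpha[free] = sparse.linalg.spsolve(Luu.tocsc(), rhs)
    return AlphaMatte(alpha=np.clip(alpha.reshape(h, w), 0.0, 1.0))


def compose_lesion(rgb_image: np.ndarray, alpha, alpha_cut: float = 0.5) -> LesionImage:
    """Cut the lesion out of the photograph: mask = (alpha >= cut), RGB zeroed outside."""
    rgb_image = np.asarray(rgb_image)
    a = alpha.alpha if isinstance(alpha, AlphaMatte) else np.asarray(alpha)
    if rgb_image.shape[:2] != a.shape:
        raise ValueError("image and alpha shapes differ")
    mask = a >= alpha_cut
    return LesionImage(rgb=rgb_image * mask[..., None], mask=mask)


@dataclass
class SegmentConfig:
    """Tunable parameters of the segmentation pipeline.

    ``threshold_on`` selects whether the Otsu-family selector sees the luma
    values of the image restricted to the salient region (default) or the
    8-bit saliency map itself.  The salient support is dilated by
    ``support_margin`` pixels before the histogram is taken so that both the
    lesion and a ring of surrounding skin contribute — a two-class histogram
    is what the threshold selectors assume.  ``opening_radius`` removes
    structures thinner than the structuring element (hairs) from the binary
    mask before the trimap stage.
    """

    saliency: str = "contrast"
    threshold_method: str = "otsu2"
    threshold_on: str = "masked_image"  # or "saliency_map"
    lesion_dark: bool = True
    erode_radius: float = 5.0
    dilate_radius: float = 5.0
    support_margin: float = 16.0
    opening_radius: float = 2.0
    knn_k: int = 10
    alpha_cut: float = 0.5
    reference_size: int = 256  # radii are scaled proportionally to image size

    def scaled_radius(self, radius: float, shape: tuple[int, int]) -> float:
        return max(1.0, radius * min(shape[:2]) / self.reference_size)


def segment(rgb_image: np.ndarray, config: SegmentConfig | None = None):
    """Full pipeline: saliency -> threshold -> trimap -> matting -> composite.

    Returns ``(LesionImage, mask)``.  Stage failures are re-raised as
    :class:`PipelineStageError` naming the stage.
    """
    config = config or SegmentConfig()
    rgb_image = np.asarray(rgb_image)

    def _stage(name, fn, *args, **kw):
        try:
            return fn(*args, **kw)
        except PipelineStageError:
            raise
        except Exception as exc:
            raise PipelineStageError(name, exc) from exc

    sal = _stage("saliency", detect_saliency, rgb_image, config.saliency)
    sal8 = np.round(sal * 255).astype(np.uint8)
    # Coarse salient support from a classic Otsu cut of the saliency map,
    # dilated so the threshold histogram sees skin as well as lesion.
    k_sal, _ = _stage("saliency", otsu_threshold, compute_histogram(sal8))
    margin = config.scaled_radius(config.support_margin, rgb_image.shape)
    support = binary_dilation(sal8 >= k_sal, structure=disk(margin))

    select = _THRESHOLDERS[config.threshold_method]
    luma = rgb_to_luma(rgb_image)
    if config.threshold_on == "saliency_map":
        k, _ = _stage("thresholding", select, compute_histogram(sal8))
        binary = apply_threshold(sal8, k, lesion_dark=False)
    else:
        k, _ = _stage("thresholding", select, compute_histogram(luma[support]))
        binary = apply_threshold(luma, k, lesion_dark=config.lesion_dark) & support
    opening = config.scaled_radius(config.opening_radius, rgb_image.shape)
    binary = _stage("postprocess", _largest_component, binary, opening)

    er = config.scaled_radius(config.erode_radius, rgb_image.shape)
    di = config.scaled_radius(config.dilate_radius, rgb_image.shape)
    trimap = _stage("trimap", generate_trimap, binary, er, di)
    matte = _stage("matting", knn_matte, rgb_image, trimap, config.knn_k)
    lesion = _stage("compose", compose_lesion, rgb_image, matte, config.alpha_cut)
    return lesion, lesion.mask


def _largest_component(binary: np.ndarray, opening_radius: float = 0.0) -> np.ndarray:
    if not binary.any():
        raise ValueError("thresholding produced an empty lesion candidate")
    if opening_radius > 0:
        opened = binary_erosion(binary, structure=disk(opening_radius))
        opened = binary_dilation(opened, structure=disk(opening_radius))
        if opened.any():  # keep the raw mask if opening annihilates everything
            binary = opened
    labeled, n = label(binary)
    if n > 1:
        sizes = np.bincount(labeled.ravel())
        sizes[0] = 0
        binary = labeled == int(np.argmax(sizes))
    return binary_fill_holes(binary)


def dice_coefficient(a: np.ndarray, g: np.ndarray, as_percent: bool = False) -> float:
    """Dice overlap 2|A∩G| / (|A| + |G|), on [0, 1] (or [0, 100] with ``as_percent``)."""
    a = np.asarray(a).astype(bool)
    g = np.asarray(g).astype(bool)
    if a.shape != g.shape:
        raise ValueError("masks must have the same shape")
    denom = a.sum() + g.sum()
    if denom == 0:
        raise ValueError("Dice coefficient undefined for two empty masks")
    d = 2.0 * np.logical_and(a, g).sum() / denom
    return 100.0 * d if as_percent else d
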