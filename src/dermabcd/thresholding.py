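"""Gray-level histogram thresholding: classic Otsu and dispersion-weighted variants.

Otsu's method picks the gray level ``k*`` that maximizes the between-class
variance of a bimodal histogram (equivalently, minimizes the within-class
variance).  The two variants replace the class-occurrence probabilities
``P_L, P_S`` in the between-class objective by dispersion weights ``D_L, D_S``
— normalized standard deviations of the mass sequences ``{i * p_i}`` of each
class — either instead of the probabilities (Otsu-II) or multiplied with them
(Otsu-II').  Weighting by dispersion makes the selected threshold less biased
toward the class with the larger variance, which matters for skin-lesion
photographs where the lesion and the surrounding skin have very different
intensity spreads.

Conventions: for a candidate threshold ``k`` the "lesion" (dark) class covers
levels ``[0, k-1]`` and the "skin" (bright) class covers ``[k, L-1]`` with
``L = 256``.  Candidates where either class is empty are excluded.  Ties are
broken toward the smallest ``k``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GrayHistogram",
    "ThresholdDiagnostics",
    "compute_histogram",
    "otsu_threshold",
    "otsu2_threshold",
    "otsu2prime_threshold",
    "apply_threshold",
]

_LEVELS = 256


class DegenerateImageError(ValueError):
    """Raised when an image/histogram has fewer than two occupied gray levels."""


@dataclass(frozen=True)
class GrayHistogram:
    """256-bin gray-level histogram treated as a probability distribution.

    Attributes
    ----------
    counts : ndarray of int, shape (256,)
        Occurrences ``n_i`` of each gray level.
    probs : ndarray of float, shape (256,)
        Normalized frequencies ``p_i = n_i / N``.
    total_pixels : int
        Total pixel count ``N``.
    """

    counts: np.ndarray
    probs: np.ndarray
    total_pixels: int
    levels: int = _LEVELS

    def __post_init__(self) -> None:
        if self.total_pixels <= 0:
            raise ValueError("histogram must describe at least one pixel")
        if not np.isclose(self.probs.sum(), 1.0, atol=1e-9):
            raise ValueError("probabilities must sum to 1")

    @property
    def n_occupied(self) -> int:
        return int(np.count_nonzero(self.counts))


@dataclass
class ThresholdDiagnostics:
    """Per-candidate quantities behind a threshold selection.

    All arrays are indexed by candidate ``k`` (length 256); entries where a
    class would be empty are NaN and the objective is ``-inf`` there.
    """

    method: str
    k_star: int
    mu_L: np.ndarray = field(repr=False)
    mu_S: np.ndarray = field(repr=False)
    mu_T: float = 0.0
    P_L: np.ndarray = field(default=None, repr=False)
    P_S: np.ndarray = field(default=None, repr=False)
    var_L: np.ndarray = field(default=None, repr=False)
    var_S: np.ndarray = field(default=None, repr=False)
    D_L: np.ndarray = field(default=None, repr=False)
    D_S: np.ndarray = field(default=None, repr=False)
    sigma2_W: np.ndarray = field(default=None, repr=False)
    sigma2_B: np.ndarray = field(default=None, repr=False)
    total_variance: float = 0.0

    @property
    def valid(self) -> np.ndarray:
        """Boolean mask of candidates with both classes non-empty."""
        return np.isfinite(self.sigma2_B)

    @property
    def eta(self) -> np.ndarray:
        """Separability ratio sigma2_B / sigma2_W per candidate."""
        with np.errstate(divide="ignore", invalid="ignore"):
            return self.sigma2_B / self.sigma2_W


def _as_gray_histogram(source) -> GrayHistogram:
    if isinstance(source, GrayHistogram):
        return source
    return compute_histogram(np.asarray(source))


def compute_histogram(image: np.ndarray) -> GrayHistogram:
    """Build the normalized 256-bin histogram of an 8-bit grayscale image.

    RGB input is converted to luma first (ITU-R BT.601 weights).
    """
    image = np.asarray(image)
    if image.size == 0:
        raise ValueError("cannot compute a histogram of an empty image")
    if image.ndim == 3 and image.shape[-1] in (3, 4):
        image = rgb_to_luma(image)
    levels = np.round(image).astype(np.int64).ravel()
    if levels.min() < 0 or levels.max() > 255:
        raise ValueError("gray levels must lie in [0, 255]")
    counts = np.bincount(levels, minlength=_LEVELS)
    total = int(counts.sum())
    return GrayHistogram(counts=counts, probs=counts / total, total_pixels=total)


def rgb_to_luma(rgb: np.ndarray) -> np.ndarray:
    """ITU-R BT.601 luma (0.299 R + 0.587 G + 0.114 B), returned as uint8."""
    rgb = np.asarray(rgb)[..., :3].astype(np.float64)
    return np.clip(np.round(rgb @ [0.299, 0.587, 0.114]), 0, 255).astype(np.uint8)


def _class_statistics(hist: GrayHistogram):
    """Cumulative class probabilities, means and variances for every k.

    Returns arrays of length 256 indexed by candidate k, NaN where the class
    is empty. Lesion class = levels [0, k-1], skin class = [k, 255].
    """
    p = hist.probs
    i = np.arange(_LEVELS, dtype=np.float64)
    ip = i * p
    iip = i * i * p

    # Prefix sums shifted so index k corresponds to levels [0, k-1].
    cp = np.concatenate([[0.0], np.cumsum(p)])[:-1]  # P_L(k), k = 0..255
    cip = np.concatenate([[0.0], np.cumsum(ip)])[:-1]
    ciip = np.concatenate([[0.0], np.cumsum(iip)])[:-1]

    P_L = cp
    P_S = 1.0 - cp
    with np.errstate(divide="ignore", invalid="ignore"):
        mu_L = np.where(P_L > 0, cip / P_L, np.nan)
        mu_S = np.where(P_S > 0, (ip.sum() - cip) / P_S, np.nan)
        ex2_L = np.where(P_L > 0, ciip / P_L, np.nan)
        ex2_S = np.where(P_S > 0, (iip.sum() - ciip) / P_S, np.nan)
    var_L = ex2_L - mu_L**2
    var_S = ex2_S - mu_S**2
    mu_T = float(ip.sum())
    total_var = float(iip.sum() - mu_T**2)
    return P_L, P_S, mu_L, mu_S, var_L, var_S, mu_T, total_var


def _dispersion_weights(hist: GrayHistogram):
    """Normalized standard deviations of the mass sequences {i*p_i} per class.

    For candidate k, D_L is the population std of the sequence
    (0*p_0, ..., (k-1)*p_{k-1}) divided by the total pixel count N, and D_S
    the same over levels [k, 255].  A class with fewer than one element gets
    D = 0.
    """
    v = np.arange(_LEVELS, dtype=np.float64) * hist.probs
    s1 = np.concatenate([[0.0], np.cumsum(v)])
    s2 = np.concatenate([[0.0], np.cumsum(v * v)])
    k = np.arange(_LEVELS, dtype=np.float64)  # size of lesion class at candidate k

    with np.errstate(divide="ignore", invalid="ignore"):
        mean_L = s1[:-1] / k
        var_L = s2[:-1] / k - mean_L**2
        n_S = _LEVELS - k
        mean_S = (s1[-1] - s1[:-1]) / n_S
        var_S = (s2[-1] - s2[:-1]) / n_S - mean_S**2
    D_L = np.sqrt(np.clip(var_L, 0.0, None)) / hist.total_pixels
    D_S = np.sqrt(np.clip(var_S, 0.0, None)) / hist.total_pixels
    D_L[k < 1] = 0.0
    D_S[n_S < 1] = 0.0
    return np.nan_to_num(D_L), np.nan_to_num(D_S)


def _select(hist: GrayHistogram, method: str) -> tuple[int, ThresholdDiagnostics]:
    if hist.n_occupied < 2:
        raise DegenerateImageError(
            "image has a single gray level; no threshold separates two classes"
        )
    P_L, P_S, mu_L, mu_S, var_L, var_S, mu_T, total_var = _class_statistics(hist)
    occupied = hist.counts > 0
    # Both classes non-empty in terms of occupied levels:
    has_lo = np.concatenate([[False], np.cumsum(occupied) > 0])[:-1]
    has_hi = (np.cumsum(occupied[::-1]) > 0)[::-1]
    valid = has_lo & has_hi

    if method == "otsu":
        w_L, w_S = P_L, P_S
        D_L = D_S = None
    else:
        D_L, D_S = _dispersion_weights(hist)
        if method == "otsu2":
            w_L, w_S = D_L, D_S
        elif method == "otsu2prime":
            w_L, w_S = D_L * P_L, D_S * P_S
        else:  # pragma: no cover - guarded by public wrappers
            raise ValueError(f"unknown method {method!r}")

    sigma2_B = w_L * (mu_L - mu_T) ** 2 + w_S * (mu_S - mu_T) ** 2
    sigma2_W = w_L * var_L + w_S * var_S
    sigma2_B = np.where(valid, sigma2_B, -np.inf)
    sigma2_W = np.where(valid, sigma2_W, np.nan)

    k_star = int(np.argmax(sigma2_B))  # first max -> smallest k on ties
    diag = ThresholdDiagnostics(
        method=method,
        k_star=k_star,
        mu_L=mu_L,
        mu_S=mu_S,
        mu_T=mu_T,
        P_L=P_L,
        P_S=P_S,
        var_L=var_L,
        var_S=var_S,
        D_L=D_L,
        D_S=D_S,
        sigma2_W=sigma2_W,
        sigma2_B=sigma2_B,
        total_variance=total_var,
    )
    return k_star, diag


def otsu_threshold(hist) -> tuple[int, ThresholdDiagnostics]:
    """Classic Otsu threshold: argmax_k of the between-class variance.

    Accepts a :class:`GrayHistogram` or a gray-level image array.
    Equivalently minimizes the within-class variance, since the two objectives
    sum to the total variance at every candidate.
    """
    return _select(_as_gray_histogram(hist), "otsu")


def otsu2_threshold(hist) -> tuple[int, ThresholdDiagnostics]:
    """Dispersion-weighted Otsu (Otsu-II): class probabilities replaced by D_L, D_S."""
    return _select(_as_gray_histogram(hist), "otsu2")


def otsu2prime_threshold(hist) -> tuple[int, ThresholdDiagnostics]:
    """Otsu-II' variant: between-class objective weighted by D * P products."""
    return _select(_as_gray_histogram(hist), "otsu2prime")


def apply_threshold(image: np.ndarray, k: int, lesion_dark: bool = True) -> np.ndarray:
    """Binarize an image at threshold ``k``.

    With ``lesion_dark`` (default) the foreground is ``image < k`` — matching
    the convention that the lesion class covers levels [0, k-1]; otherwise
    the bright class ``image >= k`` is foreground.
    """
    if not 0 <= k <= 255:
        raise ValueError("threshold must lie in [0, 255]")
    image = np.asarray(image)
    if image.ndim == 3:
        image = rgb_to_luma(image)
    return image < k if lesion_dark else image >= k
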