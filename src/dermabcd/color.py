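"""Color variegation: CIELab palettes and melanoma-suspicious color counting.

Melanoma lesions tend to show several of six suspicious pigment shades:
white, red, light brown, dark brown, blue-gray and black.  The lesion's
pixels are clustered in CIELab (k-means, k = 7 — six suspicious colors plus
a pure-black slot for any zeroed background that survived extraction) into a
dominant-color palette.  Each retained palette color that covers at least 5%
of the lesion is classified: black / dark brown / light brown by channel-wise
membership in empirically derived CIELab ranges, and white / red / blue-gray
by Minkowski (p = 3) distance below ``T = 50`` — half the p = 3 distance
between the CIELab extremes white [100, 0, 0] and black [0, 0, 0] — to a
reference color.  The suspicious-color count is the number of distinct
suspicious shades present.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
from skimage.color import lab2rgb, rgb2lab
from sklearn.cluster import KMeans

from .segmentation import LesionImage

__all__ = [
    "SUSPICIOUS_COLOR_NAMES",
    "ColorRange",
    "Palette",
    "SuspiciousColorReport",
    "load_color_table",
    "rgb_to_lab",
    "lab_to_rgb",
    "dominant_palette",
    "minkowski_distance",
    "suspicious_color_report",
]

SUSPICIOUS_COLOR_NAMES = ("black", "dark_brown", "light_brown", "white", "red", "blue_gray")

DEFAULT_T = 50.0
DEFAULT_MIN_PROP = 0.05


@dataclass(frozen=True)
class ColorRange:
    """Channel-wise CIELab box [min, max]."""

    lo: np.ndarray
    hi: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.lo > self.hi):
            raise ValueError("range min must be <= max channel-wise")

    def contains(self, lab: np.ndarray) -> np.ndarray:
        lab = np.atleast_2d(lab)
        return np.all((lab >= self.lo) & (lab <= self.hi), axis=1)

    @property
    def midpoint(self) -> np.ndarray:
        return (self.lo + self.hi) / 2.0


@dataclass(frozen=True)
class ColorTable:
    """The suspicious-color contract: three ranges and three reference points."""

    ranges: dict  # name -> ColorRange
    references: dict  # name -> (3,) Lab array


def load_color_table(path=None) -> ColorTable:
    """Load the suspicious-color table (packaged default or a user JSON file)."""
    if path is None:
        text = resources.files("dermabcd.data").joinpath("suspicious_colors.json").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    raw = json.loads(text)
    ranges = {
        name: ColorRange(lo=np.asarray(lo, float), hi=np.asarray(hi, float))
        for name, (lo, hi) in raw["ranges"].items()
    }
    refs = {name: np.asarray(v, float) for name, v in raw["references"].items()}
    return ColorTable(ranges=ranges, references=refs)


@dataclass
class Palette:
    """k dominant CIELab colors with member-pixel proportions.

    ``black_index`` flags the pure-black (background) entry if one exists;
    ``degenerate`` marks palettes padded because the input had fewer distinct
    colors than clusters requested.
    """

    colors: np.ndarray  # (k, 3) Lab
    proportions: np.ndarray  # (k,) summing to 1
    inertia: float = 0.0
    black_index: int | None = None
    degenerate: bool = False
    labels: np.ndarray | None = field(default=None, repr=False)


def rgb_to_lab(rgb_image: np.ndarray) -> np.ndarray:
    """sRGB (8-bit or float in [0,1]) to CIELab under the D65 white point."""
    rgb_image = np.asarray(rgb_image)
    if rgb_image.dtype == np.uint8:
        rgb_image = rgb_image / 255.0
    return rgb2lab(rgb_image[..., :3])


def lab_to_rgb(lab_image: np.ndarray) -> np.ndarray:
    """CIELab back to 8-bit sRGB (gamut-clipped)."""
    return np.round(np.clip(lab2rgb(lab_image), 0, 1) * 255).astype(np.uint8)


def dominant_palette(lab_pixels: np.ndarray, k: int = 7, seed: int = 0) -> Palette:
    """Dominant-color palette by seeded k-means in CIELab.

    Initialization is seeded random pixel sampling with 10 restarts (best
    within-cluster SSE kept), iterated to assignment convergence.  If the
    input has fewer distinct colors than ``k``, the palette is padded with
    duplicates and flagged degenerate.
    """
    pixels = np.asarray(lab_pixels, dtype=np.float64).reshape(-1, 3)
    if len(pixels) == 0:
        raise ValueError("no pixels to cluster")
    distinct = np.unique(pixels, axis=0)
    if len(distinct) < k:
        colors = distinct
        labels = np.argmin(
            ((pixels[:, None, :] - colors[None, :, :]) ** 2).sum(-1), axis=1
        )
        props = np.bincount(labels, minlength=len(colors)) / len(pixels)
        pad = k - len(colors)
        colors = np.vstack([colors, np.repeat(colors[-1:], pad, axis=0)])
        props = np.concatenate([props, np.zeros(pad)])
        pal = Palette(colors=colors, proportions=props, inertia=0.0,
                      degenerate=True, labels=labels)
    else:
        # tol=0: iterate until assignments stabilize, not merely until the
        # center shift is small — the palette must be a k-means fixed point.
        km = KMeans(n_clusters=k, init="random", n_init=10, random_state=seed,
                    tol=0.0, max_iter=500)
        labels = km.fit_predict(pixels)
        props = np.bincount(labels, minlength=k) / len(pixels)
        pal = Palette(colors=km.cluster_centers_, proportions=props,
                      inertia=float(km.inertia_), labels=labels)
    # Flag the background slot: darkest palette color, if essentially black.
    darkest = int(np.argmin(pal.colors[:, 0]))
    if pal.colors[darkest, 0] < 1.0:
        pal.black_index = darkest
    return pal


def minkowski_distance(x, y, p: float = 3.0) -> float:
    """Minkowski distance (sum |x_k - y_k|^p)^(1/p); Manhattan at p=1, Euclidean at p=2."""
    if p < 1:
        raise ValueError("Minkowski order p must be >= 1")
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    s = np.sum(np.abs(x - y) ** p)
    if p == 1:
        return float(s)
    if p == 2:
        return float(np.sqrt(s))
    if p == 3:
        return float(np.cbrt(s))
    return float(s ** (1.0 / p))


@dataclass
class SuspiciousColorReport:
    """Per-shade presence decisions with their evidence, and the total count."""

    presence: dict  # name -> bool
    evidence: dict  # name -> list of evidence dicts
    count: int
    threshold: float = DEFAULT_T
    min_prop: float = DEFAULT_MIN_PROP
    mode: str = "palette"

    def to_dict(self) -> dict:
        return {
            "presence": dict(self.presence),
            "evidence": self.evidence,
            "count": self.count,
            "threshold": self.threshold,
            "min_prop": self.min_prop,
            "mode": self.mode,
        }


def _classify_color(lab: np.ndarray, table: ColorTable, T: float, p: float):
    """Which suspicious shade (if any) a single Lab color indicates.

    A color can sit in overlapping ranges or within T of several references;
    it contributes to at most one shade — the nearest (range midpoint or
    reference point) by Minkowski distance wins.
    """
    candidates = []
    for name, rng in table.ranges.items():
        if bool(rng.contains(lab)[0]):
            candidates.append((minkowski_distance(lab, rng.midpoint, p), name))
    for name, ref in table.references.items():
        d = minkowski_distance(lab, ref, p)
        if d < T:
            candidates.append((d, name))
    if not candidates:
        return None, None
    d, name = min(candidates)
    return name, d


def suspicious_color_report(
    lesion,
    palette: Palette | None = None,
    table: ColorTable | None = None,
    T: float = DEFAULT_T,
    min_prop: float = DEFAULT_MIN_PROP,
    p: float = 3.0,
    seed: int = 0,
    per_pixel: bool = False,
) -> SuspiciousColorReport:
    """Count the suspicious colors present in a lesion.

    ``lesion`` is a :class:`LesionImage` (palette computed on its masked
    pixels), an (n, 3) array of lesion CIELab pixels, or ignored if a
    ``palette`` is supplied.  The pure-black palette slot is excluded; a
    retained palette color counts toward a shade only if its cluster covers
    at least ``min_prop`` of the lesion.  ``per_pixel=True`` instead applies
    the literal any-pixel reading: range shades are present if any lesion
    pixel falls in the range, distance shades if at least ``min_prop`` of
    pixels are within ``T`` of the reference.
    """
    table = table or load_color_table()
    pixels = None
    if isinstance(lesion, LesionImage):
        if not lesion.mask.any():
            raise ValueError("empty lesion: no pixels to analyze")
        pixels = rgb_to_lab(lesion.rgb)[lesion.mask]
    elif lesion is not None:
        pixels = np.asarray(lesion, dtype=np.float64).reshape(-1, 3)
        if len(pixels) == 0:
            raise ValueError("empty lesion: no pixels to analyze")

    presence = {name: False for name in SUSPICIOUS_COLOR_NAMES}
    evidence: dict = {name: [] for name in SUSPICIOUS_COLOR_NAMES}

    if per_pixel:
        if pixels is None:
            raise ValueError("per-pixel mode requires lesion pixels")
        n = len(pixels)
        for name, rng in table.ranges.items():
            hits = int(rng.contains(pixels).sum())
            if hits > 0:
                presence[name] = True
                evidence[name].append({"kind": "range", "pixel_hits": hits})
        for name, ref in table.references.items():
            d = np.sum(np.abs(pixels - ref) ** p, axis=1) ** (1.0 / p)
            frac = float((d < T).mean())
            if frac >= min_prop:
                presence[name] = True
                evidence[name].append({"kind": "distance", "pixel_fraction": frac})
        mode = "per_pixel"
    else:
        if palette is None:
            palette = dominant_palette(pixels, seed=seed)
        for i, (color, prop) in enumerate(zip(palette.colors, palette.proportions)):
            if i == palette.black_index or prop < min_prop:
                continue
            name, d = _classify_color(color, table, T, p)
            if name is not None:
                presence[name] = True
                evidence[name].append({
                    "kind": "palette",
                    "palette_index": i,
                    "lab": [round(float(c), 3) for c in color],
                    "proportion": float(prop),
                    "distance": float(d),
                })
        mode = "palette"

    count = int(sum(presence.values()))
    return SuspiciousColorReport(presence=presence, evidence=evidence, count=count,
                                 threshold=T, min_prop=min_prop, mode=mode)
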