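"""Seeded generator of dermoscopy-like test images with analytic ground truth.

Each fixture is a darker blob-shaped "lesion" on a lighter skin-toned
background.  The lesion boundary is a star-convex radial curve

    r(theta) = r0 * (1 + alpha * sum_k a_k sin(k theta + phi_k))

whose asymmetry amplitude ``alpha`` directly controls shape asymmetry
(``alpha = 0`` gives a perfect circle, hence a point-symmetric shape).  The
interior is painted by sampling a CIELab fill palette per pixel with
additive Gaussian Lab noise; optional dark curved strokes imitate body hair,
the artifact that most disturbs histogram thresholding of small lesions.

Ground truth (label, suspicious-color count, maximum diameter) is derived
from the continuous specification — the boundary curve and the fill palette —
not from the rendered raster, so rasterization error stays bounded and
measurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import binary_dilation
from skimage.draw import bezier_curve, polygon
from skimage.morphology import disk

from .color import lab_to_rgb, load_color_table, _classify_color

__all__ = ["LesionSpec", "Fixture", "render_lesion", "make_dataset"]

# Default skin tone: light skin in CIELab.
DEFAULT_SKIN = (72.0, 12.0, 16.0)
# Default lesion pigment: a dark-brown shade from the suspicious table.
DEFAULT_FILL = ((30.0, 15.0, 25.0), 1.0)

ALPHA_SYMMETRIC_CUTOFF = 0.05  # label boundary on the asymmetry amplitude


@dataclass(frozen=True)
class LesionSpec:
    """Continuous description of a synthetic lesion image."""

    canvas_size: int = 256
    shape: str = "blob"  # circle | ellipse | blob
    radius: float = 60.0
    aspect: float = 1.0  # ellipse minor/major ratio
    asymmetry: float = 0.0  # amplitude alpha of the radial perturbation
    n_harmonics: int = 4
    fill: tuple = (DEFAULT_FILL,)  # ((Lab, fraction), ...)
    skin: tuple = DEFAULT_SKIN
    noise_sd: float = 2.0  # Gaussian noise in Lab units
    hair_count: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        fracs = [f for _, f in self.fill]
        if abs(sum(fracs) - 1.0) > 1e-9:
            raise ValueError("fill fractions must sum to 1")
        if self.asymmetry < 0:
            raise ValueError("asymmetry amplitude must be >= 0")


@dataclass(frozen=True)
class Fixture:
    """Rendered image plus the analytic ground truth of every measure."""

    rgb: np.ndarray
    mask: np.ndarray
    label: str  # symmetric | asymmetric
    color_count: int
    diameter_px: float
    spec: LesionSpec = field(repr=False, default=None)


def _radial_profile(spec: LesionSpec, theta: np.ndarray, rng) -> np.ndarray:
    """r(theta) of the continuous boundary, before rasterization."""
    if spec.shape == "circle":
        return np.full_like(theta, spec.radius)
    if spec.shape == "ellipse":
        a, b = spec.radius, spec.radius * spec.aspect
        return a * b / np.sqrt((b * np.cos(theta)) ** 2 + (a * np.sin(theta)) ** 2)
    # blob: harmonic perturbation, amplitudes normalized so alpha bounds the
    # total relative deviation (keeps r > 0 for alpha < 1)
    k = np.arange(1, spec.n_harmonics + 1)
    a_k = rng.uniform(0.5, 1.0, size=spec.n_harmonics)
    a_k /= a_k.sum()
    phi = rng.uniform(0, 2 * np.pi, size=spec.n_harmonics)
    pert = (a_k[:, None] * np.sin(k[:, None] * theta[None, :] + phi[:, None])).sum(0)
    return spec.radius * (1.0 + spec.asymmetry * pert)


def _true_diameter(xs: np.ndarray, ys: np.ndarray) -> float:
    pts = np.column_stack([xs, ys])
    # boundary curves have a few hundred samples; direct pairwise max is fine
    d2 = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1)
    return float(np.sqrt(d2.max()))


def _true_color_count(spec: LesionSpec, min_prop: float = 0.05) -> int:
    table = load_color_table()
    shades = set()
    for lab, frac in spec.fill:
        if frac < min_prop:
            continue
        name, _ = _classify_color(np.asarray(lab, float), table, T=50.0, p=3.0)
        if name is not None:
            shades.add(name)
    return len(shades)


def render_lesion(spec: LesionSpec) -> Fixture:
    """Rasterize a lesion spec into an RGB fixture with ground truth."""
    rng = np.random.default_rng(spec.seed)
    n = spec.canvas_size
    theta = np.linspace(0, 2 * np.pi, 720, endpoint=False)
    r = _radial_profile(spec, theta, rng)
    if np.any(r <= 0):
        raise ValueError("asymmetry amplitude collapses the boundary (r <= 0)")
    cx = cy = (n - 1) / 2.0
    xs = cx + r * np.cos(theta)
    ys = cy + r * np.sin(theta)
    if xs.min() < 0 or ys.min() < 0 or xs.max() > n - 1 or ys.max() > n - 1:
        raise ValueError("lesion exceeds the canvas; shrink radius or asymmetry")

    rr, cc = polygon(ys, xs, shape=(n, n))
    mask = np.zeros((n, n), dtype=bool)
    mask[rr, cc] = True

    # Paint: skin background, palette-sampled lesion interior, Lab noise.
    lab = np.empty((n, n, 3), dtype=np.float64)
    lab[:] = spec.skin
    fills = np.asarray([c for c, _ in spec.fill], dtype=np.float64)
    fracs = np.asarray([f for _, f in spec.fill], dtype=np.float64)
    choice = rng.choice(len(fills), size=int(mask.sum()), p=fracs)
    lab[mask] = fills[choice]
    if spec.noise_sd > 0:
        lab += rng.normal(0.0, spec.noise_sd, size=lab.shape)
    rgb = lab_to_rgb(lab)

    if spec.hair_count > 0:
        rgb = _draw_hairs(rgb, spec.hair_count, rng)

    return Fixture(
        rgb=rgb,
        mask=mask,
        label="symmetric" if spec.asymmetry <= ALPHA_SYMMETRIC_CUTOFF else "asymmetric",
        color_count=_true_color_count(spec),
        diameter_px=_true_diameter(xs, ys),
        spec=spec,
    )


def _draw_hairs(rgb: np.ndarray, count: int, rng) -> np.ndarray:
    """Overlay dark curved strokes (1-3 px wide quadratic arcs)."""
    out = rgb.copy()
    n = rgb.shape[0]
    hair_rgb = np.array([40, 30, 25], dtype=np.uint8)
    for _ in range(count):
        p = rng.integers(0, n, size=6)
        stroke = np.zeros(rgb.shape[:2], dtype=bool)
        rr, cc = bezier_curve(p[0], p[1], p[2], p[3], p[4], p[5], weight=1.0,
                              shape=rgb.shape[:2])
        stroke[rr, cc] = True
        width = int(rng.integers(1, 4))
        if width > 1:
            stroke = binary_dilation(stroke, structure=disk(width - 1))
        out[stroke] = hair_rgb
    return out


# Fill palettes used for asymmetry/classifier datasets: pigmented shades
# drawn from the suspicious-color table so downstream color counts are known.
_PIGMENT_CHOICES = (
    ((30.0, 15.0, 25.0), "dark_brown"),
    ((60.0, 25.0, 40.0), "light_brown"),
    ((15.0, 5.0, 4.0), "black"),
)


def make_dataset(
    n: int,
    symmetric_frac: float = 0.5,
    alpha_range: tuple = (0.3, 0.5),
    canvas_size: int = 256,
    hair_count: int = 0,
    seed: int = 0,
) -> list:
    """A labeled, class-balanced fixture set for classifier experiments.

    Symmetric fixtures are circles/ellipses (alpha = 0); asymmetric fixtures
    are blobs with alpha drawn uniformly from ``alpha_range`` (kept away from
    the labeling cutoff so no fixture has an ambiguous label).  Radii, fill
    pigments and orientations vary per fixture under the master seed.
    """
    if n < 2:
        raise ValueError("need at least 2 fixtures")
    rng = np.random.default_rng(seed)
    n_sym = int(round(n * symmetric_frac))
    fixtures = []
    for i in range(n):
        symmetric = i < n_sym
        sub_seed = int(rng.integers(0, 2**31 - 1))
        sub = np.random.default_rng(sub_seed)
        radius = float(sub.uniform(0.18, 0.3) * canvas_size)
        pigment, _ = _PIGMENT_CHOICES[int(sub.integers(0, len(_PIGMENT_CHOICES)))]
        if symmetric:
            spec = LesionSpec(
                canvas_size=canvas_size,
                shape="circle",
                radius=radius,
                asymmetry=0.0,
                fill=((pigment, 1.0),),
                hair_count=hair_count,
                seed=sub_seed,
            )
        else:
            spec = LesionSpec(
                canvas_size=canvas_size,
                shape="blob",
                radius=radius,
                asymmetry=float(sub.uniform(*alpha_range)),
                n_harmonics=int(sub.integers(3, 6)),
                fill=((pigment, 1.0),),
                hair_count=hair_count,
                seed=sub_seed,
            )
        fixtures.append(render_lesion(spec))
    return fixtures
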