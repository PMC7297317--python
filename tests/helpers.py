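"""Independent oracles shared by the unit and acceptance tests.

Every function here recomputes a quantity from first principles — raw pixel
lists, explicit double loops, exhaustive scans — deliberately avoiding the
vectorized code paths of the package under test.
"""

from __future__ import annotations

import numpy as np


def two_gaussian_image(seed: int, shape=(32, 32), means=(60, 180), sd=10) -> np.ndarray:
    """Seeded bimodal test image: two Gaussian intensity modes, half each."""
    rng = np.random.default_rng(seed)
    n = shape[0] * shape[1]
    vals = np.concatenate([
        rng.normal(means[0], sd, n // 2),
        rng.normal(means[1], sd, n - n // 2),
    ])
    rng.shuffle(vals)
    return np.clip(np.round(vals), 0, 255).astype(np.uint8).reshape(shape)


def brute_force_threshold(image: np.ndarray, method: str) -> int:
    """Exhaustive threshold search re-evaluating the objective from raw pixels.

    For every candidate k in [1, 255] with both classes non-empty, the class
    probabilities, means and dispersion weights are recomputed directly from
    the pixel list and the between-class objective is evaluated; the smallest
    argmax k is returned.
    """
    levels = np.asarray(image).ravel().astype(int)
    N = levels.size
    counts = np.bincount(levels, minlength=256)
    p = counts / N
    best_score, best_k = -np.inf, None
    for k in range(1, 256):
        lo = np.arange(0, k)
        hi = np.arange(k, 256)
        if counts[lo].sum() == 0 or counts[hi].sum() == 0:
            continue
        P_L, P_S = p[lo].sum(), p[hi].sum()
        mu_L = (lo * p[lo]).sum() / P_L
        mu_S = (hi * p[hi]).sum() / P_S
        mu_T = P_L * mu_L + P_S * mu_S
        if method == "otsu":
            w_L, w_S = P_L, P_S
        else:
            f_L = lo * p[lo]
            f_S = hi * p[hi]
            D_L = float(f_L.std()) / N
            D_S = float(f_S.std()) / N
            if method == "otsu2":
                w_L, w_S = D_L, D_S
            elif method == "otsu2prime":
                w_L, w_S = D_L * P_L, D_S * P_S
            else:
                raise ValueError(method)
        score = w_L * (mu_L - mu_T) ** 2 + w_S * (mu_S - mu_T) ** 2
        if score > best_score:
            best_score, best_k = score, k
    return best_k


def brute_force_moments(mask: np.ndarray) -> dict:
    """Central moments by explicit double loop (x = column, y = row)."""
    mask = np.asarray(mask).astype(bool)
    area = xsum = ysum = 0.0
    for yy in range(mask.shape[0]):
        for xx in range(mask.shape[1]):
            if mask[yy, xx]:
                area += 1
                xsum += xx
                ysum += yy
    xb, yb = xsum / area, ysum / area
    out = {}
    for pp in range(4):
        for qq in range(4):
            if pp + qq > 3:
                continue
            s = 0.0
            for yy in range(mask.shape[0]):
                for xx in range(mask.shape[1]):
                    if mask[yy, xx]:
                        s += (xx - xb) ** pp * (yy - yb) ** qq
            out[(pp, qq)] = s
    return out


def brute_force_feret(mask: np.ndarray) -> float:
    """Max distance over all pairs of boundary pixels, O(n^2), no hull."""
    mask = np.asarray(mask).astype(bool)
    pts = []
    h, w = mask.shape
    for yy in range(h):
        for xx in range(w):
            if not mask[yy, xx]:
                continue
            on_edge = yy in (0, h - 1) or xx in (0, w - 1)
            if on_edge or not (mask[yy - 1, xx] and mask[yy + 1, xx]
                               and mask[yy, xx - 1] and mask[yy, xx + 1]):
                pts.append((yy, xx))
    pts = np.asarray(pts, dtype=float)
    if len(pts) < 2:
        return 0.0
    d2 = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1)
    return float(np.sqrt(d2.max()))


def random_blob_mask(seed: int, size: int = 96, radius: float | None = None) -> np.ndarray:
    """Seeded random star-convex blob mask for geometry oracles."""
    rng = np.random.default_rng(seed)
    r0 = radius if radius is not None else rng.uniform(0.2, 0.35) * size
    theta = np.linspace(0, 2 * np.pi, 360, endpoint=False)
    k = np.arange(1, 5)
    a = rng.uniform(0.5, 1, 4)
    a /= a.sum()
    phi = rng.uniform(0, 2 * np.pi, 4)
    pert = (a[:, None] * np.sin(k[:, None] * theta + phi[:, None])).sum(0)
    r = r0 * (1 + 0.3 * pert)
    c = (size - 1) / 2
    ys, xs = c + r * np.sin(theta), c + r * np.cos(theta)
    from skimage.draw import polygon

    mask = np.zeros((size, size), dtype=bool)
    rr, cc = polygon(ys, xs, shape=mask.shape)
    mask[rr, cc] = True
    return mask


def disk_mask(radius: int, size: int | None = None) -> np.ndarray:
    size = size or (2 * radius + 11)
    c = (size - 1) / 2
    yy, xx = np.mgrid[0:size, 0:size]
    return (yy - c) ** 2 + (xx - c) ** 2 <= radius**2
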