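"""Classical image operators composed by the segmentation pipeline.

Conventions: grayscale images are 2-D float arrays; binary images are 2-D
uint8 arrays over {0,1} with foreground = 1 = bright body tissue, so lung
fields appear as enclosed 0-holes. Label images are non-negative ints.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.feature import canny


class DegenerateImageError(ValueError):
    """Raised when an image lacks the intensity structure an operator needs."""


def _as_bool(binary):
    return np.asarray(binary) > 0


def otsu_binarize(img):
    """Binarize by Otsu's criterion on a 256-bin histogram.

    Returns ``(threshold, binary)`` where the threshold maximizes the
    between-class variance over all 255 cut points of a 256-bin histogram
    spanning the image's min-max range (ties broken toward the lower cut),
    and ``binary`` is 1 where ``img > threshold``.
    """
    img = np.asarray(img, dtype=np.float64)
    lo, hi = float(img.min()), float(img.max())
    if not hi > lo:
        raise DegenerateImageError("constant image has no Otsu threshold")
    hist, edges = np.histogram(img, bins=256, range=(lo, hi))
    p = hist / hist.sum()
    centers = 0.5 * (edges[:-1] + edges[1:])
    w0 = np.cumsum(p)[:-1]
    w1 = 1.0 - w0
    mu0 = np.cumsum(p * centers)[:-1]
    mu_total = float((p * centers).sum())
    valid = (w0 > 0) & (w1 > 0)
    sigma_b = np.zeros(255)
    sigma_b[valid] = (mu_total * w0[valid] - mu0[valid]) ** 2 / (w0[valid] * w1[valid])
    t = int(np.argmax(sigma_b))  # argmax returns the first (lowest) maximizer
    threshold = float(edges[t + 1])
    return threshold, (img > threshold).astype(np.uint8)


def clustering_tree(img, ks, seed=0):
    """k-means partitions of pixel intensities at several resolutions ``ks``.

    Each returned label image uses intensity-ordered ids 1..k (1 = darkest
    cluster). Runs are independent per k (k-means++ init, 10 restarts,
    seeded), so the tree is a family of nested-resolution clusterings rather
    than a linked hierarchy.
    """
    from sklearn.cluster import KMeans

    img = np.asarray(img, dtype=np.float64)
    values = img.reshape(-1, 1)
    n_distinct = len(np.unique(values))
    out = []
    for k in ks:
        if k < 2:
            raise ValueError("cluster counts must be >= 2")
        if n_distinct < k:
            raise DegenerateImageError(
                f"image has {n_distinct} distinct intensities, fewer than k={k}")
        km = KMeans(n_clusters=k, n_init=10, random_state=int(seed) % (2**31))
        labels = km.fit_predict(values)
        order = np.argsort(km.cluster_centers_.ravel())
        remap = np.empty(k, dtype=np.int64)
        remap[order] = np.arange(1, k + 1)
        out.append(remap[labels].reshape(img.shape).astype(np.uint8))
    return out


_STRUCT = {
    4: ndi.generate_binary_structure(2, 1),
    8: ndi.generate_binary_structure(2, 2),
}


def connected_components(binary, connectivity=8):
    """Label connected foreground components; ids follow raster order.

    Returns ``(labels, count)`` with labels 1..count assigned by the raster
    position of each component's first pixel.
    """
    if connectivity not in _STRUCT:
        raise ValueError("connectivity must be 4 or 8")
    lab, n = ndi.label(_as_bool(binary), structure=_STRUCT[connectivity])
    if n > 1:
        flat = lab.ravel()
        first = np.full(n + 1, flat.size, dtype=np.int64)
        np.minimum.at(first, flat, np.arange(flat.size))
        order = np.argsort(first[1:], kind="stable")
        remap = np.zeros(n + 1, dtype=lab.dtype)
        remap[1 + order] = np.arange(1, n + 1)
        lab = remap[lab]
    return lab.astype(np.int32), int(n)


def canny_edges(binary):
    """Canny edge set of a binary region image (Gaussian smoothing sigma=1)."""
    return canny(np.asarray(binary, dtype=float), sigma=1.0).astype(np.uint8)


def fill_holes(binary):
    """Fill background components not connected to the image border.

    The background is flooded with 4-connectivity (complementary to the
    8-connectivity used for foreground components).
    """
    return ndi.binary_fill_holes(_as_bool(binary), structure=_STRUCT[4]).astype(np.uint8)


def candidate_lung_region(img, body, min_area_frac=0.001):
    """Dark cavities enclosed by the binarized body foreground.

    Returns pixels that are background in ``body`` but foreground after hole
    filling, minus connected components smaller than ``min_area_frac`` of the
    image area (suppresses noise specks). ``img`` documents the pairing with
    its binarization and fixes the output shape contract.
    """
    body = _as_bool(body)
    if body.shape != np.asarray(img).shape:
        raise ValueError("body mask and image dimensions differ")
    cand = fill_holes(body).astype(bool) & ~body
    if not cand.any():
        return cand.astype(np.uint8)
    lab, n = connected_components(cand.astype(np.uint8), connectivity=8)
    min_area = min_area_frac * cand.size
    sizes = np.bincount(lab.ravel(), minlength=n + 1)
    keep = sizes >= min_area
    keep[0] = False
    return keep[lab].astype(np.uint8)


@dataclass(frozen=True)
class ContourQuality:
    """Contour-smoothness statistic of a candidate region.

    ``a1`` counts Canny edge pixels of the region, ``a2`` counts pixels of
    the hole-filled region, and ``tau2 = a2/a1`` grows with region size and
    contour closure: correctly extracted lungs have completely filled
    regions with smooth closed contours, hence large tau2. ``a1 == 0`` maps
    to ``tau2 = 0`` (worst quality, always refine).
    """

    a1: int
    a2: int
    tau2: float


def contour_quality(region):
    a1 = int(canny_edges(region).sum())
    a2 = int(fill_holes(region).sum())
    tau2 = a2 / a1 if a1 > 0 else 0.0
    return ContourQuality(a1=a1, a2=a2, tau2=tau2)


def dice(x, y):
    """Dice similarity 2|X∩Y| / (|X|+|Y|); two empty masks score 1.0."""
    x = _as_bool(x)
    y = _as_bool(y)
    if x.shape != y.shape:
        raise ValueError("mask dimensions differ")
    total = int(x.sum()) + int(y.sum())
    if total == 0:
        return 1.0
    return 2.0 * int((x & y).sum()) / total
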