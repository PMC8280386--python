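"""Synthetic thorax CT slice generator with exact ground-truth lung masks.

The phantom emulates the qualitative appearance of an axial thoracic CT
slice in normalized intensities: a dark air background, a bright elliptical
body, two dark lung fields inside the body, a table-like arc under the
patient, additive noise and global contrast variation. Pathology (ground
glass / fibrosis-like) is modeled as bright blobs straddling the lung
contour, which locally erase the lung/body intensity edge — the failure mode
contour refinement targets — while the ground-truth mask keeps the full
anatomical lung. Nominal tissue levels (background 0.05, lungs 0.15, table
0.55, pathology 0.65, body 0.75) are chosen so Otsu thresholding separates
air from tissue.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Tuple

import numpy as np

BACKGROUND_LEVEL = 0.05
LUNG_LEVEL = 0.15
TABLE_LEVEL = 0.55
PATHOLOGY_LEVEL = 0.65
BODY_LEVEL = 0.75

Ellipse = Tuple[float, float, float, float]  # (center_row, center_col, semi_r, semi_c)


def _default_body(s: float) -> Ellipse:
    return (0.53 * s, 0.50 * s, 0.34 * s, 0.42 * s)


def _default_lungs(s: float) -> Tuple[Ellipse, Ellipse]:
    return (
        (0.52 * s, 0.31 * s, 0.21 * s, 0.125 * s),
        (0.52 * s, 0.69 * s, 0.21 * s, 0.125 * s),
    )


@dataclass(frozen=True)
class PhantomParams:
    """Full parameterization of one synthetic slice.

    ``pathology_severity`` is the fraction of each lung's contour (by angle)
    disrupted by bright boundary blobs; ``noise_sigma`` is the std-dev of
    additive Gaussian noise in normalized intensity units; ``contrast_gain``
    rescales intensities around mid-gray (1.0 = nominal contrast). Geometry
    is given in pixels as ``(center_row, center_col, semi_axis_r, semi_axis_c)``
    ellipses; ``None`` selects defaults proportional to ``image_size``.
    Identical params (including ``seed``) give bit-identical slices.
    """

    image_size: int = 128
    lung_present: bool = True
    pathology_severity: float = 0.0
    noise_sigma: float = 0.02
    contrast_gain: float = 1.0
    body_ellipse: Optional[Ellipse] = None
    lung_ellipses: Optional[Tuple[Ellipse, ...]] = None
    table_artifact: bool = True
    seed: int = 0

    def resolved_body(self) -> Ellipse:
        return self.body_ellipse or _default_body(self.image_size)

    def resolved_lungs(self) -> Tuple[Ellipse, ...]:
        return tuple(self.lung_ellipses or _default_lungs(self.image_size))

    def validate(self) -> None:
        s = self.image_size
        if s < 64:
            raise ValueError("image_size must be >= 64")
        if not 0.0 <= self.pathology_severity <= 1.0:
            raise ValueError("pathology_severity must lie in [0, 1]")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")
        if self.contrast_gain <= 0:
            raise ValueError("contrast_gain must be positive")
        cr, cc, ar, ac = self.resolved_body()
        if cr - ar < 1 or cr + ar > s - 1 or cc - ac < 1 or cc + ac > s - 1:
            raise ValueError("body ellipse does not fit inside the image")
        for lr, lc, la, lb in self.resolved_lungs():
            # lungs must sit inside the body with margin for jitter and blobs
            margin = 0.10 * min(ar, ac)
            u = ((lr - cr) / ar) ** 2 + ((lc - cc) / ac) ** 2
            if u > 0.5 or lr - la < cr - ar + margin or lr + la > cr + ar - margin \
                    or lc - lb < cc - ac + margin or lc + lb > cc + ac - margin:
                raise ValueError("lung ellipse does not fit inside the body")


@dataclass(frozen=True)
class SliceRecord:
    """One synthetic CT slice: image in [0,1], ground-truth lung mask, flags."""

    image: np.ndarray
    mask: np.ndarray
    contains_lung: bool
    params: PhantomParams
    split: str = ""

    def __post_init__(self):
        if self.contains_lung != bool(self.mask.any()):
            raise ValueError("mask nonempty iff contains_lung")


def _ellipse_mask(shape, ellipse, rows, cols, perturb=None):
    cr, cc, ar, ac = ellipse
    dr = rows - cr
    dc = cols - cc
    rho = np.sqrt((dr / ar) ** 2 + (dc / ac) ** 2)
    if perturb is None:
        return rho <= 1.0
    theta = np.arctan2(dr, dc)
    bound = np.ones_like(theta)
    for m, amp, phase in perturb:
        bound += amp * np.cos(m * theta + phase)
    return rho <= bound


def make_thorax_slice(params: PhantomParams) -> SliceRecord:
    """Render one slice deterministically from ``params`` (incl. its seed)."""
    params.validate()
    s = params.image_size
    rng = np.random.default_rng(params.seed)
    rows, cols = np.mgrid[0:s, 0:s].astype(np.float64)

    img = np.full((s, s), BACKGROUND_LEVEL)
    body = _ellipse_mask((s, s), params.resolved_body(), rows, cols)
    img[body] = BODY_LEVEL

    if params.table_artifact:
        # thin bright arc cradling the body from below; its tips end inside
        # the body so a dark sliver between arc and body becomes an enclosed
        # cavity after hole filling — a classic false-positive component
        cr, cc, ar, ac = params.resolved_body()
        gap = (0.018 + 0.008 * rng.random()) * s
        radius = 0.40 * s
        center_r = cr + ar + gap - radius
        dist = np.sqrt((rows - center_r) ** 2 + (cols - cc) ** 2)
        arc = (np.abs(dist - radius) <= 0.012 * s) & (rows > center_r) \
            & (np.abs(cols - cc) <= 0.30 * s)
        img[arc & ~body] = TABLE_LEVEL

    mask = np.zeros((s, s), dtype=np.uint8)
    if params.lung_present:
        lungs = []
        for ellipse in params.resolved_lungs():
            cr, cc, ar, ac = ellipse
            jr = rng.uniform(-0.02, 0.02) * s
            jc = rng.uniform(-0.02, 0.02) * s
            ja = rng.uniform(0.92, 1.08)
            jb = rng.uniform(0.92, 1.08)
            ell = (cr + jr, cc + jc, ar * ja, ac * jb)
            perturb = [(m, rng.uniform(0.0, 0.04), rng.uniform(0, 2 * np.pi))
                       for m in (2, 3, 4)]
            lungs.append((ell, perturb))
        for ell, perturb in lungs:
            lung = _ellipse_mask((s, s), ell, rows, cols, perturb) & body
            img[lung] = LUNG_LEVEL
            mask[lung] = 1
        if params.pathology_severity > 0:
            for ell, perturb in lungs:
                _apply_pathology(img, body, ell, perturb, params, rng, rows, cols)

    if params.contrast_gain != 1.0:
        img = 0.5 + params.contrast_gain * (img - 0.5)
    if params.noise_sigma > 0:
        img = img + rng.normal(0.0, params.noise_sigma, size=img.shape)
    img = np.clip(img, 0.0, 1.0)

    return SliceRecord(image=img, mask=mask, contains_lung=params.lung_present,
                       params=params)


def _apply_pathology(img, body, ellipse, perturb, params, rng, rows, cols):
    """Overwrite a ``pathology_severity`` fraction of the lung contour with
    bright blobs, breaking the lung/body edge locally."""
    cr, cc, ar, ac = ellipse
    s = params.image_size
    target = params.pathology_severity * 2 * np.pi
    covered = 0.0
    r_mean = 0.5 * (ar + ac)
    while covered < target:
        theta = rng.uniform(0, 2 * np.pi)
        bound = 1.0 + sum(a * np.cos(m * theta + p) for m, a, p in perturb)
        br = cr + ar * bound * np.sin(theta)
        bc = cc + ac * bound * np.cos(theta)
        radius = rng.uniform(0.030, 0.050) * s
        blob = ((rows - br) ** 2 + (cols - bc) ** 2 <= radius ** 2) & body
        img[blob] = PATHOLOGY_LEVEL
        covered += 2.0 * radius / r_mean


def make_dataset(
    n: int,
    lung_fraction: float = 0.8,
    severity_range: Tuple[float, float] = (0.0, 0.3),
    seed: int = 0,
    image_size: int = 128,
    noise_sigma: float = 0.02,
    contrast_gain_range: Tuple[float, float] = (0.7, 1.0),
    split_fractions: Tuple[float, float, float] = (0.7, 0.15, 0.15),
):
    """Generate ``n`` slices plus a manifest, deterministically from ``seed``.

    Each slice gets an independent per-slice seed spawned from ``seed``; a
    ``lung_fraction`` of slices (binomially) contain lungs; lung slices draw
    pathology severity uniformly from ``severity_range`` and every slice
    draws a contrast gain from ``contrast_gain_range``. Train/val/test tags
    are assigned by a seeded stratified shuffle following ``split_fractions``.
    Returns ``(records, manifest)`` where the manifest is a list of per-slice
    parameter dicts.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0.0 <= lung_fraction <= 1.0:
        raise ValueError("lung_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    child_seeds = rng.integers(0, 2**31 - 1, size=n)
    has_lung = rng.random(n) < lung_fraction
    severities = np.where(has_lung, rng.uniform(*severity_range, size=n), 0.0)
    gains = rng.uniform(*contrast_gain_range, size=n)

    splits = _stratified_splits(has_lung, split_fractions, rng)

    records = []
    manifest = []
    for i in range(n):
        params = PhantomParams(
            image_size=image_size,
            lung_present=bool(has_lung[i]),
            pathology_severity=float(severities[i]),
            noise_sigma=noise_sigma,
            contrast_gain=float(gains[i]),
            seed=int(child_seeds[i]),
        )
        rec = replace(make_thorax_slice(params), split=splits[i])
        records.append(rec)
        manifest.append({
            "index": i,
            "seed": params.seed,
            "contains_lung": params.lung_present,
            "pathology_severity": params.pathology_severity,
            "contrast_gain": params.contrast_gain,
            "noise_sigma": params.noise_sigma,
            "image_size": params.image_size,
            "split": splits[i],
        })
    return records, manifest


def _stratified_splits(has_lung, fractions, rng):
    n = len(has_lung)
    splits = np.empty(n, dtype=object)
    for klass in (False, True):
        idx = np.flatnonzero(has_lung == klass)
        rng.shuffle(idx)
        n_train = int(round(fractions[0] * len(idx)))
        n_val = int(round(fractions[1] * len(idx)))
        splits[idx[:n_train]] = "train"
        splits[idx[n_train:n_train + n_val]] = "val"
        splits[idx[n_train + n_val:]] = "test"
    return list(splits)
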