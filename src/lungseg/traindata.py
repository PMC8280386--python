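"""Factories that turn slice collections into network training sets.

The manual visual-inspection steps of the original data-construction
workflow are replaced by ground-truth-driven rules, so every set can be
rebuilt automatically and deterministically: slice-level classifier labels
come from the generator's ``contains_lung`` flag, and component-level labels
come from overlap with the ground-truth mask (Dice >= 0.5 against any
ground-truth lung component = lung).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Optional

import numpy as np

from . import imgops

#: Dice overlap with a ground-truth lung component above which a connected
#: component counts as lung when labeling the component classifier set.
COMPONENT_OVERLAP = 0.5

UNET1_CONFIGS = {
    1: ("ground-truth masks", "copy of the input"),
    2: ("Otsu binary images", "copy of the input"),
    3: ("foreground images (largest Otsu component)", "copy of the input"),
    4: ("grayscale images", "two-class k-means label images"),
    5: ("grayscale images", "three-class k-means label images"),
}


@dataclass
class ClassifierSet:
    """Binary images with slice- or component-level lung/none-lung labels."""

    images: List[np.ndarray]
    labels: List[int]  # 1 = lung, 0 = none-lung
    manifest: dict = field(default_factory=dict)

    def counts(self):
        labels = np.asarray(self.labels)
        return int((labels == 1).sum()), int((labels == 0).sum())


@dataclass
class SegTrainSet:
    """Paired input/label images for a U-net, tagged with their provenance."""

    inputs: List[np.ndarray]
    labels: List[np.ndarray]
    config_id: Optional[int] = None
    n_classes: int = 2
    edge_labels: bool = False
    manifest: dict = field(default_factory=dict)


def build_cnn1_set(slices) -> ClassifierSet:
    """Slice-level set: Otsu-binarized slices labeled by ``contains_lung``."""
    if len(slices) == 0:
        raise ValueError("no slices provided")
    images, labels = [], []
    for rec in slices:
        _, binary = imgops.otsu_binarize(rec.image)
        images.append(binary)
        labels.append(1 if rec.contains_lung else 0)
    n_lung, n_none = _class_counts(labels)
    if n_lung == 0 or n_none == 0:
        warnings.warn("single-class slice collection; classifier set built anyway")
    return ClassifierSet(images, labels,
                         manifest={"kind": "cnn1", "n_lung": n_lung,
                                   "n_none_lung": n_none})


def build_cnn2_set(slices, seed: int = 0) -> ClassifierSet:
    """Component-level set from two-class k-means candidate regions.

    Each slice is clustered at k=2, candidate cavities of the bright
    (tissue) class are split into 8-connected components, and every
    component is rendered full-frame (at its original position in an
    otherwise zero image). A component is labeled lung iff its Dice overlap
    with some ground-truth lung component reaches ``COMPONENT_OVERLAP``.
    """
    images, labels = [], []
    for rec in slices:
        (clustered,) = imgops.clustering_tree(rec.image, [2], seed=seed)
        body = (clustered == 2).astype(np.uint8)  # bright class
        cand = imgops.candidate_lung_region(rec.image, body)
        comp_lab, n = imgops.connected_components(cand, connectivity=8)
        gt_comps = _gt_components(rec)
        for k in range(1, n + 1):
            comp = (comp_lab == k).astype(np.uint8)
            is_lung = any(imgops.dice(comp, g) >= COMPONENT_OVERLAP
                          for g in gt_comps)
            images.append(comp)
            labels.append(1 if is_lung else 0)
    n_lung, n_none = _class_counts(labels)
    return ClassifierSet(images, labels,
                         manifest={"kind": "cnn2", "n_lung": n_lung,
                                   "n_none_lung": n_none, "seed": seed})


def _gt_components(rec):
    if not rec.contains_lung:
        return []
    lab, n = imgops.connected_components(rec.mask, connectivity=8)
    return [(lab == k).astype(np.uint8) for k in range(1, n + 1)]


def _class_counts(labels):
    labels = np.asarray(labels)
    return int((labels == 1).sum()), int((labels == 0).sum())


def build_unet1_set(slices, config_id: int, seed: int = 0,
                    gate=None) -> SegTrainSet:
    """One of the five segmentation training-data configurations.

    1: (ground-truth mask, copy); 2: (Otsu binary, copy); 3: (foreground =
    largest Otsu component with holes unfilled, copy); 4: (grayscale,
    2-class k-means labels); 5: (grayscale, 3-class k-means labels). Label
    class ids are intensity-ordered (0 = darkest). Only lung-containing
    slices enter the set: they are the population the segmentation stage
    sees after slice gating.

    When a ``QualityGate`` is passed, each image runs through the same
    quality-evaluation/enhancement step the pipeline applies at inference,
    so the segmentation network trains on the domain it will be fed.
    """
    if config_id not in UNET1_CONFIGS:
        raise ValueError(f"unknown training-data configuration {config_id}")
    inputs, labels = [], []
    lung_slices = [rec for rec in slices if rec.contains_lung]
    if config_id == 1 and any(rec.mask is None for rec in lung_slices):
        raise ValueError("configuration 1 requires ground-truth masks")
    for rec in lung_slices:
        image = rec.image
        if gate is not None and config_id != 1:
            from .quality import apply_gate

            image, _, _ = apply_gate(image, gate)
        if config_id == 1:
            inp = rec.mask.astype(np.float64)
            lab = rec.mask.astype(np.uint8)
        elif config_id == 2:
            _, binary = imgops.otsu_binarize(image)
            inp = binary.astype(np.float64)
            lab = binary
        elif config_id == 3:
            _, binary = imgops.otsu_binarize(image)
            comp_lab, n = imgops.connected_components(binary, connectivity=8)
            if n == 0:
                continue
            sizes = np.bincount(comp_lab.ravel())[1:]
            fg = (comp_lab == 1 + int(np.argmax(sizes))).astype(np.uint8)
            inp = fg.astype(np.float64)
            lab = fg
        elif config_id == 4:
            (clustered,) = imgops.clustering_tree(image, [2], seed=seed)
            inp = image
            lab = (clustered - 1).astype(np.uint8)  # 0-based class ids
        else:
            (clustered,) = imgops.clustering_tree(image, [3], seed=seed)
            inp = image
            lab = (clustered - 1).astype(np.uint8)
        inputs.append(inp)
        labels.append(lab)
    n_classes = 3 if config_id == 5 else 2
    return SegTrainSet(inputs, labels, config_id=config_id, n_classes=n_classes,
                       manifest={"kind": "unet1", "config_id": config_id,
                                 "seed": seed, "n_items": len(inputs)})


def build_unet2_set(slices, size: Optional[int] = None) -> SegTrainSet:
    """Contour-refinement set: broken binary lung regions -> closed edge labels.

    Input: the dark lung tissue inside the ground-truth mask (mask pixels at
    or below the slice's Otsu threshold) — pathology brightens part of the
    lung, so inputs show contour gaps. Label: the Canny edge image of the
    ground-truth mask, which is always a closed contour. Slices without
    lungs are skipped.

    Edge labels are one-pixel curves, so they cannot survive label
    resampling; when ``size`` is given the mask is resampled first and the
    edge extracted at that working resolution.
    """
    inputs, labels = [], []
    for rec in slices:
        if not rec.contains_lung:
            continue
        threshold, _ = imgops.otsu_binarize(rec.image)
        broken = ((rec.mask > 0) & (rec.image <= threshold)).astype(np.uint8)
        mask = rec.mask
        if size is not None and mask.shape != (size, size):
            from .models import resize_image

            broken = (resize_image(broken.astype(np.float64), size, order=1)
                      > 0.5).astype(np.uint8)
            mask = (resize_image(mask.astype(np.float64), size, order=1)
                    > 0.5).astype(np.uint8)
        inputs.append(broken.astype(np.float64))
        labels.append(imgops.canny_edges(mask))
    return SegTrainSet(inputs, labels, config_id=None, n_classes=2,
                       edge_labels=True,
                       manifest={"kind": "unet2", "n_items": len(inputs)})
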