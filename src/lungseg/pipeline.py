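"""Three-stage segmentation orchestration and its ablation modes.

Stage 1 (preprocessing): Otsu-binarize the slice, let the slice classifier
reject non-lung slices (zero mask short-circuit), then quality-gate the
survivors (enhance low-contrast slices). Stage 2 (processing): the
segmentation U-net converts the grayscale slice to a label image whose
brightest class is the body; the candidate lung region is the set of dark
cavities enclosed by that body. Stage 3 (postprocessing): the contour
statistic tau2 decides whether the refinement U-net redraws the lung
contour; the (possibly refined) region is hole-filled, split into connected
components, and each component is kept or dropped by the component
classifier before the final mask is assembled.

Ablation modes mirror the system configurations studied alongside the full
system: ``without_cnns`` removes both classifier CNNs (slice gating and
component filtering) while keeping the U-nets; ``without_enhancement``
removes only the quality evaluation/enhancement step.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from . import imgops
from .models import TrainedModel, binary_body_view, predict_class, predict_probs
from .quality import QualityGate, apply_gate

MODES = ("three_stage", "without_cnns", "without_enhancement")


@dataclass
class PipelineConfig:
    """Models, thresholds and mode for one pipeline instantiation.

    ``tau2_threshold`` routes candidate regions with contour statistic below
    it to the refinement U-net. ``refine_enabled=False`` disables the
    refinement branch entirely (used for ablation of the refinement step).
    ``edge_closing_px`` closes 1-pixel gaps in predicted contours by
    dilation before hole filling (mirrored by erosion after, so region area
    is preserved).
    """

    models: Dict[str, Optional[TrainedModel]] = field(default_factory=dict)
    quality: QualityGate = field(default_factory=QualityGate)
    mode: str = "three_stage"
    tau2_threshold: float = 12.0
    min_area_frac: float = 0.001
    refine_enabled: bool = True
    edge_closing_px: int = 1

    def __post_init__(self):
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")
        if self.tau2_threshold <= 0:
            raise ValueError("tau2_threshold must be positive")

    @property
    def use_cnns(self) -> bool:
        return self.mode != "without_cnns"

    @property
    def use_enhancement(self) -> bool:
        return self.mode != "without_enhancement"

    def require(self, name):
        model = self.models.get(name)
        if model is None:
            raise ValueError(f"mode {self.mode!r} requires model {name!r}")
        return model


@dataclass
class SegResult:
    """Final mask plus the per-stage trace of images and gate decisions."""

    mask: np.ndarray
    trace: dict


def preprocess(slice_img, cfg: PipelineConfig):
    """Slice gating and quality gate.

    Returns ``(proceed, image, trace)``; when the slice classifier rejects
    the slice, ``proceed`` is False and ``image`` is the all-zero mask.
    """
    img = np.asarray(slice_img, dtype=np.float64)
    trace = {"mode": cfg.mode}
    _, bim = imgops.otsu_binarize(img)
    trace["BIM"] = bim
    if cfg.use_cnns:
        label, conf = predict_class(cfg.require("cnn1"), bim)
        trace["contains_lung"] = label == "lung"
        trace["cnn1_confidence"] = conf
        if label != "lung":
            return False, np.zeros_like(bim), trace
    else:
        trace["contains_lung"] = None  # gating skipped by design
    if cfg.use_enhancement:
        img, score, enhanced = apply_gate(img, cfg.quality)
        trace["quality_score"] = score
        trace["enhanced"] = enhanced
    else:
        trace["quality_score"] = None
        trace["enhanced"] = False
    trace["TQM"] = img
    return True, img, trace


def process(img, cfg: PipelineConfig):
    """U-net binarization and candidate lung-region extraction.

    Networks trained on binary-input configurations are fed the slice's
    Otsu binarization (their training domain); networks trained on
    grayscale configurations are fed the (possibly enhanced) slice itself.
    """
    img = np.asarray(img, dtype=np.float64)
    unet1 = cfg.require("unet1")
    if unet1.log.get("input_domain") == "binary":
        _, fed = imgops.otsu_binarize(img)
        fed = fed.astype(np.float64)
    else:
        fed = img
    probs = predict_probs(unet1, fed)
    label_img = probs.argmax(axis=0).astype(np.uint8)
    body = binary_body_view(label_img, fed)
    candidate = imgops.candidate_lung_region(img, body,
                                             min_area_frac=cfg.min_area_frac)
    trace = {"TCB": body, "TCR": candidate}
    return candidate, trace


def postprocess(candidate, cfg: PipelineConfig) -> SegResult:
    """tau2-gated contour refinement, hole filling and component filtering."""
    candidate = (np.asarray(candidate) > 0).astype(np.uint8)
    trace = {}
    cq = imgops.contour_quality(candidate)
    trace["tau2"] = cq.tau2
    refine = (cfg.refine_enabled and cq.tau2 < cfg.tau2_threshold
              and cfg.models.get("unet2") is not None)
    trace["refined"] = bool(refine)
    region = candidate
    if refine:
        refined = _refine_contour(candidate, cfg)
        trace["TCM"] = refined
        if refined is not None:
            region = refined
        else:
            trace["refined"] = False  # predicted contour did not close

    filled = imgops.fill_holes(region)
    labels, n = imgops.connected_components(filled, connectivity=8)
    kept, dropped = [], []
    mask = np.zeros_like(filled)
    for k in range(1, n + 1):
        comp = (labels == k).astype(np.uint8)
        if cfg.use_cnns and cfg.models.get("cnn2") is not None:
            label, _ = predict_class(cfg.require("cnn2"), comp)
            if label != "lung":
                dropped.append(k)
                continue
        kept.append(k)
        mask |= comp
    trace["components_kept"] = kept
    trace["components_dropped"] = dropped
    trace["contains_lung"] = bool(mask.any())
    return SegResult(mask=mask, trace=trace)


def _refine_contour(candidate, cfg):
    """Close the lung contour with the refinement U-net's edge prediction.

    The predicted edge map (at the model's native resolution) is thickened
    into a closing ring, upsampled onto the slice, united with the candidate
    and hole-filled; eroding the filled region by 2.5x the model-to-slice
    scale factor removes the ring's outward overhang. The final region is
    the union of that closed interior with the original candidate, so
    refinement can only bridge contour gaps, never carve away candidate
    pixels. Returns None when no contour is predicted (candidate kept)."""
    unet2 = cfg.require("unet2")
    probs = predict_probs(unet2, candidate.astype(np.float64),
                          at_model_resolution=True)
    edge = probs.argmax(axis=0) == 1
    if not edge.any():
        return None
    ring = ndi.binary_dilation(edge, iterations=cfg.edge_closing_px)
    from .models import resize_image

    ring_full = resize_image(ring.astype(np.float64), candidate.shape[0],
                             order=1) > 0.5
    base = ndi.binary_fill_holes(candidate.astype(bool) | ring_full)
    scale = candidate.shape[0] / unet2.spec.input_size
    erosion = max(1, int(round(2.5 * scale)))
    interior = ndi.binary_erosion(base, iterations=erosion)
    return (candidate.astype(bool) | interior).astype(np.uint8)


def segment_slice(slice_img, cfg: PipelineConfig) -> SegResult:
    """Full three-stage segmentation of one slice with a complete trace."""
    proceed, img_or_zero, trace1 = preprocess(slice_img, cfg)
    if not proceed:
        trace1.update({"tau2": None, "refined": False,
                       "components_kept": [], "components_dropped": []})
        return SegResult(mask=img_or_zero.astype(np.uint8), trace=trace1)
    candidate, trace2 = process(img_or_zero, cfg)
    result = postprocess(candidate, cfg)
    result.trace = {**trace1, **trace2, **result.trace}
    return result


def evaluate(dataset, cfgs, config_ids=None):
    """Mean Dice per (training configuration x system mode).

    ``cfgs`` maps ``(config_id, mode)`` to a ready ``PipelineConfig``.
    Returns ``(table, per_slice)``: a pivoted DataFrame of mean Dice and the
    per-slice scores. Slices without ground-truth masks are skipped with a
    warning.
    """
    import warnings

    rows = []
    for (config_id, mode), cfg in cfgs.items():
        for i, rec in enumerate(dataset):
            if rec.mask is None:
                warnings.warn(f"slice {i} has no ground-truth mask; skipped")
                continue
            result = segment_slice(rec.image, cfg)
            rows.append({
                "config_id": config_id,
                "mode": mode,
                "slice": i,
                "contains_lung": rec.contains_lung,
                "severity": rec.params.pathology_severity,
                "dice": imgops.dice(result.mask, rec.mask),
            })
    per_slice = pd.DataFrame(rows)
    table = per_slice.pivot_table(index="config_id", columns="mode",
                                  values="dice", aggfunc="mean")
    return table, per_slice
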