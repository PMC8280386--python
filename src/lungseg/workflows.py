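"""End-to-end desk-scale workflows: train a full system, run the benchmark.

Problem sizes here are the package's desk-scale study conditions: phantom
slices of 128x128 pixels, model input resolution 64x64, and training runs of
at most a few hundred minibatch iterations (the identity-style binary
configurations converge in a few dozen iterations).
"""

from __future__ import annotations

from dataclasses import replace
from typing import Dict, Tuple

import numpy as np

from . import traindata
from .models import ClassifierSpec, TrainConfig, UnetSpec, train_classifier, train_unet
from .phantom import make_dataset
from .pipeline import PipelineConfig, evaluate
from .quality import QualityGate


def _derive_seed(seed, offset):
    return int((int(seed) * 1000003 + offset) % (2**31 - 1))


def train_shared_models(train_slices, seed: int = 0, model_size: int = 64,
                        classifier_iterations: int = 150,
                        unet_iterations: int = 150,
                        learning_rate: float = 0.1) -> Dict[str, object]:
    """Train the training-configuration-independent models.

    The slice classifier (CNN-1), component classifier (CNN-2) and contour
    refinement network (UNET-2) do not depend on which of the five
    segmentation training-data configurations is in use, so one set serves
    every configuration.
    """
    train_slices = list(train_slices)

    cnn1_data = traindata.build_cnn1_set(train_slices)
    cnn1 = train_classifier(
        ClassifierSpec(input_size=model_size), cnn1_data,
        TrainConfig.desk_scale(seed=_derive_seed(seed, 1),
                               max_iterations=classifier_iterations,
                               learning_rate=learning_rate))

    cnn2_data = traindata.build_cnn2_set(train_slices, seed=_derive_seed(seed, 2))
    cnn2 = train_classifier(
        ClassifierSpec(input_size=model_size), cnn2_data,
        TrainConfig.desk_scale(seed=_derive_seed(seed, 3),
                               max_iterations=classifier_iterations,
                               learning_rate=learning_rate))

    unet2_data = traindata.build_unet2_set(train_slices, size=model_size)
    unet2_cfg = TrainConfig.desk_scale(seed=_derive_seed(seed, 6),
                                       max_iterations=unet_iterations,
                                       learning_rate=learning_rate)
    unet2 = train_unet(
        UnetSpec(input_size=model_size, n_classes=2), unet2_data,
        replace(unet2_cfg, class_weight="balanced"))

    return {"cnn1": cnn1, "cnn2": cnn2, "unet2": unet2}


def train_segmenter(train_slices, config_id: int, seed: int = 0,
                    model_size: int = 64, unet_iterations: int = 150,
                    learning_rate: float = 0.1):
    """Train the segmentation U-net (UNET-1) for one training configuration."""
    unet1_data = traindata.build_unet1_set(list(train_slices),
                                           config_id=config_id,
                                           seed=_derive_seed(seed, 4),
                                           gate=QualityGate())
    return train_unet(
        UnetSpec(input_size=model_size, n_classes=unet1_data.n_classes),
        unet1_data,
        TrainConfig.desk_scale(seed=_derive_seed(seed, 5),
                               max_iterations=unet_iterations,
                               learning_rate=learning_rate))


def train_system(train_slices, config_id: int = 5, seed: int = 0,
                 model_size: int = 64,
                 classifier_iterations: int = 150,
                 unet_iterations: int = 150,
                 learning_rate: float = 0.1) -> Dict[str, object]:
    """Train all four models of the system on one slice collection.

    Returns the model dict expected by ``PipelineConfig``. Training sets are
    built with the ground-truth-driven factories; each model gets its own
    seed derived from ``seed``.
    """
    train_slices = list(train_slices)
    models = train_shared_models(
        train_slices, seed=seed, model_size=model_size,
        classifier_iterations=classifier_iterations,
        unet_iterations=unet_iterations, learning_rate=learning_rate)
    models["unet1"] = train_segmenter(
        train_slices, config_id=config_id, seed=seed, model_size=model_size,
        unet_iterations=unet_iterations, learning_rate=learning_rate)
    return models


def run_benchmark(seed: int = 0, n_train: int = 500, n_test: int = 100,
                  config_ids: Tuple[int, ...] = (2, 5),
                  modes: Tuple[str, ...] = ("three_stage", "without_cnns"),
                  image_size: int = 128,
                  severity_range: Tuple[float, float] = (0.0, 0.3),
                  lung_fraction: float = 0.8,
                  refinement_ablation: bool = True,
                  n_refine_test: int = 40,
                  **train_kwargs):
    """Seeded synthetic benchmark over training configs x system modes.

    Generates ``n_train + n_test`` phantom slices (a ``lung_fraction`` of
    them with lungs, pathology severity uniform over ``severity_range``),
    trains a full system per training configuration, evaluates every
    (configuration, mode) cell, and — when ``refinement_ablation`` — scores
    an extra set of severity-0.3 lung slices with the refinement branch
    enabled vs disabled. Returns a results dict.
    """
    n = n_train + n_test
    records, manifest = make_dataset(
        n, lung_fraction=lung_fraction, severity_range=severity_range,
        seed=_derive_seed(seed, 100), image_size=image_size,
        split_fractions=(n_train / n, 0.0, n_test / n))
    train_slices = [r for r in records if r.split == "train"]
    test_slices = [r for r in records if r.split == "test"]

    shared = train_shared_models(train_slices, seed=_derive_seed(seed, 9),
                                 **train_kwargs)
    systems = {}
    cfgs = {}
    for config_id in config_ids:
        unet1 = train_segmenter(
            train_slices, config_id=config_id,
            seed=_derive_seed(seed, 10 + config_id),
            **{k: v for k, v in train_kwargs.items()
               if k in ("model_size", "unet_iterations", "learning_rate")})
        models = {**shared, "unet1": unet1}
        systems[config_id] = models
        for mode in modes:
            cfgs[(config_id, mode)] = PipelineConfig(models=models, mode=mode)

    table, per_slice = evaluate(test_slices, cfgs)

    results = {
        "table": table,
        "per_slice": per_slice,
        "systems": systems,
        "n_train": len(train_slices),
        "n_test": len(test_slices),
    }

    if refinement_ablation:
        # ablate refinement on the Otsu-identity configuration: its
        # processing stage reproduces the thresholded image, so pathology
        # leaves real contour gaps for the refinement stage to close
        config_id = config_ids[0]
        # nominal contrast isolates contour refinement from the quality
        # gate: enhancement itself darkens bright pathology, so enhanced
        # slices reach the candidate stage with partially healed contours
        refine_records, _ = make_dataset(
            n_refine_test, lung_fraction=1.0, severity_range=(0.3, 0.3),
            contrast_gain_range=(1.0, 1.0),
            seed=_derive_seed(seed, 200), image_size=image_size,
            split_fractions=(0.0, 0.0, 1.0))
        base = PipelineConfig(models=systems[config_id], mode="three_stage")
        on_cfg = {(config_id, "three_stage"): base}
        off_cfg = {(config_id, "three_stage"): replace(base, refine_enabled=False)}
        _, on = evaluate(refine_records, on_cfg)
        _, off = evaluate(refine_records, off_cfg)
        results["refinement"] = {
            "config_id": config_id,
            "n_slices": n_refine_test,
            "dice_refined": float(on["dice"].mean()),
            "dice_unrefined": float(off["dice"].mean()),
        }
    return results
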