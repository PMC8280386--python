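"""Network specifications, training and inference for the four models.

Two classifier CNNs gate the pipeline (slice-level lung/none-lung before
segmentation; component-level false-positive filtering after) and two
encoder-decoder U-nets do the pixel work (grayscale-to-mask conversion;
contour refinement via edge prediction).

Classifier: three stages of (3x3 convolution -> ReLU -> batch norm -> 2x2
max pool) with 8, 16 and 32 filters, then a fully connected softmax head
over two classes. U-net: an encoder of two 3x3 convolutions (64 filters
each, no padding) each followed by 2x2 max pooling (total down-sampling
x4), a decoder of two stride-2 3x3 transposed convolutions (64 filters
each, total up-sampling x4), a 1x1 per-pixel class head, and symmetric
zero-padding that re-aligns the shrunken no-padding maps to the input frame.

Training uses minibatch SGD with momentum 0.9 and softmax cross-entropy
(per image for classifiers, per pixel for U-nets); the optimizer and loss
are this package's choices. All randomness (init, shuffling, splits) derives
from the training config seed, so runs are bit-reproducible on one CPU.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Optional, Tuple

import numpy as np
from skimage.transform import resize as _sk_resize

from . import nn

CLASS_NAMES = ("none-lung", "lung")


@dataclass(frozen=True)
class ClassifierSpec:
    """Three-stage convolutional classifier over two classes."""

    input_size: int = 64
    filters: Tuple[int, int, int] = (8, 16, 32)
    kernel: int = 3
    n_classes: int = 2


@dataclass(frozen=True)
class UnetSpec:
    """No-padding encoder/decoder U-net with a per-pixel class head."""

    input_size: int = 64
    filters: int = 64
    kernel: int = 3
    n_classes: int = 2


@dataclass(frozen=True)
class TrainConfig:
    """Training hyperparameters.

    Defaults follow the full-scale recipe (initial learning rate 0.001,
    100 epochs max, validation every 30 iterations, minibatches of 32).
    Desk-scale runs override ``max_iterations``/``learning_rate`` to fit
    interactive budgets; see ``desk_scale``.
    """

    learning_rate: float = 0.001
    max_epochs: int = 100
    validation_frequency: int = 30
    minibatch_size: int = 32
    momentum: float = 0.9
    seed: int = 0
    max_iterations: Optional[int] = None
    early_stop_patience: Optional[int] = None
    #: "balanced" reweights the loss by inverse class frequency — needed for
    #: sparse targets such as one-pixel edge labels, which otherwise drive
    #: the net to the all-background solution.
    class_weight: Optional[str] = None

    @staticmethod
    def desk_scale(seed=0, max_iterations=80, learning_rate=0.05,
                   minibatch_size=16, validation_frequency=10):
        """Reduced-scale config for interactive/test runs."""
        return TrainConfig(learning_rate=learning_rate, max_epochs=100,
                           validation_frequency=validation_frequency,
                           minibatch_size=minibatch_size, seed=seed,
                           max_iterations=max_iterations)


class TrainedModel:
    """A fitted network plus its spec, kind and training log."""

    def __init__(self, net, spec, kind, log=None, pad=None):
        self.net = net
        self.spec = spec
        self.kind = kind  # "classifier" | "unet"
        self.log = log or {}
        self.pad = pad  # PadToInput layer for unets

    def forward(self, x, train=False):
        y = self.net.forward(x, train=train)
        if self.pad is not None:
            self.pad.target = (x.shape[2], x.shape[3])
            y = self.pad.forward(y, train=train)
        return y


def build_classifier(spec: ClassifierSpec, rng) -> TrainedModel:
    layers = []
    cin = 1
    size = spec.input_size
    for f in spec.filters:
        layers += [nn.Conv2D(cin, f, spec.kernel, rng, padding="same"),
                   nn.ReLU(), nn.BatchNorm2D(f), nn.MaxPool2D()]
        cin = f
        size //= 2
    layers += [nn.Flatten(), nn.Dense(cin * size * size, spec.n_classes, rng)]
    return TrainedModel(nn.Sequential(layers), spec, "classifier")


def build_unet(spec: UnetSpec, rng) -> TrainedModel:
    f, k = spec.filters, spec.kernel
    net = nn.Sequential([
        nn.Conv2D(1, f, k, rng, padding="valid"), nn.ReLU(), nn.MaxPool2D(),
        nn.Conv2D(f, f, k, rng, padding="valid"), nn.ReLU(), nn.MaxPool2D(),
        nn.ConvTranspose2D(f, f, k, rng, stride=2), nn.ReLU(),
        nn.ConvTranspose2D(f, f, k, rng, stride=2), nn.ReLU(),
        nn.Conv2D(f, spec.n_classes, 1, rng),
    ])
    return TrainedModel(net, spec, "unet", pad=nn.PadToInput())


def resize_image(img, size, order=1):
    """Deterministic bilinear (order=1) or nearest (order=0) square resize."""
    img = np.asarray(img, dtype=np.float64)
    if img.shape == (size, size):
        return img
    return _sk_resize(img, (size, size), order=order, mode="edge",
                      anti_aliasing=False, preserve_range=True)


def _prepare_images(images, size):
    out = np.empty((len(images), 1, size, size), dtype=np.float32)
    for i, img in enumerate(images):
        out[i, 0] = resize_image(img, size, order=1)
    return out


def _iterate_minibatches(n, batch, rng):
    idx = rng.permutation(n)
    for start in range(0, n, batch):
        yield idx[start:start + batch]


def train_classifier(spec: ClassifierSpec, data, cfg: TrainConfig) -> TrainedModel:
    """Fit the two-class CNN on a ``ClassifierSet``-like object.

    ``data`` must expose ``images`` (list of 2-D binary arrays) and
    ``labels`` (ints in {0, 1}, 1 = lung). Both classes must be present.
    """
    images, labels = list(data.images), np.asarray(data.labels, dtype=np.int64)
    if len(images) == 0:
        raise ValueError("empty training set")
    present = np.unique(labels)
    if len(present) < spec.n_classes:
        raise ValueError(f"all {spec.n_classes} classes required, got {present}")
    rng = np.random.default_rng(cfg.seed)
    model = build_classifier(spec, rng)
    x = _prepare_images(images, spec.input_size)
    log = _fit(model, x, labels, cfg, rng, pixelwise=False)
    model.log = log
    return model


def train_unet(spec: UnetSpec, data, cfg: TrainConfig) -> TrainedModel:
    """Fit a U-net on a ``SegTrainSet``-like object.

    ``data`` must expose ``inputs`` (2-D float images) and ``labels``
    (2-D int class images) whose class arity matches ``spec.n_classes``.
    """
    inputs, labels = list(data.inputs), list(data.labels)
    if len(inputs) == 0:
        raise ValueError("empty training set")
    arity = max(int(np.max(lab)) for lab in labels) + 1
    if arity > spec.n_classes:
        raise ValueError(
            f"label arity {arity} exceeds model classes {spec.n_classes}")
    rng = np.random.default_rng(cfg.seed)
    model = build_unet(spec, rng)
    s = spec.input_size
    x = _prepare_images(inputs, s)
    y = np.empty((len(labels), s, s), dtype=np.int64)
    for i, lab in enumerate(labels):
        y[i] = resize_image(lab, s, order=0)
    log = _fit(model, x, y, cfg, rng, pixelwise=True)
    # record the input domain so the pipeline can feed matching images:
    # binary-input configurations (identity-style sets and edge refinement)
    # vs grayscale-input configurations (k-means label sets)
    config_id = getattr(data, "config_id", None)
    binary_domain = bool(getattr(data, "edge_labels", False)) or config_id in (1, 2, 3)
    log["input_domain"] = "binary" if binary_domain else "gray"
    model.log = log
    return model


def _loss_and_grad(model, xb, yb, pixelwise, train=True, weights=None):
    logits = model.forward(xb, train=train)
    if pixelwise:
        n, c, h, w = logits.shape
        flat = logits.transpose(0, 2, 3, 1).reshape(-1, c)
        yflat = yb.reshape(-1)
        sw = weights[yflat] if weights is not None else None
        loss, grad = nn.softmax_xent(flat, yflat, sample_weight=sw)
        grad = grad.reshape(n, h, w, c).transpose(0, 3, 1, 2)
        acc = float((flat.argmax(axis=1) == yflat).mean())
    else:
        sw = weights[yb] if weights is not None else None
        loss, grad = nn.softmax_xent(logits, yb, sample_weight=sw)
        acc = float((logits.argmax(axis=1) == yb).mean())
    return loss, grad, acc


def _fit(model, x, y, cfg, rng, pixelwise):
    n = x.shape[0]
    weights = None
    if cfg.class_weight == "balanced":
        counts = np.bincount(np.asarray(y).reshape(-1))
        counts = np.maximum(counts, 1)
        weights = counts.sum() / (len(counts) * counts.astype(np.float64))
    n_val = max(1, int(round(0.15 * n))) if n >= 7 else 0
    perm = rng.permutation(n)
    val_idx, train_idx = perm[:n_val], perm[n_val:]
    xt, yt = x[train_idx], y[train_idx]
    xv, yv = x[val_idx], y[val_idx]

    opt = nn.SGDMomentum(model.net, cfg.learning_rate, cfg.momentum)
    log = {"train_loss": [], "val_iter": [], "val_loss": [], "val_acc": []}
    it = 0
    best_val, since_best = np.inf, 0
    stop = False
    for _epoch in range(cfg.max_epochs):
        for batch in _iterate_minibatches(len(xt), cfg.minibatch_size, rng):
            loss, grad, _ = _loss_and_grad(model, xt[batch], yt[batch], pixelwise,
                                           weights=weights)
            if model.pad is not None:
                grad = model.pad.backward(grad)
            model.net.backward(grad)
            opt.step()
            log["train_loss"].append(loss)
            it += 1
            if n_val and it % cfg.validation_frequency == 0:
                vl, va = _evaluate(model, xv, yv, cfg.minibatch_size, pixelwise)
                log["val_iter"].append(it)
                log["val_loss"].append(vl)
                log["val_acc"].append(va)
                if cfg.early_stop_patience is not None:
                    if vl < best_val - 1e-5:
                        best_val, since_best = vl, 0
                    else:
                        since_best += 1
                        if since_best >= cfg.early_stop_patience:
                            stop = True
            if cfg.max_iterations is not None and it >= cfg.max_iterations:
                stop = True
            if stop:
                break
        if stop:
            break
    log["iterations"] = it
    return log


def _evaluate(model, x, y, batch, pixelwise):
    losses, accs, weights = [], [], []
    for start in range(0, len(x), batch):
        xb, yb = x[start:start + batch], y[start:start + batch]
        loss, _, acc = _loss_and_grad(model, xb, yb, pixelwise, train=False)
        losses.append(loss)
        accs.append(acc)
        weights.append(len(xb))
    w = np.asarray(weights, dtype=float)
    return float(np.average(losses, weights=w)), float(np.average(accs, weights=w))


def _check_size(model, img):
    s = model.spec.input_size
    if img.shape != (s, s):
        warnings.warn(
            f"input {img.shape} resized to model size {(s, s)}", stacklevel=3)
    return resize_image(img, s, order=1)


def predict_class(model: TrainedModel, img):
    """Classify one image; returns ``(class_name, softmax_confidence)``."""
    x = _check_size(model, np.asarray(img, dtype=np.float64))[None, None].astype(np.float32)
    logits = model.forward(x, train=False)
    probs = nn.softmax(logits.astype(np.float64), axis=1)[0]
    k = int(np.argmax(probs))
    return CLASS_NAMES[k], float(probs[k])


def predict_probs(model: TrainedModel, img, out_shape=None,
                  at_model_resolution=False):
    """Per-pixel class probabilities ``(C, H, W)``.

    The U-nets are fully convolutional, so by default inference runs at the
    image's own resolution even when it differs from the training patch
    size — boundary placement stays pixel-accurate. With
    ``at_model_resolution`` the image is first resampled to the model's
    training size (used where downstream processing happens at that working
    resolution). ``out_shape`` bilinearly resamples the probability maps.
    """
    img = np.asarray(img, dtype=np.float64)
    if at_model_resolution:
        img = resize_image(img, model.spec.input_size, order=1)
    x = img[None, None].astype(np.float32)
    logits = model.forward(x, train=False)[0].astype(np.float64)
    probs = nn.softmax(logits, axis=0)
    if out_shape is not None and probs.shape[1:] != tuple(out_shape):
        probs = np.stack([
            _sk_resize(p, out_shape, order=1, mode="edge",
                       anti_aliasing=False, preserve_range=True)
            for p in probs])
        probs /= probs.sum(axis=0, keepdims=True)
    return probs


def predict_mask(model: TrainedModel, img):
    """Per-pixel argmax label image at the input's own resolution."""
    img = np.asarray(img, dtype=np.float64)
    probs = predict_probs(model, img)
    return probs.argmax(axis=0).astype(np.uint8)


def binary_body_view(label_img, img):
    """Binary foreground view of a label image: the class whose pixels are
    brightest in ``img`` (for CT, the body/tissue class)."""
    label_img = np.asarray(label_img)
    img = np.asarray(img, dtype=np.float64)
    present = np.unique(label_img)
    if len(present) == 1:
        return np.zeros_like(label_img, dtype=np.uint8)
    means = [img[label_img == c].mean() for c in present]
    fg = present[int(np.argmax(means))]
    return (label_img == fg).astype(np.uint8)


def save_model(model: TrainedModel, path):
    """Checkpoint: npz of parameters + JSON sidecar with spec and log."""
    path = Path(path)
    arrays = {name: v for name, v, _ in model.net.params()}
    for i, layer in enumerate(model.net.layers):
        if isinstance(layer, nn.BatchNorm2D):
            arrays[f"{i}.run_mean"] = layer.run_mean
            arrays[f"{i}.run_var"] = layer.run_var
    np.savez(path.with_suffix(".npz"), **arrays)
    sidecar = {
        "kind": model.kind,
        "spec": asdict(model.spec),
        "log": {k: v for k, v in model.log.items() if k != "train_loss"},
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def load_model(path) -> TrainedModel:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    rng = np.random.default_rng(0)
    if sidecar["kind"] == "classifier":
        spec = ClassifierSpec(**{**sidecar["spec"],
                                 "filters": tuple(sidecar["spec"]["filters"])})
        model = build_classifier(spec, rng)
    else:
        spec = UnetSpec(**sidecar["spec"])
        model = build_unet(spec, rng)
    with np.load(path.with_suffix(".npz")) as data:
        for name, v, _ in model.net.params():
            v[...] = data[name]
        for i, layer in enumerate(model.net.layers):
            if isinstance(layer, nn.BatchNorm2D):
                layer.run_mean[...] = data[f"{i}.run_mean"]
                layer.run_var[...] = data[f"{i}.run_var"]
    model.log = sidecar.get("log", {})
    model.kind = sidecar["kind"]
    return model
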