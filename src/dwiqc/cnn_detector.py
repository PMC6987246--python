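"""The slice classifiers: independent axial and sagittal artifact detectors.

Each detector is a convolutional backbone feeding a 256-unit fully connected
head with a two-way softmax, trained with RMSprop (learning rate 2e-4) and
cross-entropy. Two backbones share the interface:

``compact_scratch``
    Three 3x3 conv blocks (8/16/32 channels, each followed by ReLU and 2x2
    max pooling) into the flattened 256-unit head — small enough to train
    fully on a CPU in minutes, so the entire pipeline is exercisable end to
    end.

``vgg16_imagenet``
    A frozen VGG16 feature stack whose ImageNet weights must be supplied as
    an ``.npz`` file; only the head is trained. Without a weights file,
    building the model raises an error that points to ``compact_scratch``.

Predicted probability >= 0.5 labels a slice artifactual — the tie goes to
flagging, since in quality control a false positive costs a second look
while a false negative lets a corrupted volume through.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from skimage.transform import resize

from . import nn
from .augmentation import AugmentConfig, augment_slice, build_augmented_set
from .io_slicing import SliceSample, LABEL_ARTIFACTUAL, normalize_slice
from .reporting import ConfusionCounts, Metrics, compute_metrics

__all__ = [
    "ModelSpec", "TrainConfig", "DetectorModel", "ModelWeightsError",
    "build_model", "head_parameter_count", "preprocess_for_model",
    "train_detector", "predict_slices", "extract_features", "cross_validate",
    "save_checkpoint", "load_checkpoint", "write_training_log",
]

#: VGG16 convolutional configuration ('M' = 2x2 max pool)
VGG16_LAYERS = [64, 64, "M", 128, 128, "M", 256, 256, 256, "M",
                512, 512, 512, "M", 512, 512, 512, "M"]

COMPACT_CHANNELS = (8, 16, 32)


class ModelWeightsError(FileNotFoundError):
    """Raised when a pretrained backbone's weights cannot be located."""


@dataclass(frozen=True)
class ModelSpec:
    """Architecture of one detector.

    ``input_size`` is the (H, W) the slice is padded/resized to; channels is
    1 for the compact backbone and 3 (replicated grayscale) for VGG16.
    """

    backbone: str = "compact_scratch"
    input_size: tuple[int, int] = (64, 64)
    channels: int = 1
    head_units: int = 256
    dropout: float = 0.5
    weights_path: str | None = None

    def __post_init__(self) -> None:
        if self.backbone not in ("compact_scratch", "vgg16_imagenet"):
            raise ValueError(f"unknown backbone {self.backbone!r}")

    @classmethod
    def vgg16(cls, weights_path: str | None = None) -> "ModelSpec":
        return cls(backbone="vgg16_imagenet", input_size=(224, 224), channels=3,
                   weights_path=weights_path)

    @property
    def feature_dim(self) -> int:
        return 512 if self.backbone == "vgg16_imagenet" else COMPACT_CHANNELS[-1]


@dataclass(frozen=True)
class TrainConfig:
    """Training recipe: RMSprop with a cross-entropy loss, 20 epochs,
    batch size 32.

    The default learning rate of 2e-4 is the transfer-learning rate (a
    frozen backbone with only the head retrained). Training the compact
    backbone from scratch moves far more parameters from random init and
    needs a larger step; :meth:`for_scratch` sets 1e-3.

    Class imbalance modes: ``inverse`` weights the loss by inverse class
    frequency; ``balanced`` oversamples the minority class with augmented
    copies up to parity instead; ``none`` disables both.
    """

    epochs: int = 20
    learning_rate: float = 2e-4
    batch_size: int = 32
    class_weighting: str = "inverse"   # "inverse" | "balanced" | "none"
    augment_multiplier: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be > 0")
        if self.class_weighting not in ("inverse", "balanced", "none"):
            raise ValueError("class_weighting must be 'inverse', 'balanced' or 'none'")

    @classmethod
    def for_scratch(cls, **overrides) -> "TrainConfig":
        """Defaults for full from-scratch training of the compact backbone."""
        kwargs = {"learning_rate": 1e-3, "class_weighting": "balanced"}
        kwargs.update(overrides)
        return cls(**kwargs)


@dataclass
class DetectorModel:
    """One trained (or untrained) view-specific detector."""

    view: str
    spec: ModelSpec
    net: nn.Sequential
    n_backbone_layers: int
    training_manifest: dict = field(default_factory=dict)

    @property
    def trainable_parameter_count(self) -> int:
        return self.net.parameter_count(trainable_only=True)

    @property
    def parameter_count(self) -> int:
        return self.net.parameter_count()


def head_parameter_count(feature_dim: int, head_units: int = 256,
                         n_classes: int = 2) -> int:
    """Parameters of the retrained head: dense(d->u) + dense(u->classes)."""
    return feature_dim * head_units + head_units + head_units * n_classes + n_classes


def _head_layers(spec: ModelSpec) -> list[nn.Layer]:
    """The retrained head. Over a frozen (VGG16) backbone the final conv
    activations are average-pooled to ``feature_dim``; the compact backbone
    keeps the spatial map (flattened), since localized artifact texture is
    exactly what it must learn from scratch."""
    if spec.backbone == "vgg16_imagenet":
        first: list[nn.Layer] = [nn.GlobalAvgPool()]
        in_dim = spec.feature_dim
    else:
        first = [nn.Flatten()]
        down = 2 ** len(COMPACT_CHANNELS)
        in_dim = (spec.input_size[0] // down) * (spec.input_size[1] // down) \
            * COMPACT_CHANNELS[-1]
    return first + [
        nn.Dense(in_dim, spec.head_units),
        nn.ReLU(),
        nn.Dropout(spec.dropout),
        nn.Dense(spec.head_units, 2),
    ]


def _compact_backbone(spec: ModelSpec) -> list[nn.Layer]:
    layers: list[nn.Layer] = []
    cin = spec.channels
    for cout in COMPACT_CHANNELS:
        layers += [nn.Conv2D(cin, cout), nn.ReLU(), nn.MaxPool2x2()]
        cin = cout
    return layers


def _vgg16_backbone(spec: ModelSpec) -> list[nn.Layer]:
    if spec.weights_path is None or not Path(spec.weights_path).exists():
        raise ModelWeightsError(
            "vgg16_imagenet requires a pretrained-weights .npz file "
            f"(weights_path={spec.weights_path!r} not found). Supply "
            "ModelSpec(weights_path=...) with arrays conv{i}_W of shape "
            "(out, in, 3, 3) and conv{i}_b, or use backbone='compact_scratch' "
            "which trains from scratch without downloads."
        )
    weights = np.load(spec.weights_path)
    layers: list[nn.Layer] = []
    cin, conv_i = spec.channels, 0
    for item in VGG16_LAYERS:
        if item == "M":
            layers.append(nn.MaxPool2x2())
            continue
        conv = nn.Conv2D(cin, int(item))
        conv.params["W"] = np.asarray(weights[f"conv{conv_i}_W"], dtype=np.float64)
        conv.params["b"] = np.asarray(weights[f"conv{conv_i}_b"], dtype=np.float64)
        conv.trainable = False
        layers += [conv, nn.ReLU()]
        cin, conv_i = int(item), conv_i + 1
    return layers


def build_model(spec: ModelSpec, seed: int = 0, view: str = "axial") -> DetectorModel:
    """Assemble an untrained detector; deterministic head init given ``seed``.

    For ``vgg16_imagenet`` every backbone parameter is frozen and only the
    256-unit head (131,842 parameters over 512 pooled features) is
    trainable; ``compact_scratch`` trains end to end.
    """
    if view not in ("axial", "sagittal"):
        raise ValueError("view must be axial|sagittal")
    if spec.backbone == "vgg16_imagenet":
        backbone = _vgg16_backbone(spec)
    else:
        backbone = _compact_backbone(spec)
    net = nn.Sequential(backbone + _head_layers(spec), seed=seed)
    return DetectorModel(view=view, spec=spec, net=net,
                         n_backbone_layers=len(backbone))


def preprocess_for_model(s: SliceSample, spec: ModelSpec) -> np.ndarray:
    """Pad the slice to a square (preserving aspect ratio), resize to the
    model input size, and replicate the single channel -> (C, H, W)."""
    img = s.image
    h, w = img.shape
    if h != w:
        side = max(h, w)
        pad_h, pad_w = side - h, side - w
        img = np.pad(img, ((pad_h // 2, pad_h - pad_h // 2),
                           (pad_w // 2, pad_w - pad_w // 2)))
    if img.shape != spec.input_size:
        img = resize(img, spec.input_size, order=1, preserve_range=True,
                     anti_aliasing=False)
    return np.repeat(img[np.newaxis], spec.channels, axis=0)


def _to_arrays(samples: list[SliceSample], spec: ModelSpec,
               require_labels: bool = True) -> tuple[np.ndarray, np.ndarray | None]:
    x = np.stack([preprocess_for_model(normalize_slice(s), spec) for s in samples])
    if not require_labels:
        return x, None
    if any(s.label is None for s in samples):
        raise ValueError("all training samples must carry a label")
    y = np.array([1 if s.label == LABEL_ARTIFACTUAL else 0 for s in samples])
    return x, y


def _class_weights(y: np.ndarray, mode: str) -> dict[int, float] | None:
    if mode != "inverse":
        return None
    counts = np.bincount(y, minlength=2)
    total = counts.sum()
    return {c: total / (2.0 * counts[c]) for c in (0, 1)}


def _oversample_minority(samples: list[SliceSample], augment: AugmentConfig,
                         seed: int) -> list[SliceSample]:
    """Top up the minority class with augmented copies until class parity."""
    pos = [s for s in samples if s.label == LABEL_ARTIFACTUAL]
    neg = [s for s in samples if s.label != LABEL_ARTIFACTUAL]
    if not pos or not neg:
        return list(samples)
    minority, majority = (pos, neg) if len(pos) < len(neg) else (neg, pos)
    out = list(samples)
    for k in range(len(majority) - len(minority)):
        src = minority[k % len(minority)]
        out.append(augment_slice(src, augment, draw_seed=seed + 7919 * (k + 1)))
    return out


def train_detector(
    model: DetectorModel,
    samples: list[SliceSample],
    cfg: TrainConfig = TrainConfig(),
    augment: AugmentConfig | None = None,
) -> DetectorModel:
    """Train the detector on labeled slices of its own view.

    Augmentation (if configured) multiplies the training set before
    preprocessing; class imbalance is countered with inverse-frequency
    weights in the loss. Deterministic given the seeds. With a frozen
    backbone only the head parameters move; the backbone features are
    precomputed once for speed.
    """
    views = {s.view for s in samples}
    if views != {model.view}:
        raise ValueError(f"detector view {model.view!r} but sample views {views}")
    if augment is not None and cfg.augment_multiplier > 1:
        samples = build_augmented_set(samples, augment, cfg.augment_multiplier,
                                      seed=cfg.seed)
    if cfg.class_weighting == "balanced":
        samples = _oversample_minority(samples, augment or AugmentConfig(),
                                       seed=cfg.seed)
    x, y = _to_arrays(samples, model.spec)
    if len(np.unique(y)) < 2:
        raise ValueError("training data must contain both classes")
    weights = _class_weights(y, cfg.class_weighting)
    opt = nn.RMSprop(lr=cfg.learning_rate)
    frozen = not all(l.trainable for l in model.net.layers[: model.n_backbone_layers])
    if frozen:
        feats = _batched_forward(model.net, x, model.n_backbone_layers)
        head = nn.Sequential(model.net.layers[model.n_backbone_layers:],
                             seed=cfg.seed, init_params=False)
        head.fit(feats, y, epochs=cfg.epochs, batch_size=cfg.batch_size,
                 optimizer=opt, class_weight=weights, shuffle_seed=cfg.seed)
        model.net.loss_history = head.loss_history
        model.net.accuracy_history = head.accuracy_history
    else:
        model.net.fit(x, y, epochs=cfg.epochs, batch_size=cfg.batch_size,
                      optimizer=opt, class_weight=weights, shuffle_seed=cfg.seed)
    model.training_manifest = {
        "n_samples": len(samples),
        "n_artifactual": int(y.sum()),
        "view": model.view,
        "config": asdict(cfg),
        "loss_trace": list(model.net.loss_history),
        "accuracy_trace": list(model.net.accuracy_history),
    }
    return model


def write_training_log(model: DetectorModel, path: str | Path) -> Path:
    """Write the per-epoch training trace as CSV (epoch, loss, accuracy)."""
    manifest = model.training_manifest
    if not manifest.get("loss_trace"):
        raise ValueError("model has no recorded training trace")
    df = pd.DataFrame(
        {
            "epoch": np.arange(1, len(manifest["loss_trace"]) + 1),
            "loss": manifest["loss_trace"],
            "accuracy": manifest.get("accuracy_trace",
                                     [np.nan] * len(manifest["loss_trace"])),
        }
    )
    path = Path(path)
    df.to_csv(path, index=False)
    return path


def _batched_forward(net: nn.Sequential, x: np.ndarray, n_layers: int,
                     batch_size: int = 64) -> np.ndarray:
    outs = [net.forward_until(x[i : i + batch_size], n_layers)
            for i in range(0, len(x), batch_size)]
    return np.concatenate(outs)


def predict_slices(model: DetectorModel, slices: list[SliceSample]) -> pd.DataFrame:
    """Per-slice artifact probability and binary label (p >= 0.5 flags).

    Returns one row per input slice, in input order, with the provenance
    keys needed by the reporting module.
    """
    if any(s.view != model.view for s in slices):
        raise ValueError(f"all slices must be {model.view} view")
    x, _ = _to_arrays(slices, model.spec, require_labels=False)
    proba = model.net.predict_proba(x)[:, 1]
    return pd.DataFrame(
        {
            "volume_id": [s.volume_id for s in slices],
            "view": [s.view for s in slices],
            "gradient_index": [s.gradient_index for s in slices],
            "slice_index": [s.slice_index for s in slices],
            "probability": proba,
            "predicted_label": (proba >= 0.5).astype(int),
        }
    )


def extract_features(model: DetectorModel, slices: list[SliceSample]) -> np.ndarray:
    """Final-convolutional-layer output, average-pooled to one fixed-length
    vector per slice (``spec.feature_dim`` values)."""
    x, _ = _to_arrays(slices, model.spec, require_labels=False)
    maps = _batched_forward(model.net, x, model.n_backbone_layers)
    return maps.mean(axis=(2, 3))


def cross_validate(
    samples: list[SliceSample],
    k: int = 5,
    spec: ModelSpec = ModelSpec(),
    cfg: TrainConfig = TrainConfig(),
    augment: AugmentConfig | None = None,
    seed: int = 0,
    subject_level: bool = False,
) -> dict:
    """k-fold cross-validation of one view's detector.

    Default protocol shuffles slices into folds (so slices of one source
    volume may appear in both train and test — flagged in the returned
    summary as permitting subject leakage); ``subject_level=True`` assigns
    whole volumes to folds instead. Augmentation is applied to training
    folds only. Returns per-fold confusion counts and pooled metrics.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if len(samples) < k:
        raise ValueError("fewer samples than folds")
    view = samples[0].view
    rng = np.random.default_rng(seed)
    if subject_level:
        vols = sorted({s.volume_id for s in samples})
        order = rng.permutation(len(vols))
        fold_of_vol = {vols[j]: i % k for i, j in enumerate(order)}
        folds = [[i for i, s in enumerate(samples) if fold_of_vol[s.volume_id] == f]
                 for f in range(k)]
    else:
        order = rng.permutation(len(samples))
        folds = [list(chunk) for chunk in np.array_split(order, k)]
    per_fold: list[ConfusionCounts] = []
    for f, test_idx in enumerate(folds):
        test_set = set(test_idx)
        train = [samples[i] for i in range(len(samples)) if i not in test_set]
        test = [samples[i] for i in test_idx]
        model = build_model(spec, seed=seed + f, view=view)
        train_detector(model, train, cfg=cfg, augment=augment)
        report = predict_slices(model, test)
        y_true = np.array([1 if s.label == LABEL_ARTIFACTUAL else 0 for s in test])
        per_fold.append(ConfusionCounts.from_predictions(
            y_true, report["predicted_label"].to_numpy()))
    pooled = ConfusionCounts(
        tp=sum(c.tp for c in per_fold), fp=sum(c.fp for c in per_fold),
        tn=sum(c.tn for c in per_fold), fn=sum(c.fn for c in per_fold),
    )
    return {
        "per_fold": per_fold,
        "pooled_confusion": pooled,
        "pooled_metrics": compute_metrics(pooled),
        "fold_sizes": [len(f) for f in folds],
        "protocol": "subject_level" if subject_level else
                    "slice_level (permits subject leakage across folds)",
    }


# -- checkpoints ------------------------------------------------------------

def save_checkpoint(model: DetectorModel, path: str | Path) -> Path:
    """Serialize a detector (spec + parameters + training manifest) to .npz."""
    path = Path(path)
    arrays: dict[str, np.ndarray] = {}
    for i, layer in enumerate(model.net.layers):
        for name, p in layer.params.items():
            arrays[f"layer{i}_{name}"] = p
    meta = {
        "format_version": 1,
        "view": model.view,
        "spec": asdict(model.spec),
        "n_backbone_layers": model.n_backbone_layers,
        "training_manifest": model.training_manifest,
        "seed": model.net.seed,
    }
    if path.suffix != ".npz":
        path = path.with_suffix(path.suffix + ".npz")
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
             **arrays)
    return path


def load_checkpoint(path: str | Path) -> DetectorModel:
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        spec = ModelSpec(**{**meta["spec"],
                            "input_size": tuple(meta["spec"]["input_size"])})
        model = build_model(spec, seed=meta["seed"], view=meta["view"])
        for i, layer in enumerate(model.net.layers):
            for name in list(layer.params):
                key = f"layer{i}_{name}"
                if key in data:
                    layer.params[name] = data[key].copy()
        model.training_manifest = meta["training_manifest"]
    return model
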