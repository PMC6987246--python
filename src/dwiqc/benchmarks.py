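"""Desk-scale evaluation benchmarks run entirely on synthetic data.

Two standing benchmarks exercise the whole pipeline:

* :func:`end_to_end_benchmark` — generate a labeled synthetic corpus, train
  the compact axial and sagittal detectors on a volume-level training split,
  and score held-out slices; also sweeps ghost severity to confirm the
  axial detector's predicted artifact probability rises with severity.
* :func:`baseline_ordering_benchmark` — train the Gabor/Zernike/LBP +
  random-forest baselines on a herringbone+ghosting fixture and report each
  scheme's recall; oriented band-pass (Gabor) features are expected to
  dominate purely local (LBP) or global-shape (Zernike) descriptors on
  stripe- and replica-type artifacts.

Sizes default to a single-CPU scale (tens of volumes, a few thousand
slices, 10 epochs): large enough for stable ordering and accuracies, small
enough to rerun routinely.
"""

from __future__ import annotations

import tempfile
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.stats import spearmanr

from . import classical_baselines as cb
from . import cnn_detector as cd
from . import io_slicing as ios
from .artifact_sim import (
    ARTIFACT_TYPES,
    PhantomSpec,
    inject_ghosting,
    inject_herringbone,
    generate_dataset,
    make_phantom_volume,
)
from .augmentation import AugmentConfig
from .io_slicing import LABEL_ARTIFACT_FREE, LABEL_ARTIFACTUAL
from .reporting import ConfusionCounts, Metrics, compute_metrics

__all__ = ["end_to_end_benchmark", "baseline_ordering_benchmark",
            "severity_response", "EndToEndResult"]

GHOST_SEVERITY_LEVELS = (0.1, 0.2, 0.3, 0.4, 0.5)


@dataclass
class EndToEndResult:
    per_view: dict[str, Metrics]
    per_view_confusion: dict[str, ConfusionCounts]
    severity_levels: tuple[float, ...]
    severity_probabilities: list[float]
    severity_spearman: float
    n_train: dict[str, int]
    n_test: dict[str, int]
    models: dict[str, cd.DetectorModel] = field(default_factory=dict)


def _load_view_slices(paths, manifest, view: str):
    out = []
    for p in paths:
        vol = ios.load_volume(p)
        extent = ios.compute_brain_extent(vol)
        if view == "axial":
            out.extend(ios.extract_axial_slices(vol, extent))
        else:
            out.extend(ios.extract_sagittal_slices(vol, extent))
    return ios.attach_labels(out, manifest)


def severity_response(
    model: cd.DetectorModel,
    levels=GHOST_SEVERITY_LEVELS,
    phantom_seed: int = 555,
    n_gradients: int = 4,
) -> list[float]:
    """Mean predicted artifact probability at each ghost severity level.

    The same mid-brain axial slices of one clean phantom are re-injected at
    each severity, so the only thing that varies across levels is the ghost
    intensity.
    """
    phantom = make_phantom_volume(PhantomSpec(seed=phantom_seed,
                                              n_gradients=n_gradients), "sev")
    extent = ios.compute_brain_extent(phantom)
    retained = ios.retained_axial_indices(extent)
    mids = retained[len(retained) // 4 : 3 * len(retained) // 4]
    means = []
    for alpha in levels:
        ghosted = inject_ghosting(phantom, alpha, affected_slices=mids,
                                  affected_gradients=list(range(n_gradients)))
        slices = [s for s in ios.extract_axial_slices(ghosted, extent)
                  if s.slice_index in mids]
        report = cd.predict_slices(model, slices)
        means.append(float(report["probability"].mean()))
    return means


def end_to_end_benchmark(
    seed: int = 0,
    out_dir: str | Path | None = None,
    n_volumes: int = 60,
    artifact_fraction: float = 0.5,
    train_fraction: float = 0.75,
    max_clean_train: int = 1200,
    epochs: int = 10,
) -> EndToEndResult:
    """Train both detectors on a synthetic corpus and score held-out volumes.

    Volumes are split at the volume level (no slice of a test volume is seen
    in training). Training sets are capped at ``max_clean_train``
    artifact-free slices per view and balanced by augmented oversampling of
    the artifactual class. All randomness derives from ``seed``.
    """
    tmp = None
    if out_dir is None:
        tmp = tempfile.TemporaryDirectory(prefix="dwiqc_bench_")
        out_dir = tmp.name
    try:
        ds = generate_dataset(PhantomSpec(), list(ARTIFACT_TYPES), n_volumes,
                              artifact_fraction, seed, out_dir)
        rng = np.random.default_rng(seed + 1)
        perm = rng.permutation(len(ds.paths))
        n_train = int(round(train_fraction * len(ds.paths)))
        train_paths = [ds.paths[i] for i in perm[:n_train]]
        test_paths = [ds.paths[i] for i in perm[n_train:]]

        per_view: dict[str, Metrics] = {}
        per_conf: dict[str, ConfusionCounts] = {}
        n_tr: dict[str, int] = {}
        n_te: dict[str, int] = {}
        models: dict[str, cd.DetectorModel] = {}
        for view in ("axial", "sagittal"):
            train = _load_view_slices(train_paths, ds.manifest, view)
            test = _load_view_slices(test_paths, ds.manifest, view)
            art = [s for s in train if s.label == LABEL_ARTIFACTUAL]
            clean = [s for s in train if s.label == LABEL_ARTIFACT_FREE]
            keep = rng.permutation(len(clean))[:max_clean_train]
            train_set = art + [clean[i] for i in keep]
            model = cd.build_model(cd.ModelSpec(), seed=seed + 11, view=view)
            cfg = cd.TrainConfig.for_scratch(epochs=epochs, seed=seed + 13)
            cd.train_detector(model, train_set, cfg=cfg,
                              augment=AugmentConfig(seed=seed + 17))
            report = cd.predict_slices(model, test)
            y_true = np.array([1 if s.label == LABEL_ARTIFACTUAL else 0 for s in test])
            conf = ConfusionCounts.from_predictions(
                y_true, report["predicted_label"].to_numpy())
            per_view[view] = compute_metrics(conf)
            per_conf[view] = conf
            n_tr[view], n_te[view] = len(train_set), len(test)
            models[view] = model

        sev = severity_response(models["axial"], phantom_seed=seed + 555)
        rho = float(spearmanr(GHOST_SEVERITY_LEVELS, sev).statistic)
        return EndToEndResult(
            per_view=per_view, per_view_confusion=per_conf,
            severity_levels=GHOST_SEVERITY_LEVELS, severity_probabilities=sev,
            severity_spearman=rho, n_train=n_tr, n_test=n_te, models=models,
        )
    finally:
        if tmp is not None:
            tmp.cleanup()


# ---------------------------------------------------------------------------
# texture-baseline ordering
# ---------------------------------------------------------------------------

def _fixture_slices(seed: int, n_per_class: int):
    """Equal numbers of clean and artifactual (herringbone or ghosting)
    axial slices, artifact parameters randomized within the documented
    severity ranges, one independent injection per slice."""
    rng = np.random.default_rng(seed)
    clean, artifact = [], []
    phantom_i = 0
    while len(clean) < n_per_class or len(artifact) < n_per_class:
        spec = PhantomSpec(seed=seed + 1000 + phantom_i, n_gradients=2)
        vol = make_phantom_volume(spec, f"fix_{phantom_i}")
        extent = ios.compute_brain_extent(vol)
        retained = ios.retained_axial_indices(extent)
        for g in range(vol.n_gradients):
            for z in retained:
                target = clean if (len(clean) <= len(artifact)) else artifact
                if target is clean:
                    if len(clean) < n_per_class:
                        s = ios.SliceSample(vol.data[:, :, z, g], "axial",
                                            vol.volume_id, g, z,
                                            label=LABEL_ARTIFACT_FREE)
                        clean.append(s)
                    continue
                if len(artifact) >= n_per_class:
                    continue
                if rng.random() < 0.5:
                    alpha = rng.uniform(0.1, 0.5)
                    bad = inject_ghosting(vol, alpha, [z], [g])
                else:
                    plane_k = np.abs(np.fft.fft2(vol.data[:, :, z, g]))
                    amp = rng.uniform(2.0, 10.0) * float(np.percentile(plane_k, 95))
                    radius = rng.uniform(0.08, 0.30)
                    theta = rng.uniform(0, np.pi)
                    k_loc = (int(round(radius * np.cos(theta) * 64)) % 64,
                             int(round(radius * np.sin(theta) * 64)) % 64)
                    if k_loc == (0, 0):
                        k_loc = (0, 8)
                    bad = inject_herringbone(vol, amp, k_loc, [z], [g])
                s = ios.SliceSample(bad.data[:, :, z, g], "axial",
                                    vol.volume_id, g, z, label=LABEL_ARTIFACTUAL)
                artifact.append(s)
        phantom_i += 1
    return clean[:n_per_class], artifact[:n_per_class]


def baseline_ordering_benchmark(seed: int = 0, n_per_class: int = 400) -> dict:
    """Recall of Gabor(32)/Zernike/LBP features + random forest on a
    herringbone-and-ghosting fixture (half the slices for training, half
    held out)."""
    clean, artifact = _fixture_slices(seed, n_per_class)
    samples = clean + artifact
    y = np.array([0] * len(clean) + [1] * len(artifact))
    images = [ios.normalize_slice(s).image for s in samples]
    rng = np.random.default_rng(seed + 2)
    order = rng.permutation(len(samples))
    half = len(samples) // 2
    tr, te = order[:half], order[half:]
    recalls: dict[str, float] = {}
    extractors = {
        "gabor": lambda im: cb.gabor_features(im),
        "zernike": lambda im: cb.zernike_features(im),
        "lbp": lambda im: cb.lbp_features(im),
    }
    for name, fn in extractors.items():
        feats = np.stack([fn(im) for im in images])
        det = cb.train_feature_detector(feats[tr], y[tr],
                                        classifier="random_forest", seed=seed)
        pred = det.predict(feats[te])
        conf = ConfusionCounts.from_predictions(y[te], pred)
        m = compute_metrics(conf)
        recalls[name] = float(m.recall) if m.recall is not None else 0.0
    return recalls
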