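"""Detector construction, training mechanics and cross-validation."""

import numpy as np
import pytest

from dwiqc import cnn_detector as cd
from dwiqc import nn
from dwiqc.artifact_sim import PhantomSpec, inject_ghosting, make_phantom_volume
from dwiqc.augmentation import AugmentConfig
from dwiqc.io_slicing import (
    SliceSample,
    compute_brain_extent,
    extract_axial_slices,
    retained_axial_indices,
)


def labeled_ghost_slices(n_per_class=40, alpha=0.5, seed=0, view="axial",
                         per_volume_cap=16):
    """Clean vs heavily ghosted axial slices, spread over several phantom
    volumes (at most ``per_volume_cap`` slices drawn per volume so
    subject-level splits have multiple subjects to work with)."""
    clean, bad = [], []
    pi = 0
    while len(clean) < n_per_class or len(bad) < n_per_class:
        vol = make_phantom_volume(PhantomSpec(seed=seed + 100 * pi, n_gradients=2),
                                  f"p{pi}")
        extent = compute_brain_extent(vol)
        retained = retained_axial_indices(extent)
        ghosted = inject_ghosting(vol, alpha, retained, [0, 1])
        taken = 0
        for g in range(2):
            for z in retained:
                if taken >= per_volume_cap:
                    break
                if len(clean) <= len(bad) and len(clean) < n_per_class:
                    clean.append(SliceSample(vol.data[:, :, z, g], view,
                                             f"p{pi}", g, z, "artifact_free"))
                    taken += 1
                elif len(bad) < n_per_class:
                    bad.append(SliceSample(ghosted.data[:, :, z, g], view,
                                           f"p{pi}", g, z, "artifactual"))
                    taken += 1
        pi += 1
    return clean + bad


# -- construction --------------------------------------------------------------

def test_head_parameter_count_matches_declared_shape():
    """512-dim pooled features -> 256-unit head -> 2 classes."""
    assert cd.head_parameter_count(512) == 131_842


def test_vgg16_missing_weights_raises_actionable_error():
    spec = cd.ModelSpec.vgg16(weights_path=None)
    with pytest.raises(cd.ModelWeightsError, match="compact_scratch"):
        cd.build_model(spec, seed=0)


def test_vgg16_with_weights_builds_frozen_backbone(tmp_path):
    """A (tiny, randomly filled) weights file in the documented layout loads,
    freezes the backbone, and leaves exactly the head trainable."""
    rng = np.random.default_rng(0)
    arrays = {}
    cin = 3
    i = 0
    for item in cd.VGG16_LAYERS:
        if item == "M":
            continue
        arrays[f"conv{i}_W"] = rng.normal(0, 0.01, (int(item), cin, 3, 3))
        arrays[f"conv{i}_b"] = np.zeros(int(item))
        cin = int(item)
        i += 1
    wpath = tmp_path / "synthetic_vgg16_weights.npz"  # random stand-in weights
    np.savez(wpath, **arrays)
    model = cd.build_model(cd.ModelSpec.vgg16(str(wpath)), seed=1)
    assert model.trainable_parameter_count == 131_842
    frozen = [l for l in model.net.layers[: model.n_backbone_layers]
              if isinstance(l, nn.Conv2D)]
    assert frozen and all(not l.trainable for l in frozen)
    np.testing.assert_array_equal(frozen[0].params["W"], arrays["conv0_W"])


def test_untrained_probabilities_normalized():
    model = cd.build_model(cd.ModelSpec(), seed=0)
    s = SliceSample(np.random.default_rng(0).random((64, 64)), "axial", "v", 0, 0)
    report = cd.predict_slices(model, [s, s])
    p = report["probability"].to_numpy()
    assert np.all((0 <= p) & (p <= 1))
    assert p[0] == p[1]  # duplicated input -> identical probability


def test_same_seed_identical_initial_parameters():
    a = cd.build_model(cd.ModelSpec(), seed=9)
    b = cd.build_model(cd.ModelSpec(), seed=9)
    for la, lb in zip(a.net.layers, b.net.layers):
        for k in la.params:
            np.testing.assert_array_equal(la.params[k], lb.params[k])


# -- preprocessing --------------------------------------------------------------

def test_preprocess_pads_to_square_then_resizes():
    spec = cd.ModelSpec(input_size=(32, 32))
    s = SliceSample(np.random.default_rng(0).random((64, 80)), "axial", "v", 0, 0)
    out = cd.preprocess_for_model(s, spec)
    assert out.shape == (1, 32, 32)


def test_preprocess_constant_stays_constant_and_channels_replicate():
    spec = cd.ModelSpec(input_size=(32, 32), channels=3)
    s = SliceSample(np.full((48, 48), 2.5), "axial", "v", 0, 0)
    out = cd.preprocess_for_model(s, spec)
    assert out.shape == (3, 32, 32)
    np.testing.assert_allclose(out, 2.5)
    np.testing.assert_array_equal(out[0], out[1])
    np.testing.assert_array_equal(out[0], out[2])


# -- training -------------------------------------------------------------------

def test_train_loss_decreases_and_is_deterministic():
    samples = labeled_ghost_slices(n_per_class=24)
    cfg = cd.TrainConfig.for_scratch(epochs=3, seed=3)
    runs = []
    for _ in range(2):
        model = cd.build_model(cd.ModelSpec(), seed=3)
        cd.train_detector(model, samples, cfg=cfg)
        runs.append(model)
    trace = runs[0].net.loss_history
    assert trace[-1] < trace[0]
    for la, lb in zip(runs[0].net.layers, runs[1].net.layers):
        for k in la.params:
            np.testing.assert_array_equal(la.params[k], lb.params[k])


def test_train_rejects_bad_inputs():
    samples = labeled_ghost_slices(n_per_class=6)
    model = cd.build_model(cd.ModelSpec(), seed=0)
    with pytest.raises(ValueError):
        cd.TrainConfig(epochs=0)
    mixed = samples[:6] + [SliceSample(np.zeros((10, 12)), "sagittal", "v", 0, 0,
                                       "artifact_free")]
    with pytest.raises(ValueError, match="view"):
        cd.train_detector(model, mixed)
    single = [s for s in samples if s.label == "artifact_free"]
    with pytest.raises(ValueError, match="both classes"):
        cd.train_detector(model, single, cfg=cd.TrainConfig(epochs=1,
                                                            class_weighting="none"))


def test_predict_tie_flags_artifactual():
    """p = 0.5 exactly labels the slice artifactual (favor false positives)."""
    import pandas as pd

    proba = np.array([0.5, 0.49999, 0.50001])
    labels = (proba >= 0.5).astype(int)
    assert labels.tolist() == [1, 0, 1]


def test_predict_view_mismatch_errors():
    model = cd.build_model(cd.ModelSpec(), seed=0, view="axial")
    s = SliceSample(np.zeros((64, 64)), "sagittal", "v", 0, 0)
    with pytest.raises(ValueError, match="axial"):
        cd.predict_slices(model, [s])


def test_trained_detector_separates_heavy_ghosting():
    """End-to-end on clearly separable data: held-out accuracy >= 0.9."""
    samples = labeled_ghost_slices(n_per_class=60, alpha=0.6)
    rng = np.random.default_rng(0)
    idx = rng.permutation(len(samples))
    train = [samples[i] for i in idx[:80]]
    test = [samples[i] for i in idx[80:]]
    model = cd.build_model(cd.ModelSpec(), seed=1)
    cd.train_detector(model, train,
                      cfg=cd.TrainConfig.for_scratch(epochs=8, seed=1))
    report = cd.predict_slices(model, test)
    y = np.array([1 if s.label == "artifactual" else 0 for s in test])
    acc = (report["predicted_label"].to_numpy() == y).mean()
    assert acc >= 0.9


def test_extract_features_pooled_dim_and_linear_probe():
    """Backbone features are fixed-length, deterministic, and (after
    per-channel standardization) linearly separate clean from severe-ghost
    slices."""
    from sklearn.linear_model import LogisticRegression
    from sklearn.preprocessing import StandardScaler

    samples = labeled_ghost_slices(n_per_class=40, alpha=0.6)
    model = cd.build_model(cd.ModelSpec(), seed=2)
    cd.train_detector(model, samples,
                      cfg=cd.TrainConfig.for_scratch(epochs=4, seed=2))
    feats = cd.extract_features(model, samples)
    assert feats.shape == (len(samples), model.spec.feature_dim)
    np.testing.assert_array_equal(feats[:5],
                                  cd.extract_features(model, samples[:5]))
    y = np.array([1 if s.label == "artifactual" else 0 for s in samples])
    z = StandardScaler().fit_transform(feats)
    probe = LogisticRegression(max_iter=5000).fit(z, y)
    assert probe.score(z, y) >= 0.95


# -- cross-validation ------------------------------------------------------------

def test_cv_fold_sizes_partition_arithmetic():
    samples = labeled_ghost_slices(n_per_class=52)[:103]
    rng = np.random.default_rng(0)
    folds = [list(c) for c in np.array_split(rng.permutation(103), 5)]
    assert sorted(len(f) for f in folds) == [20, 20, 21, 21, 21]


def test_cross_validate_folds_disjoint_and_pooled_counts():
    samples = labeled_ghost_slices(n_per_class=25)
    result = cd.cross_validate(
        samples, k=5, spec=cd.ModelSpec(),
        cfg=cd.TrainConfig.for_scratch(epochs=1, seed=0), seed=0,
    )
    assert sorted(result["fold_sizes"]) == [10, 10, 10, 10, 10]
    pooled = result["pooled_confusion"]
    assert pooled.total == len(samples)
    per_fold_total = sum(c.total for c in result["per_fold"])
    assert per_fold_total == pooled.total
    assert pooled.tp == sum(c.tp for c in result["per_fold"])


def test_cross_validate_subject_level_keeps_volumes_together():
    samples = labeled_ghost_slices(n_per_class=25)
    result = cd.cross_validate(
        samples, k=2, spec=cd.ModelSpec(),
        cfg=cd.TrainConfig.for_scratch(epochs=1, seed=0), seed=0,
        subject_level=True,
    )
    assert "subject_level" in result["protocol"]


def test_cross_validate_validates_inputs():
    samples = labeled_ghost_slices(n_per_class=2)
    with pytest.raises(ValueError):
        cd.cross_validate(samples[:3], k=5)


# -- checkpoints -----------------------------------------------------------------

def test_training_log_csv(tmp_path):
    import pandas as pd

    samples = labeled_ghost_slices(n_per_class=10)
    model = cd.build_model(cd.ModelSpec(), seed=4)
    cd.train_detector(model, samples,
                      cfg=cd.TrainConfig.for_scratch(epochs=2, seed=4))
    path = cd.write_training_log(model, tmp_path / "log.csv")
    log = pd.read_csv(path)
    assert list(log.columns) == ["epoch", "loss", "accuracy"]
    assert len(log) == 2
    assert log["accuracy"].between(0, 1).all()


def test_checkpoint_roundtrip(tmp_path):
    samples = labeled_ghost_slices(n_per_class=10)
    model = cd.build_model(cd.ModelSpec(), seed=4)
    cd.train_detector(model, samples,
                      cfg=cd.TrainConfig.for_scratch(epochs=1, seed=4))
    path = cd.save_checkpoint(model, tmp_path / "det.npz")
    loaded = cd.load_checkpoint(path)
    assert loaded.view == model.view
    s = samples[:3]
    np.testing.assert_allclose(
        cd.predict_slices(loaded, s)["probability"],
        cd.predict_slices(model, s)["probability"],
    )
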