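"""Train a small axial detector on synthetic data and build QC reports.

Generates a 16-volume corpus, trains the compact detector for a few epochs,
predicts on two held-out volumes, and prints the slice-wise report plus
volume flags at a slice-count threshold.
"""

import tempfile

import numpy as np

from dwiqc import cnn_detector as cd
from dwiqc import io_slicing as ios
from dwiqc import reporting as rp
from dwiqc.artifact_sim import ARTIFACT_TYPES, PhantomSpec, generate_dataset
from dwiqc.augmentation import AugmentConfig

with tempfile.TemporaryDirectory() as out_dir:
    ds = generate_dataset(PhantomSpec(), list(ARTIFACT_TYPES), n_volumes=16,
                          artifact_fraction=0.5, seed=11, out_dir=out_dir)
    # hold out one axially-artifactual and one clean volume, train on the rest
    art_idx = next(i for i, s in enumerate(ds.artifact_specs)
                   if s is not None and s.view == "axial")
    clean_idx = next(i for i, s in enumerate(ds.artifact_specs) if s is None)
    test_paths = [ds.paths[art_idx], ds.paths[clean_idx]]
    train_paths = [p for i, p in enumerate(ds.paths) if i not in (art_idx,
                                                                  clean_idx)]

    def axial_slices(paths):
        out = []
        for p in paths:
            vol = ios.load_volume(p)
            extent = ios.compute_brain_extent(vol)
            out.extend(ios.extract_axial_slices(vol, extent))
        return ios.attach_labels(out, ds.manifest)

    train = axial_slices(train_paths)
    model = cd.build_model(cd.ModelSpec(), seed=0, view="axial")
    cd.train_detector(model, train,
                      cfg=cd.TrainConfig.for_scratch(epochs=5, seed=0),
                      augment=AugmentConfig(seed=0))
    print(f"trained on {len(train)} slices; "
          f"loss {model.net.loss_history[0]:.3f} -> {model.net.loss_history[-1]:.3f}")

    test = axial_slices(test_paths)
    predictions = cd.predict_slices(model, test)
    report = rp.slice_report(predictions, ds.manifest)
    n_flagged = int(report["predicted_label"].sum())
    print(f"slice report: {len(report)} slices, {n_flagged} flagged artifactual")

    for t in (1, 3):
        volume_report = rp.volume_flags(report, threshold=t, view="axial")
        print(f"\nvolume flags at T={t} (>= {t} artifactual slices flag the volume):")
        print(volume_report.table[["volume_id", "gradient_index",
                                   "artifactual_slices",
                                   "flagged"]].to_string(index=False))

# Ground truth: the first held-out volume carries an axial artifact on a
# subset of gradients; the second is clean. Detected slices concentrate on
# the affected gradient; a low threshold flags that gradient volume for
# inspection, a higher threshold trades recall for precision. Flagged
# volumes are the only ones the analyst opens — that is the time saving.
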