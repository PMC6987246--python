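# dwiqc — slice-wise artifact detection for diffusion MRI

Quality control of diffusion MRI (dMRI) is usually done by eye: an analyst
opens every gradient volume and scans its slices for ghosting, spikes,
chemical shift, susceptibility distortion, motion dropout and interleave
banding. On consortium-scale datasets that is days of work and the judgment
drifts with fatigue. `dwiqc` automates the screening step for researchers and
imaging cores running dMRI studies: it classifies every 2D slice as
*artifactual* or *artifact-free*, aggregates slice decisions into volume
flags, and quantifies how much manual inspection the flags save — the analyst
then opens only the flagged volumes.

## What's inside

* **Dual slice detectors.** Artifacts are screened in the view where they
  show: an *axial* detector (ghosting, herringbone, chemical shift,
  susceptibility) and a *sagittal* detector (motion dropout, multiband
  interleave). Each is a CNN emitting P(artifactual) per slice, trained with
  RMSprop (lr 2×10⁻⁴ for transfer learning, cross-entropy loss). Two
  backbones share one interface: a frozen VGG16 feature stack with a
  retrained 256-unit head (131,842 trainable parameters; requires an
  ImageNet weights file), and a compact 3-block CNN that trains from scratch
  on a CPU in minutes.
* **A physics-based artifact simulator.** Labeled dMRI QC corpora are not
  public, so the package generates its own: ellipsoid head phantoms with
  tissue contrast, a fat rim, per-gradient attenuation and Rician noise, plus
  six artifact injectors built on the acquisition mechanism of each artifact
  (e.g. a Nyquist ghost is even/odd phase-encode-line modulation in k-space;
  herringbone is a conjugate spike pair). Every generated slice carries a
  ground-truth label derived from the injection.
* **Classical baselines.** Gabor bank (32), Zernike moments (9) and uniform
  LBP (10) features with random forests, a Gabor→FC-network detector, and a
  CNN-features→PCA(98%)→SVM pipeline.
* **Reporting.** Slice-wise CSV reports, volume flags at a slice-count
  threshold T (flag ⇔ #artifactual slices ≥ T), threshold sweeps
  (precision/recall/accuracy per T), and the inspection-workload estimator.

The volume-flagging and workload arithmetic in standard notation: with
precision p = TP/(TP+FP) and recall r = TP/(TP+FN) at a chosen T, a corpus of
N volumes with N_a artifactual ones yields an expected flagged list of
r·N_a/p volumes, so the analyst inspects 100·(1 − r·N_a/(p·N))% fewer
volumes.

## Worked example

Inject artifacts into a phantom and check them against analytic oracles
(`python examples/02_inject_artifacts.py`):

```
zero-severity ghost identical: True
ghost vs image-domain oracle, max |error| = 8.88e-16
spike coefficient magnitude = 80.0 (injected 80.0)
dropout slice mean ratio = 0.30 (expect ~0.30 of the z=18 mean)
multiband touched 9 of 36 slices (every 4th)
```

The ghost built in k-space equals the analytic superposition
I(x) + α·I(x − FOV/2) to machine precision; the spike-pair injection shows up
in the difference-image spectrum at exactly the injected amplitude; a 0.7
dropout leaves 30% of the slice mean; period-4 banding touches ⌈36/4⌉ = 9
slices.

Estimate the inspection saving at the detectors' operating points
(`python examples/05_workload_reduction.py`):

```
axial, T=3: expected flagged 580.7 of 4163 volumes -> 86.05% fewer to inspect
sagittal, T=10: expected flagged 135.2 of 4163 volumes -> 96.75% fewer to inspect
```

Reading the first line: at the axial detector's threshold-3 operating point
(precision 0.94, recall 0.98) on a corpus of 4163 gradient volumes of which
557 have axial artifacts, the flagged list is expected to hold ~581 volumes —
the analyst skips 86.05% of the corpus.

The other examples generate a labeled dataset (`01`), train a detector and
produce slice/volume reports (`03`), and race the texture baselines (`04`).

## Command line

```bash
dwiqc simulate --out data/ --n-volumes 20 --artifact-fraction 0.5
dwiqc train --view axial --data data/manifest.csv --backbone compact --out axial.npz
dwiqc run --model axial.npz --input data/vol_000.nii.gz --report report.csv --volume-threshold 3
dwiqc evaluate --pred report.csv --truth data/manifest.csv --sweep
```

Every command writes a `*_replay.json` with the resolved configuration and
seed.

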