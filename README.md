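# pals — photoacoustic lesion segmentation

`pals` segments high-intensity focused ultrasound (HIFU) thermal lesions in
multi-wavelength photoacoustic (MWPA) image cubes. It implements the full
study pipeline end to end:

* **Physics-based preprocessing** — per-channel division by the laser
  pulse-energy spectrum, then per-pixel max normalization, turning each
  pixel into a normalized optical-absorption spectrum that is invariant to
  system sensitivity, Grüneisen coefficient and global fluence scale.
* **A six-layer fully-convolutional segmenter** (three 3×3 conv + ReLU +
  2×2 max-pool blocks with 53 hidden channels, two 1×1 conv layers, and a
  bilinear upsampling head back to the input size) trained with
  class-imbalance-weighted cross-entropy (Adam). The network and its
  backward pass are implemented in NumPy — no deep-learning framework is
  required.
* **Per-pixel classical baselines** — QDA, a one-hidden-layer neural
  network (53 nodes), an RBF SVM (C = 16) and a random forest (50 trees,
  `min_samples_leaf=1000`) via scikit-learn, with per-frame class
  balancing and block-wise train/test splits.
* **×24 data augmentation** — {original, 2 Gaussian-noise draws, 3 box
  blurs} × {identity, vertical flip, horizontal flip, 180° rotation}.
* **Greedy sequential forward wavelength selection** with a quadratic
  classifier, mean-spectrum/ratio diagnostics, and cube subsetting to
  reduced wavelength sets.
* **A synthetic phantom study generator** emulating the acquisition
  schedule (19 tissue blocks × 4 frames containing 0–3 lesions, 53
  wavelengths 690–950 nm) with distinct ablated/non-ablated absorption
  spectra, depth-dependent fluence decay, sensitivity fields, noise, an
  unlabeled boundary band, and optional side-lobe artifacts.

## Test

```bash
python -m pytest tests/
```

The suite includes an acceptance module (`tests/test_acceptance.py`) whose
phantom-study criterion trains all five model families at five wavelength
counts over three seeds; expect ~15 minutes on one CPU. Everything else
finishes in under a minute.

## CLI

The `pals` command exposes each stage:

```bash
pals simulate --out raw/ --blocks 19 --frames 4 --seed 0     # phantom study
pals preprocess --in raw/ --fluence raw/fluence.csv --out prep/
pals augment --in prep/ --out aug/ --sigma 0.05 --seed 0
pals make-dataset --in prep/ --split 15:4 --seed 0 --out dataset.h5
pals train-classic --family qda --dataset dataset.h5 --out qda.joblib
pals train-cnn --data prep/ --split 15:4 --epochs 200 --out cnn.npz
pals segment --model cnn.npz --in prep/frame0003_cube.tiff --out pred.png
pals select-wavelengths --dataset dataset.h5 --out trace.csv
pals subset --in prep/ --wavelengths 720,775,780,785,790 --out prep5/
pals evaluate --pred preds/ --truth prep/ --out metrics.csv
pals run --out results/ --seed 0 --seed 1 --seed 2 --epochs 30   # full grid
```

`pals run` writes the model × wavelength-count mean-F1 grid
(`grid_mean.csv`), the consecutive decrease table, per-seed selection
traces and a machine-readable run log; re-runs with an unchanged
configuration reuse cached results.

Phantom configurations are YAML files; `preset: full` selects the
full-scale 339 × 512-pixel geometry at 73.92 µm pitch, `preset: reduced`
(default) a desk-scale 96 × 128 geometry covering the same physical view.
Any `PhantomConfig` field can be overridden, e.g.:

```yaml
preset: reduced
grid: {start_nm: 690, stop_nm: 950, step_nm: 5}
noise_sigma: 0.25
side_lobes: true
```

## Package layout

```
src/pals/
  core_io.py         domain types; TIFF/HDF5 cube, PNG mask, CSV spectrum I/O
  phantom.py         forward model and synthetic study generator
  preprocess.py      fluence + per-pixel max normalization
  augment.py         ×24 photometric/geometric augmentation
  sampling.py        pixel datasets, balancing, block splits, class weights
  classic_models.py  QDA / NN / SVM / RF baselines and tuning curves
  cnn_model.py       NumPy fully-convolutional segmenter (+ Adam, backprop)
  wavesel.py         sequential forward selection, mean spectra, subsetting
  evaluation.py      confusion counts, recall/precision/F1, result grids
  orchestration.py   end-to-end experiment runner
  cli.py             click-based command line
```
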