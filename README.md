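# xfct

End-to-end toolkit for benchtop X-ray fluorescence computed tomography
(XFCT) of gold-nanoparticle (GNP) distributions:

- **Spectral simulation & augmentation** (`xfct.spectra`) — synthetic
  XRF/scatter spectra (800 channels, 0.16 keV bins) with a known noise-free
  gold Kα doublet area, plus the five augmentation operators (baseline
  shift, slope shift, multiplicative scaling, ±1-channel peak shift,
  Gaussian noise).
- **Conventional extraction** (`xfct.extraction`) — Compton-background fit,
  Kα net-count summation, 1.96σ significance filter, and the
  net-signal-to-background ratio (netSToBg) used as the learning target.
- **1D CNN extractor** (`xfct.cnn`) — 500-channel window → netSToBg
  regression (Conv 75×39 → Conv 14×13 → Dense 260 → 1, ELU, dropout 0.22,
  Huber loss, Adam 5.4e-5), with z-score scaling, 70/30 and 80/20 splits,
  early stopping and checkpointing.
- **Tomographic data** (`xfct.tomo`) — 3-hole and multi-region phantoms,
  Radon projection (30 angles / 12° steps / 360°), sinogram assembly from
  330 per-position values (30×11), projection reduction 30→5, paired
  sinogram/image augmentation, 70/20/10 splits, min–max scaling, resize to
  the network input.
- **Constant-width U-Net** (`xfct.unet`) — sinogram → image network with a
  constant 64-feature-map width; the default 256×256 configuration has
  exactly **1,616,289** trainable parameters. MAE loss, Adam 1e-4.
- **Classical reconstruction & quantification** (`xfct.recon`) — FBP and
  OSEM baselines, linear-through-origin calibration curves, ROI
  quantification (mean ± sd wt%), and scan-time/imaging-dose arithmetic at
  21.3 cGy/min.
- **Metrics** (`xfct.metrics`) — MAE, RMSE, R², Huber, SSIM, PSNR,
  Bland–Altman.
- **Pipeline & CLI** (`xfct.pipeline`, `xfct.cli`) — end-to-end runs with
  JSON manifests (seeds, data hashes, per-stage timings).

The neural networks run on a small built-in NumPy engine (`xfct.nn`) with
hand-written, gradient-checked backward passes — no deep-learning framework
is required.

## Tests

```sh
python -m pytest tests/
```

`tests/test_acceptance.py` holds one test per acceptance criterion,
including two scaled-down training runs (the 1D CNN recovery and the
sparse-view U-Net vs. FBP comparison); the full suite takes roughly 15–20
minutes on one CPU.

## CLI

```sh
xfct --help
xfct simulate-spectra --n 100 --seed 1 --out spectra.csv
xfct augment-spectra --reps 200 --seed 2 --in spectra.csv --out aug.csv
xfct extract-conventional --in aug.csv --out pairs.csv
xfct train-cnn --pairs pairs.csv --epochs 20 --seed 3 --out model/
xfct predict-cnn --model model/ --spectra pairs.csv --out pred.csv
xfct dose --projections 30 --seconds 10
xfct reconstruct-fbp --sino sino.npy --out rec.npy
xfct reconstruct-osem --sino sino.npy --subsets 5 --iters 10 --out rec.npy
xfct run --seed 0 --out runs/smoke     # scaled-down end-to-end smoke run
```

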