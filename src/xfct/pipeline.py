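"""End-to-end orchestration with run manifests.

A run executes the stages in dependency order — simulate spectra, extract
targets, train the spectral CNN, build phantom/sinogram pairs, train the
U-Net, reconstruct and quantify — and records seeds, data hashes, metrics
and wall-clock per stage in a JSON manifest.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import __version__
from .cnn import CNNHyperparams, predict_net_signal, train_cnn
from .extraction import ANALYSIS_WINDOW
from .metrics import image_metrics, regression_metrics
from .recon import fbp_reconstruct, scan_dose
from .spectra import AugmentationConfig, augment_dataset, simulate_dataset
from .tomo import (assemble_sinogram, augment_pairs, build_base_pairs,
                   make_3h_phantom, random_organ_phantom, resize_to_input,
                   split_pairs)
from .unet import UNetConfig, reconstruct, train_unet

__all__ = ["RunConfig", "run_end_to_end", "timing_report", "array_hash"]


@dataclass
class RunConfig:
    """Scaled-down end-to-end configuration (smoke-run sizes by default)."""

    seed: int = 0
    out_dir: str = "runs/smoke"
    # spectral side
    n_base_spectra: int = 20
    n_augment_reps: int = 10
    cnn_epochs: int = 2
    # tomographic side
    n_phantoms: int = 8
    grid_size: int = 63
    unet_input: int = 64
    projection_counts: tuple[int, ...] = (30, 15, 10, 7, 5)
    pair_augment_factor: int = 2
    unet_epochs: int = 2
    # dose table
    dose_seconds: tuple[float, ...] = (5.0, 10.0)

    def unet_config(self) -> UNetConfig:
        return UNetConfig(input_size=self.unet_input, base_features=16,
                          fuse_features=20, head_features=4, levels=2,
                          stem_convs=1, enc_convs=2, bottleneck_convs=1,
                          dec_extra_convs=0, learning_rate=2e-3,
                          batch_size=8, epochs=self.unet_epochs)


def array_hash(arr: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(arr).tobytes()).hexdigest()[:16]


@dataclass
class _Stage:
    name: str
    seconds: float
    outputs: dict = field(default_factory=dict)


def run_end_to_end(cfg: RunConfig) -> dict:
    """Execute all stages; returns (and writes) the manifest dict."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages: list[_Stage] = []
    rng = np.random.default_rng(cfg.seed)

    def stage(name):
        def wrap(fn):
            t0 = time.perf_counter()
            outputs = fn()
            stages.append(_Stage(name, time.perf_counter() - t0, outputs))
            return outputs
        return wrap

    try:
        @stage("simulate_spectra")
        def spectra_out():
            base = simulate_dataset(cfg.n_base_spectra, seed=cfg.seed)
            aug = augment_dataset(base, cfg.n_augment_reps,
                                  AugmentationConfig(seed=cfg.seed + 1))
            arr = np.stack([s.counts for s in aug])
            return {"n_base": len(base), "n_augmented": len(aug),
                    "hash": array_hash(arr), "_spectra": aug}

        aug = spectra_out["_spectra"]

        @stage("extract_targets")
        def extract_out():
            lo, hi = ANALYSIS_WINDOW
            x = np.stack([s.counts[lo:hi] for s in aug])
            y = np.array([s.ground_truth_netstobg for s in aug])
            return {"n_rows": len(y), "hash": array_hash(y), "_x": x, "_y": y}

        x, y = extract_out["_x"], extract_out["_y"]

        @stage("train_cnn")
        def cnn_out():
            n = len(y)
            order = np.random.default_rng(cfg.seed + 2).permutation(n)
            n_test = max(2, int(0.3 * n))
            test, pool = order[:n_test], order[n_test:]
            n_val = max(2, int(0.2 * pool.size))
            val, tr = pool[:n_val], pool[n_val:]
            h = CNNHyperparams(max_epochs=cfg.cnn_epochs, early_stop_patience=cfg.cnn_epochs)
            trained = train_cnn(x[tr], y[tr], x[val], y[val], h, seed=cfg.seed + 3)
            pred = predict_net_signal(trained, x[test])
            rep = regression_metrics(y[test], pred)
            return {"test_r2": rep.r2, "test_mae": rep.mae,
                    "n_train": int(tr.size), "_model": trained}

        cnn = cnn_out["_model"]

        @stage("build_pairs")
        def pairs_out():
            px = 32.0 / (cfg.grid_size - 1)  # keep the 30 mm object in view
            phantoms = [make_3h_phantom(tuple(rng.uniform(0.1, 1.0, 3)),
                                        grid_size=cfg.grid_size, pixel_size=px)
                        if i % 2 == 0 else
                        random_organ_phantom(grid_size=cfg.grid_size,
                                             pixel_size=px,
                                             seed=cfg.seed + 100 + i)
                        for i in range(cfg.n_phantoms)]
            base_pairs = build_base_pairs(phantoms, cfg.projection_counts)
            pairs = augment_pairs(base_pairs, cfg.pair_augment_factor,
                                  seed=cfg.seed + 4)
            split = split_pairs(pairs, seed=cfg.seed + 5)
            return {"n_base_pairs": len(base_pairs), "n_pairs": len(pairs),
                    "n_train": len(split["train"]), "n_val": len(split["val"]),
                    "n_test": len(split["test"]), "_split": split}

        split = pairs_out["_split"]

        def pack(pairs):
            xs = np.stack([resize_to_input(s, (cfg.unet_input,) * 2)
                           for s, _ in pairs])
            ys = np.stack([_resize_img(img.grid, cfg.unet_input)
                           for _, img in pairs])
            return xs, ys

        @stage("train_unet")
        def unet_out():
            xtr, ytr = pack(split["train"])
            xv, yv = pack(split["val"])
            trained = train_unet(xtr, ytr, xv, yv, cfg.unet_config(),
                                 seed=cfg.seed + 6)
            return {"final_loss": trained.history["loss"][-1],
                    "val_ssim": trained.history["val_ssim"][-1],
                    "_model": trained}

        unet = unet_out["_model"]

        @stage("reconstruct_eval")
        def recon_out():
            xte, yte = pack(split["test"])
            rng_range = float(yte.max() - yte.min()) or 1.0
            ssims = []
            for i in range(min(4, len(xte))):
                rec = reconstruct(unet, xte[i])
                ssims.append(image_metrics(yte[i], rec.grid, rng_range)["ssim"])
            return {"mean_test_ssim": float(np.mean(ssims)), "n_eval": len(ssims)}

        @stage("per_slice_inference")
        def slice_out():
            # one slice = 330 spectra -> sinogram -> image
            slice_spectra = simulate_dataset(330, seed=cfg.seed + 7)
            lo, hi = ANALYSIS_WINDOW
            xs = np.stack([s.counts[lo:hi] for s in slice_spectra])
            vals = predict_net_signal(cnn, xs)
            sino = assemble_sinogram(np.clip(vals, 0, None))
            img = fbp_reconstruct(sino)
            return {"n_spectra": len(slice_spectra),
                    "sinogram_shape": list(sino.matrix.shape),
                    "image_shape": list(img.grid.shape),
                    "hash": array_hash(img.grid)}

        @stage("dose_table")
        def dose_out():
            table = {}
            for p in cfg.projection_counts:
                for sec in cfg.dose_seconds:
                    d = scan_dose(p, sec)
                    table[f"{p}proj_{sec:g}s"] = [d.scan_time_rounded, d.dose_rounded]
            return {"table": table}

    except Exception as exc:  # halt with the failing stage named
        manifest = _manifest(cfg, stages, failed=repr(exc))
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise RuntimeError(
            f"pipeline halted after stage {len(stages)}: {exc}") from exc

    manifest = _manifest(cfg, stages)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def _resize_img(grid: np.ndarray, target: int) -> np.ndarray:
    from skimage.transform import resize
    if grid.shape == (target, target):
        return grid
    return resize(grid, (target, target), order=1, mode="edge",
                  anti_aliasing=False, preserve_range=True)


def _manifest(cfg: RunConfig, stages: list[_Stage], failed: str | None = None) -> dict:
    return {
        "version": __version__,
        "config": {k: v for k, v in asdict(cfg).items()},
        "seed": cfg.seed,
        "stages": [
            {"name": s.name, "seconds": round(s.seconds, 3),
             "outputs": {k: v for k, v in s.outputs.items()
                         if not k.startswith("_")}}
            for s in stages
        ],
        "failed": failed,
    }


def timing_report(manifest: dict) -> list[dict]:
    """Per-stage timing table from a completed manifest."""
    if manifest.get("failed"):
        raise ValueError("manifest records a failed run")
    if "stages" not in manifest or not manifest["stages"]:
        raise ValueError("manifest has no stage records")
    rows = [{"stage": s["name"], "seconds": s["seconds"]}
            for s in manifest["stages"]]
    rows.append({"stage": "total",
                 "seconds": round(sum(r["seconds"] for r in rows), 3)})
    return rows
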