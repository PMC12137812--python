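"""Constant-width U-Net mapping sinograms to concentration images.

The encoder/decoder keeps a constant number of feature maps (64 by default)
at every depth instead of doubling after each pooling.  Each decoder stage
upsamples, concatenates the matching encoder features, fuses them through a
slightly wider (80-channel) convolution, and returns to the constant width;
the output head is a per-pixel two-layer 1x1-convolution projection.  The
layer layout is reconstructed around the published trainable-parameter
count, which the default configuration reproduces exactly: 1,616,289.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import nn
from .metrics import image_metrics, regression_metrics

__all__ = [
    "UNetConfig",
    "ReconImage",
    "UNet",
    "build_unet",
    "train_unet",
    "reconstruct",
    "TrainedUNet",
    "save_unet",
    "load_unet",
]

EXPECTED_DEFAULT_PARAMS = 1_616_289


@dataclass
class ReconImage:
    """Reconstructed 2D concentration map."""

    grid: np.ndarray
    pixel_size: float = 0.5  # mm
    method: str = "unet"

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=np.float64)
        if self.grid.ndim != 2:
            raise ValueError("reconstruction must be 2D")
        if not np.all(np.isfinite(self.grid)):
            raise ValueError("reconstruction contains non-finite values")


@dataclass(frozen=True)
class UNetConfig:
    input_size: int = 256
    base_features: int = 64       # constant width at every depth
    fuse_features: int = 80       # width of the post-concatenation fuse conv
    head_features: int = 8        # hidden width of the 1x1 projection head
    levels: int = 4               # encoder levels below the stem (pools = levels+1)
    stem_convs: int = 2
    enc_convs: int = 3
    bottleneck_convs: int = 2
    dec_extra_convs: int = 1
    kernel: int = 3
    learning_rate: float = 1e-4
    batch_size: int = 128
    epochs: int = 50

    def __post_init__(self) -> None:
        pools = self.levels + 1
        if self.input_size % (2**pools) != 0:
            raise ValueError(
                f"input_size {self.input_size} not divisible by 2^{pools}")
        if min(self.base_features, self.fuse_features, self.head_features) < 1:
            raise ValueError("feature widths must be positive")
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be positive")


class UNet:
    """Hand-wired forward/backward graph over the nn layer vocabulary."""

    def __init__(self, cfg: UNetConfig, seed: int = 0):
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        b, f, k = cfg.base_features, cfg.fuse_features, cfg.kernel

        def conv(cin, cout, kk=k):
            return nn.Conv2D(cin, cout, kk, rng)

        self.stem = [conv(1, b)] + [conv(b, b) for _ in range(cfg.stem_convs - 1)]
        self.enc = [[conv(b, b) for _ in range(cfg.enc_convs)]
                    for _ in range(cfg.levels)]
        self.bottleneck = [conv(b, b) for _ in range(cfg.bottleneck_convs)]
        self.dec = []
        for _ in range(cfg.levels + 1):
            stage = {
                "up": nn.UpConv2D(b, b, k, rng),
                "fuse": conv(2 * b, f),
                "narrow": conv(f, b),
                "extra": [conv(b, b) for _ in range(cfg.dec_extra_convs)],
            }
            self.dec.append(stage)
        self.head = [conv(b, cfg.head_features, 1), conv(cfg.head_features, 1, 1)]

    # -- parameter bookkeeping ------------------------------------------------

    def _layers(self):
        for l in self.stem:
            yield l
        for block in self.enc:
            yield from block
        yield from self.bottleneck
        for st in self.dec:
            yield st["up"]
            yield st["fuse"]
            yield st["narrow"]
            yield from st["extra"]
        yield from self.head

    @property
    def params(self):
        return [p for l in self._layers() for p in l.params]

    @property
    def grads(self):
        return [g for l in self._layers() for g in l.grads]

    def param_count(self) -> int:
        return sum(int(p.size) for p in self.params)

    # -- forward / backward ---------------------------------------------------

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """x: (N, H, W) or (N, H, W, 1) -> (N, H, W)."""
        if x.ndim == 3:
            x = x[..., None]
        if x.shape[1] != self.cfg.input_size or x.shape[2] != self.cfg.input_size:
            raise ValueError(
                f"expected {self.cfg.input_size}x{self.cfg.input_size} input")
        x = x.astype(np.float32, copy=False)
        self._acts = {"relu": [], "pools": [], "skips": []}
        relus = self._acts["relu"]

        def act(layer, h):
            h = layer.forward(h, train)
            r = nn.ReLU()
            h = r.forward(h, train)
            relus.append((layer, r))
            return h

        h = x
        for l in self.stem:
            h = act(l, h)
        skips = [h]
        pools = []
        for block in self.enc:
            p = nn.MaxPool2D()
            h = p.forward(h)
            pools.append(p)
            for l in block:
                h = act(l, h)
            skips.append(h)
        p = nn.MaxPool2D()
        h = p.forward(h)
        pools.append(p)
        for l in self.bottleneck:
            h = act(l, h)

        self._acts["pools"] = pools
        self._acts["skips"] = skips
        self._dec_trace = []
        for st, skip in zip(self.dec, reversed(skips)):
            h = act(st["up"], h)
            h = np.concatenate([h, skip], axis=-1)
            h = act(st["fuse"], h)
            h = act(st["narrow"], h)
            for l in st["extra"]:
                h = act(l, h)

        hh = self.head[0].forward(h, train)
        r = nn.ReLU()
        hh = r.forward(hh, train)
        relus.append((self.head[0], r))
        out = self.head[1].forward(hh, train)
        return out[..., 0]

    def backward(self, grad_out: np.ndarray) -> None:
        b = self.cfg.base_features
        stack = list(self._acts["relu"])  # (layer, relu) in forward order
        pools = list(self._acts["pools"])
        n_skips = len(self._acts["skips"])

        def back(g):
            layer, r = stack.pop()
            return layer.backward(r.backward(g))

        g = self.head[1].backward(grad_out[..., None])
        g = back(g)  # head[0]

        # dec stage j (forward order) consumed skip n_skips-1-j, so walking
        # the stages in reverse visits skips 0, 1, ..., n_skips-1
        skip_grads = [None] * n_skips
        for i, st in zip(range(n_skips), reversed(self.dec)):
            for _ in st["extra"]:
                g = back(g)
            g = back(g)  # narrow
            g = back(g)  # fuse
            skip_grads[i] = g[..., b:]
            g = back(g[..., :b])  # up

        for _ in self.bottleneck:
            g = back(g)
        g = pools.pop().backward(g)
        for i in range(len(self.enc) - 1, -1, -1):
            g = g + skip_grads[i + 1]
            for _ in self.enc[i]:
                g = back(g)
            g = pools.pop().backward(g)
        g = g + skip_grads[0]
        for _ in self.stem:
            g = back(g)

    def predict(self, x: np.ndarray, batch_size: int = 8) -> np.ndarray:
        x = np.asarray(x, dtype=np.float32)
        single = x.ndim == 2
        if single:
            x = x[None]
        outs = [self.forward(x[i:i + batch_size], train=False)
                for i in range(0, x.shape[0], batch_size)]
        out = np.concatenate(outs)
        return out[0] if single else out


def build_unet(cfg: UNetConfig | None = None, seed: int = 0) -> UNet:
    return UNet(cfg or UNetConfig(), seed=seed)


@dataclass
class TrainedUNet:
    model: UNet
    x_scaler: "object"
    y_scaler: "object"
    history: dict[str, list[float]] = field(default_factory=dict)
    seed: int = 0


def train_unet(
    train_x: np.ndarray,
    train_y: np.ndarray,
    val_x: np.ndarray,
    val_y: np.ndarray,
    cfg: UNetConfig | None = None,
    seed: int = 0,
    verbose: bool = False,
    ssim_subsample: int = 8,
) -> TrainedUNet:
    """Train with MAE loss and Adam.  Inputs/targets are raw (unscaled)
    arrays of shape (N, H, W); global min-max scalers are fitted on the
    training arrays only.  History logs per-epoch loss plus validation MAE,
    RMSE, SSIM and PSNR (image metrics on inverse-scaled images)."""
    from .tomo import MinMaxScaler  # local import avoids a cycle

    cfg = cfg or UNetConfig()
    train_x = np.asarray(train_x, dtype=np.float64)
    train_y = np.asarray(train_y, dtype=np.float64)
    val_x = np.asarray(val_x, dtype=np.float64)
    val_y = np.asarray(val_y, dtype=np.float64)
    if train_x.shape[0] == 0 or val_x.shape[0] == 0:
        raise ValueError("train and validation sets must be non-empty")

    xs = MinMaxScaler().fit(train_x)
    ys = MinMaxScaler().fit(train_y)
    xt = xs.transform(train_x).astype(np.float32)
    yt = ys.transform(train_y).astype(np.float32)
    xv = xs.transform(val_x).astype(np.float32)
    yv = ys.transform(val_y).astype(np.float32)

    model = build_unet(cfg, seed=seed)
    opt = nn.Adam(model.params, lr=cfg.learning_rate)
    shuffle_rng = np.random.default_rng(seed + 1)

    history: dict[str, list[float]] = {
        "loss": [], "val_mae": [], "val_rmse": [], "val_ssim": [], "val_psnr": []}
    data_range = ys.data_range
    for epoch in range(cfg.epochs):
        ep_loss, n_seen = 0.0, 0
        for idx in nn.batch_indices(xt.shape[0], cfg.batch_size, shuffle_rng):
            pred = model.forward(xt[idx], train=True)
            loss, grad = nn.mae_loss(pred, yt[idx])
            model.backward(grad)
            opt.step(model.grads)
            ep_loss += loss * len(idx)
            n_seen += len(idx)
        pv = model.predict(xv)
        rep = regression_metrics(yv.ravel(), pv.ravel())
        k = min(ssim_subsample, xv.shape[0])
        ims = [image_metrics(ys.inverse_transform(yv[i]),
                             ys.inverse_transform(np.clip(pv[i], 0, 1)),
                             data_range)
               for i in range(k)]
        history["loss"].append(ep_loss / n_seen)
        history["val_mae"].append(rep.mae)
        history["val_rmse"].append(rep.rmse)
        history["val_ssim"].append(float(np.mean([m["ssim"] for m in ims])))
        psnrs = [m["psnr"] for m in ims if np.isfinite(m["psnr"])]
        history["val_psnr"].append(float(np.mean(psnrs)) if psnrs else float("inf"))
        if verbose:
            print(f"epoch {epoch}: loss {history['loss'][-1]:.5f} "
                  f"val_mae {rep.mae:.5f} val_ssim {history['val_ssim'][-1]:.4f}")
    return TrainedUNet(model=model, x_scaler=xs, y_scaler=ys,
                       history=history, seed=seed)


def reconstruct(trained: TrainedUNet, sino_input: np.ndarray,
                pixel_size: float = 0.5) -> ReconImage:
    """Reconstruct one (already resized) sinogram.  The raw sinogram is
    scaled with the training min-max scaler, passed through the network,
    clipped to [0, 1], and inverse-transformed to the original range."""
    sino_input = np.asarray(sino_input, dtype=np.float64)
    if sino_input.shape != (trained.model.cfg.input_size,) * 2:
        raise ValueError(
            f"expected a {trained.model.cfg.input_size}x"
            f"{trained.model.cfg.input_size} sinogram input")
    z = trained.x_scaler.transform(sino_input)
    out = trained.model.predict(z.astype(np.float32))
    out = np.clip(out, 0.0, 1.0)
    return ReconImage(grid=trained.y_scaler.inverse_transform(out),
                      pixel_size=pixel_size, method="unet")


def save_unet(trained: TrainedUNet, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    np.savez(outdir / "weights.npz", *trained.model.params)
    meta = {
        "config": asdict(trained.model.cfg),
        "seed": trained.seed,
        "history": trained.history,
        "n_params": trained.model.param_count(),
        "x_scaler": [trained.x_scaler.min_, trained.x_scaler.max_],
        "y_scaler": [trained.y_scaler.min_, trained.y_scaler.max_],
    }
    (outdir / "metadata.json").write_text(json.dumps(meta, indent=2))


def load_unet(outdir: str | Path) -> TrainedUNet:
    from .tomo import MinMaxScaler

    outdir = Path(outdir)
    meta = json.loads((outdir / "metadata.json").read_text())
    cfg = UNetConfig(**meta["config"])
    model = build_unet(cfg, seed=meta["seed"])
    data = np.load(outdir / "weights.npz")
    nn.restore_params(model.params, [data[k] for k in data.files])
    xs, ys = MinMaxScaler(), MinMaxScaler()
    xs.min_, xs.max_ = meta["x_scaler"]
    ys.min_, ys.max_ = meta["y_scaler"]
    return TrainedUNet(model=model, x_scaler=xs, y_scaler=ys,
                       history=meta["history"], seed=meta["seed"])
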