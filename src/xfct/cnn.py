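"""1D CNN spectral regressor: raw 500-channel window -> net XRF signal.

Architecture (optimized hyperparameters taken as fixed defaults):
input (500, 1) -> Gaussian noise -> Conv1D(75, k=39, ELU)
-> Conv1D(14, k=13, ELU) -> Dropout(0.22) -> Flatten -> Dense(260, ELU)
-> Dense(1, linear).  Compiled with the Huber loss and Adam at 5.4e-5.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import nn
from .extraction import ANALYSIS_WINDOW
from .metrics import regression_metrics
from .spectra import Spectrum

__all__ = [
    "CNNHyperparams",
    "ZScoreScaler",
    "slice_input_window",
    "build_cnn",
    "split_spectra",
    "train_cnn",
    "predict_net_signal",
    "save_cnn",
    "load_cnn",
    "TrainedCNN",
]


@dataclass(frozen=True)
class CNNHyperparams:
    conv1_filters: int = 75
    conv1_kernel: int = 39
    conv2_filters: int = 14
    conv2_kernel: int = 13
    dense_units: int = 260
    dropout_rate: float = 0.22
    learning_rate: float = 5.4e-5
    batch_size: int = 128
    max_epochs: int = 100
    early_stop_patience: int = 20
    input_length: int = 500
    huber_delta: float = 1.0
    input_noise_sd: float = 0.01  # in z-scored units, train-time only

    def __post_init__(self) -> None:
        if self.conv1_kernel > self.input_length or self.conv2_kernel > self.input_length:
            raise ValueError("kernel sizes must not exceed the input length")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")


class ZScoreScaler:
    """Per-feature standardization fitted on training data only.

    Degenerate (zero-variance) features standardize to 0 via a unit sigma.
    """

    def __init__(self) -> None:
        self.mean_: np.ndarray | None = None
        self.sigma_: np.ndarray | None = None

    def fit(self, x: np.ndarray) -> "ZScoreScaler":
        x = np.asarray(x, dtype=np.float64)
        self.mean_ = x.mean(axis=0)
        sigma = x.std(axis=0)
        self.sigma_ = np.where(sigma > 0, sigma, 1.0)
        return self

    def _check(self) -> None:
        if self.mean_ is None:
            raise RuntimeError("scaler is not fitted")

    def transform(self, x: np.ndarray) -> np.ndarray:
        self._check()
        return (np.asarray(x, dtype=np.float64) - self.mean_) / self.sigma_

    def inverse_transform(self, z: np.ndarray) -> np.ndarray:
        self._check()
        return np.asarray(z, dtype=np.float64) * self.sigma_ + self.mean_

    def state_checksum(self) -> int:
        self._check()
        return hash((self.mean_.tobytes(), self.sigma_.tobytes()))


def slice_input_window(s: Spectrum) -> np.ndarray:
    """Channels [200, 700) of an 800-channel spectrum (32-112 keV)."""
    lo, hi = ANALYSIS_WINDOW
    if s.counts.size != 800:
        raise ValueError(f"expected an 800-channel spectrum, got {s.counts.size}")
    return s.counts[lo:hi].copy()


class CNNModel(nn.Sequential):
    """The stacked model plus bookkeeping for persistence."""

    def __init__(self, h: CNNHyperparams, seed: int = 0):
        self.hyperparams = h
        rng = np.random.default_rng(seed)
        l_after1 = h.input_length - h.conv1_kernel + 1
        l_after2 = l_after1 - h.conv2_kernel + 1
        layers = [
            nn.GaussianNoise(h.input_noise_sd, rng),
            nn.Conv1D(1, h.conv1_filters, h.conv1_kernel, rng),
            nn.ELU(),
            nn.Conv1D(h.conv1_filters, h.conv2_filters, h.conv2_kernel, rng),
            nn.ELU(),
            nn.Dropout(h.dropout_rate, rng),
            nn.Flatten(),
            nn.Dense(l_after2 * h.conv2_filters, h.dense_units, rng),
            nn.ELU(),
            nn.Dense(h.dense_units, 1, rng),
        ]
        super().__init__(layers)

    def predict(self, x: np.ndarray, batch_size: int = 512) -> np.ndarray:
        """Forward pass in inference mode; x is (N, input_length)."""
        x = np.asarray(x, dtype=np.float32)[..., None]
        outs = [self.forward(x[i:i + batch_size], train=False)
                for i in range(0, x.shape[0], batch_size)]
        return np.concatenate(outs).ravel()


def build_cnn(h: CNNHyperparams | None = None, seed: int = 0) -> CNNModel:
    return CNNModel(h or CNNHyperparams(), seed=seed)


def split_spectra(
    pairs: pd.DataFrame,
    test_fraction: float = 0.30,
    val_fraction_of_train: float = 0.20,
    seed: int = 0,
) -> dict[str, pd.DataFrame]:
    """Shuffled 70/30 train/test split, then 80/20 train/val of the training
    pool.  Sizes use the floor rule on the smaller fraction so that 72,800
    rows split into 50,960/21,840 and the pool into 40,768/10,192."""
    if len(pairs) == 0:
        raise ValueError("cannot split an empty table")
    if not (0 < test_fraction < 1 and 0 < val_fraction_of_train < 1):
        raise ValueError("fractions must be in (0, 1)")
    n = len(pairs)
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    n_test = int(np.floor(n * test_fraction))
    test_idx = order[:n_test]
    pool_idx = order[n_test:]
    n_val = int(np.floor(len(pool_idx) * val_fraction_of_train))
    val_idx = pool_idx[:n_val]
    train_idx = pool_idx[n_val:]
    return {
        "train": pairs.iloc[train_idx].reset_index(drop=True),
        "val": pairs.iloc[val_idx].reset_index(drop=True),
        "test": pairs.iloc[test_idx].reset_index(drop=True),
    }


@dataclass
class TrainedCNN:
    model: CNNModel
    x_scaler: ZScoreScaler
    y_scaler: ZScoreScaler
    history: dict[str, list[float]] = field(default_factory=dict)
    best_epoch: int = -1
    seed: int = 0


def train_cnn(
    train_x: np.ndarray,
    train_y: np.ndarray,
    val_x: np.ndarray,
    val_y: np.ndarray,
    h: CNNHyperparams | None = None,
    seed: int = 0,
    verbose: bool = False,
    stop_at_val_r2: float | None = None,
) -> TrainedCNN:
    """Train with Adam + Huber loss, early stopping on validation loss with
    best-weight restoration.

    Inputs are raw (unscaled) 500-channel windows and netSToBg targets;
    z-score scalers for both are fitted on the training set only.
    ``stop_at_val_r2`` optionally ends training once the validation R2
    reaches a target (a compute budget device; reported metrics should come
    from a held-out test set).
    """
    h = h or CNNHyperparams()
    train_x = np.asarray(train_x, dtype=np.float64)
    train_y = np.asarray(train_y, dtype=np.float64).ravel()
    val_x = np.asarray(val_x, dtype=np.float64)
    val_y = np.asarray(val_y, dtype=np.float64).ravel()
    if val_x.shape[0] == 0:
        raise ValueError("validation set must be non-empty")
    if train_x.shape[1] != h.input_length:
        raise ValueError(f"inputs must have length {h.input_length}")

    xs = ZScoreScaler().fit(train_x)
    ys = ZScoreScaler().fit(train_y[:, None])
    xs_sum = xs.state_checksum()

    xt = xs.transform(train_x).astype(np.float32)[..., None]
    yt = ys.transform(train_y[:, None]).astype(np.float32)
    xv = xs.transform(val_x).astype(np.float32)[..., None]
    yv = ys.transform(val_y[:, None]).astype(np.float32)

    model = build_cnn(h, seed=seed)
    opt = nn.Adam(model.params, lr=h.learning_rate)
    shuffle_rng = np.random.default_rng(seed + 1)

    history: dict[str, list[float]] = {"loss": [], "val_loss": [], "val_mae": [],
                                       "val_rmse": [], "val_r2": []}
    best_loss = np.inf
    best_epoch = -1
    best_weights = nn.clone_params(model.params)
    wait = 0

    for epoch in range(h.max_epochs):
        ep_loss = 0.0
        n_seen = 0
        for idx in nn.batch_indices(xt.shape[0], h.batch_size, shuffle_rng):
            pred = model.forward(xt[idx], train=True)
            loss, grad = nn.huber_loss(pred, yt[idx], h.huber_delta)
            model.backward(grad)
            opt.step(model.grads)
            ep_loss += loss * len(idx)
            n_seen += len(idx)
        pv = model.forward(xv, train=False)
        val_loss, _ = nn.huber_loss(pv, yv, h.huber_delta)
        rep = regression_metrics(yv.ravel(), pv.ravel(), h.huber_delta)
        history["loss"].append(ep_loss / n_seen)
        history["val_loss"].append(val_loss)
        history["val_mae"].append(rep.mae)
        history["val_rmse"].append(rep.rmse)
        history["val_r2"].append(rep.r2)
        if verbose:
            print(f"epoch {epoch}: loss {ep_loss/n_seen:.5f} val {val_loss:.5f} "
                  f"R2 {rep.r2:.5f}")
        if val_loss < best_loss:
            best_loss = val_loss
            best_epoch = epoch
            best_weights = nn.clone_params(model.params)
            wait = 0
        else:
            wait += 1
            if wait >= h.early_stop_patience:
                break
        if stop_at_val_r2 is not None and rep.r2 >= stop_at_val_r2:
            break

    nn.restore_params(model.params, best_weights)
    if xs.state_checksum() != xs_sum:
        raise RuntimeError("input scaler was refitted during training")
    return TrainedCNN(model=model, x_scaler=xs, y_scaler=ys, history=history,
                      best_epoch=best_epoch, seed=seed)


def predict_net_signal(trained: TrainedCNN, x: np.ndarray) -> np.ndarray:
    """netSToBg predictions on the original scale, one per input row."""
    x = np.asarray(x, dtype=np.float64)
    if x.ndim == 1:
        x = x[None, :]
    if x.shape[1] != trained.model.hyperparams.input_length:
        raise ValueError("input window length mismatch")
    z = trained.x_scaler.transform(x)
    pz = trained.model.predict(z)
    return trained.y_scaler.inverse_transform(pz[:, None]).ravel()


# ---------------------------------------------------------------------------
# persistence: weights as npz + JSON metadata sidecar
# ---------------------------------------------------------------------------

def save_cnn(trained: TrainedCNN, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    np.savez(outdir / "weights.npz",
             *trained.model.params,
             x_mean=trained.x_scaler.mean_, x_sigma=trained.x_scaler.sigma_,
             y_mean=trained.y_scaler.mean_, y_sigma=trained.y_scaler.sigma_)
    meta = {
        "hyperparams": asdict(trained.model.hyperparams),
        "best_epoch": trained.best_epoch,
        "seed": trained.seed,
        "history": trained.history,
        "n_params": trained.model.param_count(),
    }
    (outdir / "metadata.json").write_text(json.dumps(meta, indent=2))


def load_cnn(outdir: str | Path) -> TrainedCNN:
    outdir = Path(outdir)
    meta = json.loads((outdir / "metadata.json").read_text())
    h = CNNHyperparams(**meta["hyperparams"])
    model = build_cnn(h, seed=meta["seed"])
    data = np.load(outdir / "weights.npz")
    arrs = [data[k] for k in data.files if k.startswith("arr_")]
    nn.restore_params(model.params, arrs)
    xs = ZScoreScaler()
    xs.mean_, xs.sigma_ = data["x_mean"], data["x_sigma"]
    ys = ZScoreScaler()
    ys.mean_, ys.sigma_ = data["y_mean"], data["y_sigma"]
    return TrainedCNN(model=model, x_scaler=xs, y_scaler=ys,
                      history=meta["history"], best_epoch=meta["best_epoch"],
                      seed=meta["seed"])
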