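import numpy as np
import pandas as pd
import pytest

from xfct.cnn import (CNNHyperparams, ZScoreScaler, build_cnn, load_cnn,
                      predict_net_signal, save_cnn, slice_input_window,
                      split_spectra, train_cnn)
from xfct.spectra import simulate_spectrum


@pytest.fixture(scope="module")
def tiny_hyperparams():
    # shrunk model for fast unit tests; architecture identical in kind
    return CNNHyperparams(conv1_filters=8, conv1_kernel=9, conv2_filters=4,
                          conv2_kernel=5, dense_units=16, dropout_rate=0.0,
                          input_noise_sd=0.0, learning_rate=3e-3,
                          batch_size=16, max_epochs=30, early_stop_patience=30)


def _linear_dataset(n, seed=0, noise=0.0):
    """Spectra-like inputs: baseline + a localized bump whose amplitude is
    the regression target.  Easily learnable by the conv stack."""
    rng = np.random.default_rng(seed)
    amp = rng.random(n)
    ch = np.arange(500)
    profile = 1.0 + 0.5 * np.sin(ch / 50.0)
    x = amp[:, None] * profile[None, :] + 0.01 * rng.random((n, 500))
    y = 3.0 * amp + 1.0
    if noise:
        y = y + rng.normal(0, noise, n)
    return x, y


class TestSliceWindow:
    def test_energy_of_first_channel(self, clean_spectrum):
        lo_energy = 200 * clean_spectrum.calibration.bin_width
        assert lo_energy == pytest.approx(32.0)

    def test_length_500(self, clean_spectrum):
        assert slice_input_window(clean_spectrum).size == 500

    def test_all_ones(self, calibration):
        from xfct.spectra import Spectrum
        s = Spectrum(counts=np.ones(800), calibration=calibration)
        np.testing.assert_array_equal(slice_input_window(s), 1.0)

    def test_wrong_channel_count(self):
        from xfct.spectra import EnergyCalibration, Spectrum
        s = Spectrum(counts=np.zeros(400),
                     calibration=EnergyCalibration(n_channels=400))
        with pytest.raises(ValueError):
            slice_input_window(s)


class TestBuildCNN:
    def test_output_layer_single_linear_unit(self):
        model = build_cnn(seed=0)
        x = np.zeros((2, 500, 1), dtype=np.float32)
        assert model.forward(x).shape == (2, 1)

    def test_dense_width_260(self):
        model = build_cnn(seed=0)
        dense = model.layers[-3]
        assert dense.W.shape[1] == 260

    def test_param_count_monotone_in_width(self):
        base = build_cnn(CNNHyperparams(), seed=0).param_count()
        wider = build_cnn(CNNHyperparams(conv1_filters=150), seed=0).param_count()
        assert wider > base

    def test_kernel_larger_than_input_rejected(self):
        with pytest.raises(ValueError):
            CNNHyperparams(conv1_kernel=501)


class TestZScoreScaler:
    def test_round_trip(self):
        rng = np.random.default_rng(0)
        x = rng.normal(5, 3, (20, 4))
        sc = ZScoreScaler().fit(x)
        np.testing.assert_allclose(sc.inverse_transform(sc.transform(x)), x,
                                   atol=1e-9)

    def test_degenerate_feature(self):
        x = np.ones((10, 2))
        x[:, 1] = np.arange(10)
        sc = ZScoreScaler().fit(x)
        z = sc.transform(x)
        np.testing.assert_array_equal(z[:, 0], 0.0)

    def test_unfitted_rejected(self):
        with pytest.raises(RuntimeError):
            ZScoreScaler().transform(np.zeros((2, 2)))


class TestSplitSpectra:
    def test_paper_sizes(self):
        df = pd.DataFrame({"v": np.arange(72_800)})
        split = split_spectra(df, seed=0)
        assert len(split["test"]) == 21_840
        assert len(split["train"]) + len(split["val"]) == 50_960
        assert len(split["val"]) == 10_192
        assert len(split["train"]) == 40_768

    def test_small_split_disjoint_exhaustive(self):
        df = pd.DataFrame({"v": np.arange(10)})
        split = split_spectra(df, seed=1)
        assert len(split["test"]) == 3
        all_v = sorted(pd.concat([split["train"], split["val"],
                                  split["test"]])["v"])
        assert all_v == list(range(10))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            split_spectra(pd.DataFrame({"v": []}))

    def test_deterministic(self):
        df = pd.DataFrame({"v": np.arange(100)})
        a = split_spectra(df, seed=5)
        b = split_spectra(df, seed=5)
        assert a["test"]["v"].tolist() == b["test"]["v"].tolist()


class TestTraining:
    def test_memorizes_tiny_linear_problem(self, tiny_hyperparams):
        x, y = _linear_dataset(200, seed=0)
        trained = train_cnn(x[:160], y[:160], x[160:], y[160:],
                            tiny_hyperparams, seed=0)
        pred = predict_net_signal(trained, x[160:])
        from xfct.metrics import regression_metrics
        assert regression_metrics(y[160:], pred).r2 > 0.99

    def test_prediction_count(self, tiny_hyperparams):
        x, y = _linear_dataset(60, seed=1)
        h = CNNHyperparams(**{**tiny_hyperparams.__dict__, "max_epochs": 2})
        trained = train_cnn(x[:40], y[:40], x[40:], y[40:], h, seed=0)
        assert predict_net_signal(trained, x).size == 60

    def test_empty_validation_rejected(self, tiny_hyperparams):
        x, y = _linear_dataset(10)
        with pytest.raises(ValueError):
            train_cnn(x, y, x[:0], y[:0], tiny_hyperparams)

    def test_early_stop_restores_best(self, tiny_hyperparams):
        x, y = _linear_dataset(80, seed=2, noise=0.3)
        h = CNNHyperparams(**{**tiny_hyperparams.__dict__,
                              "max_epochs": 25, "early_stop_patience": 3})
        trained = train_cnn(x[:60], y[:60], x[60:], y[60:], h, seed=0)
        best = min(trained.history["val_loss"])
        assert trained.history["val_loss"][trained.best_epoch] == pytest.approx(best)

    def test_deterministic_given_seed(self, tiny_hyperparams):
        x, y = _linear_dataset(40, seed=3)
        h = CNNHyperparams(**{**tiny_hyperparams.__dict__, "max_epochs": 3})
        a = train_cnn(x[:30], y[:30], x[30:], y[30:], h, seed=7)
        b = train_cnn(x[:30], y[:30], x[30:], y[30:], h, seed=7)
        for pa, pb in zip(a.model.params, b.model.params):
            np.testing.assert_array_equal(pa, pb)

    def test_history_metrics_present(self, tiny_hyperparams):
        x, y = _linear_dataset(40, seed=4)
        h = CNNHyperparams(**{**tiny_hyperparams.__dict__, "max_epochs": 2})
        trained = train_cnn(x[:30], y[:30], x[30:], y[30:], h, seed=0)
        for key in ("loss", "val_loss", "val_mae", "val_rmse", "val_r2"):
            assert len(trained.history[key]) == 2


class TestPersistence:
    def test_save_load_round_trip(self, tiny_hyperparams, tmp_path):
        x, y = _linear_dataset(40, seed=5)
        h = CNNHyperparams(**{**tiny_hyperparams.__dict__, "max_epochs": 2})
        trained = train_cnn(x[:30], y[:30], x[30:], y[30:], h, seed=0)
        save_cnn(trained, tmp_path / "model")
        loaded = load_cnn(tmp_path / "model")
        np.testing.assert_allclose(predict_net_signal(loaded, x),
                                   predict_net_signal(trained, x), rtol=1e-6)
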