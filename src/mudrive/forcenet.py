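"""Force regression network and the two conventional baselines.

Architecture (per 0.2-s sample of shape 400 x 8 x 8 x N): a time-distributed
3x3 convolution with 16 filters (stride 1, same padding, ReLU) mines the
spatial structure of the electrode grid; the flattened per-step features feed
two LSTM layers (64 units, then 1 unit, both returning sequences) and a
per-step linear readout, giving the 400 x 1 predicted force.  Training uses
Adam (lr 0.001), batch size 32, the RMSD loss, a chronological 2:1
train/validation split and best-validation-epoch checkpointing.

Baselines: quadratic polynomial regression of force on (a) the summed motor
unit firing rate and (b) the mean RMS amplitude, both computed over 250-ms
windows advanced by 50 ms.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .core import SpikeTrain
from .nn import (LSTM, Adam, Flatten, Sequential, TimeDistributedConv2D,
                 TimeDistributedDense, rmsd_loss)
from .twitch import FeatureWindow

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class NetConfig:
    conv_filters: int = 16
    conv_kernel: tuple[int, int] = (3, 3)
    lstm_units: tuple[int, int] = (64, 1)
    lr: float = 0.001
    batch: int = 32
    epochs: int = 30          # desk-scale default; the full recipe uses 150
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.conv_filters, self.batch, self.epochs, *self.lstm_units) < 1:
            raise ValueError("all network sizes must be positive")


class ForceNet:
    """The conv + LSTM + per-step dense force model for a fixed bank size N."""

    def __init__(self, n_mus: int, cfg: NetConfig = NetConfig(),
                 grid_shape: tuple[int, int] = (8, 8)):
        if n_mus < 1:
            raise ValueError("need at least one motor unit")
        self.n_mus = n_mus
        self.cfg = cfg
        self.grid_shape = grid_shape
        rng = np.random.default_rng(cfg.seed)
        rows, cols = grid_shape
        flat_dim = rows * cols * cfg.conv_filters
        self.net = Sequential([
            TimeDistributedConv2D(n_mus, cfg.conv_filters, cfg.conv_kernel, rng),
            Flatten(),
            LSTM(flat_dim, cfg.lstm_units[0], rng),
            LSTM(cfg.lstm_units[0], cfg.lstm_units[1], rng),
            TimeDistributedDense(cfg.lstm_units[1], 1, rng),
        ])
        self.input_scale = 1.0  # set at training time

    def forward(self, x: np.ndarray) -> np.ndarray:
        """Raw forward pass on a normalized batch (B, T, rows, cols, N) -> (B, T)."""
        if x.shape[-1] != self.n_mus:
            raise ValueError(
                f"MU axis {x.shape[-1]} does not match the bank size {self.n_mus}")
        return self.net.forward(x.astype(np.float32))[..., 0]

    def predict(self, tensors: np.ndarray) -> np.ndarray:
        """Predict force for feature tensors (B, T, rows, cols, N), clipped to [0, 1.2]."""
        out = self.forward(tensors / self.input_scale)
        return np.clip(out.astype(np.float64), 0.0, 1.2)


@dataclass
class TrainingHistory:
    train_rmsd: list[float] = field(default_factory=list)
    val_rmsd: list[float] = field(default_factory=list)
    best_epoch: int = -1


def _stack(windows: list[FeatureWindow]) -> tuple[np.ndarray, np.ndarray]:
    x = np.stack([w.tensor for w in windows]).astype(np.float32)
    y = np.stack([w.label for w in windows]).astype(np.float32)
    return x, y


def build_network(n_mus: int, cfg: NetConfig = NetConfig()) -> ForceNet:
    return ForceNet(n_mus, cfg)


def train(model: ForceNet, windows: list[FeatureWindow],
          cfg: NetConfig | None = None,
          val_fraction: float = 1.0 / 3.0) -> TrainingHistory:
    """Train in place with a chronological train/validation split (2:1).

    Keeps the best-validation-epoch weights.  Feature tensors are normalized
    by the training set's maximum absolute value (stored on the model so
    prediction applies the same scale).
    """
    if not windows:
        raise ValueError("empty training dataset")
    cfg = cfg or model.cfg
    windows = sorted(windows, key=lambda w: w.start_sample)
    n_val = int(round(len(windows) * val_fraction))
    train_w = windows[: len(windows) - n_val]
    val_w = windows[len(windows) - n_val:]
    if not train_w:
        raise ValueError("no training windows after the split")
    x_tr, y_tr = _stack(train_w)
    scale = float(np.abs(x_tr).max())
    model.input_scale = scale if scale > 0 else 1.0
    x_tr /= model.input_scale
    if val_w:
        x_val, y_val = _stack(val_w)
        x_val /= model.input_scale
    opt = Adam(model.net.params, lr=cfg.lr)
    rng = np.random.default_rng(cfg.seed + 1)
    history = TrainingHistory()
    best_val = np.inf
    best_weights = model.net.get_weights()
    n = len(train_w)
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        epoch_losses = []
        for start in range(0, n, cfg.batch):
            idx = order[start:start + cfg.batch]
            pred = model.net.forward(x_tr[idx])[..., 0]
            loss, grad = rmsd_loss(pred, y_tr[idx])
            model.net.backward(grad[..., None])
            opt.step(model.net.grads)
            epoch_losses.append(loss)
        history.train_rmsd.append(float(np.mean(epoch_losses)))
        if val_w:
            val_pred = model.net.forward(x_val)[..., 0]
            val_loss, _ = rmsd_loss(val_pred, y_val)
        else:
            val_loss = history.train_rmsd[-1]
        history.val_rmsd.append(val_loss)
        if val_loss < best_val:
            best_val = val_loss
            best_weights = model.net.get_weights()
            history.best_epoch = epoch
        logger.debug("epoch %d: train %.2f%% val %.2f%%", epoch,
                     history.train_rmsd[-1], val_loss)
    model.net.set_weights(best_weights)
    return history


def predict_window(model: ForceNet, window: FeatureWindow) -> np.ndarray:
    """Predicted 400-point force for one feature window."""
    return model.predict(window.tensor[None])[0]


def stitch(windows: list[FeatureWindow], outputs: list[np.ndarray],
           step: int = 400) -> np.ndarray:
    """Concatenate per-window predictions of contiguous 0.2-s steps."""
    if len(windows) != len(outputs):
        raise ValueError("windows and outputs must align")
    starts = [w.start_sample for w in windows]
    if any(b - a != step for a, b in zip(starts, starts[1:])):
        raise ValueError("windows are not contiguous 0.2-s steps")
    return np.concatenate(outputs)


def save_model(path, model: ForceNet, mu_ids: list[int] | None = None) -> None:
    """Persist weights + architecture + normalization to HDF5."""
    import json

    import h5py

    with h5py.File(path, "w") as f:
        for k, p in enumerate(model.net.params):
            f.create_dataset(f"weights/{k}", data=p)
        f.attrs["manifest"] = json.dumps({
            "n_mus": model.n_mus,
            "grid_shape": list(model.grid_shape),
            "input_scale": model.input_scale,
            "mu_ids": mu_ids or [],
            "config": {
                "conv_filters": model.cfg.conv_filters,
                "conv_kernel": list(model.cfg.conv_kernel),
                "lstm_units": list(model.cfg.lstm_units),
                "lr": model.cfg.lr, "batch": model.cfg.batch,
                "epochs": model.cfg.epochs, "seed": model.cfg.seed,
            },
        })


def load_model(path) -> tuple[ForceNet, list[int]]:
    """Inverse of :func:`save_model`; returns (model, bank mu_ids)."""
    import json

    import h5py

    with h5py.File(path, "r") as f:
        manifest = json.loads(f.attrs["manifest"])
        c = manifest["config"]
        cfg = NetConfig(conv_filters=c["conv_filters"],
                        conv_kernel=tuple(c["conv_kernel"]),
                        lstm_units=tuple(c["lstm_units"]), lr=c["lr"],
                        batch=c["batch"], epochs=c["epochs"], seed=c["seed"])
        model = ForceNet(manifest["n_mus"], cfg,
                         tuple(manifest["grid_shape"]))
        weights = [f[f"weights/{k}"][:] for k in range(len(model.net.params))]
        model.net.set_weights(weights)
        model.input_scale = manifest["input_scale"]
    return model, list(manifest["mu_ids"])


def _window_starts(n_samples: int, fs: float, win_s: float = 0.25,
                   step_s: float = 0.05) -> tuple[np.ndarray, int]:
    win = int(round(win_s * fs))
    step = int(round(step_s * fs))
    starts = np.arange(0, n_samples - win + 1, step)
    return starts, win


class PolynomialBaseline:
    """Quadratic regression of force on a scalar windowed feature."""

    def __init__(self, fs: float):
        self.fs = fs
        self.coeffs: np.ndarray | None = None

    def _features(self, data) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError

    def _windowed(self, data, n_samples: int) -> tuple[np.ndarray, np.ndarray]:
        starts, win = _window_starts(n_samples, self.fs)
        feats = self._features(data, starts, win)
        centers = starts + win // 2
        return feats, centers

    def fit(self, data, force: np.ndarray) -> "PolynomialBaseline":
        n = force.size
        feats, centers = self._windowed(data, n)
        targets = force[centers]
        if np.ptp(feats) == 0:
            raise ValueError("degenerate design matrix: constant feature")
        self.coeffs = np.polyfit(feats, targets, deg=2)
        return self

    def predict(self, data, n_samples: int) -> np.ndarray:
        if self.coeffs is None:
            raise RuntimeError("baseline must be fitted before prediction")
        feats, centers = self._windowed(data, n_samples)
        window_pred = np.polyval(self.coeffs, feats)
        return np.interp(np.arange(n_samples), centers, window_pred)


class FiringRateBaseline(PolynomialBaseline):
    """Summed MU firing count per 250-ms window (50-ms steps) -> quadratic fit."""

    def _features(self, trains: list[SpikeTrain], starts: np.ndarray,
                  win: int) -> np.ndarray:
        all_spikes = np.sort(np.concatenate([t.spikes for t in trains])) \
            if trains else np.empty(0, dtype=np.int64)
        lo = np.searchsorted(all_spikes, starts)
        hi = np.searchsorted(all_spikes, starts + win)
        return (hi - lo).astype(np.float64)


class RmsBaseline(PolynomialBaseline):
    """Per-window RMS amplitude averaged over channels -> quadratic fit."""

    def _features(self, emg: np.ndarray, starts: np.ndarray,
                  win: int) -> np.ndarray:
        feats = np.empty(starts.size)
        for k, s in enumerate(starts):
            seg = emg[s:s + win]
            feats[k] = np.sqrt(np.mean(seg**2, axis=0)).mean()
        return feats


def baseline_fr(trains: list[SpikeTrain], force: np.ndarray,
                fs: float) -> FiringRateBaseline:
    return FiringRateBaseline(fs).fit(trains, force)


def baseline_rms(emg: np.ndarray, force: np.ndarray,
                 fs: float) -> RmsBaseline:
    return RmsBaseline(fs).fit(emg, force)
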