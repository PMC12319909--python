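"""Physics-based inversion: estimating velocity from measured inflow signals.

A 1D convolutional encoder–decoder maps five input channels of length 200
(three demeaned slice inflow signals, the compartment areas, and their
positions) to a velocity time series of 1,000 points spanning the same
wall-clock window. It is trained purely on forward-model simulations (see
:mod:`csflow.training_sampler`), which is what makes the inversion
physics-based: the network never sees measured data during training.

Architecture: three convolution stages with increasing channel width, three
transposed-convolution stages with decreasing width (all kernel 3, padding
1, stride 1, batch norm + ReLU after each), then flatten and two fully
connected layers producing the 1,000-point output. Exact widths are not a
committed part of the method; any setting satisfying the shape contract is
valid and they are exposed in :class:`NetworkConfig`.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
import numpy as np
from scipy.signal import butter, filtfilt, periodogram

from ._nn import (
    Adam,
    BatchNorm1d,
    Conv1d,
    ConvTranspose1d,
    Flatten,
    Linear,
    ReLU,
    Sequential,
    mse_loss,
)
from .flow_kinematics import AreaProfile

__all__ = [
    "NetworkConfig",
    "TrainConfig",
    "build_network",
    "train",
    "predict_velocity",
    "evaluate_prediction",
    "relative_bandpower",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass(frozen=True)
class NetworkConfig:
    in_channels: int = 5
    in_length: int = 200
    out_length: int = 1000
    kernel_size: int = 3
    encoder_widths: tuple[int, ...] = (16, 32, 64)
    decoder_widths: tuple[int, ...] = (32, 16, 8)
    fc_hidden: int = 768
    seed: int = 0

    def __post_init__(self):
        if any(w <= 0 for w in self.encoder_widths + self.decoder_widths):
            raise ValueError("channel widths must be positive")
        if len(self.encoder_widths) != 3 or len(self.decoder_widths) != 3:
            raise ValueError("three encoder and three decoder stages required")


@dataclass(frozen=True)
class TrainConfig:
    batch_size: int = 16
    epochs: int = 120
    learning_rate: float = 1e-3
    test_fraction: float = 0.10
    seed: int = 0

    def __post_init__(self):
        if not (0.0 < self.test_fraction < 1.0):
            raise ValueError("test_fraction must be in (0, 1)")


def build_network(cfg: NetworkConfig | None = None) -> Sequential:
    """Construct the encoder–decoder network with seeded initialization."""
    if cfg is None:
        cfg = NetworkConfig()
    rng = np.random.default_rng(cfg.seed)
    layers = []
    cin = cfg.in_channels
    for w in cfg.encoder_widths:
        layers += [Conv1d(cin, w, cfg.kernel_size, rng), BatchNorm1d(w), ReLU()]
        cin = w
    for w in cfg.decoder_widths:
        layers += [ConvTranspose1d(cin, w, cfg.kernel_size, rng), BatchNorm1d(w), ReLU()]
        cin = w
    layers += [
        Flatten(),
        Linear(cin * cfg.in_length, cfg.fc_hidden, rng),
        ReLU(),
        Linear(cfg.fc_hidden, cfg.out_length, rng),
    ]
    model = Sequential(layers)
    model.net_config = cfg
    return model


def split_dataset(
    n_samples: int, test_fraction: float, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic train/test index split."""
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n_samples)
    n_test = max(1, int(round(test_fraction * n_samples)))
    return perm[n_test:], perm[:n_test]


def train(
    dataset: dict,
    net_cfg: NetworkConfig | None = None,
    train_cfg: TrainConfig | None = None,
    verbose: bool = False,
) -> tuple[Sequential, dict]:
    """Train the inverse network on a simulated dataset.

    ``dataset`` holds ``inputs`` (n, 5, 200) and ``targets`` (n, 1000). Ten
    percent of samples (by seeded index split) are held out and never used
    during optimization; the held-out MSE in (cm/s)² and the per-epoch
    training loss curve are returned as metrics.
    """
    if net_cfg is None:
        net_cfg = NetworkConfig()
    if train_cfg is None:
        train_cfg = TrainConfig()
    x = np.asarray(dataset["inputs"], dtype=np.float32)
    y = np.asarray(dataset["targets"], dtype=np.float32)
    n = x.shape[0]
    if n < 100:
        raise ValueError("dataset must contain at least 100 samples")

    train_idx, test_idx = split_dataset(n, train_cfg.test_fraction, train_cfg.seed)
    model = build_network(net_cfg)
    opt = Adam(model, lr=train_cfg.learning_rate)
    order_rng = np.random.default_rng(train_cfg.seed + 1)

    loss_curve = []
    bs = train_cfg.batch_size
    for epoch in range(train_cfg.epochs):
        perm = order_rng.permutation(train_idx)
        running, nb = 0.0, 0
        for start in range(0, perm.size - bs + 1, bs):
            idx = perm[start:start + bs]
            pred = model.forward(x[idx], training=True)
            loss, grad = mse_loss(pred, y[idx])
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch}, batch {nb}"
                )
            model.backward(grad)
            opt.step()
            running += loss
            nb += 1
        loss_curve.append(running / max(nb, 1))
        if verbose:
            print(f"epoch {epoch + 1}/{train_cfg.epochs}: loss {loss_curve[-1]:.5f}")

    test_mse = _batched_mse(model, x[test_idx], y[test_idx], bs)
    metrics = {
        "loss_curve": np.asarray(loss_curve),
        "test_mse": test_mse,
        "train_indices": train_idx,
        "test_indices": test_idx,
    }
    return model, metrics


def _batched_mse(model, x, y, batch_size):
    se, count = 0.0, 0
    for start in range(0, x.shape[0], batch_size):
        pred = model.forward(x[start:start + batch_size], training=False)
        se += float(np.sum((pred - y[start:start + batch_size]) ** 2))
        count += pred.size
    return se / count


def predict_velocity(
    inflow: np.ndarray,
    profile: AreaProfile,
    model: Sequential,
) -> np.ndarray:
    """Predict a 1,000-point velocity series (cm/s) from 3×200 inflow data.

    The three inflow channels are demeaned internally (predictions are
    invariant to constant channel offsets); the anatomy channels are the
    profile's areas and positions linearly resampled to length 200, with
    x = 0 at the slice-1 bottom.
    """
    inflow = np.asarray(inflow, dtype=np.float32)
    cfg = getattr(model, "net_config", NetworkConfig())
    if inflow.shape != (3, cfg.in_length):
        raise ValueError(f"inflow must have shape (3, {cfg.in_length})")
    inflow = inflow - inflow.mean(axis=1, keepdims=True)
    pos = np.linspace(profile.positions[0], profile.positions[-1], cfg.in_length)
    areas = profile.area(pos)
    x = np.vstack([inflow, areas[None, :], pos[None, :]]).astype(np.float32)
    return model(x[None]).ravel().astype(float)


def lowpass(series: np.ndarray, fs: float, cutoff: float = 0.5, order: int = 5):
    """Zero-phase Butterworth low-pass (forward–backward)."""
    b, a = butter(order, cutoff, btype="low", fs=fs)
    return filtfilt(b, a, series)


def evaluate_prediction(
    pred: np.ndarray,
    reference: np.ndarray,
    fs: float,
    max_shift_s: float = 5.0,
    cutoff: float = 0.5,
) -> float:
    """Aligned mean absolute velocity error (cm/s).

    Both series (sampled at ``fs`` Hz on a common grid) are low-passed below
    ``cutoff``, time-shifted by the lag maximizing their cross-correlation
    (to remove the phase offset of separately acquired runs), and compared by
    mean absolute difference over the overlap.
    """
    pred = np.asarray(pred, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if pred.shape != reference.shape:
        raise ValueError("series must share one grid")
    p = lowpass(pred, fs, cutoff)
    r = lowpass(reference, fs, cutoff)
    tol = 1e-9 * (1.0 + np.abs(p).max() + np.abs(r).max())
    if np.ptp(p) < tol or np.ptp(r) < tol:
        raise ValueError("constant series: cross-correlation alignment undefined")
    pc = p - p.mean()
    rc = r - r.mean()
    max_lag = int(round(max_shift_s * fs))
    full = np.correlate(pc, rc, mode="full")
    lags = np.arange(-pred.size + 1, pred.size)
    window = np.abs(lags) <= max_lag
    lag = int(lags[window][np.argmax(full[window])])
    if lag >= 0:
        a, b = p[lag:], r[:r.size - lag]
    else:
        a, b = p[:lag], r[-lag:]
    return float(np.mean(np.abs(a - b)))


def relative_bandpower(
    series: np.ndarray, fs: float, band: tuple[float, float] = (0.14, 0.19)
) -> float:
    """Fraction of total spectral power inside ``band`` (Hz)."""
    series = np.asarray(series, dtype=float)
    f, p = periodogram(series - series.mean(), fs=fs)
    total = float(np.sum(p))
    if total == 0.0:
        raise ValueError("zero total power")
    sel = (f >= band[0]) & (f <= band[1])
    return float(np.sum(p[sel]) / total)


def save_checkpoint(
    model: Sequential,
    path: str | Path,
    train_cfg: TrainConfig | None = None,
    extra_meta: dict | None = None,
) -> None:
    """Save weights plus network/training config metadata to an .npz file."""
    cfg = getattr(model, "net_config", NetworkConfig())
    meta = {
        "net_config": asdict(cfg),
        "train_config": asdict(train_cfg) if train_cfg else None,
    } | (extra_meta or {})
    state = model.state()
    np.savez(path, __meta__=json.dumps(meta), **state)


def load_checkpoint(path: str | Path) -> tuple[Sequential, dict]:
    with np.load(path, allow_pickle=False) as npz:
        meta = json.loads(str(npz["__meta__"]))
        state = {k: npz[k] for k in npz.files if k != "__meta__"}
    nc = meta["net_config"]
    nc["encoder_widths"] = tuple(nc["encoder_widths"])
    nc["decoder_widths"] = tuple(nc["decoder_widths"])
    model = build_network(NetworkConfig(**nc))
    model.load_state(state)
    return model, meta
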