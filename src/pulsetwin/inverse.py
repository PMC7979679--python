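"""LSTM inverse analysis: reconstruct hidden pressure waveforms from
the three peripheral input waveforms.

One multi-output sequence model maps the per-timestep (carotid,
brachial, femoral) pressures to the pressures at the configured hidden
sites.  Data are split by patient into training (80 %) and testing
(20 %) sets; during training the training set is further split 80/20
into fitting and validation subsets.  Channels are z-scored with
statistics from the training split only.  A reconstruction counts as
accurate when its cycle-averaged absolute error is below 0.5 mmHg.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .database import WaveformDataset
from .nn import LSTMRegressor
from .waveforms import ACCURACY_THRESHOLD_MMHG


@dataclass
class InverseModelConfig:
    """Sequence-model hyperparameters.

    The default ("full" preset) trains 2 x 32 LSTM cells for 1400
    epochs with batches of 300; the "desk" preset keeps the
    architecture and shrinks the schedule for small cohorts.
    """

    n_hidden_layers: int = 2
    cells_per_layer: int = 32
    n_input_channels: int = 3
    batch_size: int = 300
    epochs: int = 1400
    learning_rate: float = 2e-3
    train_fraction: float = 0.8
    validation_fraction: float = 0.2
    seed: int = 0

    @classmethod
    def desk(cls, seed: int = 0) -> "InverseModelConfig":
        return cls(batch_size=32, epochs=600, learning_rate=6e-3, seed=seed)


def split_by_patient(n: int, train_fraction: float, seed: int):
    """Disjoint train/test index arrays over patients."""
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    n_train = int(round(train_fraction * n))
    return np.sort(order[:n_train]), np.sort(order[n_train:])


@dataclass
class ChannelNormalizer:
    """Per-channel z-score with train-split statistics."""

    mean: np.ndarray
    std: np.ndarray

    @classmethod
    def fit(cls, data: np.ndarray) -> "ChannelNormalizer":
        mean = data.mean(axis=(0, 1))
        std = data.std(axis=(0, 1))
        std = np.where(std > 1e-12, std, 1.0)
        return cls(mean=mean, std=std)

    def normalize(self, data: np.ndarray) -> np.ndarray:
        return (data - self.mean) / self.std

    def denormalize(self, data: np.ndarray) -> np.ndarray:
        return data * self.std + self.mean


def build_inverse_model(config: InverseModelConfig,
                        n_output_channels: int = 4) -> LSTMRegressor:
    """Per-timestep 3-channel input -> stacked LSTM -> one dense output
    layer with one channel per target site."""
    return LSTMRegressor(
        n_in=config.n_input_channels, n_out=n_output_channels,
        n_hidden=config.cells_per_layer, n_layers=config.n_hidden_layers,
        seed=config.seed)


@dataclass
class TrainedInverse:
    model: LSTMRegressor
    config: InverseModelConfig
    in_norm: ChannelNormalizer
    out_norm: ChannelNormalizer
    train_idx: np.ndarray
    test_idx: np.ndarray
    history: dict = field(default_factory=dict)
    target_sites: tuple[str, ...] = ()


def train_inverse(dataset: WaveformDataset,
                  config: InverseModelConfig) -> TrainedInverse:
    """Fit the inverse model on the training split; the test patients
    are never touched."""
    if len(dataset) == 0:
        raise ValueError("empty dataset")
    train_idx, test_idx = split_by_patient(
        len(dataset), config.train_fraction, config.seed)
    in_norm = ChannelNormalizer.fit(dataset.X[train_idx])
    out_norm = ChannelNormalizer.fit(dataset.Y[train_idx])
    Xn = in_norm.normalize(dataset.X[train_idx])
    Yn = out_norm.normalize(dataset.Y[train_idx])

    rng = np.random.default_rng(config.seed + 1)
    order = rng.permutation(len(train_idx))
    n_val = int(round(config.validation_fraction * len(train_idx)))
    val_sel, fit_sel = order[:n_val], order[n_val:]

    model = build_inverse_model(config, dataset.Y.shape[2])
    history = model.fit(
        Xn[fit_sel], Yn[fit_sel], epochs=config.epochs,
        batch_size=config.batch_size, lr=config.learning_rate,
        seed=config.seed + 2,
        X_val=Xn[val_sel], Y_val=Yn[val_sel])
    return TrainedInverse(
        model=model, config=config, in_norm=in_norm, out_norm=out_norm,
        train_idx=train_idx, test_idx=test_idx, history=history,
        target_sites=dataset.target_sites)


def predict_waveforms(trained: TrainedInverse, inputs: np.ndarray) -> np.ndarray:
    """Denormalized pressure cycles (mmHg) at the target sites.

    ``inputs``: (B, N, 3) or a single (N, 3) cycle set, raw mmHg.
    """
    X = np.asarray(inputs, dtype=float)
    single = X.ndim == 2
    if single:
        X = X[None]
    if X.shape[2] != trained.config.n_input_channels:
        raise ValueError(
            f"need {trained.config.n_input_channels} input waveforms "
            f"(carotid, brachial, femoral), got {X.shape[2]}")
    Yn = trained.model.predict(trained.in_norm.normalize(X))
    Y = trained.out_norm.denormalize(Yn)
    return Y[0] if single else Y


def evaluate_inverse(trained: TrainedInverse, dataset: WaveformDataset,
                     split: str = "test",
                     threshold_mmhg: float = ACCURACY_THRESHOLD_MMHG):
    """Per-site accuracy report for a split.

    Accuracy at a site is the fraction of patients whose reconstructed
    cycle has mean absolute error below the threshold; the headline
    number is the minimum across sites.
    """
    idx = {"train": trained.train_idx, "test": trained.test_idx,
           "all": np.arange(len(dataset))}[split]
    pred = predict_waveforms(trained, dataset.X[idx])
    err = np.mean(np.abs(pred - dataset.Y[idx]), axis=1)   # (B, M)
    rows = []
    for j, site in enumerate(dataset.target_sites):
        rows.append({
            "site": site, "split": split,
            "accuracy_pct": 100.0 * float(np.mean(err[:, j] < threshold_mmhg)),
            "mean_abs_error_mmhg": float(np.mean(err[:, j])),
        })
    report = pd.DataFrame(rows)
    return report, float(report["accuracy_pct"].min())
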