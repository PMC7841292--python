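"""Layer-wise unsupervised STDP training and the supervised rate readout.

Training is greedy and layer-local: for layer k, the already-trained memory
modules of layers 1..k-1 run in perception mode and layer k's learner module
adapts its kernels by STDP over the whole (shuffled) training set; the
learned kernels are then transferred to layer k's memory module and frozen.
Neuron states reset between sequences so features are order-independent.

After all convolution layers are trained, each sequence is summarized by the
spike frequencies (Hz) of the last layer's memory neurons, and a single
fully connected sigmoid layer -- the multi-objective prediction module's
readout, partitioned into one section per prediction target -- is fit with
mini-batch SGD on binary cross-entropy against concatenated one-hot labels.
The readout is implemented in-repo: it is one linear layer and keeps the
package dependency-light.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .encoding import encode_sequence
from .network import Network
from .synthetic import SequenceSample

__all__ = [
    "TrainSchedule",
    "ReadoutModel",
    "layerwise_train",
    "extract_rate_features",
    "train_readout",
    "predict_readout",
    "predict",
    "fit",
]


@dataclass
class TrainSchedule:
    """Training schedule: per-frame observation time, seeds, readout SGD."""

    t_train: float = 300.0  # ms spent on each frame
    f_max: float = 100.0  # Hz at intensity 1.0
    encode_mode: str = "poisson"
    seed: int = 0
    epochs_per_layer: int = 1
    readout_lr: float = 0.1
    readout_epochs: int = 300
    readout_batch: int = 16

    def __post_init__(self) -> None:
        if self.t_train <= 0:
            raise ValueError("t_train must be positive")


def _sequence_seed(schedule_seed: int, index: int) -> int:
    """Stable per-sequence encoding seed (independent of visit order)."""
    return int(np.random.SeedSequence((schedule_seed, index)).generate_state(1)[0] % (2**31))


def _encode(sample: SequenceSample, schedule: TrainSchedule, seed: int) -> np.ndarray:
    return encode_sequence(
        sample.frames, f_max=schedule.f_max, t_obs=schedule.t_train,
        mode=schedule.encode_mode, seed=seed,
    )


def layerwise_train(
    network: Network,
    dataset: Sequence[SequenceSample],
    schedule: TrainSchedule,
) -> Network:
    """Train all convolution layers greedily with STDP, transferring each
    layer's kernels to its memory module before the next layer starts.

    Lower layers are frozen while an upper layer learns; sequence order is
    reshuffled per layer/epoch from the schedule seed.
    """
    if len(dataset) == 0:
        raise ValueError("dataset must be nonempty")
    rng = np.random.default_rng(schedule.seed)
    for k in range(len(network.layers)):
        for _ in range(schedule.epochs_per_layer):
            order = rng.permutation(len(dataset))
            for idx in order:
                sample = dataset[idx]
                raster = _encode(sample, schedule, _sequence_seed(schedule.seed, int(idx)))
                network.reset_state()
                for t in range(raster.shape[-1]):
                    network.forward_step(raster[None, :, :, t].astype(float), t=float(t), learn_layer=k)
        network.transfer_conductance(k)
    return network


def extract_rate_features(
    network: Network,
    sample: SequenceSample,
    schedule: TrainSchedule,
    seed: Optional[int] = None,
) -> np.ndarray:
    """Spike frequencies (Hz) of the last layer's memory neurons for one
    sequence; deterministic given the encoding seed."""
    seed = schedule.seed if seed is None else seed
    raster = _encode(sample, schedule, seed)
    network.reset_state()
    counts = network.run_perception(raster)
    total_s = raster.shape[-1] / 1000.0
    return counts / total_s


@dataclass
class ReadoutModel:
    """Sigmoid readout, one weight block (plus bias) per objective section."""

    W: np.ndarray  # (n_features + 1, total classes)
    sections: list[tuple[str, int]]
    mu: np.ndarray
    sd: np.ndarray

    def _scores(self, features: np.ndarray) -> np.ndarray:
        X = (np.atleast_2d(features) - self.mu) / self.sd
        X = np.hstack([X, np.ones((X.shape[0], 1))])
        return X @ self.W


def _one_hot(labels: np.ndarray, sections: Sequence[tuple[str, int]]) -> np.ndarray:
    labels = np.atleast_2d(labels)
    if labels.shape[1] != len(sections):
        raise ValueError("need one label column per section")
    blocks = []
    for j, (_, k) in enumerate(sections):
        if np.any(labels[:, j] < 0) or np.any(labels[:, j] >= k):
            raise ValueError(f"labels of section {j} outside [0, {k})")
        Y = np.zeros((labels.shape[0], k))
        Y[np.arange(labels.shape[0]), labels[:, j]] = 1.0
        blocks.append(Y)
    return np.hstack(blocks)


def train_readout(
    features: np.ndarray,
    labels: np.ndarray,
    sections: Sequence[tuple[str, int]],
    lr: float = 0.1,
    epochs: int = 300,
    batch_size: int = 16,
    seed: int = 0,
) -> ReadoutModel:
    """Fit the multi-objective readout with mini-batch SGD on BCE loss.

    ``labels`` holds one integer column per section; targets are the
    concatenated one-hot blocks and every output unit is an independent
    sigmoid (binary cross-entropy), as in conventional SGD training of the
    prediction module.  Features are standardized internally.
    """
    X = np.asarray(features, dtype=float)
    Y = _one_hot(np.asarray(labels, dtype=int), sections)
    n, f = X.shape
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd < 1e-9] = 1.0
    Xs = np.hstack([(X - mu) / sd, np.ones((n, 1))])
    rng = np.random.default_rng(seed)
    W = 0.01 * rng.standard_normal((f + 1, Y.shape[1]))
    for _ in range(epochs):
        order = rng.permutation(n)
        for start in range(0, n, batch_size):
            idx = order[start : start + batch_size]
            z = Xs[idx] @ W
            pred = 1.0 / (1.0 + np.exp(-z))
            grad = Xs[idx].T @ (pred - Y[idx]) / len(idx)
            W -= lr * grad
    return ReadoutModel(W=W, sections=list(sections), mu=mu, sd=sd)


def bce_loss(model: ReadoutModel, features: np.ndarray, labels: np.ndarray) -> float:
    """Mean binary cross-entropy of the readout on a labelled set."""
    Y = _one_hot(np.asarray(labels, dtype=int), model.sections)
    z = model._scores(features)
    # numerically stable log(1+exp)
    return float(np.mean(np.logaddexp(0.0, z) - Y * z))


def predict_readout(model: ReadoutModel, features: np.ndarray) -> np.ndarray:
    """Per-section argmax labels, shape (n_samples, n_sections).

    Sections are independent: each is decided from its own weight block of
    the shared feature vector.
    """
    scores = model._scores(features)
    out = np.zeros((scores.shape[0], len(model.sections)), dtype=int)
    start = 0
    for j, (_, k) in enumerate(model.sections):
        out[:, j] = scores[:, start : start + k].argmax(axis=1)
        start += k
    return out


def predict(
    network: Network,
    model: ReadoutModel,
    sample: SequenceSample,
    schedule: TrainSchedule,
    seed: Optional[int] = None,
) -> np.ndarray:
    """End-to-end per-section prediction for one sequence."""
    feats = extract_rate_features(network, sample, schedule, seed=seed)
    return predict_readout(model, feats)[0]


def fit(
    network: Network,
    train_set: Sequence[SequenceSample],
    sections: Sequence[tuple[str, int]],
    schedule: TrainSchedule,
    label_fields: Sequence[str] = ("class_label", "translation_label"),
) -> tuple[Network, ReadoutModel]:
    """Full pipeline: layer-wise STDP -> transfer -> rate features -> readout."""
    layerwise_train(network, train_set, schedule)
    feats = np.stack([
        extract_rate_features(network, s, schedule, seed=_sequence_seed(schedule.seed, i))
        for i, s in enumerate(train_set)
    ])
    labels = np.array([[getattr(s, f) for f in label_fields] for s in train_set])
    model = train_readout(
        feats, labels, sections,
        lr=schedule.readout_lr, epochs=schedule.readout_epochs,
        batch_size=schedule.readout_batch, seed=schedule.seed,
    )
    return network, model
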