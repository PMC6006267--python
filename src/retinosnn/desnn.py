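"""Rank-order deSNN output stage and cross-validation driver.

The dynamic evolving SNN (deSNN) classifier creates one output neuron
per sample, connected to every reservoir neuron.  A reservoir neuron's
initial weight is ``Mod ** order`` where ``order`` counts neurons by
ascending first-spike time (rank-order coding: earlier spikes carry
more weight).  After its first spike a neuron's weight drifts by
``+Drift`` in each bin where it spikes again and ``-Drift`` where it
stays silent.  Samples are classified by K-nearest-neighbor search
over the resulting weight vectors; no error signal is fed back into
the network.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.metrics import confusion_matrix
from sklearn.model_selection import StratifiedKFold

from .reservoir import Reservoir, STDPConfig, propagate_and_record, run_unsupervised
from .retina import SpikeRaster

__all__ = [
    "DeSNNConfig",
    "OutputNeuron",
    "train_output_neuron",
    "classify",
    "cross_validate",
]

logger = logging.getLogger(__name__)

_METRICS = {"euclidean": "euclidean", "manhattan": "cityblock"}


@dataclass(frozen=True)
class DeSNNConfig:
    """Mod/Drift and KNN parameters (defaults Mod=0.8, Drift=0.005, K=1)."""

    mod: float = 0.8
    drift: float = 0.005
    k_neighbors: int = 1
    distance: str = "euclidean"

    def __post_init__(self) -> None:
        if not 0.0 < self.mod <= 1.0:
            raise ValueError("mod must be in (0, 1]")
        if self.drift < 0:
            raise ValueError("drift must be >= 0")
        if self.k_neighbors < 1:
            raise ValueError("k_neighbors must be >= 1")
        if self.distance not in _METRICS:
            raise ValueError(f"distance must be one of {sorted(_METRICS)}")


@dataclass
class OutputNeuron:
    """One trained output neuron: a weight per reservoir neuron plus label."""

    weights: np.ndarray
    label: object
    sample_id: object = None


def train_output_neuron(
    reservoir_raster: np.ndarray,
    label: object,
    config: DeSNNConfig,
    sample_id: object = None,
) -> OutputNeuron:
    """Rank-order initialization plus drift over one reservoir record.

    ``reservoir_raster`` is the (N x T) boolean spike record of the
    reservoir for one sample.  Neurons that never spike get weight 0
    and no drift.  Ties in first-spike time break by neuron index.
    """
    spikes = np.asarray(reservoir_raster, dtype=bool)
    n, T = spikes.shape
    w = np.zeros(n)
    if T == 0 or not spikes.any():
        logger.warning("sample %r produced no reservoir spikes", sample_id)
        return OutputNeuron(w, label, sample_id)
    ever = spikes.any(axis=1)
    first = np.where(ever, spikes.argmax(axis=1), T)
    ranked = np.lexsort((np.arange(n), first))[: int(ever.sum())]
    w[ranked] = config.mod ** np.arange(len(ranked))
    # Drift bookkeeping over the bins strictly after each first spike.
    spikes_after = spikes.sum(axis=1)[ever] - 1
    bins_after = T - 1 - first[ever]
    w[ever] += config.drift * (2 * spikes_after - bins_after)
    return OutputNeuron(w, label, sample_id)


def classify(
    query_weights: np.ndarray,
    training_set: Sequence[OutputNeuron],
    config: DeSNNConfig,
) -> object:
    """Majority label among the K nearest training weight vectors.

    Ties break by smallest summed distance to the query, then by the
    lowest class id.
    """
    if not training_set:
        raise ValueError("training set is empty")
    query = np.asarray(query_weights, dtype=float)
    X = np.stack([neuron.weights for neuron in training_set])
    if query.shape != X.shape[1:]:
        raise ValueError(f"query dimension {query.shape} != {X.shape[1:]}")
    k = config.k_neighbors
    if k > len(training_set):
        raise ValueError(f"k={k} exceeds training set size {len(training_set)}")
    d = cdist(query[None, :], X, metric=_METRICS[config.distance])[0]
    nearest = np.argsort(d, kind="stable")[:k]
    votes: dict[object, list] = {}
    for idx in nearest:
        lab = training_set[idx].label
        votes.setdefault(lab, [0, 0.0])
        votes[lab][0] += 1
        votes[lab][1] += float(d[idx])
    return min(votes, key=lambda lab: (-votes[lab][0], votes[lab][1], lab))


def cross_validate(
    samples: Sequence[tuple[SpikeRaster, object]],
    reservoir_factory: Callable[[], Reservoir],
    stdp_config: STDPConfig,
    desnn_config: DeSNNConfig,
    n_folds: int = 10,
    seed: int = 0,
) -> dict:
    """Stratified k-fold cross-validation of the full learning stage.

    Each fold builds a fresh reservoir, trains it with STDP on the
    fold's training rasters, re-propagates every raster through the
    frozen network to grow output neurons, and classifies the test
    rasters by KNN.  Returns per-fold accuracies, their mean, and a
    pooled confusion matrix (rows true, columns predicted, classes in
    sorted order).
    """
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    labels = np.array([lab for _, lab in samples])
    classes = sorted(set(labels.tolist()))
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    fold_acc: list[float] = []
    y_true: list[object] = []
    y_pred: list[object] = []
    for fold, (train_idx, test_idx) in enumerate(
        skf.split(np.zeros(len(samples)), labels)
    ):
        missing = set(classes) - set(labels[train_idx].tolist())
        if missing:
            logger.warning("fold %d: classes %s absent from training", fold, missing)
        res = reservoir_factory()
        train_rasters = [samples[i][0] for i in train_idx]
        run_unsupervised(res, train_rasters, stdp_config)
        train_neurons = [
            train_output_neuron(
                propagate_and_record(res, samples[i][0]),
                labels[i],
                desnn_config,
                sample_id=int(i),
            )
            for i in train_idx
        ]
        correct = 0
        for i in test_idx:
            record = propagate_and_record(res, samples[i][0])
            query = train_output_neuron(record, None, desnn_config, sample_id=int(i))
            pred = classify(query.weights, train_neurons, desnn_config)
            y_true.append(labels[i])
            y_pred.append(pred)
            correct += bool(pred == labels[i])
        fold_acc.append(correct / len(test_idx))
    cm = confusion_matrix(y_true, y_pred, labels=classes)
    return {
        "n_folds": n_folds,
        "classes": [str(c) for c in classes],
        "fold_accuracies": fold_acc,
        "mean_accuracy": float(np.mean(fold_acc)),
        "confusion_matrix": cm.tolist(),
    }
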