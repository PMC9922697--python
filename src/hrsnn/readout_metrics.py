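"""Reservoir state extraction, linear readout, and separation metrics.

The state of the network for one stimulus is the vector of output-layer
membrane potentials at the end of the presentation.  Stacking the states of N
stimuli row-wise gives the state matrix F; its 99%-energy effective rank (the
smallest number of leading singular values containing 99% of the singular
value sum) measures the linear separation property of the reservoir.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np
from sklearn.linear_model import LogisticRegression, RidgeClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler

from .engine import (Network, SimulationConfig, SimulationRecord, SpikeTrainSet,
                     reset_states, run_network)
from .exceptions import ShapeError, SpecificationError

__all__ = [
    "StateMatrix",
    "extract_state",
    "build_state_matrix",
    "effective_rank",
    "fit_linear_classifier",
    "classification_accuracy",
    "average_neuronal_activation",
    "count_active_neurons",
]


@dataclass
class StateMatrix:
    """N_stimuli x N_readout final-state matrix with per-row class labels."""

    values: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        self.labels = np.asarray(self.labels)
        if self.labels.size != self.values.shape[0]:
            raise ShapeError("one label per state-matrix row required")

    @property
    def n_stimuli(self) -> int:
        return self.values.shape[0]

    # -- serialization: delimited text with a trailing label column --------
    def to_text(self, path) -> None:
        data = np.column_stack([self.values, self.labels.astype(float)])
        np.savetxt(path, data, delimiter="\t",
                   header=f"n_readout={self.values.shape[1]}")

    @classmethod
    def from_text(cls, path) -> "StateMatrix":
        data = np.loadtxt(path, delimiter="\t", ndmin=2)
        return cls(data[:, :-1], data[:, -1].astype(int))


def extract_state(record: SimulationRecord) -> np.ndarray:
    """Final output-layer membrane potentials of a completed run."""
    state = record.output_membrane_final
    if state is None or state.size == 0:
        raise ShapeError("record has no output layer to read out")
    return np.asarray(state, dtype=float)


def build_state_matrix(network: Network, stimuli: Sequence[SpikeTrainSet],
                       sim: SimulationConfig,
                       labels: Optional[Sequence[int]] = None) -> StateMatrix:
    """One row per stimulus: run, extract the final state, reset.

    Intended for the post-training phase, so a plasticity-on config is
    rejected to avoid silently mutating weights while reading out.
    """
    if sim.plasticity_on:
        raise SpecificationError("state extraction requires plasticity off")
    rows: List[np.ndarray] = []
    for st in stimuli:
        reset_states(network)
        record = run_network(network, st, sim)
        rows.append(extract_state(record))
    reset_states(network)
    if labels is None:
        labels = [getattr(s, "label", -1) for s in stimuli]
    return StateMatrix(np.vstack(rows) if rows else np.zeros((0, network.n_output)),
                       np.asarray(list(labels)))


def effective_rank(F, energy: float = 0.99) -> int:
    """Smallest k with (s_1 + ... + s_k) >= energy * sum(s), singular values descending.

    Accepts a StateMatrix or a plain 2-D array.  An all-zero matrix has rank 0.
    The cumulative comparison is closed (>=) with a tiny relative tolerance so
    an exact-threshold top value counts.
    """
    values = F.values if isinstance(F, StateMatrix) else np.atleast_2d(np.asarray(F, float))
    if values.size == 0:
        return 0
    s = np.linalg.svd(values, compute_uv=False)
    total = s.sum()
    if total <= 0:
        return 0
    target = energy * total - 1e-9 * total
    return int(np.searchsorted(np.cumsum(s), target) + 1)


def fit_linear_classifier(F: StateMatrix, seed: int = 0, reg: float = 1.0,
                          kind: str = "logistic"):
    """Fit a linear decision rule on state rows.

    ``kind='logistic'`` (default) is multinomial logistic regression with L2
    penalty; ``kind='ridge'`` is ridge regression on one-hot labels.  Columns
    are standardized (fitted on the training rows) before the linear model.
    """
    labels = np.asarray(F.labels)
    if np.unique(labels).size < 2:
        raise SpecificationError("need at least two classes to fit a classifier")
    if kind == "logistic":
        clf = LogisticRegression(C=1.0 / reg, max_iter=2000, random_state=seed)
    elif kind == "ridge":
        clf = RidgeClassifier(alpha=reg, random_state=seed)
    else:
        raise SpecificationError(f"unknown classifier kind {kind!r}")
    model = make_pipeline(StandardScaler(), clf)
    model.fit(F.values, labels)
    return model


def classification_accuracy(model, F_test: StateMatrix) -> float:
    """Fraction of rows whose predicted class equals the label."""
    if F_test.n_stimuli == 0:
        raise SpecificationError("empty test set")
    pred = model.predict(F_test.values)
    return float(np.mean(pred == np.asarray(F_test.labels)))


def average_neuronal_activation(spikes: SpikeTrainSet, n_recurrent: int,
                                t_steps: Optional[int] = None) -> float:
    """Total recurrent spike count over all neurons and timesteps, divided by N_R.

    Only events from sources < n_recurrent (the recurrent layer) are counted;
    ``t_steps`` is accepted for interface symmetry but the sum over timesteps
    is simply the event count.
    """
    if n_recurrent <= 0:
        raise SpecificationError("n_recurrent must be positive")
    count = int(np.count_nonzero(spikes.sources < n_recurrent))
    return count / n_recurrent


def count_active_neurons(spikes: SpikeTrainSet, n_recurrent: int) -> int:
    """Distinct recurrent neurons with at least one event."""
    rec = spikes.sources[spikes.sources < n_recurrent]
    return int(np.unique(rec).size)
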