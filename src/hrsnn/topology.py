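"""Network construction: spatial placement and the three synapse sets.

The recurrent layer lives on a 3-D integer lattice.  Recurrent synapses are
drawn pairwise-independently with the distance-dependent probability

    P(i, j) = C * exp(-(D(i, j) / lambda)**2)

where C depends on the (pre-type, post-type) class in {EE, EI, IE, II}.
Input projections target a fixed random 30% subset of the recurrent layer
with uniform probability P_IR; output neurons tap a random subset of the
recurrent layer through fixed, non-plastic weights.

Sign convention (Dale's law): every synapse whose pre-neuron is excitatory
carries a non-negative weight, inhibitory pre-neurons carry non-positive
weights.  Plasticity operates on weight magnitudes so the convention is
preserved under learning.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np
from scipy.spatial.distance import cdist

from .exceptions import ConfigurationError, SpecificationError
from .lif_core import NeuronPopulation

__all__ = [
    "NetworkConfig",
    "SynapseSet",
    "place_neurons_on_grid",
    "connection_probability",
    "build_recurrent_synapses",
    "build_input_synapses",
    "build_output_taps",
    "default_grid_shape",
]

# Per-class connection amplitudes; configurable, following common
# liquid-state-machine practice.
DEFAULT_C_BY_TYPE: Dict[str, float] = {"EE": 0.3, "EI": 0.2, "IE": 0.4, "II": 0.1}

INPUT_TARGET_FRACTION = 0.3
OUTPUT_TAP_FRACTION = 0.1


@dataclass
class SynapseSet:
    """Sparse directed weighted connections of one class.

    ``synapse_class`` is one of {"input", "recurrent", "output"} and applies
    to every synapse in the set, as does the ``plastic`` flag.
    """

    pre_index: np.ndarray
    post_index: np.ndarray
    weight: np.ndarray
    synapse_class: str
    plastic: bool
    sign: Optional[np.ndarray] = None  # persistent Dale sign; inferred from weights if omitted

    def __post_init__(self) -> None:
        self.pre_index = np.asarray(self.pre_index, dtype=np.int64)
        self.post_index = np.asarray(self.post_index, dtype=np.int64)
        self.weight = np.asarray(self.weight, dtype=float)
        if not (self.pre_index.size == self.post_index.size == self.weight.size):
            raise SpecificationError("synapse arrays must share one length")
        if self.sign is None:
            self.sign = np.where(self.weight < 0, -1.0, 1.0)
        else:
            self.sign = np.asarray(self.sign, dtype=float)
            if self.sign.size != self.weight.size:
                raise SpecificationError("sign array must match the synapse count")

    @property
    def size(self) -> int:
        return self.pre_index.size

    def copy(self) -> "SynapseSet":
        return SynapseSet(self.pre_index.copy(), self.post_index.copy(),
                          self.weight.copy(), self.synapse_class, self.plastic,
                          sign=self.sign.copy())

    # -- serialization: 4-column edge list ---------------------------------
    def to_edge_list(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# class={self.synapse_class} plastic={int(self.plastic)}\n")
            fh.write("pre\tpost\tweight\tclass\n")
            for p, q, w in zip(self.pre_index, self.post_index, self.weight):
                fh.write(f"{int(p)}\t{int(q)}\t{float(w)!r}\t{self.synapse_class}\n")

    @classmethod
    def from_edge_list(cls, path) -> "SynapseSet":
        with open(path) as fh:
            header = fh.readline().strip()
            meta = dict(tok.split("=") for tok in header.lstrip("# ").split())
            fh.readline()  # column header
            rows = [line.split("\t") for line in fh if line.strip()]
        pre = np.array([int(r[0]) for r in rows], dtype=np.int64)
        post = np.array([int(r[1]) for r in rows], dtype=np.int64)
        w = np.array([float(r[2]) for r in rows])
        return cls(pre, post, w, meta["class"], bool(int(meta["plastic"])))


def default_grid_shape(n: int) -> Tuple[int, int, int]:
    """Most-cubic integer box with capacity >= n."""
    if n <= 0:
        raise ConfigurationError("grid must hold at least one neuron")
    a = max(1, round(n ** (1 / 3)))
    while a > 1 and a * a * a > 4 * n:
        a -= 1
    b = max(1, int(np.ceil(np.sqrt(n / a))))
    c = int(np.ceil(n / (a * b)))
    return (a, b, c)


@dataclass
class NetworkConfig:
    """Structural hyperparameters of the three-layer network."""

    n_input: int
    n_recurrent: int = 500
    n_output: int = 50
    ei_ratio: Tuple[int, int] = (4, 1)
    grid_shape: Optional[Tuple[int, int, int]] = None
    C_by_type: Dict[str, float] = field(default_factory=lambda: dict(DEFAULT_C_BY_TYPE))
    lambda_conn: float = 2.0
    P_IR: float = 0.3
    W_scale: float = 1.0
    input_w_scale: float = 1.0
    output_tap_fraction: float = OUTPUT_TAP_FRACTION
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lambda_conn <= 0 or self.W_scale <= 0:
            raise SpecificationError("lambda_conn and W_scale must be positive")
        if not (0.0 <= self.P_IR <= 1.0):
            raise SpecificationError("P_IR must lie in [0, 1]")
        for key, c in self.C_by_type.items():
            if not (0.0 <= c <= 1.0):
                raise SpecificationError(f"C_by_type[{key}] must lie in [0, 1]")
        if self.grid_shape is None:
            self.grid_shape = default_grid_shape(self.n_recurrent)
        if int(np.prod(self.grid_shape)) < self.n_recurrent:
            raise ConfigurationError("grid capacity below n_recurrent")

    @property
    def n_excitatory(self) -> int:
        e, i = self.ei_ratio
        return round(self.n_recurrent * e / (e + i))

    @property
    def n_inhibitory(self) -> int:
        return self.n_recurrent - self.n_excitatory


def place_neurons_on_grid(n: int, grid_shape: Tuple[int, int, int],
                          seed: int) -> np.ndarray:
    """Assign ``n`` distinct integer lattice sites uniformly without replacement."""
    capacity = int(np.prod(grid_shape))
    if capacity < n:
        raise ConfigurationError(f"grid {grid_shape} cannot hold {n} neurons")
    rng = np.random.default_rng(seed)
    flat = rng.choice(capacity, size=n, replace=False)
    return np.stack(np.unravel_index(flat, grid_shape), axis=1).astype(float)


def connection_probability(d, C: float, lam: float):
    """Distance-dependent connection probability C*exp(-(d/lam)^2), clamped to [0,1]."""
    if lam <= 0:
        raise SpecificationError("lam must be positive")
    if not (0.0 <= C <= 1.0):
        raise SpecificationError("C must lie in [0, 1]")
    d = np.asarray(d, dtype=float)
    p = np.clip(C * np.exp(-((d / lam) ** 2)), 0.0, 1.0)
    return float(p) if p.ndim == 0 else p


def build_recurrent_synapses(pop: NeuronPopulation, config: NetworkConfig,
                             seed: Optional[int] = None) -> SynapseSet:
    """Draw the recurrent synapse set from the distance-dependent law.

    Each ordered pair (i, j), i != j, connects independently with probability
    ``C_by_type[(type_i, type_j)] * exp(-(D(i,j)/lambda)^2)``.  Initial weight
    magnitudes are |Normal(0,1)| * W_scale; the sign follows the pre-neuron
    type.  All recurrent synapses are plastic.
    """
    if pop.position is None:
        raise ConfigurationError("population must be placed on a grid first")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = pop.size
    dist = cdist(pop.position, pop.position)
    exc = pop.is_excitatory
    type_char = np.where(exc, "E", "I")
    amp = np.empty((n, n))
    for pre_t in ("E", "I"):
        for post_t in ("E", "I"):
            mask = np.outer(type_char == pre_t, type_char == post_t)
            amp[mask] = config.C_by_type[pre_t + post_t]
    prob = amp * np.exp(-((dist / config.lambda_conn) ** 2))
    np.fill_diagonal(prob, 0.0)
    mask = rng.random((n, n)) < prob
    pre, post = np.nonzero(mask)
    magnitude = np.abs(rng.standard_normal(pre.size)) * config.W_scale
    sign = np.where(exc[pre], 1.0, -1.0)
    return SynapseSet(pre, post, sign * magnitude, "recurrent", plastic=True,
                      sign=sign)


def input_target_subset(n_recurrent: int, seed: int) -> np.ndarray:
    """The fixed random subset of recurrent neurons targeted by the input layer."""
    n_targets = round(INPUT_TARGET_FRACTION * n_recurrent)
    rng = np.random.default_rng(seed)
    return np.sort(rng.choice(n_recurrent, size=n_targets, replace=False))


def build_input_synapses(n_input: int, pop: NeuronPopulation, P_IR: float,
                         seed: int, w_scale: float = 1.0) -> SynapseSet:
    """Connect encoding neurons to a fixed 30% target subset of R.

    The target subset of exactly ``round(0.3 * N_R)`` neurons is drawn once
    per network; each (encoding neuron, target) pair then connects with
    uniform probability ``P_IR``.  Encoding neurons are excitatory, so all
    weights are positive; the synapses are plastic.
    """
    if n_input < 1:
        raise SpecificationError("n_input must be at least 1")
    if not (0.0 <= P_IR <= 1.0):
        raise SpecificationError("P_IR must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    targets = np.sort(rng.choice(pop.size, size=round(INPUT_TARGET_FRACTION * pop.size),
                                 replace=False))
    mask = rng.random((n_input, targets.size)) < P_IR
    pre, tcol = np.nonzero(mask)
    post = targets[tcol]
    weight = np.abs(rng.standard_normal(pre.size)) * w_scale
    return SynapseSet(pre, post, weight, "input", plastic=True)


def build_output_taps(pop: NeuronPopulation, n_output: int, seed: int,
                      fraction: float = OUTPUT_TAP_FRACTION,
                      weight: float = 1.0) -> SynapseSet:
    """Fixed-weight, non-plastic projections from random subsets of R to O.

    Each output neuron taps ``round(fraction * N_R)`` distinct recurrent
    neurons.  Weight magnitude is a shared constant; sign follows the
    pre-neuron type so Dale's law holds for the tap set as well.
    """
    if n_output < 0:
        raise SpecificationError("n_output must be non-negative")
    if n_output == 0:
        empty = np.zeros(0, dtype=np.int64)
        return SynapseSet(empty, empty, np.zeros(0), "output", plastic=False)
    if not (0.0 < fraction <= 1.0):
        raise SpecificationError("fraction must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    n_taps = max(1, round(fraction * pop.size))
    pre_list = []
    post_list = []
    for o in range(n_output):
        sources = rng.choice(pop.size, size=n_taps, replace=False)
        pre_list.append(sources)
        post_list.append(np.full(n_taps, o, dtype=np.int64))
    pre = np.concatenate(pre_list)
    post = np.concatenate(post_list)
    sign = np.where(pop.is_excitatory[pre], 1.0, -1.0)
    return SynapseSet(pre, post, sign * float(weight), "output", plastic=False,
                      sign=sign)
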