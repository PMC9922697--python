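"""Trace-based STDP with per-synapse heterogeneous constants.

Each synapse carries a pre-synaptic trace T_pre and a post-synaptic trace
T_post that decay exponentially (time constants tau_plus / tau_minus) and jump
by a_plus / a_minus on pre / post spikes.  Weight updates are event-driven:

    on a post spike:  |w| += A_plus  * T_pre     (potentiation, causal pairs)
    on a pre  spike:  |w| -= A_minus * T_post    (depression, anti-causal pairs)

Weight magnitudes are clipped to [0, w_max]; the sign of a synapse never
changes (Dale's law), so inhibitory weights move in mirrored sign.

Heterogeneity enters through gamma distributions over (A_plus, A_minus,
tau_plus, tau_minus); a_plus and a_minus stay scalar.  CV = 0 everywhere
reproduces standard homogeneous pair-based STDP.

Within a single dt that contains both a pre and a post spike the order is:
decay traces, apply both trace increments, then potentiation before
depression, which pins the closed-form pair window at delta_t = 0 to
``A_plus*a_plus - A_minus*a_minus``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .exceptions import SpecificationError
from .lif_core import GammaSpec
from .topology import SynapseSet

__all__ = [
    "STDPParameters",
    "TraceState",
    "STDPHeterogeneityConfig",
    "sample_stdp_parameters",
    "update_traces",
    "apply_stdp_update",
    "pair_delta_w_closed_form",
]

DEFAULT_W_MAX = 1.0


@dataclass
class STDPParameters:
    """Per-synapse STDP constants (scalars broadcast on construction)."""

    A_plus: np.ndarray
    A_minus: np.ndarray
    a_plus: np.ndarray
    a_minus: np.ndarray
    tau_plus: np.ndarray
    tau_minus: np.ndarray

    def __post_init__(self) -> None:
        names = ("A_plus", "A_minus", "a_plus", "a_minus", "tau_plus", "tau_minus")
        arrays = {k: np.atleast_1d(np.asarray(getattr(self, k), dtype=float)) for k in names}
        n = max(arr.size for arr in arrays.values())
        for k, arr in arrays.items():
            if arr.size == 1:
                arr = np.full(n, arr[0])
            elif arr.size != n:
                raise SpecificationError("STDPParameters arrays must share one length")
            setattr(self, k, arr)
        for k in ("A_plus", "A_minus", "a_plus", "a_minus"):
            if np.any(getattr(self, k) < 0):
                raise SpecificationError(f"{k} must be non-negative")
        for k in ("tau_plus", "tau_minus"):
            if np.any(getattr(self, k) <= 0):
                raise SpecificationError(f"{k} must be positive")

    @property
    def size(self) -> int:
        return self.A_plus.size


@dataclass
class TraceState:
    """Per-synapse pre/post trace variables (non-negative)."""

    t_pre: np.ndarray
    t_post: np.ndarray

    def __post_init__(self) -> None:
        self.t_pre = np.asarray(self.t_pre, dtype=float)
        self.t_post = np.asarray(self.t_post, dtype=float)
        if self.t_pre.size != self.t_post.size:
            raise SpecificationError("trace arrays must share one length")

    @classmethod
    def zeros(cls, n: int) -> "TraceState":
        return cls(np.zeros(n), np.zeros(n))

    def reset(self) -> None:
        self.t_pre[:] = 0.0
        self.t_post[:] = 0.0


@dataclass(frozen=True)
class STDPHeterogeneityConfig:
    """Gamma specs for the heterogeneous STDP constants.

    Heterogeneity is carried by the scaling constants (A_plus, A_minus) and
    the decay time constants (tau_plus, tau_minus); the trace increments stay
    at a_plus = a_minus = 1.
    """

    A_plus_spec: GammaSpec = GammaSpec(5e-3, 0.5)
    A_minus_spec: GammaSpec = GammaSpec(5e-3, 0.5)
    tau_plus_spec: GammaSpec = GammaSpec(20.0, 0.5)
    tau_minus_spec: GammaSpec = GammaSpec(20.0, 0.5)
    a_plus: float = 1.0
    a_minus: float = 1.0

    def homogeneous(self) -> "STDPHeterogeneityConfig":
        from dataclasses import replace
        return replace(
            self,
            A_plus_spec=self.A_plus_spec.with_cv(0.0),
            A_minus_spec=self.A_minus_spec.with_cv(0.0),
            tau_plus_spec=self.tau_plus_spec.with_cv(0.0),
            tau_minus_spec=self.tau_minus_spec.with_cv(0.0),
        )


def sample_stdp_parameters(config: STDPHeterogeneityConfig, n_synapses: int,
                           seed: int) -> STDPParameters:
    """Per-synapse draws from the four gamma specs; deterministic under seed."""
    if n_synapses < 0:
        raise SpecificationError("n_synapses must be non-negative")
    rng = np.random.default_rng(seed)
    return STDPParameters(
        A_plus=config.A_plus_spec.sample(n_synapses, rng),
        A_minus=config.A_minus_spec.sample(n_synapses, rng),
        a_plus=np.full(n_synapses, config.a_plus),
        a_minus=np.full(n_synapses, config.a_minus),
        tau_plus=config.tau_plus_spec.sample(n_synapses, rng),
        tau_minus=config.tau_minus_spec.sample(n_synapses, rng),
    )


def update_traces(state: TraceState, pre_spiked: np.ndarray, post_spiked: np.ndarray,
                  params: STDPParameters, dt: float,
                  decay_pre: np.ndarray = None, decay_post: np.ndarray = None) -> TraceState:
    """Decay both traces by exp(-dt/tau), then add spike increments in place.

    ``pre_spiked`` / ``post_spiked`` are per-synapse boolean masks (the caller
    gathers neuron-level spikes through the synapse index arrays).  The decay
    factors may be passed in precomputed for speed.
    """
    if dt <= 0:
        raise SpecificationError("dt must be positive")
    if decay_pre is None:
        decay_pre = np.exp(-dt / params.tau_plus)
    if decay_post is None:
        decay_post = np.exp(-dt / params.tau_minus)
    state.t_pre *= decay_pre
    state.t_post *= decay_post
    if pre_spiked.any():
        state.t_pre[pre_spiked] += params.a_plus[pre_spiked]
    if post_spiked.any():
        state.t_post[post_spiked] += params.a_minus[post_spiked]
    return state


def apply_stdp_update(synapses: SynapseSet, state: TraceState, pre_spiked: np.ndarray,
                      post_spiked: np.ndarray, params: STDPParameters, dt: float,
                      w_max: float = DEFAULT_W_MAX) -> SynapseSet:
    """Event-driven weight update on magnitudes, preserving each synapse's sign.

    Must be called after :func:`update_traces` for the same step.  Potentiation
    (post spikes) is applied before depression (pre spikes); magnitudes are
    clipped to [0, w_max].
    """
    if not (pre_spiked.any() or post_spiked.any()):
        return synapses
    sign = synapses.sign
    mag = np.abs(synapses.weight)
    if post_spiked.any():
        mag[post_spiked] += params.A_plus[post_spiked] * state.t_pre[post_spiked]
    if pre_spiked.any():
        mag[pre_spiked] -= params.A_minus[pre_spiked] * state.t_post[pre_spiked]
    np.clip(mag, 0.0, w_max, out=mag)
    synapses.weight = sign * mag
    return synapses


def pair_delta_w_closed_form(delta_t: float, params: STDPParameters,
                             index: int = 0) -> float:
    """Closed-form weight change for one isolated pre/post pair.

    ``delta_t = t_post - t_pre``.  Positive lags potentiate with
    ``A_plus*a_plus*exp(-delta_t/tau_plus)``, negative lags depress with
    ``-A_minus*a_minus*exp(delta_t/tau_minus)``; at delta_t = 0 the
    simultaneous-update convention yields ``A_plus*a_plus - A_minus*a_minus``.
    """
    ap = float(params.A_plus[index]) * float(params.a_plus[index])
    am = float(params.A_minus[index]) * float(params.a_minus[index])
    if delta_t > 0:
        return ap * math.exp(-delta_t / float(params.tau_plus[index]))
    if delta_t < 0:
        return -am * math.exp(delta_t / float(params.tau_minus[index]))
    return ap - am
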