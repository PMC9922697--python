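"""Leaky integrate-and-fire dynamics and gamma-distributed parameter heterogeneity.

The membrane potential of each neuron follows

    tau_m * dv/dt = a + R_m * I - v

with a hard threshold: when ``v > v_threshold`` the neuron emits a spike, the
membrane is reset to ``v_reset`` and held there for the refractory period.
Integration uses the exponential-Euler update, which is exact for
piecewise-constant input current.

Per-neuron heterogeneity is expressed through :class:`GammaSpec`, a gamma
distribution parameterized by its mean and coefficient of variation (CV).
CV = 0 denotes the degenerate (homogeneous) case where every draw equals the
mean, so a homogeneous network is the CV -> 0 limit of a heterogeneous one.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Optional

import numpy as np
from scipy import stats

from .exceptions import ConfigurationError, SpecificationError

__all__ = [
    "GammaSpec",
    "LIFParameters",
    "NeuronPopulation",
    "HeterogeneityConfig",
    "sample_lif_parameters",
    "lif_step",
    "analytic_first_spike_time",
]


@dataclass(frozen=True)
class GammaSpec:
    """Gamma distribution given by (mean, coefficient of variation).

    For CV > 0 the shape is ``k = 1/CV**2`` and the scale ``theta = mean*CV**2``
    so that ``k*theta == mean``.  CV = 0 is the point mass at ``mean``.
    """

    mean: float
    cv: float = 0.0

    def __post_init__(self) -> None:
        if not (self.mean > 0):
            raise SpecificationError(f"GammaSpec mean must be positive, got {self.mean}")
        if self.cv < 0:
            raise SpecificationError(f"GammaSpec cv must be non-negative, got {self.cv}")
        if 0 < self.cv < 1e-9:  # numerically degenerate
            object.__setattr__(self, "cv", 0.0)

    @property
    def shape(self) -> float:
        if self.cv == 0:
            return math.inf
        return 1.0 / self.cv**2

    @property
    def scale(self) -> float:
        if self.cv == 0:
            return 0.0
        return self.mean * self.cv**2

    @property
    def variance(self) -> float:
        return (self.mean * self.cv) ** 2

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw ``n`` values; degenerate (CV = 0) specs return a constant array."""
        if n < 0:
            raise SpecificationError("sample size must be non-negative")
        if self.cv == 0:
            return np.full(n, self.mean, dtype=float)
        return rng.gamma(self.shape, self.scale, size=n)

    def quantiles(self, u: np.ndarray) -> np.ndarray:
        """Quantile function evaluated at probabilities ``u`` in (0, 1)."""
        u = np.asarray(u, dtype=float)
        if self.cv == 0:
            return np.full(u.shape, self.mean, dtype=float)
        return stats.gamma.ppf(u, a=self.shape, scale=self.scale)

    def quantile_grid(self, n: int) -> np.ndarray:
        """Quantiles on the midpoint grid ((i+0.5)/n); cached, read-only."""
        if self.cv == 0:
            return np.full(n, self.mean, dtype=float)
        return _gamma_ppf_cached(self.shape, self.scale, n)

    def with_cv(self, cv: float) -> "GammaSpec":
        return replace(self, cv=cv)


@lru_cache(maxsize=4096)
def _gamma_ppf_cached(shape: float, scale: float, n: int) -> np.ndarray:
    u = (np.arange(n) + 0.5) / n
    q = stats.gamma.ppf(u, a=shape, scale=scale)
    q.setflags(write=False)
    return q


@dataclass
class LIFParameters:
    """Per-neuron LIF parameter arrays (scalars broadcast on construction)."""

    tau_m: np.ndarray
    r_m: np.ndarray
    a: np.ndarray
    v_threshold: np.ndarray
    v_reset: np.ndarray
    refractory: np.ndarray

    def __post_init__(self) -> None:
        arrays = {k: np.atleast_1d(np.asarray(getattr(self, k), dtype=float))
                  for k in ("tau_m", "r_m", "a", "v_threshold", "v_reset", "refractory")}
        n = max(arr.size for arr in arrays.values())
        for k, arr in arrays.items():
            if arr.size == 1:
                arr = np.full(n, arr[0])
            elif arr.size != n:
                raise SpecificationError("LIFParameters arrays must share one length")
            setattr(self, k, arr)
        if np.any(self.tau_m <= 0):
            raise SpecificationError("tau_m must be positive")
        if np.any(self.refractory < 0):
            raise SpecificationError("refractory must be non-negative")
        if np.any(self.v_reset >= self.v_threshold):
            raise SpecificationError("v_reset must be below v_threshold")

    @property
    def size(self) -> int:
        return self.tau_m.size

    def copy(self) -> "LIFParameters":
        return LIFParameters(**{k: getattr(self, k).copy() for k in
                                ("tau_m", "r_m", "a", "v_threshold", "v_reset", "refractory")})


@dataclass
class NeuronPopulation:
    """A population of LIF neurons with shared state arrays.

    ``spiking=False`` turns the population into pure leaky integrators whose
    membrane never resets; this is how the output (decoding) layer is modelled.
    """

    params: LIFParameters
    is_excitatory: np.ndarray
    position: Optional[np.ndarray] = None
    spiking: bool = True
    membrane: np.ndarray = field(init=False)
    refractory_until: np.ndarray = field(init=False)
    t: float = field(init=False, default=0.0)

    def __post_init__(self) -> None:
        self.is_excitatory = np.asarray(self.is_excitatory, dtype=bool)
        if self.is_excitatory.size != self.params.size:
            raise SpecificationError("is_excitatory length must match parameter arrays")
        if self.position is not None:
            self.position = np.asarray(self.position, dtype=float)
            if self.position.shape != (self.size, 3):
                raise SpecificationError("position must be (n, 3)")
        self.membrane = self.params.a.copy()
        self.refractory_until = np.zeros(self.size)

    @property
    def size(self) -> int:
        return self.params.size

    @property
    def n_excitatory(self) -> int:
        return int(self.is_excitatory.sum())

    @property
    def n_inhibitory(self) -> int:
        return int((~self.is_excitatory).sum())

    def reset(self) -> None:
        """Membrane back to rest, refractory clocks and the clock cleared."""
        self.membrane = self.params.a.copy()
        self.refractory_until = np.zeros(self.size)
        self.t = 0.0

    # -- serialization -----------------------------------------------------
    def to_npz(self, path) -> None:
        np.savez(
            path,
            tau_m=self.params.tau_m, r_m=self.params.r_m, a=self.params.a,
            v_threshold=self.params.v_threshold, v_reset=self.params.v_reset,
            refractory=self.params.refractory,
            is_excitatory=self.is_excitatory,
            position=(self.position if self.position is not None else np.zeros((0, 3))),
            spiking=np.array([self.spiking]),
        )

    @classmethod
    def from_npz(cls, path) -> "NeuronPopulation":
        with np.load(path) as f:
            params = LIFParameters(
                tau_m=f["tau_m"], r_m=f["r_m"], a=f["a"],
                v_threshold=f["v_threshold"], v_reset=f["v_reset"],
                refractory=f["refractory"],
            )
            position = f["position"] if f["position"].size else None
            return cls(params=params, is_excitatory=f["is_excitatory"],
                       position=position, spiking=bool(f["spiking"][0]))


@dataclass(frozen=True)
class HeterogeneityConfig:
    """Distributions for the heterogeneous LIF parameters.

    Excitatory membrane time constants are drawn from ``tau_m_E`` and
    inhibitory ones from ``tau_m_I``; biologically the excitatory mean is the
    larger of the two, which is enforced unless ``allow_reversed`` is set.
    Threshold heterogeneity is supported through ``v_threshold_spec`` but
    degenerate (None) by default.
    """

    tau_m_E: GammaSpec = GammaSpec(20.0, 0.5)
    tau_m_I: GammaSpec = GammaSpec(10.0, 0.5)
    v_threshold_spec: Optional[GammaSpec] = None
    allow_reversed: bool = False
    tau_floor: float = 2.0  # ms; keeps every draw integrable at the default dt
    threshold_floor: float = 0.3  # lower clip on sampled thresholds
    # tau_m = R_m * C_m with a shared membrane capacitance: R_m co-varies with
    # tau_m (normalized to the excitatory mean), so a spike injects the same
    # charge-response in every neuron and heterogeneity acts on timescales only
    constant_capacitance: bool = True

    def __post_init__(self) -> None:
        if not self.allow_reversed and self.tau_m_E.mean <= self.tau_m_I.mean:
            raise SpecificationError(
                "excitatory tau_m mean must exceed inhibitory mean "
                "(set allow_reversed=True to override)")

    def homogeneous(self) -> "HeterogeneityConfig":
        """Degenerate counterpart: tau CVs zeroed, uniform baseline threshold."""
        return replace(
            self,
            tau_m_E=self.tau_m_E.with_cv(0.0),
            tau_m_I=self.tau_m_I.with_cv(0.0),
            v_threshold_spec=None,
        )


# Default electrical constants (normalized units, overridable per call).
DEFAULT_A = 0.0
DEFAULT_V_RESET = 0.0
DEFAULT_V_THRESHOLD = 1.0
DEFAULT_REFRACTORY = 2.0
DEFAULT_R_M = 1.0


def sample_lif_parameters(
    config: HeterogeneityConfig,
    n_exc: int,
    n_inh: int,
    seed: int,
    *,
    a: float = DEFAULT_A,
    v_reset: float = DEFAULT_V_RESET,
    v_threshold: float = DEFAULT_V_THRESHOLD,
    refractory: float = DEFAULT_REFRACTORY,
    r_m: float = DEFAULT_R_M,
) -> NeuronPopulation:
    """Sample a population of ``n_exc + n_inh`` neurons from ``config``.

    Excitatory neurons come first in all arrays.  Deterministic under ``seed``.
    """
    if n_exc < 0 or n_inh < 0:
        raise SpecificationError("neuron counts must be non-negative")
    rng = np.random.default_rng(seed)
    n = n_exc + n_inh
    tau = np.concatenate([config.tau_m_E.sample(n_exc, rng),
                          config.tau_m_I.sample(n_inh, rng)])
    if config.tau_floor > 0:
        np.maximum(tau, config.tau_floor, out=tau)
    if config.v_threshold_spec is not None:
        v_th = config.v_threshold_spec.sample(n, rng)
        floor = max(config.threshold_floor, v_reset + 1e-6 * max(abs(v_threshold), 1.0))
        np.maximum(v_th, floor, out=v_th)
    else:
        v_th = np.full(n, float(v_threshold))
    if config.constant_capacitance:
        r_m_arr = float(r_m) * tau / config.tau_m_E.mean
    else:
        r_m_arr = np.full(n, float(r_m))
    params = LIFParameters(
        tau_m=tau,
        r_m=r_m_arr,
        a=np.full(n, float(a)),
        v_threshold=v_th,
        v_reset=np.full(n, float(v_reset)),
        refractory=np.full(n, float(refractory)),
    )
    is_exc = np.zeros(n, dtype=bool)
    is_exc[:n_exc] = True
    return NeuronPopulation(params=params, is_excitatory=is_exc)


def lif_step(pop: NeuronPopulation, input_current: np.ndarray, dt: float) -> np.ndarray:
    """Advance the population by one step of length ``dt``; return spike mask.

    Exponential-Euler: v <- v_inf + (v - v_inf)*exp(-dt/tau) with
    v_inf = a + R_m*I held constant over the step.  Refractory neurons are
    clamped at v_reset and ignore input.  Threshold crossing is strict
    (v > v_threshold), detected at step end.
    """
    if dt <= 0:
        raise ConfigurationError("dt must be positive")
    if dt > float(np.min(pop.params.tau_m)) / 2.0:
        raise ConfigurationError(
            f"dt={dt} violates the stability guard dt <= min(tau_m)/2")
    current = np.broadcast_to(np.asarray(input_current, dtype=float), (pop.size,))
    p = pop.params
    active = pop.t >= pop.refractory_until - 1e-12
    v_inf = p.a + p.r_m * current
    decay = np.exp(-dt / p.tau_m)
    v_new = np.where(active, v_inf + (pop.membrane - v_inf) * decay, p.v_reset)
    if pop.spiking:
        spiked = active & (v_new > p.v_threshold)
        if spiked.any():
            v_new = np.where(spiked, p.v_reset, v_new)
            pop.refractory_until[spiked] = pop.t + dt + p.refractory[spiked]
    else:
        spiked = np.zeros(pop.size, dtype=bool)
    pop.membrane = v_new
    pop.t += dt
    return spiked


def analytic_first_spike_time(params: LIFParameters, constant_current: float,
                              index: int = 0) -> float:
    """Closed-form first-spike time under constant current, starting at v = a.

    Returns ``t* = tau_m * ln(R_m*I / (a + R_m*I - v_threshold))`` when the
    steady state exceeds threshold, else ``math.inf`` ("never").
    """
    tau = float(params.tau_m[index])
    r_m = float(params.r_m[index])
    a = float(params.a[index])
    v_th = float(params.v_threshold[index])
    drive = r_m * float(constant_current)
    if a + drive <= v_th:
        return math.inf
    return tau * math.log(drive / (a + drive - v_th))
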