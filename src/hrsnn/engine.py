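"""Clock-driven simulation of the full input -> recurrent -> output network.

Within each step of length dt: spikes produced at the previous step (and the
external input events falling in the current bin) are delivered as
instantaneous current increments weight/dt onto their post-neurons; both
populations take one LIF step; if plasticity is on, the traces and weights of
the plastic synapse sets are updated with the current-step spike masks.
Output-layer neurons are non-spiking leaky integrators by default — their
final membrane potential is the state read out downstream — and their
activity never feeds back.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional

import numpy as np

from .exceptions import ShapeError, SpecificationError
from .lif_core import (DEFAULT_R_M, HeterogeneityConfig, LIFParameters,
                       NeuronPopulation, lif_step, sample_lif_parameters)
from .plasticity import (DEFAULT_W_MAX, STDPHeterogeneityConfig, STDPParameters,
                         TraceState, apply_stdp_update, sample_stdp_parameters,
                         update_traces)
from .topology import (NetworkConfig, SynapseSet, build_input_synapses,
                       build_output_taps, build_recurrent_synapses,
                       place_neurons_on_grid)

__all__ = [
    "SpikeTrainSet",
    "SimulationConfig",
    "SimulationRecord",
    "Network",
    "build_network",
    "run_network",
    "reset_states",
]


@dataclass
class SpikeTrainSet:
    """Timestamped spike events over a set of sources.

    Events are stored sorted by time (ties broken by source index); all times
    lie in [0, duration].
    """

    sources: np.ndarray
    times: np.ndarray
    n_sources: int
    duration: float

    def __post_init__(self) -> None:
        self.sources = np.asarray(self.sources, dtype=np.int64)
        self.times = np.asarray(self.times, dtype=float)
        if self.sources.size != self.times.size:
            raise ShapeError("sources and times must have equal length")
        if self.times.size:
            if self.times.min() < -1e-9 or self.times.max() > self.duration + 1e-9:
                raise SpecificationError("spike times must lie in [0, duration]")
            order = np.lexsort((self.sources, self.times))
            self.sources = self.sources[order]
            self.times = self.times[order]
            if self.sources.max() >= self.n_sources:
                raise ShapeError("source index out of range")

    @property
    def n_events(self) -> int:
        return self.times.size

    def raster(self, dt: float, n_steps: Optional[int] = None) -> np.ndarray:
        """Event counts per (step, source) bin; events at t land in floor(t/dt)."""
        if n_steps is None:
            n_steps = max(1, int(np.ceil(self.duration / dt)))
        grid = np.zeros((n_steps, self.n_sources), dtype=np.int32)
        if self.times.size:
            steps = np.minimum((self.times / dt).astype(np.int64), n_steps - 1)
            np.add.at(grid, (steps, self.sources), 1)
        return grid

    def counts_per_source(self) -> np.ndarray:
        return np.bincount(self.sources, minlength=self.n_sources)

    # -- serialization: two-column text ------------------------------------
    def to_text(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# n_sources={self.n_sources} duration={self.duration!r}\n")
            for s, t in zip(self.sources, self.times):
                fh.write(f"{int(s)}\t{float(t)!r}\n")

    @classmethod
    def from_text(cls, path) -> "SpikeTrainSet":
        with open(path) as fh:
            meta = dict(tok.split("=") for tok in fh.readline().lstrip("# ").split())
            rows = [line.split() for line in fh if line.strip()]
        sources = np.array([int(r[0]) for r in rows], dtype=np.int64)
        times = np.array([float(r[1]) for r in rows])
        return cls(sources, times, int(meta["n_sources"]), float(meta["duration"]))


@dataclass
class SimulationConfig:
    dt: float = 1.0
    duration: Optional[float] = None  # defaults to the input train's duration
    plasticity_on: bool = False
    record_membrane: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise SpecificationError("dt must be positive")
        if self.duration is not None and self.duration < self.dt:
            raise SpecificationError("duration must be at least dt")


@dataclass
class SimulationRecord:
    spikes: SpikeTrainSet                      # recurrent (+ output, if spiking)
    output_membrane_final: np.ndarray
    membrane_history: Optional[np.ndarray]     # (n_steps, N_R + N_O) when recorded
    weight_snapshot: Dict[str, np.ndarray]
    n_steps: int
    dt: float


@dataclass
class Network:
    """The assembled three-layer model with its plasticity state."""

    pop_r: NeuronPopulation
    pop_o: NeuronPopulation
    s_ir: SynapseSet
    s_rr: SynapseSet
    s_ro: SynapseSet
    stdp_ir: STDPParameters
    stdp_rr: STDPParameters
    traces_ir: TraceState
    traces_rr: TraceState
    n_input: int
    config: NetworkConfig
    w_max: float = DEFAULT_W_MAX

    @property
    def n_recurrent(self) -> int:
        return self.pop_r.size

    @property
    def n_output(self) -> int:
        return self.pop_o.size


DEFAULT_OUTPUT_TAU = 20.0


def build_network(
    net_config: NetworkConfig,
    neuron_config: Optional[HeterogeneityConfig] = None,
    stdp_config: Optional[STDPHeterogeneityConfig] = None,
    seed: Optional[int] = None,
    output_tau: float = DEFAULT_OUTPUT_TAU,
    spiking_output: bool = False,
    w_max: float = DEFAULT_W_MAX,
    **neuron_kwargs,
) -> Network:
    """Assemble a network: sample neurons, place them, draw all synapse sets.

    All randomness is derived from one seed through independent child streams,
    so identical seeds give bitwise-identical networks.
    """
    if neuron_config is None:
        neuron_config = HeterogeneityConfig()
    if stdp_config is None:
        stdp_config = STDPHeterogeneityConfig()
    root = np.random.SeedSequence(net_config.seed if seed is None else seed)
    seeds = [int(s.generate_state(1)[0]) for s in root.spawn(6)]

    pop_r = sample_lif_parameters(neuron_config, net_config.n_excitatory,
                                  net_config.n_inhibitory, seeds[0], **neuron_kwargs)
    pop_r.position = place_neurons_on_grid(pop_r.size, net_config.grid_shape, seeds[1])
    s_rr = build_recurrent_synapses(pop_r, net_config, seed=seeds[2])
    s_ir = build_input_synapses(net_config.n_input, pop_r, net_config.P_IR,
                                seeds[3], w_scale=net_config.input_w_scale)
    s_ro = build_output_taps(pop_r, net_config.n_output, seeds[4],
                             fraction=net_config.output_tap_fraction)
    stdp_rr = sample_stdp_parameters(stdp_config, s_rr.size, seeds[5])
    stdp_ir = sample_stdp_parameters(stdp_config, s_ir.size, seeds[5] + 1)

    out_params = LIFParameters(
        tau_m=np.full(max(net_config.n_output, 1), output_tau),
        r_m=neuron_kwargs.get("r_m", DEFAULT_R_M), a=0.0, v_threshold=1.0,
        v_reset=0.0, refractory=0.0)
    pop_o = NeuronPopulation(
        params=out_params,
        is_excitatory=np.ones(max(net_config.n_output, 1), dtype=bool),
        spiking=spiking_output)
    if net_config.n_output == 0:
        # keep a 1-neuron placeholder population but an empty tap set
        pop_o = NeuronPopulation(params=out_params, is_excitatory=np.ones(1, bool),
                                 spiking=spiking_output)

    return Network(pop_r=pop_r, pop_o=pop_o, s_ir=s_ir, s_rr=s_rr, s_ro=s_ro,
                   stdp_ir=stdp_ir, stdp_rr=stdp_rr,
                   traces_ir=TraceState.zeros(s_ir.size),
                   traces_rr=TraceState.zeros(s_rr.size),
                   n_input=net_config.n_input, config=net_config, w_max=w_max)


def _deliver(post_accum: np.ndarray, syn: SynapseSet, pre_active: np.ndarray,
             inv_dt: float) -> None:
    """Add weight/dt for every synapse whose pre-neuron spiked."""
    if syn.size == 0:
        return
    m = pre_active[syn.pre_index]
    if not m.any():
        return
    post_accum += np.bincount(syn.post_index[m], weights=syn.weight[m],
                              minlength=post_accum.size) * inv_dt


def run_network(network: Network, input_spikes: SpikeTrainSet,
                sim: SimulationConfig) -> SimulationRecord:
    """Simulate one stimulus presentation and record spikes and final state."""
    if input_spikes.n_sources != network.n_input:
        raise ShapeError(
            f"input has {input_spikes.n_sources} sources, network expects "
            f"{network.n_input}")
    dt = sim.dt
    duration = sim.duration if sim.duration is not None else max(input_spikes.duration, dt)
    n_steps = max(1, int(np.ceil(duration / dt - 1e-9)))
    raster = input_spikes.raster(dt, n_steps)
    inv_dt = 1.0 / dt
    pop_r, pop_o = network.pop_r, network.pop_o

    plastic_sets = []
    if sim.plasticity_on:
        for syn, stdp, traces in ((network.s_ir, network.stdp_ir, network.traces_ir),
                                  (network.s_rr, network.stdp_rr, network.traces_rr)):
            if syn.plastic and syn.size:
                plastic_sets.append((syn, stdp, traces,
                                     np.exp(-dt / stdp.tau_plus),
                                     np.exp(-dt / stdp.tau_minus)))

    spike_steps: List[np.ndarray] = []
    spike_ids: List[np.ndarray] = []
    history = np.empty((n_steps, pop_r.size + pop_o.size)) if sim.record_membrane else None
    prev_spiked = np.zeros(pop_r.size, dtype=bool)

    for k in range(n_steps):
        cur_r = np.zeros(pop_r.size)
        cur_o = np.zeros(pop_o.size)
        in_counts = raster[k]
        in_active = in_counts > 0
        if in_active.any():
            syn = network.s_ir
            m = in_active[syn.pre_index]
            if m.any():
                contrib = syn.weight[m] * in_counts[syn.pre_index[m]]
                cur_r += np.bincount(syn.post_index[m], weights=contrib,
                                     minlength=pop_r.size) * inv_dt
        if prev_spiked.any():
            _deliver(cur_r, network.s_rr, prev_spiked, inv_dt)
            _deliver(cur_o, network.s_ro, prev_spiked, inv_dt)

        spiked = lif_step(pop_r, cur_r, dt)
        lif_step(pop_o, cur_o, dt)

        for syn, stdp, traces, dec_p, dec_m in plastic_sets:
            if syn.synapse_class == "input":
                pre_mask = in_active[syn.pre_index]
            else:
                pre_mask = spiked[syn.pre_index]
            post_mask = spiked[syn.post_index]
            update_traces(traces, pre_mask, post_mask, stdp, dt, dec_p, dec_m)
            apply_stdp_update(syn, traces, pre_mask, post_mask, stdp, dt,
                              w_max=network.w_max)

        if spiked.any():
            ids = np.nonzero(spiked)[0]
            spike_ids.append(ids)
            spike_steps.append(np.full(ids.size, k, dtype=np.int64))
        if history is not None:
            history[k, :pop_r.size] = pop_r.membrane
            history[k, pop_r.size:] = pop_o.membrane
        prev_spiked = spiked

    if spike_ids:
        sources = np.concatenate(spike_ids)
        times = (np.concatenate(spike_steps) + 1) * dt  # relative to run start
    else:
        sources = np.zeros(0, dtype=np.int64)
        times = np.zeros(0)
    spikes = SpikeTrainSet(sources, times, pop_r.size + pop_o.size,
                           duration=n_steps * dt)
    return SimulationRecord(
        spikes=spikes,
        output_membrane_final=pop_o.membrane.copy(),
        membrane_history=history,
        weight_snapshot={"input": network.s_ir.weight.copy(),
                         "recurrent": network.s_rr.weight.copy(),
                         "output": network.s_ro.weight.copy()},
        n_steps=n_steps,
        dt=dt,
    )


def reset_states(network: Network) -> Network:
    """Membranes to rest, traces to zero, clocks cleared; weights untouched."""
    network.pop_r.reset()
    network.pop_o.reset()
    network.traces_ir.reset()
    network.traces_rr.reset()
    return network
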