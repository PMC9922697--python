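"""Desk-scale experimental protocols.

Reproduces the structure of the paper-style experiments on the synthetic
motion task: the four-way heterogeneity ablation, sparsity sweeps over
(lambda, W_scale), limited-training-data sweeps, and the average-activation
comparison.  External video/event benchmarks are out of scope; all results
are trends (orderings, monotonicities) at configurable scale.

Protocol per (variant, seed): build the network, run STDP training with each
training clip presented once per epoch (plasticity on, states reset between
clips), freeze the weights, extract train/test state matrices, fit the linear
readout on the training states, and evaluate on the test states.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .encoding import EncoderConfig, FrameSequence, encode_sequence
from .engine import (Network, SimulationConfig, SpikeTrainSet, build_network,
                     reset_states, run_network)
from .exceptions import SpecificationError
from .lif_core import GammaSpec, HeterogeneityConfig
from .plasticity import STDPHeterogeneityConfig
from .readout_metrics import (StateMatrix, build_state_matrix,
                              classification_accuracy, effective_rank,
                              fit_linear_classifier)
from .synthetic_data import train_test_split
from .topology import NetworkConfig

__all__ = [
    "VARIANTS",
    "AblationSpec",
    "PipelineConfig",
    "SweepResult",
    "variant_configs",
    "encode_dataset",
    "train_stdp",
    "run_pipeline",
    "run_ablation",
    "sparsity_sweep",
    "limited_data_sweep",
    "activation_comparison",
]

VARIANTS = ("HoNHoS", "HeNHoS", "HoNHeS", "HeNHeS")


@dataclass
class PipelineConfig:
    """Everything needed to train and evaluate one network on encoded clips."""

    n_recurrent: int = 500
    n_output: int = 50
    lambda_conn: float = 2.0
    P_IR: float = 0.3
    W_scale: float = 1.0
    input_w_scale: float = 0.8
    r_m: float = 4.0              # membrane resistance (drive gain) of R and O neurons
    output_tau: float = 150.0     # readout integrator time constant (ms)
    dt: float = 1.0
    epochs: int = 3
    test_fraction: float = 0.3
    weight_change_tol: float = 1e-4   # early-stop threshold on per-epoch drift
    neuron_config: HeterogeneityConfig = field(default_factory=HeterogeneityConfig)
    stdp_config: STDPHeterogeneityConfig = field(default_factory=STDPHeterogeneityConfig)
    encoder: EncoderConfig = field(default_factory=EncoderConfig)

    def network_config(self, n_input: int, seed: int) -> NetworkConfig:
        return NetworkConfig(
            n_input=n_input, n_recurrent=self.n_recurrent, n_output=self.n_output,
            lambda_conn=self.lambda_conn, P_IR=self.P_IR, W_scale=self.W_scale,
            input_w_scale=self.input_w_scale, seed=seed)


def variant_configs(variant: str, base: PipelineConfig
                    ) -> Tuple[HeterogeneityConfig, STDPHeterogeneityConfig]:
    """Zero out the CVs dictated by the ablation variant (Ho = homogeneous)."""
    if variant not in VARIANTS:
        raise SpecificationError(f"unknown variant {variant!r}")
    neuron = base.neuron_config if variant[:3] == "HeN" else base.neuron_config.homogeneous()
    stdp = base.stdp_config if variant[3:] == "HeS" else base.stdp_config.homogeneous()
    return neuron, stdp


def encode_dataset(clips: Sequence[FrameSequence], encoder: EncoderConfig
                   ) -> Tuple[List[SpikeTrainSet], List[int]]:
    """Encode every clip; the crop is pinned to the frame shape so all clips
    share one encoding-neuron count."""
    if not clips:
        raise SpecificationError("empty dataset")
    if encoder.crop_shape is None:
        encoder = replace(encoder, crop_shape=tuple(clips[0].shape))
    spikes = [encode_sequence(c, encoder) for c in clips]
    labels = [c.label for c in clips]
    n_sources = {s.n_sources for s in spikes}
    if len(n_sources) != 1:
        raise SpecificationError("clips produced inconsistent encoding sizes")
    return spikes, labels


def train_stdp(network: Network, train_spikes: Sequence[SpikeTrainSet],
               dt: float, epochs: int, weight_change_tol: float = 0.0) -> Network:
    """Present each training clip once per epoch with plasticity on.

    States are reset between presentations; weights persist.  If the combined
    weight drift over an epoch falls below ``weight_change_tol`` (L2 norm per
    synapse), training stops early.
    """
    sim = SimulationConfig(dt=dt, plasticity_on=True)
    for _ in range(max(epochs, 0)):
        w_before = np.concatenate([network.s_ir.weight, network.s_rr.weight])
        for st in train_spikes:
            reset_states(network)
            run_network(network, st, sim)
        w_after = np.concatenate([network.s_ir.weight, network.s_rr.weight])
        if weight_change_tol > 0 and w_before.size:
            drift = float(np.linalg.norm(w_after - w_before)) / np.sqrt(w_before.size)
            if drift < weight_change_tol:
                break
    reset_states(network)
    return network


@dataclass
class PipelineResult:
    accuracy: float
    nu_bar: float                # mean recurrent spikes per neuron per test stimulus
    eff_rank: int
    active_neurons: int
    network: Network
    state_train: StateMatrix
    state_test: StateMatrix


def run_pipeline(variant: str, config: PipelineConfig,
                 train: Sequence[SpikeTrainSet], train_labels: Sequence[int],
                 test: Sequence[SpikeTrainSet], test_labels: Sequence[int],
                 seed: int) -> PipelineResult:
    """Build, train, and evaluate one network; also collect activity metrics."""
    neuron_cfg, stdp_cfg = variant_configs(variant, config)
    n_input = train[0].n_sources
    net = build_network(config.network_config(n_input, seed), neuron_cfg, stdp_cfg,
                        seed=seed, r_m=config.r_m, output_tau=config.output_tau)
    train_stdp(net, train, config.dt, config.epochs, config.weight_change_tol)
    sim = SimulationConfig(dt=config.dt, plasticity_on=False)
    f_train = build_state_matrix(net, train, sim, labels=train_labels)
    # test pass: states plus spike-based activity metrics
    rows = []
    total_spikes = 0
    active: set = set()
    for st in test:
        reset_states(net)
        rec = run_network(net, st, sim)
        rows.append(rec.output_membrane_final.copy())
        total_spikes += int(np.count_nonzero(rec.spikes.sources < net.n_recurrent))
        active.update(rec.spikes.sources[rec.spikes.sources < net.n_recurrent].tolist())
    reset_states(net)
    f_test = StateMatrix(np.vstack(rows), np.asarray(list(test_labels)))
    model = fit_linear_classifier(f_train, seed=seed)
    acc = classification_accuracy(model, f_test)
    nu_bar = total_spikes / (net.n_recurrent * max(len(test), 1))
    return PipelineResult(
        accuracy=acc, nu_bar=nu_bar,
        eff_rank=effective_rank(f_test),
        active_neurons=len(active),
        network=net, state_train=f_train, state_test=f_test)


@dataclass
class AblationSpec:
    """Which variants to run, at what scale, over how many seeds."""

    variants: Tuple[str, ...] = VARIANTS
    config: PipelineConfig = field(default_factory=PipelineConfig)
    n_seeds: int = 5
    base_seed: int = 0

    def __post_init__(self) -> None:
        for v in self.variants:
            if v not in VARIANTS:
                raise SpecificationError(f"unknown variant {v!r}")
        if self.n_seeds < 1:
            raise SpecificationError("n_seeds must be at least 1")


@dataclass
class SweepResult:
    """Axis values plus per-cell raw seed values for each measured quantity."""

    axes: Dict[str, np.ndarray]
    raw: Dict[str, np.ndarray]   # metric -> array of shape (*axis_lens, n_seeds)

    def mean(self, metric: str) -> np.ndarray:
        return self.raw[metric].mean(axis=-1)

    def sd(self, metric: str) -> np.ndarray:
        return self.raw[metric].std(axis=-1, ddof=0)


def _prepared_splits(dataset: Sequence[FrameSequence], config: PipelineConfig,
                     seed: int):
    spikes, labels = encode_dataset(dataset, config.encoder)
    idx = list(range(len(spikes)))
    tr, te = train_test_split(idx, config.test_fraction, seed,
                              labels=[labels[i] for i in idx])
    return ([spikes[i] for i in tr], [labels[i] for i in tr],
            [spikes[i] for i in te], [labels[i] for i in te])


def run_ablation(spec: AblationSpec, dataset: Sequence[FrameSequence],
                 ) -> Dict[str, Dict[str, object]]:
    """Accuracy (and activation) mean +/- sd per variant over seeds.

    The train/test split and network seeds are paired across variants so the
    comparison is matched.
    """
    labels = [c.label for c in dataset]
    if np.unique(labels).size < 2:
        raise SpecificationError("ablation needs at least two classes")
    results: Dict[str, Dict[str, object]] = {}
    for variant in spec.variants:
        accs, nus, ranks = [], [], []
        for s in range(spec.n_seeds):
            seed = spec.base_seed + s
            tr, trl, te, tel = _prepared_splits(dataset, spec.config, seed)
            out = run_pipeline(variant, spec.config, tr, trl, te, tel, seed)
            accs.append(out.accuracy)
            nus.append(out.nu_bar)
            ranks.append(out.eff_rank)
        results[variant] = {
            "accuracy_mean": float(np.mean(accs)),
            "accuracy_sd": float(np.std(accs, ddof=0)),
            "accuracy_per_seed": accs,
            "nu_bar_mean": float(np.mean(nus)),
            "nu_bar_per_seed": nus,
            "eff_rank_mean": float(np.mean(ranks)),
        }
    return results


def sparsity_sweep(lambda_grid: Sequence[float], wscale_grid: Sequence[float],
                   config: PipelineConfig, dataset: Sequence[FrameSequence],
                   n_seeds: int = 5, base_seed: int = 0,
                   variant: str = "HeNHeS", train: bool = False) -> SweepResult:
    """Active-neuron count and effective rank over a (lambda, W_scale) grid.

    Each cell is averaged over ``n_seeds`` independently initialized networks
    driven by the test split of the dataset.  By default the networks are
    untrained (plasticity frozen), which isolates the structural effect of
    (lambda, W_scale); set ``train=True`` for the full protocol.
    """
    lambda_grid = np.asarray(list(lambda_grid), dtype=float)
    wscale_grid = np.asarray(list(wscale_grid), dtype=float)
    if lambda_grid.size == 0 or wscale_grid.size == 0:
        raise SpecificationError("grids must be non-empty")
    shape = (lambda_grid.size, wscale_grid.size, n_seeds)
    raw = {"active_neurons": np.zeros(shape), "eff_rank": np.zeros(shape),
           "nu_bar": np.zeros(shape)}
    for i, lam in enumerate(lambda_grid):
        for j, ws in enumerate(wscale_grid):
            cell_cfg = replace(config, lambda_conn=float(lam), W_scale=float(ws))
            for s in range(n_seeds):
                seed = base_seed + s
                tr, trl, te, tel = _prepared_splits(dataset, cell_cfg, seed)
                neuron_cfg, stdp_cfg = variant_configs(variant, cell_cfg)
                net = build_network(cell_cfg.network_config(te[0].n_sources, seed),
                                    neuron_cfg, stdp_cfg, seed=seed, r_m=cell_cfg.r_m,
                                    output_tau=cell_cfg.output_tau)
                if train:
                    train_stdp(net, tr, cell_cfg.dt, cell_cfg.epochs)
                sim = SimulationConfig(dt=cell_cfg.dt, plasticity_on=False)
                rows = []
                active: set = set()
                total = 0
                for st in te:
                    reset_states(net)
                    rec = run_network(net, st, sim)
                    rows.append(rec.output_membrane_final.copy())
                    rec_sources = rec.spikes.sources[rec.spikes.sources < net.n_recurrent]
                    total += rec_sources.size
                    active.update(rec_sources.tolist())
                raw["active_neurons"][i, j, s] = len(active)
                raw["eff_rank"][i, j, s] = effective_rank(np.vstack(rows))
                raw["nu_bar"][i, j, s] = total / (net.n_recurrent * max(len(te), 1))
    return SweepResult(axes={"lambda": lambda_grid, "W_scale": wscale_grid}, raw=raw)


def limited_data_sweep(fractions: Sequence[float], variants: Sequence[str],
                       dataset: Sequence[FrameSequence], config: PipelineConfig,
                       n_seeds: int = 5, base_seed: int = 0) -> SweepResult:
    """Accuracy per (training fraction, variant); stratified subsampling."""
    fractions = list(fractions)
    for f in fractions:
        if not (0.0 < f <= 1.0):
            raise SpecificationError("fractions must lie in (0, 1]")
    shape = (len(fractions), len(variants), n_seeds)
    raw = {"accuracy": np.zeros(shape)}
    for s in range(n_seeds):
        seed = base_seed + s
        tr, trl, te, tel = _prepared_splits(dataset, config, seed)
        for fi, frac in enumerate(fractions):
            if frac >= 1.0:
                sub, subl = tr, trl
            else:
                idx = list(range(len(tr)))
                kept, _ = train_test_split(idx, 1.0 - frac, seed + 7919,
                                           labels=[trl[i] for i in idx])
                sub = [tr[i] for i in kept]
                subl = [trl[i] for i in kept]
            for vi, variant in enumerate(variants):
                out = run_pipeline(variant, config, sub, subl, te, tel, seed)
                raw["accuracy"][fi, vi, s] = out.accuracy
    return SweepResult(axes={"fraction": np.asarray(fractions),
                             "variant": np.asarray(variants)}, raw=raw)


def separation_rank_experiment(dataset: Sequence[FrameSequence],
                               config: Optional[PipelineConfig] = None,
                               n_seeds: int = 10, base_seed: int = 0,
                               ) -> List[Tuple[int, int]]:
    """Paired effective ranks (homogeneous, heterogeneous) over matched seeds.

    Runs the separation-property protocol: untrained networks in the
    strong-coupling regime (the regime where reservoir dynamics, not the
    feed-forward drive, dominate the states), one pair of networks per seed
    sharing topology seed and stimuli.  The heterogeneous variant includes
    threshold heterogeneity here, since threshold diversity is what breaks the
    synchrony of the strongly coupled homogeneous reservoir.  Returns a list
    of (rank_hom, rank_het).
    """
    if config is None:
        config = PipelineConfig(
            W_scale=2.0, r_m=8.0,
            neuron_config=HeterogeneityConfig(
                v_threshold_spec=GammaSpec(1.0, 0.5)))
    spikes, labels = encode_dataset(dataset, config.encoder)
    sim = SimulationConfig(dt=config.dt, plasticity_on=False)
    pairs: List[Tuple[int, int]] = []
    for s in range(n_seeds):
        seed = base_seed + s
        ranks = {}
        for variant in ("HoNHoS", "HeNHeS"):
            neuron_cfg, stdp_cfg = variant_configs(variant, config)
            net = build_network(config.network_config(spikes[0].n_sources, seed),
                                neuron_cfg, stdp_cfg, seed=seed, r_m=config.r_m,
                                output_tau=config.output_tau)
            F = build_state_matrix(net, spikes, sim, labels=labels)
            ranks[variant] = effective_rank(F)
        pairs.append((ranks["HoNHoS"], ranks["HeNHeS"]))
    return pairs


def activation_comparison(variants: Sequence[str], dataset: Sequence[FrameSequence],
                          config: PipelineConfig, n_seeds: int = 5,
                          base_seed: int = 0) -> Dict[str, float]:
    """Per-variant mean average-activation on the test split (trained networks)."""
    spec = AblationSpec(variants=tuple(variants), config=config, n_seeds=n_seeds,
                        base_seed=base_seed)
    results = run_ablation(spec, dataset)
    return {v: results[v]["nu_bar_mean"] for v in variants}
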