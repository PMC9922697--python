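# hrsnn

A heterogeneous recurrent spiking neural network (HRSNN) toolkit: a reservoir
of leaky integrate-and-fire neurons whose parameters are drawn from gamma
distributions, trained with trace-based STDP whose constants are themselves
heterogeneous per synapse, read out through non-spiking membrane integrators
and a linear classifier, and tuned by Bayesian optimization over the
*parameter distributions* using a Matérn kernel on the Wasserstein metric.

## Layout

| module | contents |
| --- | --- |
| `hrsnn.lif_core` | LIF dynamics (exponential Euler), gamma-parameterized heterogeneity, closed-form first-spike oracle |
| `hrsnn.topology` | 3-D lattice placement, distance-dependent recurrent connectivity `C·exp(−(d/λ)²)`, 30% input targeting, output taps |
| `hrsnn.plasticity` | per-synapse trace-based STDP with heterogeneous `A±`, `τ±`; closed-form pair window oracle |
| `hrsnn.engine` | clock-driven simulation of the input → recurrent → output network, spike recording, state reset |
| `hrsnn.encoding` | scan-based re-centering filter, temporal-difference thresholding, square-cosine latency code, max-pooling |
| `hrsnn.readout_metrics` | state matrices, 99%-energy effective rank, linear classification, activation metrics |
| `hrsnn.bayesopt` | 1-D/sliced Wasserstein and debiased Sinkhorn distances, Matérn-Wasserstein GP, expected improvement, BO loop |
| `hrsnn.synthetic_data` | labelled moving-object clips and DVS-style event streams (class = motion direction and speed) |
| `hrsnn.experiments` | heterogeneity ablations, sparsity sweeps, limited-data sweeps, separation-rank protocol |

## CLI

```bash
hrsnn generate --config task.yaml --seed 1 --out clips.npz
hrsnn encode   --input clips.npz --out spikes/
hrsnn simulate --input spikes/clip_0000.spikes --out record.spikes --seed 0
hrsnn evaluate --states states.tsv --split 0.3
hrsnn optimize --config pipeline.yaml --budget 50 --out bo.log
hrsnn ablate | sweep | limited-data | activation --config cfg.yaml --out out.json
```

Config files are YAML mirrors of the dataclasses in
`hrsnn.synthetic_data.SyntheticTaskConfig`, `hrsnn.experiments.PipelineConfig`
and `hrsnn.encoding.EncoderConfig`.

## Notes on scale

Experiments default to a desk-scale setup (recurrent layer of 250–500
neurons, 16×16 synthetic clips) chosen so that every protocol — STDP
training, state readout, effective-rank analysis, Bayesian optimization —
runs end-to-end in minutes on one CPU while preserving the qualitative
behaviour studied at larger scale.
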