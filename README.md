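# spikelearn

Teacher–student supervised learning with asynchronous inputs, a leaky
integrate-and-fire (LIF) output with decaying input summation, STDP-like
multiplicative adaptation, and perceptron-style learning steps.

Two architecturally identical feedforward networks — a teacher and a
student — receive the same asynchronous stimulation examples. The student
sees the teacher's output spike timings and must imitate its responses.
Three scenarios are implemented:

* **synaptic** — N adaptive weights feed a single LIF output unit;
* **dendritic** — K = N/5 adaptive dendritic strengths multiply fixed
  weights, each dendrite integrating its five members independently;
  learning emerges from bounded multiplicative oscillations whose
  boundary clips synchronize teacher and student exactly;
* **multilayer** — a fully connected input→hidden layer of LIF units plus
  a single LIF output, with fixed random delays on both layers.

## Layout

| module                      | contents                                                       |
|-----------------------------|----------------------------------------------------------------|
| `spikelearn.inputs`         | asynchronous example generation (synaptic/dendritic/multilayer)|
| `spikelearn.lif_neuron`     | event-driven LIF integration, per-dendrite variant             |
| `spikelearn.plasticity`     | STDP-like multiplicative adaptation (exp/step kernels, time- and rank-window pairing) |
| `spikelearn.learning_rules` | mismatch-driven learning steps, attractive/repulsive bookkeeping |
| `spikelearn.networks`       | scenario containers and the per-example 3-phase protocol       |
| `spikelearn.experiments`    | generalization error, overlap diagnostics, learning curves, power-law fits |
| `spikelearn.cli_io`         | run configs, presets, CLI entry points                         |

## CLI

```bash
# train a preset scenario and write curve.csv / run.json / checkpoint.json
spikelearn run --preset synaptic-small --out runs/synaptic --seed 1

# or from a YAML/JSON config (see RunConfig.to_dict for the schema)
spikelearn run --config config.yaml --out runs/custom

# fit a power-law exponent to a stored curve over a p-range
spikelearn fit-exponent --curve runs/synaptic/curve.csv --range 2000:10000

# re-measure the generalization error of a stored checkpoint
spikelearn eval --checkpoint runs/synaptic/checkpoint.json --n-test 1000
```

Every output embeds a hash of the configuration; re-running into the same
directory with a different config is refused unless `--force` is given.
Presets cover the published protocol parameter sets (`synaptic-n1000`,
`synaptic-small`, `dendritic-n1000`, `dendritic-small`,
`dendritic-strong-small`, `multilayer-small`, plus robustness variants).
Note one documented ambiguity in the source protocol: the dendritic
scenario is described both as "adaptation only" and with a learning step
of 1/N; both modes are supported (set `learning.step_size` to 0 for
adaptation-only), and the `dendritic-*` presets use the 1/N step.

## Reproducibility

All randomness flows from explicit `numpy.random.Generator` streams
derived from a master seed via `SeedSequence.spawn`; training, teacher
initialization, student initialization and test-example streams are
independent, so measurement never perturbs the training trajectory, and a
repeated run is byte-identical.
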