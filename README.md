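# hetsnn

A heterogeneous spiking neural network (H-SNN) toolkit for unsupervised
learning of spatiotemporal patterns — object class *and* motion dynamics —
from rate-coded frame sequences, without recurrence and without
backpropagation through the feature layers.

The core idea: a feedforward spiking convolutional network in which each
layer pairs an **STDP-learning module** (learner neurons) with a frozen
**memory module** built from two LIF populations with different dynamics —
fast-decaying *short-term* neurons and slow-decaying *long-term* neurons.
Crossover connections between the memory modules of successive layers
realize every ordered long/short sequence as a **memory pathway**. For a
pathway of m neurons with uniform refractory period r and per-stage spike
requirements γᵢ (the minimal number of input spikes stage i needs to
fire), the input-rate → output-rate mapping has the closed form

    Φ(f_in) = ( r + ∏ᵢ γᵢ / f_in + r · Σ_{k=0}^{m-2} ∏_{j=0}^{k} γ_{m-j} )⁻¹

— the composition of the single-neuron response F(f) = f/(γ + r·f).
Distinct pathways have distinct Φ, and each pathway has its own cut-off
frequency f₀ = b / ln(X/(X + cG)) and retention length T, so one
feedforward stack represents temporal structure at many time scales. The
package implements the neurons (LIF, forward Euler at 1 ms), soft-bounded
exponential STDP, the spiking convolution with cross-depth / local /
section-lateral winner-take-all inhibition, the pathway calculus with
brute-force spiking cross-checks, rate encoders, a synthetic moving-object
generator (five motion dynamics for translation and rotation), the
layer-wise training pipeline with a multi-objective readout, and a CLI.

Intended users: computational-neuroscience and neuromorphic-engineering
researchers who want a tested, desk-scale reference implementation of
heterogeneous-dynamics SNNs and their memory-pathway analysis.

## Worked example: pathway analytics

```python
from hetsnn.neurons import NEURON_TYPES
from hetsnn.pathways import (PathwaySpec, pathway_response, simulate_pathway,
                             retention_length, calibrate_leak_slope,
                             cutoff_frequency_linear, CUTOFF_REFERENCE_HZ,
                             CUTOFF_REFERENCE_G)

for types in [("short_term", "short_term"), ("long_term", "short_term"),
              ("short_term", "long_term"), ("long_term", "long_term")]:
    spec = PathwaySpec.from_types(types)          # default gammas: long 2, short 4
    pred = 1000 * pathway_response(0.1, spec)     # 100 Hz in, spikes/ms internally
    sim = simulate_pathway(100.0, spec, seed=42)  # brute-force spiking chain
    c = NEURON_TYPES[types[-1]].c
    s = calibrate_leak_slope(CUTOFF_REFERENCE_HZ[types[-1]], c, CUTOFF_REFERENCE_G)
    T = retention_length(spec, cutoff_frequency_linear(s, c, 0.5) / 1000.0)
    name = "->".join(t.split("_")[0] for t in types)
    print(f"{name:12s} Phi(100 Hz) = {pred:5.2f} Hz   simulated = {sim:5.2f} Hz   T = {T:5.1f} ms")
```

prints

```
short->short Phi(100 Hz) =  4.76 Hz   simulated =  4.67 Hz   T =  13.3 ms
long->short  Phi(100 Hz) =  7.69 Hz   simulated =  7.62 Hz   T =  26.7 ms
short->long  Phi(100 Hz) =  9.09 Hz   simulated =  9.00 Hz   T =  17.2 ms
long->long   Phi(100 Hz) = 14.29 Hz   simulated = 14.36 Hz   T =  34.4 ms
```

Each row is one two-layer memory pathway. The closed-form response Φ
agrees with the spiking simulation to within ~1–2%; the four ordered
long/short combinations all respond differently (distinguishability), and
retention length is shortest for the all-short-term pathway and longest
for the all-long-term one (13.3 ms vs 34.4 ms at G = 0.5) — the hierarchy
of time scales the architecture is built around.

## End-to-end pipeline

```python
from hetsnn.config import RunConfig
from hetsnn.network import build_network
from hetsnn.training import fit

cfg = RunConfig({"seed": 1})          # 2 classes x 2 translation dynamics, 32x32
train, test = cfg.build_dataset()
net = build_network(cfg.build_network_config())
sections = [(str(n), int(k)) for n, k in cfg.data["network"]["sections"]]
net, model = fit(net, train, sections, cfg.build_schedule())
```

runs layer-wise STDP, transfers the learned kernels to the memory module,
extracts last-layer spike-frequency features and fits the per-section
sigmoid readout; on the held-out perturbed test sequences (σ_ts = 1) this
seeded run reaches joint accuracy 0.875 over class × translation (chance
0.25). The same flow is available from the shell:

```
hetsnn gen-data --seed 7 --out data/
hetsnn train --data data/ --out model.npz
hetsnn predict --model model.npz --data data/ --out predictions.csv
hetsnn analytics --out analytics.csv     # cut-off / response / retention tables
hetsnn verify                            # built-in property suite
```

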