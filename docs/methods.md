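# Methods

This note documents the models, parameter choices and numerical decisions
behind `hetsnn`, in the spirit of a simulator's model reference.

## Neuron model

All units are leaky integrate-and-fire (LIF) neurons integrated by forward
Euler on a 1 ms grid:

    v <- v + dt * (a + b*v + c*I),    spike if v > v_threshold (strict),
    then v <- v_reset for r_refrac ms.

`b = -1/tau_m` and `c = R_m/tau_m`, so the classical form
`tau_m dv/dt = a + R_m I - v` is recoverable. Input is delta-current: one
pre-synaptic spike through conductance `G` raises the membrane by `c*G`.
During the refractory period the membrane is clamped to `v_reset` and
inputs are discarded; this makes the per-neuron spike bookkeeping match the
response calculus below (a neuron needs `gamma` *fresh* input spikes after
each output spike). A configurable fine step (`dt` down to 1 µs) exists for
oracle cross-checks only; forward Euler is first-order, and the test suite
checks convergence of the stepped trajectory to the closed-form solution
(deviation ~3e-3 at dt = 0.01 ms, < 1e-3 at dt = 0.001 ms on the learner
trajectories it uses).

Three parameterizations (`a`, `b` [1/ms], `c`, `r` [ms]) are built in:

| type | a | b | c | r | role |
|---|---|---|---|---|---|
| learner | -4.1 | -0.01 | 0.31 | 20 | STDP feature learning |
| short-term | -5.1 | -0.02 | 0.45 | 10 | fast-decaying memory |
| long-term | -1.6 | -0.001 | 0.16 | 10 | slow-decaying memory |

`v_reset`/`v_threshold` are free configuration (defaults 0 and 1 in
`neurons`; potential units are arbitrary).

### Operating point

The printed `{a, b, c}` leave the working regime undetermined: with
`v_reset = 0`, `v_threshold = 1` the drive deficit `|a| ~ 4.1` units/ms
dwarfs the per-spike gain `cG <= 0.45`, and no unit could ever fire from a
rate-coded input. The network therefore places each unit near its leak
equilibrium: `v_reset` is chosen so that the effective offset
`X = v_reset + a/b` equals the value calibrated from the measured cut-off
frequencies at `G = 0.1` (learner 0.3127, short-term 0.1560, long-term
1.0080). In that regime the leak slope near reset, `|b|·X ~ 1e-3` units/ms,
is commensurate with `cG`, which is the only operating point consistent
with cut-offs in the printed 10–100 Hz range. The threshold-to-reset gap is
then the tunable excitability parameter (below).

## STDP

Synaptic conductances live in `[G_min, G_max] = [0, 1]` and follow
soft-bounded exponential STDP

    dG_p = alpha_p exp(-Δt (G - G_min)/(tau_pot (G_max - G_min)))
    dG_d = alpha_d exp(-Δt (G_max - G)/(tau_dep (G_max - G_min)))

with `alpha_p = 0.1`, `alpha_d = 0.03`, `tau_pot = 10` ms, `tau_dep = 80` ms.
Pairing is nearest-neighbor (the most recent pre spike per post spike;
all-pairs available behind a flag). Two policy decisions close gaps the
update rules leave open:

* **LTD horizon.** "No pre spike at all" needs a bounded lookback;
  `ltd_window = 50` ms. An afferent silent within the window is depressed
  with `Δt = ltd_window`; one whose nearest pre spike *follows* the post
  spike is depressed with `Δt = |t_post - t_pre|` (the signed form would
  explode the exponential).
* **Ordering.** Updates apply at post-spike times in temporal order, using
  the running (already-updated) conductance, and are clamped to the bounds.

## Spiking convolution and inhibition

Each convolution layer holds a learner module and a memory module on the
same grid; kernels are shared conductance tensors `(depth, c_in, kh, kw)`
initialized uniformly in `[0.3, 0.7]` (seeded). Geometry: odd kernels,
zero padding "same-before-stride", default stride 2. Three inhibition
schemes:

* **Cross-depth** (learner only): per location, the candidate with the
  highest pre-reset membrane wins (ties to the lowest depth index). The
  *other depths at that location are reset and given a full refractory
  period*, not merely reset: with reset alone, the runner-up kernel fires a
  few ms into the winner's refractory period and every kernel converges to
  every pattern (we verified pairwise kernel cosine similarity of 1.0).
  Synchronized re-races keep the depth-wise competition meaningful.
* **Local** (learner and memory): a winner suppresses all same-depth units
  within Chebyshev radius `rho` (default 1) for the current step;
  suppressed units neither fire nor suppress (greedy by membrane, ties by
  linear index).
* **Section-lateral** (prediction module): a spike suppresses only the
  other units of its own section, keeping the objectives independent.

Inhibition removes spikes, never adds them; all winner rules are
deterministic and seed-independent.

The learner threshold gap defaults to 0.6; memory gaps default to 0.15
(long-term) and 0.8 (short-term), scaled per layer by `threshold_scale`
(reference stack: 1.0/0.8/0.6/0.5) to counter the diminishing spike
frequency along layers. The per-type memory gaps are the threshold-scaling
hyperparameter: at `G = 0.5` they give `gamma = 2` (long-term) and
`gamma = 4` (short-term). Long-term units needing *fewer* spikes is a
deliberate choice — with a shared gap the printed input gains
(`c_stn > c_ltn`) would invert the intended time-scale ordering of memory
pathways (all-short-term shortest, all-long-term longest retention), which
this default restores.

## Memory pathways and their calculus

The two memory populations of each layer project to every population of
the next (crossover wiring), so every ordered long/short sequence across
layers is a realized pathway. For a chain with uniform refractory `r` and
per-stage spike requirements `gamma_i`, the response function is

    Phi(f_in) = ( r + prod_i gamma_i / f_in
                    + r * sum_{k=0}^{m-2} prod_{j=0}^{k} gamma_{m-j} )^{-1}

the m-fold composition of `F(f) = f/(gamma + r f)` (an exact algebraic
identity, property-tested). Distinct ordered gamma sequences give distinct
response functions; the retention length of a pathway is

    T = ( 1/f_c^m - r - r * sum_{k=0}^{m-3} prod_{j=0}^{k} gamma_{m-1-j} )
        / prod_{i=1}^{m-1} gamma_i

with the empty-sum convention at `m = 2` (so `T = (1/f_c - r)/gamma_1`).
`T <= 0` signals a pathway that cannot retain at that cut-off and is
returned as-is rather than raised.

### Cut-off frequency

Under periodic input the per-period membrane increment changes sign at

    f0 = b / ln( X / (X + cG) ),     X = v_reset + a/b > 0,

(the sign convention chosen so f0 is positive; frequencies are spikes/ms
internally and reported in Hz). In the small-`cG` regime this reduces to a
constant-leak law `f0 = s/(cG)` with `s = |b| X`, under which the cut-off
scales exactly as `1/G` — the scaling the reference cut-off table follows.
Because `v_reset`/`v_threshold` are free, reproducing that table calibrates
one constant per neuron type from its `G = 0.1` column and predicts the
remaining five columns; both the exact (`X`) and constant-leak (`s`)
calibrations are provided, the constant-leak form being the one the table's
exact `1/G` scaling validates.

### Simulation oracles

Every closed form is cross-checked against brute-force spiking simulation:

* **Response functions.** Each stage is a refractory integrator needing
  exactly `gamma` spikes, simulated event-equivalently to dense 1 ms LIF
  stepping (the equivalence itself is a test). Stages are chained by rate:
  each is driven by a seeded Bernoulli(`f·dt`) train at the measured rate
  of the previous stage. For memoryless input the mean inter-spike interval
  is exactly `r + gamma/f` (Wald), so this chaining is unbiased for the
  quantity the calculus describes — rates, the network's information
  carrier. Literal spike-train chaining (`mode="direct"`) is also
  implemented; because consecutive stages share the refractory period it
  never loses input spikes to refractoriness and runs up to `r` per output
  period faster than the formula (a known bias of the calculus, not of the
  simulator). Simulated durations stretch to ~1200 output intervals per
  stage, keeping Monte Carlo error well under the 5% comparison band.
* **Cut-offs.** Bisection on a fine-step (0.1 ms) simulation with the
  threshold gap set to `cG(1 + 1e-9)`: at gap `cG` the reach-threshold
  cut-off coincides with the increment-sign cut-off, because the asymptotic
  potential under periodic input at exactly `f0` is `v_reset + cG`. With a
  smaller gap a lone spike would cross threshold at any rate; with a larger
  one the simulated cut-off shifts upward by ~`|b|(gap - cG)/cG` per ms.

## Encoding

Pixel intensity in `[0, 1]` maps linearly to 0–100 Hz. Default mode is
Poisson (per-bin Bernoulli, seeded, bit-reproducible); periodic mode emits
evenly spaced spikes starting one full period in (count =
`floor(p·f_max·t_obs/1000)`) and exists because the analytic lemmas assume
regular trains. Event lists accumulate into frames over half-open windows
(default 20 ms), both polarities additive by default, counts normalized by
the per-sequence maximum; out-of-bounds rows are skipped with a logged
count.

## Training pipeline

Training is layer-wise and greedy: memory modules of layers `1..k-1` run in
perception mode while layer `k`'s learner module adapts over the whole
shuffled training set (one pass per layer by default), then its kernels are
copied verbatim to the layer's memory module and frozen. Neuron states
reset between sequences; per-sequence encoding seeds derive from the
schedule seed and the sequence index, so features are independent of
presentation order. Each sequence is summarized by the spike frequencies
(Hz) of the last layer's memory neurons; a single sigmoid layer partitioned
into one section per objective is fit with seeded mini-batch SGD on binary
cross-entropy against concatenated one-hot targets (features standardized
internally). The readout is deliberately in-repo — it is one linear layer.

## Synthetic data

Sequences place a procedural sprite (bars, cross, blob, ring — distinct
spatial-frequency content, no external imagery) on a canvas under
independent translation and rotation, each with one of five dynamics:
static, constant, accelerating, decelerating (speed clamped at zero),
oscillating (sinusoidal; the period is a parameter). Training sequences use
exact dynamic parameters; test sequences perturb every numeric parameter
with `N(0, sigma_ts)` noise around the training value. Defaults are
desk-scale: 32x32 canvas, 10 frames, `sigma_ts = 1`; class-agnostic and
motion-agnostic hold-out splits are supported. Rotation uses bilinear
resampling; sprites about to leave the canvas clamp at the edge (or raise,
per flag).

What the generator does *not* emulate: sensor noise, background clutter,
occlusion, illumination change, event-camera timing statistics. Passing the
end-to-end test therefore shows that the pipeline learns and separates the
designed spatiotemporal factors, not that it handles natural video.

## Problem sizes and defaults in the shipped tests

The end-to-end check trains one 5x5/depth-6 convolution layer on a
2-class x 2-translation-dynamic set (24 training and 24 test sequences,
10 frames at 50 ms per frame) and requires joint accuracy > 0.7 against
chance 0.25. Lemma cross-checks run pathways up to length 3 over
20–100 Hz. These sizes were chosen so the whole suite exercises every
mechanism at desk scale; accuracy at realistic scale (the reference
four-layer stack, 300 ms per frame, thousands of sequences) is out of scope
here, though the stack itself builds and its 474,400 trainable
conductances are verified.

## Known limitations

* With sequences containing a single oriented pattern each, `alpha_p = 0.1`
  makes kernels track the most recent sequence (recency dominance); the
  oriented-kernel test therefore presents both orientations within each
  sequence. Smaller learning rates with many epochs would be the
  alternative at larger scale.
* The decay-time ratio between long- and short-term neurons depends on the
  (unprinted) reset convention and starting potential; the analytics CLI
  prints it for a shared offset as a demo, and no test asserts a particular
  value.
* The direct-chained pathway simulation is systematically faster than the
  response calculus (see above); the calculus should be read as a
  rate-coding model, exact for memoryless trains.
* Euler at 1 ms quantizes spike timing; all analytic comparisons carry
  tolerance bands (5% responses, 2 Hz cut-offs) sized for that grid.
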