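"""Heterogeneous spiking convolutional network structure.

Each convolution layer holds two modules on the same spatial grid:

* a **learner module** (all learner neurons) that receives the previous
  layer's memory output through the *learning path* and adapts its kernel
  conductances by STDP;
* a **memory module** (one long-term and one short-term population per
  depth slice) whose kernels are frozen copies of the learner's, installed
  by the *transfer path* and used by the *perception path* that feeds the
  next layer.

Both memory populations of a layer project to every population of the next
layer (crossover wiring), so each ordered long/short sequence across layers
exists as a memory pathway.  Competition is enforced by winner-take-all
inhibition: cross-depth (one winner per receptive-field location, learner
modules only), local (a spike suppresses same-depth neighbors within a
Chebyshev radius), and section-lateral (inside the multi-objective
prediction module, a spike suppresses the rest of its section only).

Neurons are placed at the operating point where ``v_reset + a/b`` equals the
per-type effective offset calibrated from the measured cut-off frequencies,
the regime in which per-spike conductance gains (~cG) and the leak slope
(~1e-3 units/ms) are commensurate and the network actually fires at
rate-coded input frequencies of 0-100 Hz.  See docs/methods.md.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import ndimage

from .neurons import LIFGrid, NeuronParams, NEURON_TYPES
from .pathways import CUTOFF_REFERENCE_G, CUTOFF_REFERENCE_HZ, calibrate_offset
from .plasticity import StdpParams, ltd_delta, ltp_delta

__all__ = [
    "ConvLayerSpec",
    "NetworkConfig",
    "SynapseStore",
    "Network",
    "build_network",
    "count_parameters",
    "default_config",
    "cross_depth_inhibit",
    "local_inhibit",
    "section_lateral_inhibit",
]

# Default threshold-to-reset gaps (potential units).  The memory gaps encode
# the threshold-scaling hyperparameter: at G = 0.5 they give gamma = 2 for
# long-term and gamma = 4 for short-term units, realizing the intended
# short/long retention ordering of memory pathways.
DEFAULT_LEARNER_GAP = 0.6
DEFAULT_MEMORY_GAPS = {"long_term": 0.15, "short_term": 0.8}


@dataclass(frozen=True)
class ConvLayerSpec:
    """One spiking convolution layer (learner + memory modules)."""

    kernel: tuple[int, int]
    depth: int
    stride: int = 2
    padding: str = "same"
    threshold_scale: float = 1.0
    memory_mix: tuple[str, ...] = ("long_term", "short_term")

    def __post_init__(self) -> None:
        kh, kw = self.kernel
        if kh % 2 == 0 or kw % 2 == 0:
            raise ValueError("kernels must be odd-sized")
        if self.depth < 1 or self.stride < 1:
            raise ValueError("depth and stride must be >= 1")
        if not (0 < self.threshold_scale <= 1):
            raise ValueError("threshold_scale must lie in (0, 1]")
        if self.padding != "same":
            raise ValueError("only 'same-before-stride' zero padding is supported")
        if not self.memory_mix or any(t not in ("long_term", "short_term") for t in self.memory_mix):
            raise ValueError("memory_mix must list 'long_term'/'short_term' populations")

    def out_shape(self, in_shape: tuple[int, int]) -> tuple[int, int]:
        H, W = in_shape
        kh, kw = self.kernel
        if kh > H or kw > W:
            raise ValueError(f"kernel {self.kernel} larger than feature map {in_shape}")
        return ((H - 1) // self.stride + 1, (W - 1) // self.stride + 1)


def default_layer_stack() -> list[ConvLayerSpec]:
    """The reference four-layer stack Conv2D{[3x3,32],[3x3,64],[5x5,128],[7x7,40]}.

    Per-layer memory threshold scales default to (1.0, 0.8, 0.6, 0.5) to
    counter the diminishing spike frequency along layers.
    """
    cfg = [((3, 3), 32, 1.0), ((3, 3), 64, 0.8), ((5, 5), 128, 0.6), ((7, 7), 40, 0.5)]
    return [ConvLayerSpec(kernel=k, depth=d, threshold_scale=s) for k, d, s in cfg]


@dataclass
class NetworkConfig:
    """Full network geometry, inhibition radii and seeds."""

    input_shape: tuple[int, int] = (128, 128)
    layers: list[ConvLayerSpec] = field(default_factory=default_layer_stack)
    mopm_sections: list[tuple[str, int]] = field(default_factory=list)
    local_radius: int = 1
    seed: int = 0
    learner_gap: float = DEFAULT_LEARNER_GAP
    memory_gaps: dict = field(default_factory=lambda: dict(DEFAULT_MEMORY_GAPS))
    stdp: StdpParams = field(default_factory=StdpParams)

    def __post_init__(self) -> None:
        if not self.layers:
            raise ValueError("at least one convolution layer is required")
        if self.local_radius < 0:
            raise ValueError("local_radius must be >= 0")


def default_config(**overrides) -> NetworkConfig:
    return NetworkConfig(**overrides)


@dataclass
class SynapseStore:
    """Bounded conductances: per-layer (D, Cin, kh, kw) tensors + MoPM matrix."""

    learner: list[np.ndarray]
    memory: list[np.ndarray]
    mopm: Optional[np.ndarray] = None


def count_parameters(config: NetworkConfig) -> tuple[int, int]:
    """(trainable conductances, neuron state variables) for a config.

    Trainable = sum over layers of kh*kw*Cin*D (single-channel input, full
    depth connectivity, no bias), plus the MoPM weight matrix if sections
    are configured.  State variables = one membrane potential per neuron
    (learner + each memory population + MoPM).
    """
    trainable = 0
    state_vars = 0
    cin = 1
    shape = config.input_shape
    for spec in config.layers:
        kh, kw = spec.kernel
        trainable += kh * kw * cin * spec.depth
        shape = spec.out_shape(shape)
        units = spec.depth * shape[0] * shape[1]
        state_vars += units * (1 + len(spec.memory_mix))
        cin = spec.depth
    if config.mopm_sections:
        feat = cin * shape[0] * shape[1] * len(config.layers[-1].memory_mix)
        n_out = sum(k for _, k in config.mopm_sections)
        trainable += feat * n_out
        state_vars += n_out
    return trainable, state_vars


# ---------------------------------------------------------------------------
# Inhibition primitives
# ---------------------------------------------------------------------------

def cross_depth_inhibit(candidates: np.ndarray, v: np.ndarray) -> np.ndarray:
    """One winner per spatial location across depths.

    The winner is the candidate with the highest pre-reset membrane
    potential; ties break to the lowest depth index.  Returns the surviving
    spike mask (losers are to be reset by the caller).
    """
    if candidates.shape != v.shape:
        raise ValueError("candidates and membrane array must have equal shape")
    if not candidates.any():
        return candidates
    masked = np.where(candidates, v, -np.inf)
    best = masked.argmax(axis=0)  # first max -> lowest depth on ties
    winners = np.zeros_like(candidates)
    yy, xx = np.nonzero(candidates.any(axis=0))
    winners[best[yy, xx], yy, xx] = True
    return winners & candidates


def local_inhibit(spikes: np.ndarray, v: np.ndarray, radius: int) -> np.ndarray:
    """Within each depth map, a winner suppresses neighbors within Chebyshev
    ``radius`` for the current timestep.

    Winners are chosen greedily by highest membrane potential, ties by
    lowest linear index; a suppressed unit neither spikes nor suppresses.
    """
    if radius < 0:
        raise ValueError("radius must be >= 0")
    if radius == 0 or not spikes.any():
        return spikes.copy()
    out = np.zeros_like(spikes)
    D, H, W = spikes.shape
    for d in range(D):
        idx = np.flatnonzero(spikes[d])
        if idx.size == 0:
            continue
        order = idx[np.lexsort((idx, -v[d].ravel()[idx]))]
        suppressed = np.zeros(H * W, dtype=bool)
        for lin in order:
            if suppressed[lin]:
                continue
            y, x = divmod(int(lin), W)
            out[d, y, x] = True
            ys, xs = slice(max(y - radius, 0), y + radius + 1), slice(max(x - radius, 0), x + radius + 1)
            block = np.zeros((H, W), dtype=bool)
            block[ys, xs] = True
            block[y, x] = False
            suppressed |= block.ravel()
    return out


def section_lateral_inhibit(
    spikes: np.ndarray, v: np.ndarray, sections: Sequence[tuple[str, int]]
) -> np.ndarray:
    """Per section, a spike suppresses all other units of that section only.

    The survivor is the spiking unit with the highest membrane potential
    (ties to the lowest index); other sections are unaffected.
    """
    sizes = [k for _, k in sections]
    if sum(sizes) != spikes.shape[0]:
        raise ValueError("section sizes must sum to the number of units")
    out = np.zeros_like(spikes)
    start = 0
    for k in sizes:
        block = slice(start, start + k)
        if spikes[block].any():
            masked = np.where(spikes[block], v[block], -np.inf)
            out[start + int(masked.argmax())] = True
        start += k
    return out


# ---------------------------------------------------------------------------
# The network
# ---------------------------------------------------------------------------

def _operating_params(type_tag: str, gap: float) -> NeuronParams:
    base = NEURON_TYPES[type_tag]
    X = calibrate_offset(CUTOFF_REFERENCE_HZ[type_tag], base, CUTOFF_REFERENCE_G)
    return base.with_operating_point(X, gap)


class _Layer:
    def __init__(self, spec: ConvLayerSpec, in_shape: tuple[int, int], cin: int,
                 config: NetworkConfig, rng: np.random.Generator):
        self.spec = spec
        self.cin = cin
        self.in_shape = in_shape
        self.out_shape = spec.out_shape(in_shape)
        kh, kw = spec.kernel
        shape = (spec.depth,) + self.out_shape
        # kernels start at mid-range conductance with seeded jitter
        p = config.stdp
        span = p.G_max - p.G_min
        self.W_learn = p.G_min + span * rng.uniform(0.3, 0.7, size=(spec.depth, cin, kh, kw))
        self.W_mem = self.W_learn.copy()
        self.learner = LIFGrid(_operating_params("learner", config.learner_gap), shape)
        self.memory = {
            tag: LIFGrid(
                _operating_params(tag, config.memory_gaps[tag] * spec.threshold_scale), shape
            )
            for tag in spec.memory_mix
        }
        self.pad = (kh // 2, kw // 2)
        # most recent pre-synaptic spike time per padded input coordinate
        self.last_pre = np.full((cin, in_shape[0] + 2 * self.pad[0], in_shape[1] + 2 * self.pad[1]), -np.inf)

    def reset(self) -> None:
        self.learner.reset()
        for grid in self.memory.values():
            grid.reset()
        self.last_pre.fill(-np.inf)

    def conv(self, x: np.ndarray, W: np.ndarray) -> np.ndarray:
        """Afferent current (D, Ho, Wo) from input spike counts (Cin, H, W)."""
        ph, pw = self.pad
        xp = np.pad(x, ((0, 0), (ph, ph), (pw, pw)))
        win = sliding_window_view(xp, self.spec.kernel, axis=(1, 2))
        s = self.spec.stride
        win = win[:, ::s, ::s]
        return np.einsum("cyxhw,dchw->dyx", win, W, optimize=True)


class Network:
    """A built heterogeneous spiking convolutional network."""

    def __init__(self, config: NetworkConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        self.layers: list[_Layer] = []
        shape, cin = config.input_shape, 1
        for spec in config.layers:
            layer = _Layer(spec, shape, cin, config, rng)
            self.layers.append(layer)
            shape, cin = layer.out_shape, spec.depth
        self.feature_dim = cin * shape[0] * shape[1] * len(config.layers[-1].memory_mix)
        if config.mopm_sections:
            n_out = sum(k for _, k in config.mopm_sections)
            self.W_mopm = rng.uniform(0.0, 0.1, size=(self.feature_dim, n_out))
            self.mopm = LIFGrid(_operating_params("learner", config.learner_gap), (n_out,))
        else:
            self.W_mopm = None
            self.mopm = None

    # -- bookkeeping --------------------------------------------------------

    @property
    def synapses(self) -> SynapseStore:
        return SynapseStore(
            learner=[l.W_learn for l in self.layers],
            memory=[l.W_mem for l in self.layers],
            mopm=self.W_mopm,
        )

    def reset_state(self) -> None:
        for layer in self.layers:
            layer.reset()
        if self.mopm is not None:
            self.mopm.reset()

    def memory_pathways(self) -> list[tuple[str, ...]]:
        """All ordered long/short type sequences realized by crossover wiring."""
        paths: list[tuple[str, ...]] = [()]
        for layer in self.layers:
            paths = [p + (tag,) for p in paths for tag in layer.spec.memory_mix]
        return paths

    def transfer_conductance(self, layer_index: int) -> None:
        """Copy learned kernels from the learner module to the memory module.

        The copy is exact and shared by both memory populations; memory
        kernels are never touched by STDP afterwards (idempotent).
        """
        layer = self.layers[layer_index]
        layer.W_mem = layer.W_learn.copy()

    # -- dynamics -----------------------------------------------------------

    def _neighborhood(self, winners: np.ndarray) -> np.ndarray:
        """Units within the local-inhibition radius of a winner (same depth)."""
        rho = self.config.local_radius
        if rho == 0 or not winners.any():
            return np.zeros_like(winners)
        size = 2 * rho + 1
        return ndimage.maximum_filter(winners, size=(1, size, size), mode="constant") & ~winners

    def _memory_step(self, layer: _Layer, x: np.ndarray) -> tuple[np.ndarray, list[np.ndarray]]:
        """Advance all memory populations one step.

        Returns (summed spike counts fanned out to the next layer, list of
        per-population winner masks in memory_mix order)."""
        current = layer.conv(x, layer.W_mem)
        out = np.zeros((layer.spec.depth,) + layer.out_shape)
        pops = []
        for grid in layer.memory.values():
            cand = grid.integrate(current)
            winners = local_inhibit(cand, grid.v, self.config.local_radius)
            grid.commit(winners, inhibited=(cand & ~winners) | self._neighborhood(winners))
            out += winners
            pops.append(winners)
        return out, pops

    def _learner_step(self, k: int, x: np.ndarray, t: float,
                      learn: bool = False) -> np.ndarray:
        """Advance layer k's learner module; optionally apply STDP at time t.

        Inhibition order: cross-depth (one winner per location; the other
        depths at a winning location are reset *and* made refractory so the
        next race starts level -- this is what keeps kernels from learning
        the same pattern), then local (a winner resets same-depth units
        within the Chebyshev radius)."""
        layer = self.layers[k]
        if learn:
            ph, pw = layer.pad
            sp = x > 0
            layer.last_pre[:, ph : ph + layer.in_shape[0], pw : pw + layer.in_shape[1]][sp] = t
        current = layer.conv(x, layer.W_learn)
        cand = layer.learner.integrate(current)
        w_depth = cross_depth_inhibit(cand, layer.learner.v)
        depth_losers = w_depth.any(axis=0)[None] & ~w_depth
        winners = local_inhibit(w_depth, layer.learner.v, self.config.local_radius)
        local_losers = (w_depth & ~winners) | self._neighborhood(winners)
        layer.learner.commit(winners, inhibited=local_losers,
                             refractory_inhibited=depth_losers & ~winners)
        if learn and winners.any():
            self._stdp_update(layer, winners, t)
        return winners.astype(float)

    def _stdp_update(self, layer: _Layer, post: np.ndarray, t: float) -> None:
        p = self.config.stdp
        s = layer.spec.stride
        kh, kw = layer.spec.kernel
        for d, y, x in zip(*np.nonzero(post)):
            patch_t = layer.last_pre[:, y * s : y * s + kh, x * s : x * s + kw]
            dt = t - patch_t
            ltp = dt <= p.ltd_window  # last pre within window (dt >= 0 causal)
            W = layer.W_learn[d]
            W[ltp] = np.minimum(W[ltp] + ltp_delta(dt[ltp], W[ltp], p), p.G_max)
            W[~ltp] = np.maximum(W[~ltp] - ltd_delta(p.ltd_window, W[~ltp], p), p.G_min)

    def forward_step(self, x: np.ndarray, t: float = 0.0,
                     learn_layer: Optional[int] = None) -> dict:
        """One 1 ms step of the perception path (and optionally one learner).

        Parameters
        ----------
        x : (Cin=1, H, W) input spike counts for this step.
        learn_layer : if given, layers < learn_layer run their memory
            modules, layer ``learn_layer`` runs its learner module with STDP,
            and deeper layers stay idle (layer-wise training contract).

        Returns a dict with per-layer memory outputs, the learner output
        when training, and MoPM spikes when sections are configured.
        """
        out: dict = {"memory": [], "learner": None, "mopm": None}
        pops: list[np.ndarray] = []
        for k, layer in enumerate(self.layers):
            if learn_layer is not None and k == learn_layer:
                out["learner"] = self._learner_step(k, x, t, learn=True)
                return out
            x, pops = self._memory_step(layer, x)
            out["memory"].append(x)
        if self.mopm is not None and learn_layer is None:
            feats = np.stack(pops).reshape(-1).astype(float)
            current = feats @ self.W_mopm
            cand = self.mopm.integrate(current)
            winners = section_lateral_inhibit(cand, self.mopm.v, self.config.mopm_sections)
            self.mopm.commit(winners, inhibited=cand & ~winners)
            out["mopm"] = winners
        return out

    def run_perception(self, raster: np.ndarray) -> np.ndarray:
        """Drive the perception path with an (H, W, T) raster; return the
        accumulated spike counts of the last layer's memory populations,
        flattened in (population, depth, y, x) order."""
        n_pops = len(self.config.layers[-1].memory_mix)
        last = self.layers[-1]
        counts = np.zeros((n_pops, last.spec.depth) + last.out_shape)
        for t in range(raster.shape[-1]):
            x = raster[None, :, :, t].astype(float)
            for layer in self.layers:
                x, pops = self._memory_step(layer, x)
            counts += np.stack(pops)
        return counts.reshape(-1)


def build_network(config: NetworkConfig) -> Network:
    """Instantiate learner/memory modules, crossover wiring and the MoPM."""
    return Network(config)
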