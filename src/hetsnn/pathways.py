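"""Closed-form calculus of memory pathways and its simulation cross-checks.

A *memory pathway* is an ordered chain of memory neurons (long-term and/or
short-term), one per network layer, connected front to back.  With a uniform
refractory period ``r`` and per-stage spike requirements ``gamma_i`` (the
minimal number of input spikes stage ``i`` needs to fire), the chain maps an
input spike rate to an output spike rate through the response function

    Phi(f_in) = ( r + prod(gamma_i)/f_in
                    + r * sum_{k=0}^{m-2} prod_{j=0}^{k} gamma_{m-j} )^{-1}

which is the m-fold composition of the single-neuron response
``F(f) = f/(gamma + r f)``.  Distinct ordered gamma sequences give distinct
response functions, and each pathway has a *retention length* ``T`` -- the
longest duration over which it can carry rate-coded information -- derived
from the cut-off frequency of its last stage.

Frequencies are handled internally in spikes/ms; user-facing helpers convert
to Hz (x1000).  The module also houses the cut-off-frequency calculus: the
exact form ``f0 = b / ln(X/(X + cG))`` with ``X = v_reset + a/b``, and the
constant-leak (small ``cG``) approximation ``f0 = s/(cG)`` under which the
cut-off scales exactly as ``1/G``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .neurons import LIFGrid, NeuronParams

__all__ = [
    "PathwaySpec",
    "CutoffModel",
    "DEFAULT_GAMMA",
    "DEFAULT_PATHWAY_REFRAC",
    "CUTOFF_REFERENCE_HZ",
    "CUTOFF_REFERENCE_G",
    "neuron_response",
    "pathway_response",
    "responses_distinct",
    "cutoff_frequency_exact",
    "cutoff_frequency_linear",
    "calibrate_offset",
    "calibrate_leak_slope",
    "mapped_cutoff_frequency",
    "retention_length",
    "simulate_pathway",
    "simulated_cutoff",
]

# Default per-stage spike requirements for the two memory neuron types.
# These realize the intended time-scale ordering (all-short-term pathways
# retain the shortest, all-long-term the longest): the memory-module
# threshold scaling is chosen so a long-term unit integrates to threshold in
# fewer input spikes than a short-term unit.  See docs/methods.md.
DEFAULT_GAMMA = {"long_term": 2, "short_term": 4}
DEFAULT_PATHWAY_REFRAC = 10.0  # ms, shared by long- and short-term neurons

# Calibration anchors: measured cut-off frequencies (Hz) of the three neuron
# types at synapse conductance G = 0.1, used to fix the one free per-type
# constant (the effective leak offset / slope) that the tabulated {a, b, c}
# leave undetermined.
CUTOFF_REFERENCE_G = 0.1
CUTOFF_REFERENCE_HZ = {"learner": 105.8, "short_term": 78.9, "long_term": 63.5}


@dataclass(frozen=True)
class PathwaySpec:
    """Ordered stages of one memory pathway.

    stages : ordered tuple of (neuron type tag, gamma) pairs
    r : uniform refractory period (ms)
    """

    stages: tuple[tuple[str, int], ...]
    r: float = DEFAULT_PATHWAY_REFRAC

    def __post_init__(self) -> None:
        if len(self.stages) < 1:
            raise ValueError("a pathway needs at least one stage")
        if any(g < 1 for _, g in self.stages):
            raise ValueError("all gamma must be >= 1")
        if self.r < 0:
            raise ValueError("refractory period must be >= 0")

    @property
    def gammas(self) -> tuple[int, ...]:
        return tuple(g for _, g in self.stages)

    @classmethod
    def from_types(cls, types: Sequence[str], r: float = DEFAULT_PATHWAY_REFRAC,
                   gamma: Optional[dict] = None) -> "PathwaySpec":
        """Build a spec from neuron-type tags using the default gammas."""
        gamma = DEFAULT_GAMMA if gamma is None else gamma
        return cls(stages=tuple((t, gamma[t]) for t in types), r=r)


@dataclass(frozen=True)
class CutoffModel:
    """Per-neuron-type cut-off model.

    params : the LIF parameterization
    G : synapse conductance
    X : effective leak offset v_reset + a/b (possibly calibrated)
    s : constant leak slope (potential units per ms, possibly calibrated)
    """

    params: NeuronParams
    G: float
    X: Optional[float] = None
    s: Optional[float] = None


def neuron_response(f_in: float, gamma: int, r: float) -> float:
    """Single-neuron response function F(f) = f/(gamma + r f), spikes/ms."""
    if f_in < 0 or gamma < 1 or r < 0:
        raise ValueError("f_in and r must be >= 0 and gamma >= 1")
    if f_in == 0:
        return 0.0
    return f_in / (gamma + r * f_in)


def pathway_response(f_in: float, spec: PathwaySpec) -> float:
    """Pathway response Phi(f_in), spikes/ms.

    Equals the left-to-right composition of :func:`neuron_response` over the
    stages; for a single stage it reduces to the neuron response exactly.
    """
    if f_in < 0:
        raise ValueError("f_in must be >= 0")
    if f_in == 0:
        return 0.0
    g = spec.gammas
    m = len(g)
    prod_all = math.prod(g)
    tail = 0.0
    for k in range(m - 1):  # k = 0 .. m-2
        tail += math.prod(g[m - 1 - j] for j in range(k + 1))
    return 1.0 / (spec.r + prod_all / f_in + spec.r * tail)


def responses_distinct(
    spec1: PathwaySpec,
    spec2: PathwaySpec,
    grid: Sequence[float] = (0.02, 0.04, 0.06, 0.08, 0.1),
) -> tuple[bool, Optional[float]]:
    """Whether two pathways have distinct response functions.

    Returns (distinct, witness frequency in spikes/ms or None).  Ordered
    gamma sequences that differ always yield a witness on a positive grid.
    """
    for f in grid:
        if abs(pathway_response(f, spec1) - pathway_response(f, spec2)) > 1e-15:
            return True, f
    return False, None


def calibrate_offset(f0_ref_hz: float, params: NeuronParams, G_ref: float) -> float:
    """Invert the exact cut-off law for the effective offset X.

    From f0 = b/ln(X/(X+cG)):  X = cG / (exp(-1000*b/f0) - 1).
    """
    if f0_ref_hz <= 0 or G_ref <= 0:
        raise ValueError("reference frequency and conductance must be positive")
    expo = math.exp(-1000.0 * params.b / f0_ref_hz)  # b < 0 so expo > 1
    return params.c * G_ref / (expo - 1.0)


def calibrate_leak_slope(f0_ref_hz: float, c: float, G_ref: float) -> float:
    """Invert the constant-leak law f0 = s/(cG) for the slope s (units/ms)."""
    if f0_ref_hz <= 0 or c <= 0 or G_ref <= 0:
        raise ValueError("all calibration arguments must be positive")
    return (f0_ref_hz / 1000.0) * c * G_ref


def cutoff_frequency_exact(model: CutoffModel) -> float:
    """Exact cut-off frequency (Hz): f0 = b / ln(X/(X + cG)).

    A periodic input strictly below f0 can never elicit a post-synaptic
    spike: below it the per-period membrane increment is negative.
    """
    p, G = model.params, model.G
    X = model.X if model.X is not None else p.v_reset + p.a / p.b
    if X <= 0:
        raise ValueError(f"domain error: effective offset X = {X} must be positive")
    if p.c * G <= 0:
        raise ValueError("c*G must be positive")
    return 1000.0 * p.b / math.log(X / (X + p.c * G))


def cutoff_frequency_linear(s: float, c: float, G: float) -> float:
    """Constant-leak cut-off (Hz): f0 = s/(cG); scales exactly as 1/G."""
    if s <= 0 or c <= 0 or G <= 0:
        raise ValueError("s, c and G must be positive")
    return 1000.0 * s / (c * G)


def mapped_cutoff_frequency(spec: PathwaySpec, f_c_last: float,
                            tol: float = 1e-9) -> float:
    """Input frequency whose pathway output hits the last stage's cut-off.

    Inverts the response function of the first m-1 stages by monotone
    bisection (Phi is strictly increasing) to tolerance ``tol``.  The
    retention length of the full pathway is the reciprocal of this mapped
    cut-off; a non-finite (infinite) retention demand maps to 0.
    """
    if f_c_last <= 0:
        raise ValueError("f_c_last must be positive")
    g = spec.gammas
    if len(g) < 2:
        raise ValueError("mapping requires a pathway of length >= 2")
    head = PathwaySpec(stages=spec.stages[:-1], r=spec.r)
    ceiling = pathway_response(1e15, head)  # saturation of the head chain
    if f_c_last >= ceiling:
        raise ValueError("cut-off exceeds the head pathway's rate ceiling")
    lo, hi = 0.0, 1.0
    while pathway_response(hi, head) < f_c_last:
        hi *= 2.0
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if pathway_response(mid, head) < f_c_last:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def retention_length(spec: PathwaySpec, f_c_last: float) -> float:
    """Retention length T (ms) of a pathway given its last stage's cut-off.

    T = ( 1/f_c - r - r * sum_{k=0}^{m-3} prod_{j=0}^{k} gamma_{m-1-j} )
        / prod_{i=1}^{m-1} gamma_i

    with frequencies in spikes/ms.  For m = 2 the sum is empty and
    T = (1/f_c - r)/gamma_1.  A non-positive return value signals that the
    pathway cannot retain information at this cut-off (not an exception).
    """
    if f_c_last <= 0:
        raise ValueError("f_c_last must be positive")
    g = spec.gammas
    m = len(g)
    if m < 2:
        raise ValueError("retention length requires a pathway of length >= 2")
    tail = 0.0
    for k in range(m - 2):  # k = 0 .. m-3
        tail += math.prod(g[m - 2 - j] for j in range(k + 1))
    return (1.0 / f_c_last - spec.r - spec.r * tail) / math.prod(g[: m - 1])


# ---------------------------------------------------------------------------
# Brute-force spiking oracles
# ---------------------------------------------------------------------------

def _integrator_params(gamma: int, r: float) -> NeuronParams:
    """Near-perfect integrator firing after exactly ``gamma`` unit inputs."""
    return NeuronParams(a=0.0, b=-1e-9, c=1.0, r_refrac=r,
                        v_reset=0.0, v_threshold=gamma - 0.5)


def _stage_outputs_from_inputs(input_bins: np.ndarray, gamma: int, r: float) -> np.ndarray:
    """Output spike bins of one refractory integrator given input spike bins.

    Event-driven walk equivalent to stepping :class:`LIFGrid` with a
    near-perfect integrator (verified against the dense simulation in the
    test suite): after an output spike at bin T the unit is dead through
    bin T + r (inputs discarded), then needs ``gamma`` further input spikes.
    """
    outs = []
    T = -1e18
    n = len(input_bins)
    while True:
        i = int(np.searchsorted(input_bins, T + r + 1))
        if i + gamma - 1 >= n:
            break
        T = float(input_bins[i + gamma - 1])
        outs.append(T)
    return np.asarray(outs)


def _dense_stage_outputs(input_bins: np.ndarray, gamma: int, r: float,
                         n_bins: int) -> np.ndarray:
    """Same stage dynamics via dense 1 ms stepping of :class:`LIFGrid`."""
    train = np.zeros(n_bins)
    train[np.asarray(input_bins, dtype=int)] = 1.0
    grid = LIFGrid(_integrator_params(gamma, r), shape=(1,))
    outs = []
    cur = np.zeros(1)
    for i in range(n_bins):
        cur[0] = train[i]
        if grid.step(cur)[0]:
            outs.append(i)
    return np.asarray(outs, dtype=float)


def _simulate_stage(f_in: float, gamma: int, r: float, rng: np.random.Generator,
                    min_duration: float, min_intervals: int = 1200) -> float:
    """Drive one refractory integrator with a Bernoulli(f_in) train (1 ms bins).

    Returns the measured output rate in spikes/ms over full inter-spike
    epochs.  For memoryless input the mean inter-spike interval is exactly
    r + gamma/f_in, so the measurement converges to the response function
    F(f_in) = f_in/(gamma + r*f_in).  The simulated duration is stretched so
    that at least ~``min_intervals`` output intervals are observed.
    """
    duration = max(min_duration, min_intervals * (r + gamma / f_in))
    n_bins = int(duration)
    input_bins = np.flatnonzero(rng.random(n_bins) < f_in)
    outs = _stage_outputs_from_inputs(input_bins, gamma, r)
    if len(outs) < 2:
        return 0.0
    return (len(outs) - 1) / (outs[-1] - outs[0])


def simulate_pathway(
    f_in_hz: float,
    spec: PathwaySpec,
    duration_ms: float = 30_000.0,
    seed: int = 0,
    mode: str = "rate",
    dt: float = 1.0,
    min_intervals: int = 1200,
) -> float:
    """Brute-force spiking simulation of a pathway; returns output rate (Hz).

    mode="rate" (default): each stage is a genuine spiking simulation of a
    refractory integrator needing ``gamma`` input spikes, driven by a seeded
    Bernoulli train at the *measured* rate of the previous stage.  This is
    the rate-coded chaining the response calculus describes (information is
    carried by rates) and is unbiased for memoryless input.

    mode="direct": the literal output spike train of each stage feeds the
    next.  Because consecutive stages share the refractory period, the
    direct chain never loses input spikes to refractoriness and runs faster
    than the calculus by up to r per output period; exposed for comparison.
    """
    if f_in_hz < 0:
        raise ValueError("f_in_hz must be >= 0")
    if mode not in ("rate", "direct"):
        raise ValueError(f"unknown mode {mode!r}")
    rng = np.random.default_rng(seed)
    f = f_in_hz / 1000.0
    if mode == "rate":
        for _, gamma in spec.stages:
            if f <= 0:
                return 0.0
            f = _simulate_stage(f, gamma, spec.r, rng, min_duration=duration_ms,
                                min_intervals=min_intervals)
        return f * 1000.0

    n_bins = int(round(duration_ms / dt))
    bins = np.flatnonzero(rng.random(n_bins) < f * dt)
    for _, gamma in spec.stages:
        bins = _stage_outputs_from_inputs(bins, gamma, spec.r)
    if bins.size < 2:
        return 0.0
    return 1000.0 * (bins.size - 1) / ((bins[-1] - bins[0]) * dt)


def _spikes_at(params: NeuronParams, G: float, f_hz: float, duration_ms: float,
               dt: float = 0.1) -> int:
    """Fine-step Euler count of output spikes under periodic input at f_hz.

    Each input spike deposits the exact delta-current jump c*G after the
    leak update of its step.
    """
    period = 1000.0 / f_hz
    n_steps = int(round(duration_ms / dt))
    spike_bins = np.zeros(n_steps, dtype=bool)
    k = 1
    while k * period < duration_ms:
        spike_bins[int(k * period / dt)] = True
        k += 1
    v = params.v_reset
    refrac = 0.0
    count = 0
    a, b, c = params.a, params.b, params.c
    for i in range(n_steps):
        if refrac > 0:
            refrac -= dt
            v = params.v_reset
            continue
        v = v + dt * (a + b * v)
        if spike_bins[i]:
            v += c * G
        if v > params.v_threshold:
            count += 1
            v = params.v_reset
            refrac = params.r_refrac
    return count


def simulated_cutoff(
    params: NeuronParams,
    G: float,
    X: float,
    f_lo_hz: float,
    f_hi_hz: float,
    duration_ms: float = 10_000.0,
    tol_hz: float = 1.0,
    dt: float = 0.1,
) -> float:
    """Bisection estimate (Hz) of the lowest periodic rate that elicits spikes.

    The neuron is placed at the operating point ``v_reset + a/b = X`` with a
    threshold gap of ``cG`` (plus a hair to keep a lone spike subthreshold):
    at that gap the reach-threshold cut-off coincides with the
    increment-sign cut-off of the exact law, because the asymptotic
    potential under periodic input at exactly f0 is v_reset + cG.
    """
    p = params.with_operating_point(X, params.c * G * (1.0 + 1e-9))
    if _spikes_at(p, G, f_lo_hz, duration_ms, dt=dt) > 0:
        raise ValueError("f_lo_hz already elicits spikes; lower the bracket")
    if _spikes_at(p, G, f_hi_hz, duration_ms, dt=dt) == 0:
        raise ValueError("f_hi_hz elicits no spikes; raise the bracket")
    lo, hi = f_lo_hz, f_hi_hz
    while hi - lo > tol_hz:
        mid = 0.5 * (lo + hi)
        if _spikes_at(p, G, mid, duration_ms, dt=dt) > 0:
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)
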