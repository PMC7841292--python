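"""Leaky integrate-and-fire membrane dynamics for the three heterogeneous neuron types.

The membrane obeys ``dv/dt = a + b*v + c*I`` with ``b = -1/tau_m`` and
``c = R_m/tau_m``, so the classical LIF form ``tau_m dv/dt = a + R_m I - v``
is recovered with ``tau_m = -1/b`` and ``R_m = -c/b``.  A spike is emitted
when ``v > v_threshold`` (strict, evaluated after the Euler update); the
membrane is then clamped to ``v_reset`` for the refractory period, during
which inputs are discarded.

Three parameterizations are used throughout the package:

* **learner** -- balanced decay/response, drives STDP learning;
* **short-term** -- fast decay, represents short memory;
* **long-term** -- slow decay, represents long memory.

Time is in milliseconds and the default integration step is 1 ms (forward
Euler); a finer ``dt`` exists for oracle-style cross checks.  Input current
is interpreted per-step such that one pre-synaptic spike carried with
conductance ``G`` raises the membrane by ``c*G`` (delta-current convention;
see :func:`drive_with_spikes`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "NeuronParams",
    "NeuronState",
    "LEARNER",
    "SHORT_TERM",
    "LONG_TERM",
    "NEURON_TYPES",
    "step",
    "decay_time",
    "membrane_closed_form",
    "gamma_no_decay",
    "gamma_min_spikes",
    "drive_with_spikes",
    "LIFGrid",
]


@dataclass(frozen=True)
class NeuronParams:
    """LIF parameterization {a, b, c} plus reset/threshold/refractory.

    a : drive term (potential units per ms)
    b : leak coefficient (1/ms, negative); tau_m = -1/b
    c : input gain (potential units per unit synaptic conductance); R_m = -c/b
    r_refrac : refractory period (ms)
    v_reset, v_threshold : reset and spiking threshold potentials
    """

    a: float
    b: float
    c: float
    r_refrac: float = 0.0
    v_reset: float = 0.0
    v_threshold: float = 1.0

    def __post_init__(self) -> None:
        if not self.b < 0:
            raise ValueError(f"leak coefficient b must be negative, got {self.b}")
        if self.r_refrac < 0:
            raise ValueError(f"refractory period must be >= 0, got {self.r_refrac}")
        if not self.v_threshold > self.v_reset:
            raise ValueError("v_threshold must exceed v_reset")

    @property
    def tau_m(self) -> float:
        """Membrane time constant (ms)."""
        return -1.0 / self.b

    @property
    def R_m(self) -> float:
        """Membrane resistance (potential units per unit current)."""
        return -self.c / self.b

    @property
    def v_equilibrium(self) -> float:
        """Resting point of the leak, -a/b."""
        return -self.a / self.b

    def with_operating_point(self, offset: float, gap: float) -> "NeuronParams":
        """Return params shifted so that ``v_reset + a/b == offset``.

        ``offset`` is the effective leak offset X near the working range and
        ``gap`` the threshold-to-reset distance.  Used by the network to run
        neurons in the regime consistent with their calibrated cut-off
        frequencies.
        """
        v_reset = offset - self.a / self.b
        return replace(self, v_reset=v_reset, v_threshold=v_reset + gap)


# Manually tuned parameters of the three neuron types (a, b, c, r in ms).
LEARNER = NeuronParams(a=-4.1, b=-0.01, c=0.31, r_refrac=20.0)
SHORT_TERM = NeuronParams(a=-5.1, b=-0.02, c=0.45, r_refrac=10.0)
LONG_TERM = NeuronParams(a=-1.6, b=-0.001, c=0.16, r_refrac=10.0)

NEURON_TYPES = {
    "learner": LEARNER,
    "short_term": SHORT_TERM,
    "long_term": LONG_TERM,
}


@dataclass
class NeuronState:
    """Per-neuron membrane state."""

    v: float
    refractory_remaining: float = 0.0
    last_spike_time: Optional[float] = None


def step(
    state: NeuronState,
    params: NeuronParams,
    input_current: float,
    dt: float = 1.0,
    t: Optional[float] = None,
) -> tuple[NeuronState, bool]:
    """Advance one Euler step; return (new state, spiked).

    During the refractory period the membrane is held at ``v_reset`` and the
    input is discarded; only the refractory counter advances.
    """
    if not (dt > 0):
        raise ValueError(f"dt must be positive, got {dt}")
    if not math.isfinite(input_current):
        raise ValueError(f"input current must be finite, got {input_current}")

    if state.refractory_remaining > 0:
        return (
            NeuronState(
                v=params.v_reset,
                refractory_remaining=max(0.0, state.refractory_remaining - dt),
                last_spike_time=state.last_spike_time,
            ),
            False,
        )

    v = state.v + dt * (params.a + params.b * state.v + params.c * input_current)
    if v > params.v_threshold:
        return (
            NeuronState(
                v=params.v_reset,
                refractory_remaining=params.r_refrac,
                last_spike_time=t,
            ),
            True,
        )
    return NeuronState(v=v, refractory_remaining=0.0, last_spike_time=state.last_spike_time), False


def decay_time(params: NeuronParams, input_current_pulse: float) -> float:
    """Time (ms) for the membrane to decay back to ``v_reset``.

    After a single pulse that lifts the membrane from ``v_reset`` to
    ``v_reset + c*I``, the decay time is

        t_decay = (1/b) * [ln(v_reset + a/b) - ln(v_reset + a/b + c*I)]

    which requires both log arguments positive under the adopted convention.
    """
    X = params.v_reset + params.a / params.b
    arg2 = X + params.c * input_current_pulse
    if X <= 0:
        raise ValueError(f"domain error: v_reset + a/b = {X} must be positive")
    if arg2 <= 0:
        raise ValueError(f"domain error: v_reset + a/b + c*I = {arg2} must be positive")
    return (math.log(X) - math.log(arg2)) / params.b


def membrane_closed_form(
    params: NeuronParams,
    pre_spike_times: Sequence[float],
    G: float,
    t: float,
) -> float:
    """Closed-form membrane potential under delta-current pre-synaptic spikes.

    v(t) = v_reset e^{bt} - (a/b)(1 - e^{bt}) + c e^{bt} sum_i G e^{-b t_i}

    Pure function of the spike times (sorted, all <= t).
    """
    if t < 0:
        raise ValueError("t must be >= 0")
    times = np.asarray(pre_spike_times, dtype=float)
    if times.size and (np.any(np.diff(times) < 0) or np.any(times > t)):
        raise ValueError("pre-synaptic spike times must be sorted and <= t")
    a, b, c = params.a, params.b, params.c
    ebt = math.exp(b * t)
    v = params.v_reset * ebt - (a / b) * (1.0 - ebt)
    if times.size:
        v += c * G * float(np.sum(np.exp(b * (t - times))))
    return v


def gamma_no_decay(params: NeuronParams, G: float) -> int:
    """No-decay approximation of gamma: ceil((v_th - v_reset)/(c G))."""
    if G <= 0:
        raise ValueError("G must be positive")
    return math.ceil((params.v_threshold - params.v_reset) / (params.c * G))


def gamma_min_spikes(
    params: NeuronParams,
    G: float,
    f_in: float,
    max_spikes: int = 100_000,
) -> Optional[int]:
    """Minimal number of periodic input spikes (at ``f_in`` spikes/ms) to fire.

    Simulates the exact between-spike decay recurrence.  Returns ``None``
    (the no-spike signal) when the input frequency is at/below the neuron's
    cut-off, i.e. when the membrane can never reach threshold regardless of
    the number of input spikes.
    """
    if G <= 0 or f_in <= 0:
        raise ValueError("G and f_in must be positive")
    a, b, c = params.a, params.b, params.c
    dt_period = 1.0 / f_in
    decay = math.exp(b * dt_period)
    v = params.v_reset
    for n in range(1, max_spikes + 1):
        v_after = v + c * G
        if v_after > params.v_threshold:
            return n
        v_next = (v_after + a / b) * decay - a / b
        if n > 1 and v_next - v <= 1e-12:
            # per-period gain non-positive (below cut-off) or membrane has
            # converged to an asymptote under threshold: will never fire
            return None
        v = v_next
    return None


def drive_with_spikes(
    params: NeuronParams,
    spike_times: Sequence[float],
    G: float,
    t_end: float,
    dt: float = 1.0,
    v0: Optional[float] = None,
) -> tuple[np.ndarray, list[float]]:
    """Euler-integrate a single neuron driven by delta-current input spikes.

    Each input spike deposits ``c*G`` of potential (current ``G/dt`` applied
    for one step).  Returns the membrane trajectory sampled at every step and
    the list of output spike times.  Serves as the brute-force oracle for the
    closed-form expressions.
    """
    n_steps = int(round(t_end / dt))
    bins = np.zeros(n_steps, dtype=np.int64)
    for ts in spike_times:
        idx = int(math.floor(ts / dt + 1e-9))
        if 0 <= idx < n_steps:
            bins[idx] += 1
    state = NeuronState(v=params.v_reset if v0 is None else v0)
    traj = np.empty(n_steps + 1)
    traj[0] = state.v
    out: list[float] = []
    for i in range(n_steps):
        current = bins[i] * G / dt
        state, spiked = step(state, params, current, dt=dt, t=i * dt)
        if spiked:
            out.append(i * dt)
        traj[i + 1] = state.v
    return traj, out


class LIFGrid:
    """Vectorized LIF population on an arbitrary grid shape.

    All units share one :class:`NeuronParams`; an optional per-grid threshold
    override supports memory-module threshold scaling.  The two-phase
    interface (``integrate`` then ``commit``) lets callers interpose
    winner-take-all inhibition between threshold crossing and reset.
    """

    def __init__(self, params: NeuronParams, shape: tuple[int, ...], dt: float = 1.0):
        self.params = params
        self.shape = shape
        self.dt = dt
        self.v = np.full(shape, params.v_reset, dtype=float)
        self.refrac = np.zeros(shape, dtype=float)

    def reset(self) -> None:
        self.v.fill(self.params.v_reset)
        self.refrac.fill(0.0)

    def integrate(self, current: np.ndarray) -> np.ndarray:
        """Euler-update active units, advance refractory counters.

        Returns the boolean mask of threshold crossings (spike candidates).
        The membrane is left at its pre-reset value so that inhibition can
        rank candidates by potential; call :meth:`commit` to finalize.
        """
        p = self.params
        active = self.refrac <= 0
        self.refrac[~active] -= self.dt
        np.maximum(self.refrac, 0.0, out=self.refrac)
        dv = self.dt * (p.a + p.b * self.v + p.c * current)
        self.v = np.where(active, self.v + dv, p.v_reset)
        return active & (self.v > p.v_threshold)

    def commit(
        self,
        spikes: np.ndarray,
        inhibited: Optional[np.ndarray] = None,
        refractory_inhibited: Optional[np.ndarray] = None,
    ) -> None:
        """Reset spiking units (entering refractory) and inhibited losers.

        ``refractory_inhibited`` marks losers that are additionally given a
        full refractory period (used by cross-depth competition so that all
        depths at a location re-race from an equal start).
        """
        p = self.params
        self.v[spikes] = p.v_reset
        self.refrac[spikes] = p.r_refrac
        if inhibited is not None:
            self.v[inhibited] = p.v_reset
        if refractory_inhibited is not None:
            self.v[refractory_inhibited] = p.v_reset
            self.refrac[refractory_inhibited] = p.r_refrac

    def step(self, current: np.ndarray) -> np.ndarray:
        """Plain step without inhibition: integrate and commit in one call."""
        spikes = self.integrate(current)
        self.commit(spikes)
        return spikes
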