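"""Conductance-dependent STDP (LTP/LTD) with soft bounds.

The update magnitude depends exponentially on both the pre/post spike-time
difference and the current conductance, so that potentiation saturates as
``G`` approaches ``G_max`` and depression saturates toward ``G_min``
(soft-bound behavior):

    dG_p = alpha_p * exp(-dt * (G - G_min) / (tau_pot * (G_max - G_min)))
    dG_d = alpha_d * exp(-dt * (G_max - G) / (tau_dep * (G_max - G_min)))

``dt = t_post - t_pre >= 0`` triggers LTP (causal pairing).  A post spike
whose nearest pre spike arrives *after* it is depressed with
``dt = |t_post - t_pre|``; a post spike with no pre spike within the LTD
window is depressed with ``dt = ltd_window`` (bounded-memory policy).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["StdpParams", "ltp_delta", "ltd_delta", "apply_stdp"]


@dataclass(frozen=True)
class StdpParams:
    """STDP parameters; defaults are the tuned values used throughout."""

    alpha_p: float = 0.1
    alpha_d: float = 0.03
    G_max: float = 1.0
    G_min: float = 0.0
    tau_pot: float = 10.0
    tau_dep: float = 80.0
    ltd_window: float = 50.0

    def __post_init__(self) -> None:
        if not self.G_max > self.G_min:
            raise ValueError("G_max must exceed G_min")
        if self.alpha_p <= 0 or self.alpha_d <= 0:
            raise ValueError("alpha_p and alpha_d must be positive")
        if self.tau_pot <= 0 or self.tau_dep <= 0 or self.ltd_window <= 0:
            raise ValueError("time constants must be positive")


def _check_G(G, p: StdpParams) -> np.ndarray:
    G = np.asarray(G, dtype=float)
    if np.any(G < p.G_min - 1e-12) or np.any(G > p.G_max + 1e-12):
        raise ValueError("conductance outside [G_min, G_max]")
    return G


def ltp_delta(delta_t, G, p: StdpParams = StdpParams()):
    """Potentiation magnitude for a causal pair at lag ``delta_t >= 0``."""
    delta_t = np.asarray(delta_t, dtype=float)
    if np.any(delta_t < 0):
        raise ValueError("delta_t must be >= 0")
    G = _check_G(G, p)
    out = p.alpha_p * np.exp(-delta_t * (G - p.G_min) / (p.tau_pot * (p.G_max - p.G_min)))
    return float(out) if out.ndim == 0 else out


def ltd_delta(delta_t, G, p: StdpParams = StdpParams()):
    """Depression magnitude at lag ``delta_t >= 0``."""
    delta_t = np.asarray(delta_t, dtype=float)
    if np.any(delta_t < 0):
        raise ValueError("delta_t must be >= 0")
    G = _check_G(G, p)
    out = p.alpha_d * np.exp(-delta_t * (p.G_max - G) / (p.tau_dep * (p.G_max - p.G_min)))
    return float(out) if out.ndim == 0 else out


def apply_stdp(
    synapses: np.ndarray,
    pre_raster: np.ndarray,
    post_raster: np.ndarray,
    p: StdpParams = StdpParams(),
    policy: str = "nearest",
) -> np.ndarray:
    """Apply pair-based STDP over full rasters; returns updated conductances.

    Parameters
    ----------
    synapses : (n_pre, n_post) conductance matrix (modified copy returned).
    pre_raster : (n_pre, n_bins) binary spike raster on the 1 ms grid.
    post_raster : (n_post, n_bins) binary raster on the same grid.
    policy : "nearest" pairs each post spike with the temporally nearest pre
        spike per afferent (default); "all" pairs with every causal pre spike
        inside the LTD window.

    For each post spike, per afferent: a pre spike at ``dt = t_post - t_pre``
    in ``[0, ltd_window]`` potentiates; a nearest pre spike after the post
    spike (within the window) depresses with ``dt = |t_post - t_pre|``; no
    pre spike within the window depresses with ``dt = ltd_window``.  Updates
    are applied in temporal order using the running conductance and clamped
    to ``[G_min, G_max]``.
    """
    if policy not in ("nearest", "all"):
        raise ValueError(f"unknown pairing policy {policy!r}")
    pre = np.asarray(pre_raster, dtype=bool)
    post = np.asarray(post_raster, dtype=bool)
    if pre.ndim != 2 or post.ndim != 2 or pre.shape[1] != post.shape[1]:
        raise ValueError("pre and post rasters must be 2-D on the same time grid")
    G = np.array(synapses, dtype=float)
    if G.shape != (pre.shape[0], post.shape[0]):
        raise ValueError("synapse matrix shape must be (n_pre, n_post)")
    _check_G(G, p)

    n_pre, n_bins = pre.shape
    pre_times = [np.flatnonzero(pre[i]).astype(float) for i in range(n_pre)]
    for t_post in np.flatnonzero(post.any(axis=0)).astype(float):
        posts = np.flatnonzero(post[:, int(t_post)])
        for i in range(n_pre):
            times = pre_times[i]
            causal = times[(times <= t_post) & (t_post - times <= p.ltd_window)]
            acausal = times[(times > t_post) & (times - t_post <= p.ltd_window)]
            for j in posts:
                if causal.size:
                    if policy == "all":
                        for tp in causal:
                            dG = ltp_delta(t_post - tp, G[i, j], p)
                            G[i, j] = min(G[i, j] + dG, p.G_max)
                    else:
                        dG = ltp_delta(t_post - causal[-1], G[i, j], p)
                        G[i, j] = min(G[i, j] + dG, p.G_max)
                elif acausal.size:
                    dG = ltd_delta(acausal[0] - t_post, G[i, j], p)
                    G[i, j] = max(G[i, j] - dG, p.G_min)
                else:
                    dG = ltd_delta(p.ltd_window, G[i, j], p)
                    G[i, j] = max(G[i, j] - dG, p.G_min)
    return G
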