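"""Rate encoding of frames into spike rasters, and event-stream accumulation.

Pixel intensity ``p`` in [0, 1] maps linearly to a firing rate ``p * f_max``
(default 0-100 Hz).  Rasters live on a 1 ms grid with at most one spike per
unit per bin; shape is ``(units..., n_bins)``.

Two encoders are provided: ``poisson`` (default; per-bin Bernoulli draws,
biologically standard for rate codes) and ``periodic`` (evenly spaced
spikes starting at the first full period; the analytic pathway lemmas
assume regular trains).

Event lists (timestamp, x, y, polarity) from an event camera are
accumulated into frames over fixed half-open time windows; counts are
normalized to [0, 1] by the per-sequence maximum.
"""

from __future__ import annotations

import json
import logging
import math
from pathlib import Path

import numpy as np

__all__ = [
    "frames_to_spikes",
    "encode_sequence",
    "events_to_frames",
    "save_raster",
    "load_raster",
]

logger = logging.getLogger(__name__)

DT_MS = 1.0


def frames_to_spikes(
    frame: np.ndarray,
    f_max: float = 100.0,
    t_obs: float = 300.0,
    mode: str = "poisson",
    seed: int = 0,
) -> np.ndarray:
    """Encode one intensity frame as a spike raster of shape (H, W, n_bins).

    A pixel with intensity ``p`` fires at rate ``p * f_max`` Hz over
    ``t_obs`` ms.  Periodic mode places spike k at time (k+1)/rate (first
    spike after one full period), so the count is floor(p*f_max*t_obs/1000).
    Poisson mode draws per-bin Bernoulli(p*f_max*dt) with the given seed.
    """
    frame = np.asarray(frame, dtype=float)
    if np.any(frame < 0) or np.any(frame > 1):
        raise ValueError("intensities must lie in [0, 1] (divide 8-bit input by 255)")
    if f_max <= 0 or t_obs <= 0:
        raise ValueError("f_max and t_obs must be positive")
    n_bins = int(round(t_obs / DT_MS))
    rate_per_ms = frame * f_max / 1000.0  # spikes per ms per pixel

    if mode == "poisson":
        rng = np.random.default_rng(seed)
        return rng.random(frame.shape + (n_bins,)) < rate_per_ms[..., None]
    if mode == "periodic":
        raster = np.zeros(frame.shape + (n_bins,), dtype=bool)
        it = np.nditer(rate_per_ms, flags=["multi_index"])
        for q in it:
            q = float(q)
            if q <= 0:
                continue
            period = 1.0 / q
            k = 1
            while k * period <= n_bins + 1e-9:
                raster[it.multi_index + (math.ceil(k * period) - 1,)] = True
                k += 1
        return raster
    raise ValueError(f"unknown encoding mode {mode!r}")


def encode_sequence(
    frames: np.ndarray,
    f_max: float = 100.0,
    t_obs: float = 300.0,
    mode: str = "poisson",
    seed: int = 0,
) -> np.ndarray:
    """Encode a (T, H, W) frame stack into one (H, W, T*n_bins) raster.

    Each frame is observed for ``t_obs`` ms; per-frame sub-seeds are derived
    from ``seed`` so the encoding is reproducible frame by frame.
    """
    frames = np.asarray(frames, dtype=float)
    if frames.ndim != 3:
        raise ValueError("frames must be a (T, H, W) stack")
    ss = np.random.SeedSequence(seed).spawn(frames.shape[0])
    parts = [
        frames_to_spikes(frames[i], f_max=f_max, t_obs=t_obs, mode=mode,
                         seed=int(ss[i].generate_state(1)[0] % (2**31)))
        for i in range(frames.shape[0])
    ]
    return np.concatenate(parts, axis=-1)


def events_to_frames(
    events: np.ndarray,
    window: float = 20.0,
    resolution: tuple[int, int] = (128, 128),
    polarity: str = "both",
    normalize: bool = True,
) -> np.ndarray:
    """Accumulate (t, x, y, p) event rows into a (T, H, W) frame stack.

    Frame ``k`` collects events with ``t in [k*window, (k+1)*window)``
    (half-open).  Both polarities are accumulated additively by default;
    ``polarity="positive"`` keeps only rows with p > 0.  Out-of-bounds
    coordinates are skipped with a logged warning count.  With
    ``normalize=True`` counts are scaled to [0, 1] by the per-sequence max.
    """
    events = np.asarray(events, dtype=float)
    if events.size == 0:
        return np.zeros((1,) + tuple(resolution))
    if events.ndim != 2 or events.shape[1] != 4:
        raise ValueError("events must be rows of (t, x, y, polarity)")
    if polarity not in ("both", "positive"):
        raise ValueError(f"unknown polarity mode {polarity!r}")
    H, W = resolution
    t, x, y, p = events.T
    keep = np.ones(len(events), dtype=bool)
    if polarity == "positive":
        keep &= p > 0
    in_bounds = (x >= 0) & (x < W) & (y >= 0) & (y < H)
    n_skipped = int(np.count_nonzero(keep & ~in_bounds))
    if n_skipped:
        logger.warning("events_to_frames: skipped %d out-of-bounds events", n_skipped)
    keep &= in_bounds
    t, x, y = t[keep], x[keep].astype(int), y[keep].astype(int)
    n_frames = max(1, int(np.max(t) // window) + 1)
    frames = np.zeros((n_frames, H, W))
    k = (t // window).astype(int)
    np.add.at(frames, (k, y, x), 1.0)
    if normalize and frames.max() > 0:
        frames /= frames.max()
    return frames


def save_raster(path, raster: np.ndarray) -> None:
    """Write a raster as packed bits plus a JSON sidecar header (.hdr.json)."""
    path = Path(path)
    raster = np.asarray(raster, dtype=bool)
    packed = np.packbits(raster.reshape(-1))
    path.write_bytes(packed.tobytes())
    header = {"shape": list(raster.shape), "dtype": "bool", "packing": "bitorder=big"}
    path.with_suffix(path.suffix + ".hdr.json").write_text(json.dumps(header))


def load_raster(path) -> np.ndarray:
    path = Path(path)
    header = json.loads(path.with_suffix(path.suffix + ".hdr.json").read_text())
    shape = tuple(header["shape"])
    n = int(np.prod(shape))
    bits = np.unpackbits(np.frombuffer(path.read_bytes(), dtype=np.uint8), count=n)
    return bits.astype(bool).reshape(shape)
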