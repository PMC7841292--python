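"""Synthetic moving-object sequences and toy spike patterns.

Renders a sprite onto a canvas with independently controlled translation
and rotation, each following one of five motion dynamics:

* ``static`` -- no change;
* ``constant`` -- linear in time;
* ``accelerating`` -- quadratic with positive acceleration;
* ``decelerating`` -- quadratic with negative acceleration, speed clamped
  at zero;
* ``oscillating`` -- sinusoidal.

Training sequences use the exact dynamic parameters; test sequences perturb
each numeric parameter with Gaussian noise of standard deviation
``sigma_ts`` around the training value, emulating motion never seen exactly
during training.  Sprites default to procedurally generated shapes (bars,
crosses, blobs with distinct spatial-frequency content) so no external
imagery is needed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage

from .encoding import DT_MS

__all__ = [
    "MOTION_KINDS",
    "MotionSpec",
    "SequenceSample",
    "make_sprite",
    "default_sprites",
    "render_sequence",
    "make_dataset",
    "toy_spike_pattern",
]

MOTION_KINDS = ("static", "constant", "accelerating", "decelerating", "oscillating")


@dataclass(frozen=True)
class MotionSpec:
    """One motion dynamic applied to translation or rotation.

    For translation, speed/acceleration/amplitude are in px per frame (and
    px/frame^2); ``direction`` is the unit heading in (dy, dx).  For
    rotation the same fields are read in degrees per frame.
    ``period`` (frames) applies to the oscillating kind only.
    """

    kind: str
    applies_to: str = "translation"
    speed: float = 0.0
    acceleration: float = 0.0
    amplitude: float = 0.0
    period: float = 8.0
    direction: tuple[float, float] = (0.0, 1.0)

    def __post_init__(self) -> None:
        if self.kind not in MOTION_KINDS:
            raise ValueError(f"kind must be one of {MOTION_KINDS}, got {self.kind!r}")
        if self.applies_to not in ("translation", "rotation"):
            raise ValueError("applies_to must be 'translation' or 'rotation'")
        for name in ("speed", "acceleration", "amplitude", "period"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")

    def displacement(self, t: float) -> float:
        """Scalar displacement along the motion axis at frame index ``t``."""
        if self.kind == "static":
            return 0.0
        if self.kind == "constant":
            return self.speed * t
        if self.kind == "accelerating":
            return self.speed * t + 0.5 * self.acceleration * t * t
        if self.kind == "decelerating":
            # speed ramps down to zero at t_stop and stays there
            a = abs(self.acceleration)
            if a == 0:
                return self.speed * t
            t_stop = self.speed / a
            if t <= t_stop:
                return self.speed * t - 0.5 * a * t * t
            return 0.5 * self.speed * t_stop
        # oscillating
        return self.amplitude * math.sin(2.0 * math.pi * t / self.period)

    def perturbed(self, rng: np.random.Generator, sigma: float) -> "MotionSpec":
        """Gaussian-perturb each numeric parameter (mean = this spec)."""
        if sigma < 0:
            raise ValueError("sigma must be >= 0")
        if sigma == 0:
            return self
        return replace(
            self,
            speed=self.speed + rng.normal(0.0, sigma),
            acceleration=self.acceleration + rng.normal(0.0, sigma),
            amplitude=self.amplitude + rng.normal(0.0, sigma),
            period=max(1.0, self.period + rng.normal(0.0, sigma)),
        )


@dataclass
class SequenceSample:
    """Rendered frame stack plus its generating labels."""

    frames: np.ndarray  # (T, H, W) intensities in [0, 1]
    class_label: int
    rotation_label: int
    translation_label: int


def make_sprite(kind: str, size: int = 12) -> np.ndarray:
    """Procedural sprite with intensities in [0, 1]."""
    s = np.zeros((size, size))
    mid = size // 2
    w = max(1, size // 6)
    if kind == "vbar":
        s[:, mid - w : mid + w] = 1.0
    elif kind == "hbar":
        s[mid - w : mid + w, :] = 1.0
    elif kind == "cross":
        s[:, mid - w : mid + w] = 1.0
        s[mid - w : mid + w, :] = 1.0
    elif kind == "blob":
        yy, xx = np.mgrid[0:size, 0:size]
        s = np.exp(-(((yy - mid) ** 2 + (xx - mid) ** 2) / (2 * (size / 4.0) ** 2)))
    elif kind == "ring":
        yy, xx = np.mgrid[0:size, 0:size]
        rr = np.sqrt((yy - mid) ** 2 + (xx - mid) ** 2)
        s = ((rr > size / 4.0) & (rr < size / 2.5)).astype(float)
    else:
        raise ValueError(f"unknown sprite kind {kind!r}")
    return s


def default_sprites(n_classes: int = 2, size: int = 12) -> list[np.ndarray]:
    kinds = ("vbar", "cross", "hbar", "blob", "ring")
    if n_classes > len(kinds):
        raise ValueError(f"at most {len(kinds)} default sprite classes")
    return [make_sprite(k, size) for k in kinds[:n_classes]]


def render_sequence(
    sprite: np.ndarray,
    translation: MotionSpec,
    rotation: MotionSpec,
    canvas: tuple[int, int] = (32, 32),
    n_frames: int = 10,
    seed: int = 0,
    start: Optional[tuple[float, float]] = None,
    on_exit: str = "clamp",
    labels: tuple[int, int, int] = (0, 0, 0),
) -> SequenceSample:
    """Render a sprite under the given translation/rotation kinematics.

    Frame ``t`` places the (bilinearly rotated) sprite centered at
    ``start + displacement(t) * direction``; background is zero.  A sprite
    about to leave the canvas is clamped at the edge (``on_exit="clamp"``)
    or raises (``on_exit="error"``).
    """
    if translation.applies_to != "translation" or rotation.applies_to != "rotation":
        raise ValueError("pass a translation spec and a rotation spec, in that order")
    if on_exit not in ("clamp", "error"):
        raise ValueError("on_exit must be 'clamp' or 'error'")
    sprite = np.asarray(sprite, dtype=float)
    H, W = canvas
    sh = sprite.shape[0]
    half = sh / 2.0
    if sh > min(H, W):
        raise ValueError("sprite does not fit the canvas")
    if start is None:
        margin = half + 1.0
        start = (H / 2.0, margin) if abs(translation.direction[1]) >= abs(translation.direction[0]) else (margin, W / 2.0)

    dy, dx = translation.direction
    norm = math.hypot(dy, dx) or 1.0
    dy, dx = dy / norm, dx / norm
    frames = np.zeros((n_frames, H, W))
    for t in range(n_frames):
        d = translation.displacement(float(t))
        cy, cx = start[0] + d * dy, start[1] + d * dx
        lo = half
        if not (lo <= cy <= H - lo and lo <= cx <= W - lo):
            if on_exit == "error":
                raise ValueError(f"sprite leaves canvas at frame {t}")
            cy = min(max(cy, lo), H - lo)
            cx = min(max(cx, lo), W - lo)
        theta = rotation.displacement(float(t))
        patch = sprite if theta == 0.0 else np.clip(
            ndimage.rotate(sprite, theta, reshape=False, order=1, mode="constant"), 0.0, 1.0
        )
        # paste with subpixel shift (bilinear) at integer anchor
        y0i, x0i = int(math.floor(cy - half)), int(math.floor(cx - half))
        fy, fx = (cy - half) - y0i, (cx - half) - x0i
        shifted = ndimage.shift(patch, (fy, fx), order=1, mode="constant", cval=0.0)
        ys, xs = slice(max(y0i, 0), min(y0i + sh, H)), slice(max(x0i, 0), min(x0i + sh, W))
        pys = slice(ys.start - y0i, ys.stop - y0i)
        pxs = slice(xs.start - x0i, xs.stop - x0i)
        frames[t, ys, xs] = np.maximum(frames[t, ys, xs], shifted[pys, pxs])
    return SequenceSample(frames=np.clip(frames, 0.0, 1.0), class_label=labels[0],
                          rotation_label=labels[1], translation_label=labels[2])


def make_dataset(
    sprites: Sequence[np.ndarray],
    translation_dynamics: Sequence[MotionSpec],
    rotation_dynamics: Sequence[MotionSpec],
    sigma_ts: float = 1.0,
    n_train_per_combo: int = 2,
    n_test_per_combo: int = 2,
    canvas: tuple[int, int] = (32, 32),
    n_frames: int = 10,
    seed: int = 0,
    holdout_classes: Sequence[int] = (),
    holdout_dynamics: Sequence[tuple[int, int]] = (),
) -> tuple[list[SequenceSample], list[SequenceSample]]:
    """Generate shuffled train/test sequence sets over class x motion combos.

    Train sequences use the exact dynamic parameters; test sequences perturb
    each parameter by N(0, sigma_ts) around the training value.  Optional
    hold-out supports class-agnostic splits (``holdout_classes`` appear only
    in the test set) and motion-agnostic splits (``holdout_dynamics`` pairs
    of (rotation index, translation index) appear only in the test set).
    """
    if len(sprites) == 0:
        raise ValueError("at least one sprite class is required")
    if sigma_ts < 0:
        raise ValueError("sigma_ts must be >= 0")
    rng = np.random.default_rng(seed)
    train: list[SequenceSample] = []
    test: list[SequenceSample] = []
    for ci, sprite in enumerate(sprites):
        for ri, rot in enumerate(rotation_dynamics):
            for ti, tra in enumerate(translation_dynamics):
                held = ci in holdout_classes or (ri, ti) in holdout_dynamics
                if not held:
                    for _ in range(n_train_per_combo):
                        train.append(render_sequence(
                            sprite, tra, rot, canvas=canvas, n_frames=n_frames,
                            seed=int(rng.integers(2**31)), labels=(ci, ri, ti)))
                for _ in range(n_test_per_combo):
                    test.append(render_sequence(
                        sprite, tra.perturbed(rng, sigma_ts), rot.perturbed(rng, sigma_ts),
                        canvas=canvas, n_frames=n_frames,
                        seed=int(rng.integers(2**31)), labels=(ci, ri, ti)))
    rng.shuffle(train)  # shuffles across class and both motion categories
    rng.shuffle(test)
    return train, test


def toy_spike_pattern(spec: str, duration: float = 1000.0, seed: int = 0, **kw) -> np.ndarray:
    """Deterministic toy rasters for unit tests and lemma checks.

    Patterns: ``periodic`` (rate_hz), ``poisson`` (rate_hz),
    ``step`` (f1_hz -> f2_hz at duration/2), ``correlated_pair``
    (two units, the second echoing the first at lag_ms).
    Returns a raster of shape (units, n_bins).
    """
    n_bins = int(round(duration / DT_MS))
    rng = np.random.default_rng(seed)

    def periodic(rate_hz: float, n: int) -> np.ndarray:
        out = np.zeros(n, dtype=bool)
        if rate_hz > 0:
            period = 1000.0 / rate_hz
            k = 1
            while k * period <= n + 1e-9:
                out[math.ceil(k * period) - 1] = True
                k += 1
        return out

    if spec == "periodic":
        return periodic(kw.get("rate_hz", 50.0), n_bins)[None, :]
    if spec == "poisson":
        q = kw.get("rate_hz", 50.0) / 1000.0
        return (rng.random(n_bins) < q)[None, :]
    if spec == "step":
        half = n_bins // 2
        a = periodic(kw.get("f1_hz", 20.0), half)
        b = periodic(kw.get("f2_hz", 80.0), n_bins - half)
        return np.concatenate([a, b])[None, :]
    if spec == "correlated_pair":
        lag = int(round(kw.get("lag_ms", 2.0)))
        base = rng.random(n_bins) < kw.get("rate_hz", 50.0) / 1000.0
        echo = np.zeros(n_bins, dtype=bool)
        echo[lag:] = base[: n_bins - lag]
        return np.stack([base, echo])
    raise ValueError(f"unknown pattern {spec!r}")
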