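"""Synthetic event-camera recordings and V1-like coordinate clouds.

A DVS pointed at a screen emits events only where brightness changes,
so a moving shape produces events along its moving edges.  The
generator renders a binary glyph at 1 ms frame resolution along a
diagonal back-and-forth trajectory (two full cycles over ~2.5 s,
emulating screen recordings of moving digits) and draws a Poisson
number of events per occupancy-changing pixel per frame, with uniform
microsecond jitter inside the frame and polarity equal to the sign of
the change.  Background noise events are added at a per-pixel rate.

Also generates a deterministic "V1-like" 3D neuron cloud: a curved,
bilaterally symmetric posterior-anterior slab with a posterior midline
gap (so short-range wiring cannot cross between the hemispheres at the
occipital pole), rescaled so the median nearest-neighbor distance is
1.0 and a wiring radius of 2.5 is a local neighborhood.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from importlib import resources

import numpy as np
from scipy.spatial import cKDTree

from .events import EventStream
from .reservoir import NeuronCoordinates

__all__ = [
    "MovingShapeSpec",
    "bar_glyph",
    "ring_glyph",
    "cross_glyph",
    "wedge_glyph",
    "generate_recording",
    "generate_class_set",
    "generate_v1_cloud",
    "default_v1_coordinates",
]

_FRAME_US = 1_000  # rendering resolution; the encoder bins at 10 ms


def bar_glyph(size: int) -> np.ndarray:
    """Vertical bar, one third of the box wide."""
    mask = np.zeros((size, size), dtype=bool)
    w = max(size // 3, 1)
    x0 = (size - w) // 2
    mask[:, x0 : x0 + w] = True
    return mask


def ring_glyph(size: int) -> np.ndarray:
    """Annulus with outer radius size/2 and inner radius size/4."""
    c = (size - 1) / 2.0
    yy, xx = np.mgrid[0:size, 0:size]
    r = np.hypot(xx - c, yy - c)
    return (r <= size / 2.0) & (r >= size / 4.0)


def cross_glyph(size: int) -> np.ndarray:
    mask = np.zeros((size, size), dtype=bool)
    w = max(size // 4, 1)
    lo = (size - w) // 2
    mask[lo : lo + w, :] = True
    mask[:, lo : lo + w] = True
    return mask


def wedge_glyph(size: int) -> np.ndarray:
    """Lower-left triangular wedge."""
    yy, xx = np.mgrid[0:size, 0:size]
    return xx <= yy


@dataclass(frozen=True)
class MovingShapeSpec:
    """One recording: a glyph oscillating diagonally across the sensor.

    ``event_rate`` is the expected number of events per
    occupancy-changing pixel per 1 ms frame; ``noise_rate`` is the
    background event rate per pixel per second (~0.05 Hz for a DVS in
    a static scene).  The trajectory runs from the bottom-left of the
    middle of the screen to the top-right and back, ``n_cycles`` times.
    """

    shape: np.ndarray
    duration_us: int = 2_500_000
    amplitude_px: float = 24.0
    n_cycles: int = 2
    event_rate: float = 1.0
    noise_rate: float = 0.05
    width: int = 128
    height: int = 128
    center: tuple[float, float] | None = None
    seed: int = 0


def _trajectory(spec: MovingShapeSpec, n_frames: int) -> tuple[np.ndarray, np.ndarray]:
    """Glyph top-left corner per frame (triangle wave along the diagonal)."""
    cx, cy = spec.center if spec.center else (spec.width / 2.0, spec.height / 2.0)
    phase = np.arange(n_frames) / n_frames * spec.n_cycles
    saw = phase % 1.0
    tri = np.where(saw < 0.5, -1.0 + 4.0 * saw, 3.0 - 4.0 * saw)
    off = spec.amplitude_px * tri
    gh, gw = spec.shape.shape
    # moving toward the top right = +x, -y (y grows downward)
    x0 = np.round(cx + off - gw / 2.0).astype(np.int64)
    y0 = np.round(cy - off - gh / 2.0).astype(np.int64)
    return x0, y0


def generate_recording(spec: MovingShapeSpec) -> EventStream:
    """Render one recording; a pure function of ``spec`` (incl. seed)."""
    glyph = np.asarray(spec.shape, dtype=bool)
    if spec.event_rate < 0 or spec.noise_rate < 0:
        raise ValueError("rates must be >= 0")
    n_frames = spec.duration_us // _FRAME_US
    x0, y0 = _trajectory(spec, n_frames)
    gh, gw = glyph.shape
    if (
        x0.min() < 0
        or y0.min() < 0
        or x0.max() + gw > spec.width
        or y0.max() + gh > spec.height
    ):
        raise ValueError("glyph leaves the sensor along the trajectory")
    rng = np.random.default_rng(spec.seed)
    ts_parts, x_parts, y_parts, p_parts = [], [], [], []
    prev = np.zeros((spec.height, spec.width), dtype=bool)
    prev[y0[0] : y0[0] + gh, x0[0] : x0[0] + gw] = glyph
    for f in range(1, n_frames):
        frame = np.zeros_like(prev)
        frame[y0[f] : y0[f] + gh, x0[f] : x0[f] + gw] = glyph
        changed = np.flatnonzero(frame != prev)
        if changed.size and spec.event_rate > 0:
            counts = rng.poisson(spec.event_rate, changed.size)
            rep = np.repeat(changed, counts)
            if rep.size:
                ts_parts.append(f * _FRAME_US + rng.integers(0, _FRAME_US, rep.size))
                x_parts.append(rep % spec.width)
                y_parts.append(rep // spec.width)
                p_parts.append(np.where(frame.ravel()[rep], 1, -1))
        prev = frame
    n_noise = rng.poisson(spec.noise_rate * spec.width * spec.height * spec.duration_us / 1e6)
    if n_noise:
        ts_parts.append(rng.integers(0, spec.duration_us, n_noise))
        x_parts.append(rng.integers(0, spec.width, n_noise))
        y_parts.append(rng.integers(0, spec.height, n_noise))
        p_parts.append(rng.choice(np.array([-1, 1]), n_noise))
    if ts_parts:
        stream = EventStream(
            np.concatenate(ts_parts),
            np.concatenate(x_parts),
            np.concatenate(y_parts),
            np.concatenate(p_parts),
            width=spec.width,
            height=spec.height,
            duration_us=spec.duration_us,
        ).sorted()
    else:
        stream = EventStream.empty(spec.width, spec.height)
        stream.duration_us = spec.duration_us
    return stream.validate()


def generate_class_set(
    n_per_class: int, class_specs: list[MovingShapeSpec], seed: int = 0
) -> list[tuple[EventStream, int]]:
    """Seeded labeled dataset with per-sample trajectory jitter.

    Each sample perturbs its class spec's amplitude (+-10%), base
    position (+-3 px) and event seed.  Labels are 0..n_classes-1.
    """
    if len(class_specs) < 2:
        raise ValueError("need at least 2 classes")
    rng = np.random.default_rng(seed)
    out: list[tuple[EventStream, int]] = []
    for label, spec in enumerate(class_specs):
        for _ in range(n_per_class):
            cx, cy = spec.center if spec.center else (spec.width / 2.0, spec.height / 2.0)
            jittered = dataclasses.replace(
                spec,
                amplitude_px=spec.amplitude_px * rng.uniform(0.9, 1.1),
                center=(
                    cx + int(rng.integers(-3, 4)),
                    cy + int(rng.integers(-3, 4)),
                ),
                seed=int(rng.integers(0, 2**31)),
            )
            out.append((generate_recording(jittered), label))
    return out


def generate_v1_cloud(n: int = 732, seed: int = 0) -> NeuronCoordinates:
    """Deterministic V1-like neuron cloud (see module docstring).

    Axis 0 is lateral (left/right), axis 1 posterior->anterior, axis 2
    vertical.  The posterior fifth keeps a midline gap wider than the
    default wiring radius.
    """
    if n < 128:
        raise ValueError("need at least 128 neurons")
    rng = np.random.default_rng(seed)
    m = n // 2
    length, half_width = 30.0, 12.0
    a = rng.uniform(0.0, length, m)
    gap_half = np.where(a < length / 5.0, 3.0, 0.4)
    lat = rng.uniform(gap_half, half_width)
    vert = 4.0 * np.sin(np.pi * a / length) + rng.uniform(-3.0, 3.0, m)
    right = np.column_stack([lat, a, vert])
    left = np.column_stack([-lat, a, vert])
    pts = np.concatenate([right, left])
    if n % 2:
        pts = np.vstack([pts, [0.0, length - 1.0, 2.0]])
    nn_dist, _ = cKDTree(pts).query(pts, k=2)
    pts = pts / np.median(nn_dist[:, 1])
    return NeuronCoordinates(pts, anterior_axis=1)


def default_v1_coordinates() -> NeuronCoordinates:
    """Load the packaged 732-neuron synthetic V1-like fixture."""
    with resources.as_file(
        resources.files("retinosnn.data") / "v1_cloud_synthetic_732.csv"
    ) as path:
        return NeuronCoordinates.from_csv(path, anterior_axis=1)
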