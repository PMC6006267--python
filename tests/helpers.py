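"""Shared test utilities: random streams and a brute-force reference encoder."""

from __future__ import annotations

import math

import numpy as np

from retinosnn.events import EventStream
from retinosnn.retina import RetinaMap, SpikeRaster, ThresholdConfig


def random_stream(
    rng: np.random.Generator,
    n: int = 200,
    width: int = 128,
    height: int | None = None,
    t_max: int = 1_000_000,
) -> EventStream:
    """Uniform random event stream, sorted, in sensor bounds."""
    height = width if height is None else height
    ts = np.sort(rng.integers(0, t_max, n))
    return EventStream(
        ts,
        rng.integers(0, width, n),
        rng.integers(0, height, n),
        rng.choice(np.array([-1, 1]), n),
        width=width,
        height=height,
    )


def naive_encode(
    stream: EventStream,
    rmap: RetinaMap,
    config: ThresholdConfig,
    bin_width_us: int = 10_000,
) -> SpikeRaster:
    """Per-event nested-loop reference: count, then threshold.

    Deliberately independent of the vectorized implementation: walks
    every event against every receptive-field rectangle.
    """
    T = int(math.ceil(stream.duration_us / bin_width_us))
    if len(stream):
        T = max(T, int(stream.timestamp_us.max()) // bin_width_us + 1)
    counts = np.zeros((rmap.n_cells, T), dtype=int)
    for t, x, y in zip(stream.timestamp_us, stream.x, stream.y):
        b = int(t) // bin_width_us
        for i, f in enumerate(rmap.fields):
            x0, y0, x1, y1 = f.rect
            if x0 <= x < x1 and y0 <= y < y1:
                counts[i, b] += 1
    spikes = np.zeros((rmap.n_cells, T), dtype=bool)
    for i, f in enumerate(rmap.fields):
        if f.group == "fovea":
            trigger = 1
        else:
            trigger = int(math.floor(config.theta(f.group) * f.area)) + 1
        spikes[i] = counts[i] >= trigger
    return SpikeRaster(spikes, bin_width_us)
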