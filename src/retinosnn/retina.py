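"""Ganglion-cell pooling and threshold encoding of DVS events.

The encoder mimics the retina's convergence of photoreceptors onto
ganglion cells.  A 128x128 sensor is covered by 128 overlapping
receptive fields: 64 one-pixel *foveal* cells on the central 8x8
pixels, plus four concentric groups of 16 cells whose fields grow
toward the periphery (4x4, 8x8, 16x16 and 32x32 pixels).  On the
default sensor an average of 170.5 pixels converge onto one cell.

Events are counted in 10 ms bins per receptive field.  A foveal cell
spikes whenever its pixel saw at least one event in a bin; a group
cell spikes when its count *exceeds* a per-group fractional threshold
of its field area.  The result is a binary 128 x T spike raster, so no
cell can exceed 100 Hz.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .events import EventStream

__all__ = [
    "GROUPS",
    "ReceptiveField",
    "RetinaMap",
    "ThresholdConfig",
    "SpikeRaster",
    "build_retina_map",
    "bin_event_counts",
    "min_trigger_count",
    "encode",
    "average_spike_rate",
    "default_threshold_schedule",
]

#: Peripheral-to-central order of the four pooling groups.
GROUPS = ("g1", "g2", "g3", "g4")

#: Canonical cell ordering: 1-16 g1, 17-32 g2, 33-48 g3, 49-64 g4, 65-128 fovea.
GROUP_SLICES = {
    "g1": slice(0, 16),
    "g2": slice(16, 32),
    "g3": slice(32, 48),
    "g4": slice(48, 64),
    "fovea": slice(64, 128),
}


class ConfigurationError(ValueError):
    """Unsupported geometry or threshold configuration."""


@dataclass(frozen=True)
class ReceptiveField:
    """One ganglion cell's pixel rectangle, half-open ``[x0,x1) x [y0,y1)``."""

    cell_id: int  # 1..128
    group: str  # 'fovea' or 'g1'..'g4' (g1 outermost)
    rect: tuple[int, int, int, int]

    @property
    def area(self) -> int:
        x0, y0, x1, y1 = self.rect
        return (x1 - x0) * (y1 - y0)

    @property
    def center(self) -> tuple[float, float]:
        x0, y0, x1, y1 = self.rect
        return ((x0 + x1) / 2.0, (y0 + y1) / 2.0)


@dataclass(frozen=True)
class ThresholdConfig:
    """Fractional spike thresholds per pooling group (fovea has none)."""

    g1: float = 0.005
    g2: float = 0.01
    g3: float = 0.02
    g4: float = 0.04

    def __post_init__(self) -> None:
        for g in GROUPS:
            v = getattr(self, g)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"threshold {g}={v} outside [0, 1]")

    def theta(self, group: str) -> float:
        if group not in GROUPS:
            raise ConfigurationError(f"no threshold for group {group!r}")
        return getattr(self, group)


def default_threshold_schedule(base: float) -> ThresholdConfig:
    """Thresholds doubling from periphery to center: (base, 2b, 4b, 8b)."""
    if base < 0:
        raise ConfigurationError("base threshold must be >= 0")
    if 8 * base > 1:
        raise ConfigurationError(f"8*base = {8 * base} exceeds 1")
    return ThresholdConfig(g1=base, g2=2 * base, g3=4 * base, g4=8 * base)


class RetinaMap:
    """The 128 receptive fields covering one sensor, in canonical order."""

    def __init__(self, fields: list[ReceptiveField], width: int, height: int):
        self.fields = list(fields)
        self.width = width
        self.height = height
        self._coverage: sp.csr_matrix | None = None
        self.areas = np.array([f.area for f in self.fields], dtype=np.int64)
        self.groups = [f.group for f in self.fields]

    @property
    def n_cells(self) -> int:
        return len(self.fields)

    def group_area(self, group: str) -> int:
        if group not in GROUPS:
            raise ConfigurationError(f"{group!r} is not a pooling group")
        return int(self.areas[GROUP_SLICES[group]][0])

    def cells_covering(self, x: int, y: int) -> list[int]:
        """0-based indices of all cells whose field contains pixel (x, y)."""
        out = []
        for i, f in enumerate(self.fields):
            x0, y0, x1, y1 = f.rect
            if x0 <= x < x1 and y0 <= y < y1:
                out.append(i)
        return out

    def coverage_matrix(self) -> sp.csr_matrix:
        """Boolean (n_cells x width*height) cell-covers-pixel matrix."""
        if self._coverage is None:
            rows, cols = [], []
            for i, f in enumerate(self.fields):
                x0, y0, x1, y1 = f.rect
                ys, xs = np.mgrid[y0:y1, x0:x1]
                pix = (ys * self.width + xs).ravel()
                rows.append(np.full(pix.size, i, dtype=np.int64))
                cols.append(pix)
            self._coverage = sp.csr_matrix(
                (
                    np.ones(sum(r.size for r in rows), dtype=np.int64),
                    (np.concatenate(rows), np.concatenate(cols)),
                ),
                shape=(self.n_cells, self.width * self.height),
            )
        return self._coverage


def _tile(group: str, size: int, extent0: int, n_per_side: int, first_id: int):
    fields = []
    cid = first_id
    for r in range(n_per_side):
        for c in range(n_per_side):
            x0 = extent0 + c * size
            y0 = extent0 + r * size
            fields.append(ReceptiveField(cid, group, (x0, y0, x0 + size, y0 + size)))
            cid += 1
    return fields


def build_retina_map(width: int = 128, height: int | None = None) -> RetinaMap:
    """Build the concentric receptive-field layout for a square sensor.

    For a sensor of side ``w`` (divisible by 32): group g1 cells of side
    w/4 tile the full frame, g2 cells of side w/8 tile the central
    w/2 square, g3 cells of side w/16 the central w/4 square, g4 cells
    of side w/32 the central w/8 square, and 64 one-pixel foveal cells
    tile the central 8x8 pixels.  Fields overlap by construction.
    """
    if height is None:
        height = width
    if width != height:
        raise ConfigurationError("sensor must be square")
    if width < 32 or width % 32:
        raise ConfigurationError("sensor side must be a multiple of 32 (>= 32)")
    w = width
    fields: list[ReceptiveField] = []
    # (group, cell side, tiled extent side); 4x4 cells per group.
    for i, (group, size, extent) in enumerate(
        [
            ("g1", w // 4, w),
            ("g2", w // 8, w // 2),
            ("g3", w // 16, w // 4),
            ("g4", w // 32, w // 8),
        ]
    ):
        fields.extend(_tile(group, size, (w - extent) // 2, 4, 16 * i + 1))
    # Fovea: 64 single-pixel cells on the central 8x8, row-major.
    f0 = w // 2 - 4
    for r in range(8):
        for c in range(8):
            x0, y0 = f0 + c, f0 + r
            fields.append(ReceptiveField(65 + r * 8 + c, "fovea", (x0, y0, x0 + 1, y0 + 1)))
    return RetinaMap(fields, width, height)


def min_trigger_count(rmap: RetinaMap, group: str, theta: float) -> int:
    """Smallest event count that *exceeds* ``theta`` x field area.

    At a 10% threshold this is 2 events for a group-4 (4x4 px) field
    and 103 for a group-1 (32x32 px) field on the default sensor.
    Foveal cells have no threshold (they fire on any event) and raise.
    """
    if group == "fovea":
        raise ConfigurationError("foveal cells fire on any event; no trigger count")
    area = rmap.group_area(group)
    return int(math.floor(theta * area)) + 1


def bin_event_counts(
    stream: EventStream, rmap: RetinaMap, bin_width_us: int = 10_000
) -> np.ndarray:
    """Per-cell event counts in half-open time bins ``[k*d, (k+1)*d)``.

    Polarity is ignored.  Returns an ``(n_cells, T)`` integer matrix
    with ``T = ceil(duration_us / bin_width_us)`` (100 bins per second
    at the 10 ms default).
    """
    if bin_width_us <= 0:
        raise ValueError("bin_width_us must be positive")
    if stream.width != rmap.width or stream.height != rmap.height:
        raise ValueError("stream sensor size does not match the retina map")
    T = int(math.ceil(stream.duration_us / bin_width_us))
    if len(stream) == 0:
        return np.zeros((rmap.n_cells, T), dtype=np.int64)
    bins = stream.timestamp_us // bin_width_us
    T = max(T, int(bins.max()) + 1)
    pix = stream.y * rmap.width + stream.x
    per_pixel = sp.csr_matrix(
        (np.ones(len(stream), dtype=np.int64), (pix, bins)),
        shape=(rmap.width * rmap.height, T),
    )
    return np.asarray((rmap.coverage_matrix() @ per_pixel).todense())


@dataclass
class SpikeRaster:
    """Binary cells x time-bins spike matrix (canonical cell order)."""

    spikes: np.ndarray
    bin_width_us: int = 10_000

    def __post_init__(self) -> None:
        self.spikes = np.asarray(self.spikes, dtype=bool)
        if self.spikes.ndim != 2:
            raise ValueError("spikes must be a 2-D cells x bins matrix")

    @property
    def n_cells(self) -> int:
        return self.spikes.shape[0]

    @property
    def n_bins(self) -> int:
        return self.spikes.shape[1]

    def to_csv(self, path) -> Path:
        """Write the spike list as ``cell_id,bin_index`` (1-based cells)."""
        cells, bins = np.nonzero(self.spikes)
        pd.DataFrame({"cell_id": cells + 1, "bin_index": bins}).to_csv(
            Path(path), index=False
        )
        return Path(path)

    @classmethod
    def from_csv(cls, path, n_cells: int, n_bins: int, bin_width_us: int = 10_000):
        df = pd.read_csv(path)
        spikes = np.zeros((n_cells, n_bins), dtype=bool)
        if len(df):
            spikes[df["cell_id"].to_numpy() - 1, df["bin_index"].to_numpy()] = True
        return cls(spikes, bin_width_us)


def encode(
    counts: np.ndarray, rmap: RetinaMap, config: ThresholdConfig
) -> SpikeRaster:
    """Threshold binned counts into a binary spike raster.

    Foveal cells spike on count >= 1; a group cell spikes when its
    count strictly exceeds ``theta_g * area`` of its field.
    """
    counts = np.asarray(counts)
    if counts.ndim != 2 or counts.shape[0] != rmap.n_cells:
        raise ValueError(
            f"counts must be ({rmap.n_cells}, T); got {counts.shape}"
        )
    trigger = np.ones(rmap.n_cells, dtype=np.int64)
    for g in GROUPS:
        trigger[GROUP_SLICES[g]] = min_trigger_count(rmap, g, config.theta(g))
    return SpikeRaster(counts >= trigger[:, None])


def average_spike_rate(raster: SpikeRaster) -> dict[str, float]:
    """Fraction of bins in which cells fire, per group and overall.

    The per-group rate averages, over the group's cells, the fraction
    of time bins with a spike; 'total' averages over all 128 cells.
    """
    if raster.n_bins == 0:
        raise ValueError("raster has no time bins")
    per_cell = raster.spikes.mean(axis=1)
    out = {g: float(per_cell[s].mean()) for g, s in GROUP_SLICES.items()}
    out["total"] = float(per_cell.mean())
    return out
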