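"""Container for address-event-representation (AER) streams.

A dynamic vision sensor (DVS) does not produce frames: each pixel
asynchronously emits an *event* whenever its log-brightness changes,
so a recording is a time-ordered list of (timestamp, x, y, polarity)
tuples on a 128x128 pixel grid.  :class:`EventStream` holds one such
recording as four parallel numpy arrays.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["EventStream", "ValidationError"]


class ValidationError(ValueError):
    """An event stream violates its invariants (bounds, polarity, order)."""


@dataclass(eq=False)
class EventStream:
    """A timestamp-sorted DVS recording.

    Parameters
    ----------
    timestamp_us
        Event times in integer microseconds since stream start,
        non-decreasing.
    x, y
        Pixel column / row, 0-based, origin at the top-left corner.
    polarity
        +1 for a brightening pixel, -1 for a darkening one.
    width, height
        Sensor size in pixels (DVS128 default: 128 x 128).
    duration_us
        Recording length; defaults to the last event timestamp.
    """

    timestamp_us: np.ndarray
    x: np.ndarray
    y: np.ndarray
    polarity: np.ndarray
    width: int = 128
    height: int = 128
    duration_us: int | None = field(default=None)

    def __post_init__(self) -> None:
        self.timestamp_us = np.asarray(self.timestamp_us, dtype=np.int64)
        self.x = np.asarray(self.x, dtype=np.int64)
        self.y = np.asarray(self.y, dtype=np.int64)
        self.polarity = np.asarray(self.polarity, dtype=np.int64)
        n = len(self.timestamp_us)
        if not (len(self.x) == len(self.y) == len(self.polarity) == n):
            raise ValidationError("event field arrays have mismatched lengths")
        if self.duration_us is None:
            self.duration_us = int(self.timestamp_us.max()) if n else 0

    def __len__(self) -> int:
        return len(self.timestamp_us)

    @property
    def n_events(self) -> int:
        return len(self)

    def validate(self) -> "EventStream":
        """Raise :class:`ValidationError` unless all invariants hold."""
        if len(self) and np.any(np.diff(self.timestamp_us) < 0):
            raise ValidationError("timestamps are not non-decreasing")
        if np.any((self.x < 0) | (self.x >= self.width)):
            raise ValidationError("x coordinate out of sensor bounds")
        if np.any((self.y < 0) | (self.y >= self.height)):
            raise ValidationError("y coordinate out of sensor bounds")
        if np.any(np.abs(self.polarity) != 1):
            raise ValidationError("polarity must be +1 or -1")
        if len(self) and self.duration_us < int(self.timestamp_us[-1]):
            raise ValidationError("duration_us precedes the last event")
        return self

    def sorted(self) -> "EventStream":
        """Return a copy sorted by timestamp (stable)."""
        order = np.argsort(self.timestamp_us, kind="stable")
        return EventStream(
            self.timestamp_us[order],
            self.x[order],
            self.y[order],
            self.polarity[order],
            width=self.width,
            height=self.height,
            duration_us=self.duration_us,
        )

    def equals(self, other: "EventStream") -> bool:
        """Event-sequence equality (geometry and events, not duration)."""
        return (
            self.width == other.width
            and self.height == other.height
            and np.array_equal(self.timestamp_us, other.timestamp_us)
            and np.array_equal(self.x, other.x)
            and np.array_equal(self.y, other.y)
            and np.array_equal(self.polarity, other.polarity)
        )

    @classmethod
    def empty(cls, width: int = 128, height: int = 128) -> "EventStream":
        z = np.empty(0, dtype=np.int64)
        return cls(z, z.copy(), z.copy(), z.copy(), width=width, height=height)
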