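"""Rolling-buffer stabilization of the perimeter stream.

Adding fluid (or bumping the plate) disturbs the surface, and the measured
perimeter fluctuates wildly until the surface settles.  A reading is
therefore accepted only when the rolling buffer of recent per-frame
perimeters has settled: the buffer is full, enough of its slots hold valid
readings, and their sample standard deviation is at or below a threshold.
The accepted value is the mean of the valid buffer entries.

The buffer keeps rolling after an acceptance, so a stable stream yields an
acceptance every frame; consumers that want one reading per dispensing
step simply keep the last acceptance before the next disturbance.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass

import numpy as np

from .detect import FrameReading

__all__ = ["StabilizerConfig", "StableReading", "Stabilizer"]


@dataclass(frozen=True)
class StabilizerConfig:
    """Acceptance rule parameters.

    ``buffer_size`` frames are held; acceptance requires at least
    ``min_valid_fraction`` of them to be valid readings and the sample
    (n-1) standard deviation of the valid values to be <= ``sigma_max``
    px.
    """

    buffer_size: int = 10
    sigma_max: float = 2.0
    min_valid_fraction: float = 1.0

    def __post_init__(self) -> None:
        if self.buffer_size < 2:
            raise ValueError("buffer_size must be >= 2")
        if self.sigma_max <= 0:
            raise ValueError("sigma_max must be positive")
        if not 0.0 < self.min_valid_fraction <= 1.0:
            raise ValueError("min_valid_fraction must be in (0, 1]")


@dataclass(frozen=True)
class StableReading:
    """A buffer-accepted measurement."""

    perimeter: float  # px, mean of valid buffer values
    frame_index: int  # frame at which acceptance occurred
    buffer_sigma: float  # px, sample std of valid buffer values
    n_valid: int


class Stabilizer:
    """Streaming acceptance filter over per-frame readings.

    Feed readings in frame order with :meth:`update`; it returns a
    :class:`StableReading` when the buffer qualifies, else ``None``.
    Missing (invalid) readings occupy buffer slots but never count toward
    the statistics, so a burst of failed detections delays acceptance
    instead of corrupting it.
    """

    def __init__(self, config: StabilizerConfig = StabilizerConfig()) -> None:
        self.config = config
        self._buffer: deque[float | None] = deque(maxlen=config.buffer_size)

    def reset(self) -> None:
        self._buffer.clear()

    def update(self, reading: FrameReading) -> StableReading | None:
        self._buffer.append(reading.perimeter if reading.valid else None)
        cfg = self.config
        if len(self._buffer) < cfg.buffer_size:
            return None
        valid = [v for v in self._buffer if v is not None]
        if len(valid) < 2 or len(valid) / cfg.buffer_size < cfg.min_valid_fraction:
            return None
        sigma = float(np.std(valid, ddof=1))
        if sigma > cfg.sigma_max:
            return None
        return StableReading(
            perimeter=float(np.mean(valid)),
            frame_index=reading.frame_index,
            buffer_sigma=sigma,
            n_valid=len(valid),
        )
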