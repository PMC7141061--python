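"""Core container for discretely sampled gaze trajectories.

A gaze recording is the *protocol*: the time-ordered sequence of points of
regard sampled at a constant rate.  Because the rate is constant, time is a
pure ordering parameter and only the sample index is kept; wall-clock times
are derived from ``index / sampling_rate`` on demand.  Samples lost to blinks
or tracking failure are kept in place with ``valid=False`` — no row of a
recording is ever dropped, interpolated or gap-filled.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

__all__ = ["GazeSample", "GazeRecording"]


@dataclass(frozen=True)
class GazeSample:
    """One sample of the protocol: ordinal index, 2D position, validity."""

    index: int
    position: tuple[float, float]
    valid: bool


@dataclass
class GazeRecording:
    """Time-ordered, validity-flagged 2D samples at a constant rate.

    Parameters
    ----------
    id : str
        Identifier carried through to downstream results.
    positions : (n, 2) float array
        Point-of-regard coordinates in display units.  Rows of invalid
        samples may hold NaN.
    valid : (n,) bool array
        False marks data loss (blink, off-screen, tracker dropout).
    sampling_rate : float
        Samples per second; strictly positive.
    units : str
        Display unit label, ``"px"`` or ``"deg"``.
    """

    id: str
    positions: np.ndarray
    valid: np.ndarray
    sampling_rate: float
    units: str = "px"
    features: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 2:
            raise ValueError("positions must be an (n, 2) array")
        n = self.positions.shape[0]
        if n < 1:
            raise ValueError("a recording needs at least one sample")
        if self.valid is None:
            self.valid = np.ones(n, dtype=bool)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.valid.shape != (n,):
            raise ValueError("valid must be an (n,) boolean array")
        if not self.sampling_rate > 0:
            raise ValueError("sampling_rate must be strictly positive")
        if self.units not in ("px", "deg"):
            raise ValueError(f"unknown units {self.units!r} (use 'px' or 'deg')")
        bad = self.valid & ~np.isfinite(self.positions).all(axis=1)
        if bad.any():
            raise ValueError(
                f"sample {int(np.nonzero(bad)[0][0])} is flagged valid but has "
                "a non-finite coordinate"
            )

    @property
    def n(self) -> int:
        return self.positions.shape[0]

    def time_ms(self, index: int | np.ndarray) -> float | np.ndarray:
        """Time of a sample in milliseconds, derived from the index."""
        return np.asarray(index) / self.sampling_rate * 1000.0

    def samples(self) -> Iterator[GazeSample]:
        for i in range(self.n):
            yield GazeSample(i, tuple(self.positions[i]), bool(self.valid[i]))

    def reversed(self) -> "GazeRecording":
        """Time-mirrored copy (used by symmetry checks)."""
        return GazeRecording(
            id=self.id + "-reversed",
            positions=self.positions[::-1].copy(),
            valid=self.valid[::-1].copy(),
            sampling_rate=self.sampling_rate,
            units=self.units,
        )
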