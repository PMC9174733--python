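"""Positional trajectory container.

A :class:`Trajectory` is a time-ordered stream of (t, x, y) fixes for one
individual, with timestamps in epoch seconds and coordinates in pen-local
metres. Streams are kept as plain numpy arrays; pandas enters only at the
I/O boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

SECONDS_PER_DAY = 86_400


@dataclass
class Trajectory:
    individual_id: str
    t: np.ndarray  # epoch seconds, strictly increasing
    x: np.ndarray  # metres
    y: np.ndarray  # metres
    nominal_hz: float = 1.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (len(self.t) == len(self.x) == len(self.y)):
            raise ValueError("t, x, y must have equal length")
        if len(self.t) > 1 and not np.all(np.diff(self.t) > 0):
            raise ValueError(
                f"timestamps must be strictly increasing for {self.individual_id!r}")
        if len(self.t) and not (np.isfinite(self.x).all() and np.isfinite(self.y).all()
                                and np.isfinite(self.t).all()):
            raise ValueError("non-finite coordinates or timestamps")
        if self.nominal_hz <= 0:
            raise ValueError("nominal_hz must be positive")

    def __len__(self) -> int:
        return len(self.t)

    @property
    def xy(self) -> np.ndarray:
        return np.column_stack([self.x, self.y])

    def subset(self, mask: np.ndarray) -> "Trajectory":
        """New trajectory keeping samples where ``mask`` is True; order kept."""
        return Trajectory(self.individual_id, self.t[mask], self.x[mask],
                          self.y[mask], self.nominal_hz, dict(self.meta))

    def day_index(self) -> np.ndarray:
        """Calendar-day index of every sample (local midnight boundaries)."""
        return (self.t // SECONDS_PER_DAY).astype(int)
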