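"""Bead trajectories: timestamped 2D positions in micrometres.

The raw measurement record of the instrument.  CSV round-trip uses the
columns ``time_s, x_um, y_um``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["BeadTrajectory"]


@dataclass
class BeadTrajectory:
    """Timestamped 2D bead positions (µm) with the bead radius.

    ``truncated`` flags records that ended early (e.g. the virtual bead
    reached the needle before the schedule finished).
    """

    time_s: np.ndarray
    x_um: np.ndarray
    y_um: np.ndarray
    bead_radius_um: float = 2.25
    truncated: bool = False
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.x_um = np.asarray(self.x_um, dtype=float)
        self.y_um = np.asarray(self.y_um, dtype=float)
        if not (self.time_s.shape == self.x_um.shape == self.y_um.shape):
            raise ValueError("time/x/y must have identical shapes")
        if self.time_s.size > 1 and np.any(np.diff(self.time_s) <= 0):
            raise ValueError("timestamps must be strictly increasing")
        if not self.bead_radius_um > 0:
            raise ValueError("bead radius must be positive")

    def __len__(self) -> int:
        return self.time_s.size

    @property
    def positions_um(self) -> np.ndarray:
        """(n, 2) array of (x, y) positions in µm."""
        return np.column_stack([self.x_um, self.y_um])

    def displacement_um(self, axis: np.ndarray | None = None,
                        origin: np.ndarray | None = None) -> np.ndarray:
        """Signed scalar displacement from the first sample.

        Positions are projected onto ``axis`` (unit vector).  If ``axis`` is
        None it is taken as the principal direction of motion, with the sign
        chosen so the largest excursion is positive.
        """
        pos = self.positions_um
        p0 = pos[0] if origin is None else np.asarray(origin, dtype=float)
        rel = pos - p0
        if axis is None:
            centred = rel - rel.mean(axis=0)
            cov = centred.T @ centred
            _, vecs = np.linalg.eigh(cov)
            axis = vecs[:, -1]
        axis = np.asarray(axis, dtype=float)
        axis = axis / np.linalg.norm(axis)
        s = rel @ axis
        if abs(s.min()) > abs(s.max()):
            s = -s
        return s

    def distance_to(self, point_um) -> np.ndarray:
        """Euclidean distance of each sample to a fixed point (µm)."""
        p = np.asarray(point_um, dtype=float)
        return np.hypot(self.x_um - p[0], self.y_um - p[1])

    # -- I/O --------------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_s": self.time_s,
                             "x_um": self.x_um, "y_um": self.y_um})

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.9g")

    @classmethod
    def from_csv(cls, path: str | Path, bead_radius_um: float = 2.25) -> "BeadTrajectory":
        df = pd.read_csv(path)
        return cls(df["time_s"].to_numpy(), df["x_um"].to_numpy(),
                   df["y_um"].to_numpy(), bead_radius_um=bead_radius_um)
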