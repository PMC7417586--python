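"""Image stacks: multi-page grayscale frames with physical pixel size.

TIFF round-trip uses :mod:`tifffile` plus a small JSON sidecar carrying
``pixel_size_um`` and the frame timestamps.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

__all__ = ["ImageStack"]


@dataclass
class ImageStack:
    """A sequence of grayscale frames with uniform shape.

    ``roi`` is an optional ``(row0, col0, height, width)`` rectangle in
    pixel coordinates restricting analysis.  Pixel (0, 0) is the top-left,
    positions refer to pixel centres, x runs right (columns) and y down
    (rows); physical coordinates are pixel coordinates times
    ``pixel_size_um``.
    """

    frames: np.ndarray
    pixel_size_um: float
    timestamps: np.ndarray
    roi: tuple[int, int, int, int] | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.frames = np.asarray(self.frames)
        if self.frames.ndim == 2:
            self.frames = self.frames[None]
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (n, h, w) array")
        if not self.pixel_size_um > 0:
            raise ValueError("pixel_size_um must be positive")
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        if self.timestamps.shape != (self.frames.shape[0],):
            raise ValueError("one timestamp per frame required")
        if self.timestamps.size > 1 and np.any(np.diff(self.timestamps) <= 0):
            raise ValueError("timestamps must be strictly increasing")
        if self.roi is not None:
            r0, c0, h, w = self.roi
            H, W = self.frames.shape[1:]
            if not (0 <= r0 and 0 <= c0 and r0 + h <= H and c0 + w <= W and h > 0 and w > 0):
                raise ValueError("roi must lie within the frames")

    def __len__(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]

    def crop_roi(self, frame_index: int = 0) -> np.ndarray:
        f = self.frames[frame_index]
        if self.roi is None:
            return f
        r0, c0, h, w = self.roi
        return f[r0:r0 + h, c0:c0 + w]

    # -- I/O --------------------------------------------------------------
    def save(self, path: str | Path) -> None:
        path = Path(path)
        tifffile.imwrite(path, self.frames)
        sidecar = {"pixel_size_um": self.pixel_size_um,
                   "timestamps_s": self.timestamps.tolist(),
                   "roi": list(self.roi) if self.roi else None}
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "ImageStack":
        path = Path(path)
        frames = tifffile.imread(path)
        side = json.loads(path.with_suffix(".json").read_text())
        roi = tuple(side["roi"]) if side.get("roi") else None
        return cls(frames, side["pixel_size_um"],
                   np.asarray(side["timestamps_s"]), roi=roi)
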