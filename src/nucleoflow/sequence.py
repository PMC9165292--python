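"""Time-lapse image sequence container with physical metadata.

All downstream stages consume an :class:`ImageSequence`: a stack of 2D
intensity frames acquired at a constant frame interval, together with the
pixel size needed to convert image coordinates to micrometres.

Conventions used throughout the package:

* pixel coordinates are 0-based, referring to pixel centers; ``x`` runs
  rightward (columns), ``y`` downward (rows);
* positions exported in tables are in micrometres with the same orientation;
* rates (velocities, divergences, strain rates) are per hour.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import tifffile


@dataclass
class ImageSequence:
    """Time-ordered stack of 2D fluorescence frames.

    Parameters
    ----------
    frames : ndarray, shape (T, H, W)
        Intensity frames, time-ordered.
    pixel_size_um : float
        Lateral pixel size in micrometres per pixel.
    dt_min : float
        Constant time interval between consecutive frames, in minutes.
    """

    frames: np.ndarray
    pixel_size_um: float
    dt_min: float

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError(f"frames must be (T, H, W), got shape {self.frames.shape}")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if self.dt_min <= 0:
            raise ValueError("dt_min must be positive")

    # -- basic geometry -------------------------------------------------
    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]

    @property
    def dt_h(self) -> float:
        """Frame interval in hours."""
        return self.dt_min / 60.0

    @property
    def duration_h(self) -> float:
        """Time spanned from first to last frame, in hours."""
        return (self.n_frames - 1) * self.dt_h

    @property
    def timestamps_min(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.dt_min

    @property
    def times_h(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.dt_h

    @property
    def fov_area_um2(self) -> float:
        h, w = self.frame_shape
        return h * w * self.pixel_size_um**2

    # -- convenience ----------------------------------------------------
    def copy(self) -> "ImageSequence":
        return replace(self, frames=self.frames.copy())

    def with_frames(self, frames: np.ndarray) -> "ImageSequence":
        return replace(self, frames=frames)

    # -- I/O -------------------------------------------------------------
    @classmethod
    def from_tiff(cls, path, pixel_size_um: float, dt_min: float) -> "ImageSequence":
        """Read a multi-page TIFF stack."""
        frames = tifffile.imread(path)
        if frames.ndim == 2:
            frames = frames[None]
        return cls(frames.astype(np.float64), pixel_size_um, dt_min)

    def to_tiff(self, path) -> None:
        """Write the stack as a 16-bit multi-page TIFF."""
        data = np.clip(np.round(self.frames), 0, 65535).astype(np.uint16)
        tifffile.imwrite(path, data)
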