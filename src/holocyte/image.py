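"""Quantitative phase-shift images and their on-disk representation.

A digital holographic microscope measures, per pixel, the optical path
delay that light accumulates when passing through a cell.  After wavefield
reconstruction (outside the scope of this package) each frame is a 2-D map
of phase shifts in radians.  :class:`PhaseImage` is that map plus the
acquisition metadata every downstream stage needs: the physical pixel
size, the acquisition time within the time-lapse, and free-form tags
(condition, well, calibration age).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import tifffile

__all__ = ["PhaseImage", "read_phase_tiff", "write_phase_tiff"]


@dataclass
class PhaseImage:
    """One quantitative phase-shift frame.

    Parameters
    ----------
    pixels : ndarray of float, shape (rows, cols)
        Phase-shift values in radians.
    pixel_size_um : float
        Physical side length of one pixel in micrometres.
    t : float
        Hours since the start of the experiment.
    meta : dict
        Free-form acquisition tags (condition, well, ...).
    """

    pixels: np.ndarray
    pixel_size_um: float
    t: float = 0.0
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValueError("PhaseImage requires a 2-D pixel grid")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("PhaseImage pixels must all be finite")
        if not self.pixel_size_um > 0:
            raise ValueError("pixel_size_um must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]


def read_phase_tiff(
    path: str | Path,
    pixel_size_um: float,
    *,
    unit_scale: float = 1.0,
    t: float = 0.0,
    meta: Mapping[str, Any] | None = None,
) -> PhaseImage:
    """Load a grayscale TIFF as a :class:`PhaseImage`.

    ``unit_scale`` converts instrument units to radians (stored value is
    ``raw * unit_scale``); pass 1.0 when the file already stores radians.
    """
    raw = tifffile.imread(str(path)).astype(float)
    if raw.ndim != 2:
        raise ValueError(f"{path}: expected a single 2-D grayscale frame")
    return PhaseImage(
        pixels=raw * unit_scale,
        pixel_size_um=pixel_size_um,
        t=t,
        meta=dict(meta or {}),
    )


def write_phase_tiff(image: PhaseImage, path: str | Path) -> None:
    """Write a frame as 32-bit float grayscale TIFF."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(str(path), image.pixels.astype(np.float32))
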