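"""Hologram standardization metrics and frame-quality filtering.

The laser diodes of a holographic microscope drift between calibrations,
so visually similar phase-shift frames can carry quantitatively
incomparable data.  Three per-frame metrics over the *non-segmented*
space standardize frames:

* ``BgAv``  — mean phase shift over background pixels,
* ``BgSD``  — population standard deviation of the background,
* ``SNR``   — ``20 * log10((mean object phase - BgAv) / BgSD)`` in dB.

``BgSD`` is independent of what the cells are doing (it only sees the
background) and predicts downstream classification accuracy; frames with
``BgSD`` above a threshold (0.5 in image units by default) are discarded
before feature extraction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import math

import numpy as np
import pandas as pd

from .image import PhaseImage
from .segmentation import SegmentedObject

__all__ = [
    "FrameQuality",
    "frame_quality",
    "filter_by_bgsd",
    "bgsd_threshold_sweep",
    "DEFAULT_MAX_BGSD",
]

DEFAULT_MAX_BGSD = 0.5
BGSD_SWEEP_THRESHOLDS = (0.45, 0.5, 0.55, 0.6)


@dataclass(frozen=True)
class FrameQuality:
    """Standardization metrics of one frame.

    ``snr_db`` is ``None`` when undefined (zero background spread, no
    object pixels, or object mean not above background); ``snr_flag``
    then says why.
    """

    bg_av: float
    bg_sd: float
    snr_db: float | None
    n_bg_pixels: int
    n_ob_pixels: int
    snr_flag: str | None = None

    @property
    def snr_defined(self) -> bool:
        return self.snr_db is not None


def frame_quality(image: PhaseImage, objects: Sequence[SegmentedObject]) -> FrameQuality:
    """Background mean/spread and object signal-to-noise of one frame.

    Background = every pixel not inside any segmented object.  The
    standard deviation uses the population (1/N) divisor.
    """
    ob_mask = np.zeros(image.shape, dtype=bool)
    for obj in objects:
        ob_mask[obj.pixel_set[:, 0], obj.pixel_set[:, 1]] = True
    bg = image.pixels[~ob_mask]
    ob = image.pixels[ob_mask]
    if bg.size == 0:
        raise ValueError("frame has no background pixels")

    bg_av = float(bg.mean())
    bg_sd = float(bg.std())  # population sd

    snr: float | None
    flag: str | None
    if bg_sd == 0.0:
        snr, flag = None, "zero background sd"
    elif ob.size == 0:
        snr, flag = None, "no object pixels"
    else:
        signal = float(ob.mean()) - bg_av
        if signal <= 0.0:
            snr, flag = None, "object mean not above background"
        else:
            snr, flag = 20.0 * math.log10(signal / bg_sd), None

    return FrameQuality(
        bg_av=bg_av,
        bg_sd=bg_sd,
        snr_db=snr,
        n_bg_pixels=int(bg.size),
        n_ob_pixels=int(ob.size),
        snr_flag=flag,
    )


def filter_by_bgsd(
    qualities: Sequence[FrameQuality],
    max_bgsd: float = DEFAULT_MAX_BGSD,
) -> tuple[list[int], float]:
    """Indices of frames with ``BgSD <= max_bgsd`` and the removed fraction."""
    kept = [i for i, q in enumerate(qualities) if q.bg_sd <= max_bgsd]
    removed_fraction = 1.0 - len(kept) / len(qualities) if qualities else 0.0
    return kept, removed_fraction


def bgsd_threshold_sweep(
    qualities: Sequence[FrameQuality],
    frame_labels: Sequence[Sequence[str]],
    train_eval: Callable[[Sequence[int]], float],
    thresholds: Sequence[float] = BGSD_SWEEP_THRESHOLDS,
) -> pd.DataFrame:
    """Evaluate classification accuracy at increasing BgSD cutoffs.

    ``train_eval`` receives the retained frame indices and returns the
    macro classification accuracy after retraining on those frames.
    ``frame_labels`` gives the class labels present in each frame; a
    threshold that removes every frame of some class is reported as
    infeasible (accuracy NaN).
    """
    all_classes = set()
    for labels in frame_labels:
        all_classes.update(labels)

    rows = []
    for thr in thresholds:
        kept, removed = filter_by_bgsd(qualities, thr)
        kept_classes = set()
        for i in kept:
            kept_classes.update(frame_labels[i])
        feasible = kept_classes == all_classes and len(kept) > 0
        acc = train_eval(kept) if feasible else float("nan")
        rows.append(
            {
                "max_bgsd": thr,
                "n_retained": len(kept),
                "removed_fraction": removed,
                "feasible": feasible,
                "macro_accuracy": acc,
            }
        )
    return pd.DataFrame(rows)


def quality_table(qualities: Sequence[FrameQuality], times: Sequence[float],
                  max_bgsd: float = DEFAULT_MAX_BGSD) -> pd.DataFrame:
    """Per-frame quality CSV layout: frame, t, bg_av, bg_sd, snr, retained."""
    kept, _ = filter_by_bgsd(qualities, max_bgsd)
    kept_set = set(kept)
    return pd.DataFrame(
        {
            "frame": range(len(qualities)),
            "t": list(times),
            "bg_av": [q.bg_av for q in qualities],
            "bg_sd": [q.bg_sd for q in qualities],
            "snr_db": [q.snr_db if q.snr_defined else float("nan") for q in qualities],
            "retained": [i in kept_set for i in range(len(qualities))],
        }
    )
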