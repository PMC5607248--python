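"""Segmentation of single cell events from phase-shift images.

Cells delay light, so they stand out from the background as regions of
elevated phase shift.  Segmentation follows the classic recipe used by
holographic-cytometry acquisition software: a global threshold (Otsu's
method over a 256-bin histogram, or a fixed instrument threshold supplied
by the operator), 8-connected component labelling, and removal of
components smaller than a minimum object size (default 26 pixels).

The returned :class:`SegmentedObject` carries the exact pixel set, the
centroid in micrometres, and the "crack" boundary polygon traced along
pixel edges — so the perimeter of an n x n pixel square is exactly
``4 * n * pixel_size``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
from skimage import measure

from .image import PhaseImage

__all__ = ["SegmentedObject", "otsu_threshold", "segment_frame", "crack_perimeter_px"]

N_OTSU_BINS = 256
DEFAULT_MIN_SIZE = 26  # pixels; minimum object size used throughout


@dataclass
class SegmentedObject:
    """One segmented cell event.

    ``pixel_set`` is an (n, 2) integer array of (row, col) pairs, 0-based.
    ``centroid_um`` is (x, y) in micrometres with x along columns and y
    along rows.  ``boundary_um`` is the closed outer crack polygon as an
    (m, 2) array of (x, y) vertices in micrometres (first vertex repeated
    at the end).
    """

    object_id: int
    pixel_set: np.ndarray
    centroid_um: tuple[float, float]
    boundary_um: np.ndarray
    frame_ref: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pixel_set = np.asarray(self.pixel_set, dtype=int)
        if self.pixel_set.ndim != 2 or self.pixel_set.shape[1] != 2:
            raise ValueError("pixel_set must be an (n, 2) array of (row, col)")
        if len(self.pixel_set) == 0:
            raise ValueError("pixel_set must be non-empty")

    @property
    def n_pixels(self) -> int:
        return len(self.pixel_set)

    def mask(self, shape: tuple[int, int]) -> np.ndarray:
        m = np.zeros(shape, dtype=bool)
        m[self.pixel_set[:, 0], self.pixel_set[:, 1]] = True
        return m

    def values(self, image: PhaseImage) -> np.ndarray:
        """Phase-shift values over the pixel set."""
        return image.pixels[self.pixel_set[:, 0], self.pixel_set[:, 1]]


def otsu_threshold(image: PhaseImage | np.ndarray) -> float:
    """Otsu's threshold over a 256-bin histogram of the observed range.

    Returns the cut maximizing the between-class variance
    ``w0 * w1 * (mu0 - mu1)**2``; the threshold is the midpoint between
    the last bin of the low class and the first bin of the high class.
    Raises ``ValueError`` on a constant image (degenerate histogram).
    """
    pixels = image.pixels if isinstance(image, PhaseImage) else np.asarray(image, float)
    lo, hi = float(pixels.min()), float(pixels.max())
    if lo == hi:
        raise ValueError("degenerate histogram: image is constant")
    counts, edges = np.histogram(pixels.ravel(), bins=N_OTSU_BINS, range=(lo, hi))
    centers = 0.5 * (edges[:-1] + edges[1:])

    w = counts.astype(float)
    total = w.sum()
    # cumulative weight and mean of the low class for each candidate cut
    cw = np.cumsum(w)
    cm = np.cumsum(w * centers)
    w0 = cw[:-1] / total
    w1 = 1.0 - w0
    valid = (w0 > 0) & (w1 > 0)
    mu0 = np.where(cw[:-1] > 0, cm[:-1] / np.maximum(cw[:-1], 1e-300), 0.0)
    mu1 = (cm[-1] - cm[:-1]) / np.maximum(cw[-1] - cw[:-1], 1e-300)
    between = np.where(valid, w0 * w1 * (mu0 - mu1) ** 2, -np.inf)
    k = int(np.argmax(between))
    # cut between bin k and bin k+1
    return float(0.5 * (centers[k] + centers[k + 1]))


def crack_perimeter_px(mask: np.ndarray) -> int:
    """Total exposed pixel-edge count of a binary mask (holes included)."""
    m = np.asarray(mask, bool)
    pad = np.pad(m, 1)
    exposed = 0
    for shift_axis, shift in (((0,), 1), ((0,), -1), ((1,), 1), ((1,), -1)):
        exposed += int(np.sum(pad & ~np.roll(pad, shift, axis=shift_axis[0])))
    return exposed


def _crack_polygon(mask: np.ndarray, pixel_size_um: float) -> np.ndarray:
    """Outer boundary polygon along pixel edges, vertices in um (x, y).

    Each exposed pixel side contributes one directed edge (interior kept
    on a consistent side); the edges chain into closed loops and the loop
    enclosing the largest area is the outer boundary.
    """
    m = np.asarray(mask, bool)
    rows, cols = np.nonzero(m)
    padded = np.pad(m, 1)
    edges: dict[tuple[int, int], list[tuple[int, int]]] = {}

    def add(a: tuple[int, int], b: tuple[int, int]) -> None:
        edges.setdefault(a, []).append(b)

    for r, c in zip(rows, cols):
        if not padded[r, c + 1]:  # no neighbour above
            add((r, c), (r, c + 1))
        if not padded[r + 1, c + 2]:  # right
            add((r, c + 1), (r + 1, c + 1))
        if not padded[r + 2, c + 1]:  # below
            add((r + 1, c + 1), (r + 1, c))
        if not padded[r + 1, c]:  # left
            add((r + 1, c), (r, c))

    loops: list[list[tuple[int, int]]] = []
    while edges:
        start = next(iter(edges))
        loop = [start]
        cur = start
        while True:
            nxts = edges[cur]
            nxt = nxts.pop()
            if not nxts:
                del edges[cur]
            loop.append(nxt)
            cur = nxt
            if cur == start:
                break
        loops.append(loop)

    def shoelace(loop: list[tuple[int, int]]) -> float:
        a = 0.0
        for (r0, c0), (r1, c1) in zip(loop[:-1], loop[1:]):
            a += c0 * r1 - c1 * r0
        return abs(a) / 2.0

    outer = max(loops, key=shoelace)
    poly = np.array([(c * pixel_size_um, r * pixel_size_um) for r, c in outer])
    return poly


def object_from_mask(
    mask: np.ndarray, pixel_size_um: float = 1.0, object_id: int = 0
) -> SegmentedObject:
    """Build a :class:`SegmentedObject` directly from a boolean mask."""
    mask = np.asarray(mask, bool)
    pix = np.argwhere(mask)
    if len(pix) == 0:
        raise ValueError("mask is empty")
    centroid = (
        float((pix[:, 1].mean() + 0.5) * pixel_size_um),
        float((pix[:, 0].mean() + 0.5) * pixel_size_um),
    )
    return SegmentedObject(
        object_id=object_id,
        pixel_set=pix,
        centroid_um=centroid,
        boundary_um=_crack_polygon(mask, pixel_size_um),
    )


def segment_frame(
    image: PhaseImage,
    threshold: float,
    min_size: int = DEFAULT_MIN_SIZE,
) -> list[SegmentedObject]:
    """Threshold + 8-connected components + minimum-size filter.

    Pixels strictly above ``threshold`` are foreground.  Components with
    fewer than ``min_size`` pixels are discarded.  Objects are returned
    ordered by the (top, left) corner of their bounding box.
    """
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    if min_size < 1:
        raise ValueError("min_size must be >= 1")

    fg = image.pixels > threshold
    labels = measure.label(fg, connectivity=2)
    objs: list[SegmentedObject] = []
    order: list[tuple[int, int]] = []
    for region in measure.regionprops(labels):
        if region.area < min_size:
            continue
        pix = np.asarray(region.coords, dtype=int)
        mask = np.zeros(image.shape, dtype=bool)
        mask[pix[:, 0], pix[:, 1]] = True
        r_c, c_c = pix[:, 0].mean(), pix[:, 1].mean()
        # pixel centres sit at +0.5 from the pixel's top-left corner
        centroid = (
            float((c_c + 0.5) * image.pixel_size_um),
            float((r_c + 0.5) * image.pixel_size_um),
        )
        boundary = _crack_polygon(mask, image.pixel_size_um)
        objs.append(
            SegmentedObject(
                object_id=-1,
                pixel_set=pix,
                centroid_um=centroid,
                boundary_um=boundary,
                frame_ref={"t": image.t, **image.meta},
            )
        )
        order.append((int(pix[:, 0].min()), int(pix[:, 1].min())))

    ranked = sorted(range(len(objs)), key=lambda i: order[i])
    out = []
    for new_id, i in enumerate(ranked):
        objs[i].object_id = new_id
        out.append(objs[i])
    return out
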