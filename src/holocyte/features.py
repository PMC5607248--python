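"""The 26 biologically independent per-cell features and their selection.

Every feature a holographic cytometer reports derives from a single
per-pixel quantity — the phase shift — so many of the raw metrics are
redundant.  The profiling strategy implemented here keeps a fixed panel
of 26 features spanning four families:

* **morphology** — area, crack perimeter, rotated-bounding-box length and
  breadth, eccentricity, two convexity measures, irregularity;
* **optical** — thickness statistics and volume obtained from the phase
  shift via ``t = phi * lambda / (2 * pi * delta_n)``, plus the minimum
  and standard deviation of the raw phase shift;
* **roughness** — moments of the residual after subtracting a local mean
  filter (local variability of the optical surface);
* **texture** — ten Haralick-family statistics of a gray-level
  co-occurrence matrix (GLCM) restricted to the cell's own pixels.

The module also implements the independence-selection procedure used to
arrive at such a panel: per-experiment absolute Pearson correlations,
reduced across experiments by the minimum, with greedy elimination of
pairs that stay above a cutoff (default 0.98) in *every* experiment.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from shapely.geometry import MultiPoint

from .image import PhaseImage
from .segmentation import SegmentedObject, crack_perimeter_px

logger = logging.getLogger(__name__)

__all__ = [
    "FEATURE_NAMES",
    "CalibrationParams",
    "morphology_features",
    "optical_features",
    "roughness_features",
    "texture_features",
    "extract_features",
    "extract_table",
    "min_abs_correlation",
    "select_independent_features",
]

#: Canonical (alphabetical) order of the 26-feature panel; units in the names.
FEATURE_NAMES: tuple[str, ...] = (
    "Area (μm2)",
    "Boxed breadth (μm)",
    "Boxed length (μm)",
    "Eccentricity",
    "Hull convexity",
    "Irregularity",
    "Perimeter length (μm)",
    "Phaseshift min",
    "Phaseshift std. dev.",
    "Roughness avg",
    "Roughness kurtosis",
    "Roughness skewness",
    "Shape convexity",
    "Texture clustershade",
    "Texture clustertendency",
    "Texture contrast",
    "Texture correlation",
    "Texture correlation info1",
    "Texture correlation info2",
    "Texture energy",
    "Texture entropy",
    "Texture homogeneity",
    "Texture maxprob",
    "Thickness avg (μm)",
    "Thickness max (μm)",
    "Volume (μm3)",
)

#: GLCM offsets (row, col) averaged at distance 1: right, down, down-right, down-left.
GLCM_OFFSETS: tuple[tuple[int, int], ...] = ((0, 1), (1, 0), (1, 1), (1, -1))


@dataclass(frozen=True)
class CalibrationParams:
    """Optical calibration converting phase shift to physical thickness.

    ``wavelength_um`` is the laser wavelength (0.635 um for the common
    635 nm diode); ``delta_n`` the assumed constant refractive-index
    difference between cell and medium (0.04).
    """

    pixel_size_um: float
    wavelength_um: float = 0.635
    delta_n: float = 0.04

    def __post_init__(self) -> None:
        if not (self.pixel_size_um > 0 and self.wavelength_um > 0 and self.delta_n > 0):
            raise ValueError("calibration parameters must all be positive")

    def thickness_um(self, phase_rad: np.ndarray | float) -> np.ndarray | float:
        """Physical thickness t = phi * lambda / (2 * pi * delta_n)."""
        return phase_rad * self.wavelength_um / (2.0 * math.pi * self.delta_n)


# ---------------------------------------------------------------------------
# morphology


def _pixel_corner_points(pixel_set: np.ndarray) -> np.ndarray:
    """All four corner points of every pixel, in (col, row) order."""
    r = pixel_set[:, 0][:, None]
    c = pixel_set[:, 1][:, None]
    corners = np.concatenate(
        [
            np.hstack([c + dc, r + dr])
            for dr in (0, 1)
            for dc in (0, 1)
        ]
    )
    return np.unique(corners, axis=0)


def morphology_features(obj: SegmentedObject, pixel_size_um: float) -> dict[str, float]:
    """Shape descriptors of one segmented object.

    Area counts pixels; perimeter is the crack-boundary length (holes
    included); boxed length/breadth are the side lengths of the
    minimum-area rotated bounding rectangle of the pixel corners;
    eccentricity comes from the second central moments of the pixel
    coverage (a single pixel is perfectly round, eccentricity 0).
    """
    px = pixel_set = obj.pixel_set
    n = len(px)
    area = n * pixel_size_um**2

    perim = crack_perimeter_px(obj.mask(_mask_shape(pixel_set))) * pixel_size_um

    corners = _pixel_corner_points(pixel_set).astype(float) * pixel_size_um
    hull = MultiPoint([tuple(p) for p in corners]).convex_hull
    rect = hull.minimum_rotated_rectangle
    if rect.geom_type == "Polygon":
        xy = np.asarray(rect.exterior.coords)
        sides = np.linalg.norm(np.diff(xy, axis=0), axis=1)
        length, breadth = float(np.max(sides[:2])), float(np.min(sides[:2]))
    else:  # degenerate (collinear corners cannot occur for >=1 pixel, but be safe)
        length = breadth = pixel_size_um

    # second central moments of the pixel coverage: pixel-centre scatter
    # plus the 1/12 per-pixel square term, so a lone pixel is isotropic
    centred = px - px.mean(axis=0)
    cov = centred.T @ centred / n + np.eye(2) / 12.0
    evals = np.linalg.eigvalsh(cov)
    lam2, lam1 = float(evals[0]), float(evals[1])
    eccentricity = math.sqrt(max(0.0, 1.0 - lam2 / lam1)) if lam1 > 0 else 0.0

    hull_area = float(hull.area) if hull.geom_type == "Polygon" else area
    hull_perim = float(hull.length) if hull.geom_type == "Polygon" else perim
    shape_convexity = area / hull_area if hull_area > 0 else 1.0
    hull_convexity = hull_perim / perim if perim > 0 else 1.0
    irregularity = perim / (2.0 * math.sqrt(math.pi * area)) - 1.0

    return {
        "Area (μm2)": area,
        "Perimeter length (μm)": perim,
        "Boxed length (μm)": length,
        "Boxed breadth (μm)": breadth,
        "Eccentricity": eccentricity,
        "Shape convexity": shape_convexity,
        "Hull convexity": hull_convexity,
        "Irregularity": irregularity,
    }


def _mask_shape(pixel_set: np.ndarray) -> tuple[int, int]:
    return (int(pixel_set[:, 0].max()) + 1, int(pixel_set[:, 1].max()) + 1)


# ---------------------------------------------------------------------------
# optical


def optical_features(
    obj: SegmentedObject, image: PhaseImage, calib: CalibrationParams
) -> dict[str, float]:
    """Thickness/volume and raw phase-shift statistics over the object."""
    phi = obj.values(image)
    t = np.asarray(calib.thickness_um(phi), dtype=float)
    area_px = calib.pixel_size_um**2
    return {
        "Thickness avg (μm)": float(t.mean()),
        "Thickness max (μm)": float(t.max()),
        "Volume (μm3)": float(t.sum() * area_px),
        "Phaseshift min": float(phi.min()),
        "Phaseshift std. dev.": float(phi.std()),  # population sd
    }


# ---------------------------------------------------------------------------
# roughness


def _sample_skew_kurt(x: np.ndarray) -> tuple[float, float]:
    """Bias-uncorrected sample skewness and excess kurtosis; 0 on zero variance."""
    m = x.mean()
    s2 = np.mean((x - m) ** 2)
    if s2 <= 0:
        return 0.0, 0.0
    m3 = np.mean((x - m) ** 3)
    m4 = np.mean((x - m) ** 4)
    return float(m3 / s2**1.5), float(m4 / s2**2 - 3.0)


def roughness_features(
    obj: SegmentedObject, image: PhaseImage, kernel_px: int = 5
) -> dict[str, float]:
    """Local-variability statistics of the phase surface.

    The residual map is the phase image minus its ``kernel_px`` square
    mean filter, restricted to the object's pixels.  The filter
    reproduces linear ramps away from edges, so a tilted but smooth cell
    has near-zero roughness.
    """
    smooth = ndimage.uniform_filter(image.pixels, size=kernel_px, mode="nearest")
    resid = (image.pixels - smooth)[obj.pixel_set[:, 0], obj.pixel_set[:, 1]]
    skew, kurt = _sample_skew_kurt(resid)
    return {
        "Roughness avg": float(np.abs(resid).mean()),
        "Roughness skewness": skew,
        "Roughness kurtosis": kurt,
    }


# ---------------------------------------------------------------------------
# texture (masked GLCM)


def quantize_object(values: np.ndarray, levels: int) -> np.ndarray:
    """Quantize values over their observed range into ``levels`` gray levels."""
    vmin, vmax = float(values.min()), float(values.max())
    if vmax == vmin:
        return np.zeros(len(values), dtype=int)
    q = np.floor((values - vmin) / (vmax - vmin) * levels).astype(int)
    return np.minimum(q, levels - 1)


def masked_glcm(
    obj: SegmentedObject,
    image: PhaseImage,
    levels: int = 32,
    distance_px: int = 1,
    offsets: Sequence[tuple[int, int]] = GLCM_OFFSETS,
) -> np.ndarray:
    """Symmetric normalized GLCM averaged over offsets, masked to the object.

    Unlike a whole-image GLCM, only pairs with *both* pixels inside the
    object's pixel set are counted, so background never contaminates the
    texture statistics.  Offsets with no valid pair are skipped.
    """
    shape = _mask_shape(obj.pixel_set)
    level_img = np.full(shape, -1, dtype=int)
    vals = obj.values(image)
    level_img[obj.pixel_set[:, 0], obj.pixel_set[:, 1]] = quantize_object(vals, levels)

    mats = []
    for dr, dc in offsets:
        dr, dc = dr * distance_px, dc * distance_px
        counts = np.zeros((levels, levels), dtype=float)
        rows, cols = obj.pixel_set[:, 0], obj.pixel_set[:, 1]
        r2, c2 = rows + dr, cols + dc
        ok = (r2 >= 0) & (r2 < shape[0]) & (c2 >= 0) & (c2 < shape[1])
        r2, c2 = r2[ok], c2[ok]
        a = level_img[rows[ok], cols[ok]]
        b = level_img[r2, c2]
        valid = b >= 0
        a, b = a[valid], b[valid]
        if len(a) == 0:
            continue
        np.add.at(counts, (a, b), 1.0)
        counts = counts + counts.T  # symmetric
        mats.append(counts / counts.sum())
    if not mats:
        # isolated pixels: fall back to the degenerate single-entry GLCM
        counts = np.zeros((levels, levels))
        counts[0, 0] = 1.0
        mats = [counts]
    return np.mean(mats, axis=0)


def glcm_statistics(P: np.ndarray) -> dict[str, float]:
    """The ten Haralick-family statistics of a normalized GLCM.

    Entropy uses the natural log.  Correlation and both information
    measures of correlation are defined as 0 for degenerate (single
    gray level) matrices.
    """
    L = P.shape[0]
    i = np.arange(L)[:, None]
    j = np.arange(L)[None, :]
    px = P.sum(axis=1)
    mu_i = float((i[:, 0] * px).sum())
    mu_j = mu_i  # symmetric
    var_i = float(((i[:, 0] - mu_i) ** 2 * px).sum())

    contrast = float((P * (i - j) ** 2).sum())
    if var_i > 0:
        correlation = float((P * (i - mu_i) * (j - mu_j)).sum() / var_i)
    else:
        correlation = 0.0
    energy = float((P**2).sum())
    nz = P > 0
    entropy = float(-(P[nz] * np.log(P[nz])).sum())
    homogeneity = float((P / (1.0 + (i - j) ** 2)).sum())
    maxprob = float(P.max())
    dev = i + j - mu_i - mu_j
    clustershade = float((P * dev**3).sum())
    clustertendency = float((P * dev**2).sum())

    pnz = px > 0
    hx = float(-(px[pnz] * np.log(px[pnz])).sum())
    outer = px[:, None] * px[None, :]
    onz = outer > 0
    hxy1 = float(-(P[onz] * np.log(outer[onz])).sum())
    hxy2 = float(-(outer[onz] * np.log(outer[onz])).sum())
    if hx > 0:
        info1 = (entropy - hxy1) / hx  # max(HX, HY) = HX by symmetry
        info2 = math.sqrt(max(0.0, 1.0 - math.exp(-2.0 * (hxy2 - entropy))))
    else:
        info1 = 0.0
        info2 = 0.0

    return {
        "Texture contrast": contrast,
        "Texture correlation": correlation,
        "Texture energy": energy,
        "Texture entropy": entropy,
        "Texture homogeneity": homogeneity,
        "Texture maxprob": maxprob,
        "Texture clustershade": clustershade,
        "Texture clustertendency": clustertendency,
        "Texture correlation info1": float(info1),
        "Texture correlation info2": float(info2),
    }


def texture_features(
    obj: SegmentedObject,
    image: PhaseImage,
    levels: int = 32,
    distance_px: int = 1,
) -> dict[str, float]:
    """Ten GLCM texture statistics over the object's own pixels."""
    if obj.n_pixels < 2:
        raise ValueError("texture features require at least 2 pixels")
    P = masked_glcm(obj, image, levels=levels, distance_px=distance_px)
    return glcm_statistics(P)


# ---------------------------------------------------------------------------
# full panel + tables


def extract_features(
    obj: SegmentedObject,
    image: PhaseImage,
    calib: CalibrationParams,
    *,
    roughness_kernel_px: int = 5,
    glcm_levels: int = 32,
    glcm_distance_px: int = 1,
) -> dict[str, float]:
    """All 26 features for one object, keyed by the canonical names."""
    out: dict[str, float] = {}
    out.update(morphology_features(obj, calib.pixel_size_um))
    out.update(optical_features(obj, image, calib))
    out.update(roughness_features(obj, image, kernel_px=roughness_kernel_px))
    out.update(texture_features(obj, image, levels=glcm_levels, distance_px=glcm_distance_px))
    return {name: out[name] for name in FEATURE_NAMES}


def extract_table(
    images: Sequence[PhaseImage],
    objects_per_image: Sequence[Sequence[SegmentedObject]],
    calib: CalibrationParams,
    **feature_kwargs,
) -> pd.DataFrame:
    """One row per object across frames; metadata columns attached.

    Objects whose feature computation fails are dropped with a logged
    reason rather than aborting the whole table.
    """
    rows = []
    for image, objects in zip(images, objects_per_image):
        for obj in objects:
            try:
                feats = extract_features(obj, image, calib, **feature_kwargs)
            except Exception as exc:  # pragma: no cover - defensive
                logger.warning(
                    "dropping object %s at t=%.1f h: %s", obj.object_id, image.t, exc
                )
                continue
            meta = {
                "t": image.t,
                "object_id": obj.object_id,
                "centroid_x_um": obj.centroid_um[0],
                "centroid_y_um": obj.centroid_um[1],
            }
            meta.update({k: v for k, v in image.meta.items() if np.isscalar(v) or isinstance(v, str)})
            rows.append({**meta, **feats})
    if not rows:
        return pd.DataFrame(columns=["t", "object_id", "centroid_x_um", "centroid_y_um", *FEATURE_NAMES])
    df = pd.DataFrame(rows)
    meta_cols = [c for c in df.columns if c not in FEATURE_NAMES]
    return df[meta_cols + list(FEATURE_NAMES)]


# ---------------------------------------------------------------------------
# feature-independence selection


def _abs_pearson(table: pd.DataFrame, features: Sequence[str]) -> pd.DataFrame:
    """|Pearson r| matrix for one experiment; zero-variance features -> NaN."""
    X = table[list(features)].to_numpy(float)
    sd = X.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.abs(np.corrcoef(X, rowvar=False))
    bad = sd == 0
    if bad.any():
        logger.info("zero-variance features in experiment: %s",
                    [f for f, b in zip(features, bad) if b])
        corr[bad, :] = np.nan
        corr[:, bad] = np.nan
    np.fill_diagonal(corr, 1.0)
    return pd.DataFrame(corr, index=features, columns=features)


def min_abs_correlation(
    tables: Iterable[pd.DataFrame],
    features: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Minimal |Pearson r| across experiments for every feature pair.

    Correlations are computed per experiment; the matrix entry is the
    minimum over experiments, ignoring experiments where either feature
    has zero variance.  Small minima mean the pair carried independent
    information in at least one biological condition.
    """
    tables = list(tables)
    if not tables:
        raise ValueError("need at least one feature table")
    if features is None:
        common = set(tables[0].columns)
        for t in tables[1:]:
            common &= set(t.columns)
        features = [f for f in tables[0].columns if f in common and f in FEATURE_NAMES] or [
            f for f in tables[0].columns if f in common
        ]
    for t in tables:
        if len(t) < 3:
            raise ValueError("each experiment table needs at least 3 rows")
    stack = np.stack([_abs_pearson(t, features).to_numpy() for t in tables])
    mat = np.nanmin(stack, axis=0)
    np.fill_diagonal(mat, 1.0)
    return pd.DataFrame(mat, index=list(features), columns=list(features))


def select_independent_features(
    per_table_correlations: Sequence[pd.DataFrame],
    cutoff: float = 0.98,
    *,
    exclude: Sequence[str] = (),
) -> list[str]:
    """Greedy elimination of features redundant in *every* experiment.

    A pair is redundant only if |r| > cutoff in all experiments; the
    later feature in canonical order is dropped.  ``exclude`` removes
    declared constant multiples and positional metrics up front.
    """
    per_table_correlations = list(per_table_correlations)
    if not per_table_correlations:
        raise ValueError("need correlations from at least one experiment")
    features = list(per_table_correlations[0].columns)
    stack = np.stack([c.loc[features, features].to_numpy() for c in per_table_correlations])
    min_corr = np.nanmin(np.abs(stack), axis=0)

    retained = [f for f in features if f not in set(exclude)]
    idx = {f: i for i, f in enumerate(features)}
    kept: list[str] = []
    for f in retained:
        redundant = any(min_corr[idx[g], idx[f]] > cutoff for g in kept)
        if not redundant:
            kept.append(f)
    return kept
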