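"""Synthetic phase-shift scenes with known ground truth.

Real holographic-cytometry datasets are instrument-bound, so every
downstream stage of the pipeline is exercised against a controllable
generator instead:

* per-state feature distributions are class-conditional multivariate
  Gaussians (:class:`StateModel`), matching how well-separated cell
  states actually distribute in the 26-feature space;
* rendered frames place smooth elliptical "phase caps"
  (``phase(r) = peak_phase * (1 - r^2)`` over the normalized elliptical
  radius) plus band-limited interior texture on a noisy background;
* the background noise standard deviation drifts upward with time
  (:class:`DriftModel`), emulating a laser diode going stale after
  calibration;
* time-lapse simulation moves cells, divides them, and kills them by
  per-hour hazards, recording every event and per-hour state label in
  :class:`TruthTrack` objects.

Everything is driven by a single :class:`numpy.random.Generator`, so a
fixed seed reproduces frames, truth, and tables bit for bit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .features import FEATURE_NAMES
from .image import PhaseImage, write_phase_tiff

__all__ = [
    "CellSpec",
    "CellRenderParams",
    "StateModel",
    "DriftModel",
    "ConditionSpec",
    "ExperimentDesign",
    "SceneTruth",
    "TruthObject",
    "TruthTrack",
    "sample_feature_vectors",
    "render_frame",
    "simulate_timelapse",
    "example_state_models",
]


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class CellSpec:
    """Geometry and optical profile of one rendered cell."""

    state_label: str
    center_um: tuple[float, float]  # (x, y)
    semi_axes_um: tuple[float, float]  # (a, b), a >= b
    orientation_rad: float = 0.0
    peak_phase_rad: float = 2.0
    texture_amp_rad: float = 0.0
    texture_scale_px: float = 2.0

    def __post_init__(self) -> None:
        a, b = self.semi_axes_um
        if not (a >= b > 0):
            raise ValueError("semi-axes must satisfy a >= b > 0")
        if not self.peak_phase_rad > 0:
            raise ValueError("peak_phase must be positive")
        if self.texture_amp_rad < 0:
            raise ValueError("texture_amp must be non-negative")


@dataclass(frozen=True)
class CellRenderParams:
    """How cells of one state look when rendered."""

    semi_axes_um: tuple[float, float] = (8.0, 6.0)
    peak_phase_rad: float = 2.0
    texture_amp_rad: float = 0.1
    texture_scale_px: float = 2.0


@dataclass(frozen=True)
class StateModel:
    """Class-conditional feature distribution and behaviour of one state.

    ``feature_mean``/``feature_cov`` define the 26-feature multivariate
    Gaussian; hazards are per-hour probabilities; ``motility_step_um``
    is the per-axis standard deviation of the hourly Gaussian step.
    """

    label: str
    feature_mean: np.ndarray
    feature_cov: np.ndarray
    division_hazard: float = 0.0
    death_hazard: float = 0.0
    motility_step_um: float = 1.0
    render: CellRenderParams = field(default_factory=CellRenderParams)

    def __post_init__(self) -> None:
        mean = np.asarray(self.feature_mean, dtype=float)
        cov = np.asarray(self.feature_cov, dtype=float)
        object.__setattr__(self, "feature_mean", mean)
        object.__setattr__(self, "feature_cov", cov)
        if cov.shape != (len(mean), len(mean)):
            raise ValueError("feature_cov shape does not match feature_mean")
        if not np.allclose(cov, cov.T):
            raise ValueError("feature_cov must be symmetric")
        evals = np.linalg.eigvalsh(cov)
        if evals.min() < -1e-8 * max(evals.max(), 1.0):
            raise ValueError(
                f"feature_cov is not positive semi-definite (min eigenvalue {evals.min():.3g})"
            )
        for name in ("division_hazard", "death_hazard"):
            h = getattr(self, name)
            if not 0.0 <= h <= 1.0:
                raise ValueError(f"{name} must be in [0, 1] per hour")


@dataclass(frozen=True)
class DriftModel:
    """Linear upward drift of the background noise level.

    ``sd(t) = bg_sd_start + bg_sd_rate * t`` — the qualitative shape of
    a laser module going out of calibration over a two-day time lapse.
    """

    bg_sd_start: float = 0.05
    bg_sd_rate: float = 0.0125  # crosses a 0.5 threshold near 36-40 h from 0.05
    bg_mean: float = 0.0

    def __post_init__(self) -> None:
        if self.bg_sd_rate < 0:
            raise ValueError("bg_sd_rate must be non-negative")
        if self.bg_sd_start < 0:
            raise ValueError("bg_sd_start must be non-negative")

    def sd_at(self, t_hours: float) -> float:
        return self.bg_sd_start + self.bg_sd_rate * t_hours


@dataclass(frozen=True)
class ConditionSpec:
    """One treatment condition: name plus a state-transition schedule.

    ``schedule`` maps onset hours to state labels, e.g.
    ``((0, "NT"), (6, "St"))`` = untreated behaviour for 6 h, then the
    pre-apoptotic state.
    """

    name: str
    schedule: tuple[tuple[float, str], ...]

    def label_at(self, t: float) -> str:
        label = self.schedule[0][1]
        for onset, lab in self.schedule:
            if t >= onset:
                label = lab
        return label


@dataclass(frozen=True)
class ExperimentDesign:
    """Layout of a simulated time-lapse experiment."""

    conditions: tuple[ConditionSpec, ...]
    n_cells: int = 10
    duration_h: float = 48.0
    frame_interval_h: float = 1.0
    image_shape_px: tuple[int, int] = (256, 256)
    pixel_size_um: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_h < 1:
            raise ValueError("duration_h must be >= 1")
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")

    @property
    def frame_times(self) -> np.ndarray:
        return np.arange(0.0, self.duration_h + 1e-9, self.frame_interval_h)


@dataclass
class TruthObject:
    """Ground-truth record of one rendered cell in one frame."""

    label: str
    pixel_set: np.ndarray  # (n, 2) of (row, col)
    centroid_um: tuple[float, float]
    overlaps: bool = False
    track_id: int | None = None


@dataclass
class SceneTruth:
    objects: list[TruthObject]
    t: float


@dataclass
class TruthTrack:
    """Ground-truth single-cell track: hourly observations plus events."""

    track_id: int
    condition: str
    parent_id: int | None = None
    times: list[float] = field(default_factory=list)
    positions_um: list[tuple[float, float]] = field(default_factory=list)
    labels: list[str] = field(default_factory=list)
    features: list[np.ndarray] = field(default_factory=list)
    division_time: float | None = None
    death_time: float | None = None

    @property
    def alive_at_end(self) -> bool:
        return self.division_time is None and self.death_time is None

    def feature_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(np.asarray(self.features), columns=list(FEATURE_NAMES))
        df.insert(0, "t", self.times)
        df.insert(1, "track_id", self.track_id)
        df.insert(2, "label", self.labels)
        return df


# ---------------------------------------------------------------------------
# feature sampling


def sample_feature_vectors(
    model: StateModel, n: int, rng: np.random.Generator | int | None = None
) -> pd.DataFrame:
    """Draw ``n`` feature vectors from a state's multivariate Gaussian."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(rng)
    X = rng.multivariate_normal(model.feature_mean, model.feature_cov, size=n,
                                method="svd")
    df = pd.DataFrame(X, columns=list(FEATURE_NAMES))
    df["label"] = model.label
    return df


# ---------------------------------------------------------------------------
# rendering


def _elliptical_radius_sq(
    shape: tuple[int, int], pixel_size_um: float, cell: CellSpec
) -> np.ndarray:
    rows = (np.arange(shape[0]) + 0.5) * pixel_size_um
    cols = (np.arange(shape[1]) + 0.5) * pixel_size_um
    yy, xx = np.meshgrid(rows, cols, indexing="ij")
    dx = xx - cell.center_um[0]
    dy = yy - cell.center_um[1]
    ct, st = np.cos(cell.orientation_rad), np.sin(cell.orientation_rad)
    u = dx * ct + dy * st
    v = -dx * st + dy * ct
    a, b = cell.semi_axes_um
    return (u / a) ** 2 + (v / b) ** 2


def render_frame(
    cells: Sequence[CellSpec],
    drift: DriftModel,
    t: float,
    *,
    image_shape_px: tuple[int, int] = (256, 256),
    pixel_size_um: float = 0.5,
    rng: np.random.Generator | int | None = None,
    meta: Mapping | None = None,
) -> tuple[PhaseImage, SceneTruth]:
    """Render one frame: phase caps + interior texture + drifting noise.

    Each cell is a smooth elliptical cap (``peak_phase`` at the centre,
    0 at the boundary); texture is low-pass-filtered white noise scaled
    to ``texture_amp`` inside the cell; i.i.d. Gaussian background noise
    with sd ``drift.sd_at(t)`` is added everywhere.  Overlapping cells
    add their phases and are flagged in the truth.
    """
    rng = np.random.default_rng(rng)
    img = np.full(image_shape_px, float(drift.bg_mean))
    claimed = np.zeros(image_shape_px, dtype=np.int16)
    truths: list[TruthObject] = []

    for cell in cells:
        r2 = _elliptical_radius_sq(image_shape_px, pixel_size_um, cell)
        mask = r2 < 1.0
        if not mask.any():
            raise ValueError(f"cell at {cell.center_um} falls outside the frame")
        img[mask] += cell.peak_phase_rad * (1.0 - r2[mask])
        if cell.texture_amp_rad > 0:
            noise = ndimage.gaussian_filter(
                rng.standard_normal(image_shape_px), sigma=cell.texture_scale_px
            )
            sd = noise.std()
            if sd > 0:
                img[mask] += cell.texture_amp_rad * noise[mask] / sd
        claimed[mask] += 1
        pix = np.argwhere(mask)
        truths.append(
            TruthObject(
                label=cell.state_label,
                pixel_set=pix,
                centroid_um=cell.center_um,
            )
        )

    for tr in truths:
        tr.overlaps = bool(np.any(claimed[tr.pixel_set[:, 0], tr.pixel_set[:, 1]] > 1))

    sd = drift.sd_at(t)
    if sd > 0:
        img += rng.normal(0.0, sd, size=image_shape_px)

    image = PhaseImage(pixels=img, pixel_size_um=pixel_size_um, t=t, meta=dict(meta or {}))
    return image, SceneTruth(objects=truths, t=t)


# ---------------------------------------------------------------------------
# time-lapse simulation


@dataclass
class _LiveCell:
    track: TruthTrack
    x: float
    y: float
    orientation: float


def simulate_timelapse(
    design: ExperimentDesign,
    state_models: Mapping[str, StateModel],
    drift: DriftModel,
    rng: np.random.Generator | int | None = None,
    *,
    render: bool = True,
) -> dict[str, tuple[list[PhaseImage], list[TruthTrack]]]:
    """Simulate every condition of a design; returns frames + truth tracks.

    Per hour each live cell takes a Gaussian motility step, may divide
    (two daughters placed one semi-minor axis to either side along a
    random axis) or die according to the hazards of its current state,
    and records a feature vector drawn from that state's Gaussian.
    Hazards are evaluated on the state active at the *new* frame time,
    so schedule switches take effect at their onset hour.
    """
    rng = np.random.default_rng(design.seed if rng is None else rng)
    results: dict[str, tuple[list[PhaseImage], list[TruthTrack]]] = {}
    h_px, w_px = design.image_shape_px
    width_um = w_px * design.pixel_size_um
    height_um = h_px * design.pixel_size_um

    for cond in design.conditions:
        tracks: list[TruthTrack] = []
        live: list[_LiveCell] = []
        margin = max(
            sm.render.semi_axes_um[0] for sm in state_models.values()
        ) + 2 * design.pixel_size_um

        def new_track(parent: int | None, x: float, y: float) -> _LiveCell:
            tr = TruthTrack(track_id=len(tracks), condition=cond.name, parent_id=parent)
            tracks.append(tr)
            return _LiveCell(
                track=tr,
                x=float(np.clip(x, margin, width_um - margin)),
                y=float(np.clip(y, margin, height_um - margin)),
                orientation=float(rng.uniform(0, np.pi)),
            )

        for _ in range(design.n_cells):
            live.append(
                new_track(
                    None,
                    rng.uniform(margin, width_um - margin),
                    rng.uniform(margin, height_um - margin),
                )
            )

        frames: list[PhaseImage] = []
        for k, t in enumerate(design.frame_times):
            label = cond.label_at(t)
            model = state_models[label]

            if k > 0:
                survivors: list[_LiveCell] = []
                for cell in live:
                    u_death = rng.uniform()
                    u_div = rng.uniform()
                    step = rng.normal(0.0, model.motility_step_um, size=2)
                    if u_death < model.death_hazard:
                        cell.track.death_time = t
                        continue
                    if u_div < model.division_hazard:
                        cell.track.division_time = t
                        angle = rng.uniform(0, 2 * np.pi)
                        off = model.render.semi_axes_um[1]
                        dx, dy = off * np.cos(angle), off * np.sin(angle)
                        for sign in (+1, -1):
                            survivors.append(
                                new_track(
                                    cell.track.track_id,
                                    cell.x + sign * dx,
                                    cell.y + sign * dy,
                                )
                            )
                        continue
                    cell.x = float(np.clip(cell.x + step[0], margin, width_um - margin))
                    cell.y = float(np.clip(cell.y + step[1], margin, height_um - margin))
                    survivors.append(cell)
                live = survivors

            specs: list[CellSpec] = []
            for cell in live:
                feats = rng.multivariate_normal(
                    model.feature_mean, model.feature_cov, method="svd"
                )
                cell.track.times.append(float(t))
                cell.track.positions_um.append((cell.x, cell.y))
                cell.track.labels.append(label)
                cell.track.features.append(feats)
                rp = model.render
                specs.append(
                    CellSpec(
                        state_label=label,
                        center_um=(cell.x, cell.y),
                        semi_axes_um=rp.semi_axes_um,
                        orientation_rad=cell.orientation,
                        peak_phase_rad=rp.peak_phase_rad,
                        texture_amp_rad=rp.texture_amp_rad,
                        texture_scale_px=rp.texture_scale_px,
                    )
                )

            if render:
                image, truth = render_frame(
                    specs,
                    drift,
                    t,
                    image_shape_px=design.image_shape_px,
                    pixel_size_um=design.pixel_size_um,
                    rng=rng,
                    meta={"condition": cond.name, "frame": k},
                )
                for tr_obj, cell in zip(truth.objects, live):
                    tr_obj.track_id = cell.track.track_id
                image.meta["truth"] = truth
                frames.append(image)

        results[cond.name] = (frames, tracks)
    return results


# ---------------------------------------------------------------------------
# example state models (fixture parameters, not measured biology)


def _base_mean() -> np.ndarray:
    vals = {
        "Area (μm2)": 380.0,
        "Boxed breadth (μm)": 16.0,
        "Boxed length (μm)": 26.0,
        "Eccentricity": 0.75,
        "Hull convexity": 0.92,
        "Irregularity": 0.25,
        "Perimeter length (μm)": 90.0,
        "Phaseshift min": 0.08,
        "Phaseshift std. dev.": 0.45,
        "Roughness avg": 0.05,
        "Roughness kurtosis": 0.4,
        "Roughness skewness": 0.1,
        "Shape convexity": 0.88,
        "Texture clustershade": 8.0,
        "Texture clustertendency": 45.0,
        "Texture contrast": 6.0,
        "Texture correlation": 0.85,
        "Texture correlation info1": -0.35,
        "Texture correlation info2": 0.85,
        "Texture energy": 0.05,
        "Texture entropy": 3.4,
        "Texture homogeneity": 0.55,
        "Texture maxprob": 0.12,
        "Thickness avg (μm)": 3.2,
        "Thickness max (μm)": 7.5,
        "Volume (μm3)": 1220.0,
    }
    return np.array([vals[n] for n in FEATURE_NAMES])


#: Per-feature shift applied per unit of state effect; index-aligned to FEATURE_NAMES.
_STATE_SHIFTS = {
    # pre-apoptotic: shrunken, thick, rough, high-contrast texture
    "St": {
        "Area (μm2)": -150.0,
        "Thickness avg (μm)": 2.0,
        "Thickness max (μm)": 4.0,
        "Roughness avg": 0.05,
        "Texture contrast": 5.0,
        "Phaseshift std. dev.": 0.35,
        "Shape convexity": 0.06,
        "Irregularity": -0.1,
    },
    # CDK4/6-inhibited: spread out, flat, smooth
    "CDKi": {
        "Area (μm2)": 300.0,
        "Boxed length (μm)": 10.0,
        "Boxed breadth (μm)": 6.0,
        "Perimeter length (μm)": 35.0,
        "Thickness avg (μm)": -1.2,
        "Thickness max (μm)": -2.5,
        "Texture entropy": 0.4,
        "Texture homogeneity": 0.1,
    },
    # M-phase: small, round, very thick
    "M": {
        "Area (μm2)": -180.0,
        "Eccentricity": -0.45,
        "Irregularity": -0.18,
        "Thickness avg (μm)": 3.5,
        "Thickness max (μm)": 6.0,
        "Shape convexity": 0.1,
        "Volume (μm3)": 250.0,
    },
    "NT": {},
}

_RELATIVE_SD = 0.12  # per-feature sd as a fraction of a characteristic scale


def example_state_models(
    separation: float = 1.0,
    *,
    division_hazards: Mapping[str, float] | None = None,
    death_hazards: Mapping[str, float] | None = None,
    motility_um: Mapping[str, float] | None = None,
) -> dict[str, StateModel]:
    """Four plausible cell-state models (NT, St, CDKi, M) for fixtures.

    ``separation`` scales the between-state mean shifts: 1.0 gives
    partially overlapping states, large values make states trivially
    separable.  These parameters are fixture choices, not measurements
    of any real cell line.
    """
    base = _base_mean()
    scale = np.maximum(np.abs(base) * _RELATIVE_SD, 0.02)
    cov = np.diag(scale**2)
    if division_hazards is None:
        division_hazards = {"NT": 0.04, "St": 0.0, "CDKi": 0.0, "M": 0.3}
    if death_hazards is None:
        death_hazards = {"NT": 0.002, "St": 0.08, "CDKi": 0.002, "M": 0.002}
    if motility_um is None:
        motility_um = {"NT": 2.0, "St": 0.8, "CDKi": 1.2, "M": 1.0}

    renders = {
        "NT": CellRenderParams((9.0, 6.5), 2.0, 0.10, 2.0),
        "St": CellRenderParams((6.0, 5.0), 3.2, 0.25, 1.5),
        "CDKi": CellRenderParams((13.0, 9.0), 1.2, 0.06, 3.0),
        "M": CellRenderParams((6.0, 5.8), 3.6, 0.12, 2.0),
    }

    models = {}
    name_to_idx = {n: i for i, n in enumerate(FEATURE_NAMES)}
    for label in ("NT", "St", "CDKi", "M"):
        mean = base.copy()
        for feat, shift in _STATE_SHIFTS[label].items():
            mean[name_to_idx[feat]] += separation * shift
        models[label] = StateModel(
            label=label,
            feature_mean=mean,
            feature_cov=cov,
            division_hazard=division_hazards.get(label, 0.0),
            death_hazard=death_hazards.get(label, 0.0),
            motility_step_um=motility_um.get(label, 1.0),
            render=renders[label],
        )
    return models


# ---------------------------------------------------------------------------
# on-disk formats


def write_frames(
    frames: Sequence[PhaseImage], outdir: str | Path, condition: str, well: str = "A1"
) -> list[Path]:
    """Write frames as float TIFFs named ``{condition}/{well}_{t:03d}.tif``."""
    outdir = Path(outdir)
    paths = []
    for k, frame in enumerate(frames):
        path = outdir / condition / f"{well}_{k:03d}.tif"
        write_phase_tiff(frame, path)
        paths.append(path)
    return paths


def tracks_to_json(tracks: Sequence[TruthTrack], path: str | Path | None = None) -> str:
    doc = [
        {
            "track_id": tr.track_id,
            "condition": tr.condition,
            "parent_id": tr.parent_id,
            "times": tr.times,
            "positions_um": [list(p) for p in tr.positions_um],
            "labels": tr.labels,
            "features": [np.asarray(f).tolist() for f in tr.features],
            "division_time": tr.division_time,
            "death_time": tr.death_time,
        }
        for tr in tracks
    ]
    text = json.dumps(doc)
    if path is not None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        Path(path).write_text(text)
    return text


def tracks_from_json(source: str | Path) -> list[TruthTrack]:
    p = Path(str(source))
    text = p.read_text() if p.exists() else str(source)
    doc = json.loads(text)
    return [
        TruthTrack(
            track_id=d["track_id"],
            condition=d["condition"],
            parent_id=d["parent_id"],
            times=d["times"],
            positions_um=[tuple(p) for p in d["positions_um"]],
            labels=d["labels"],
            features=[np.asarray(f) for f in d["features"]],
            division_time=d["division_time"],
            death_time=d["death_time"],
        )
        for d in doc
    ]
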