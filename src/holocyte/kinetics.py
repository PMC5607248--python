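"""Single-cell kinetics: tracking, state-probability time courses,
super-metrics, and condition clustering.

A time-lapse experiment yields, per condition, a stack of hourly frames.
Objects are linked across frames by greedy nearest-centroid matching
under a maximum-step gate; an object that two next-frame objects link to
records a division, a track without a successor records a death/exit.
Each track's per-hour state probabilities (from the trained classifier)
are smoothed with a Savitzky-Golay filter (degree 2, window 5) and
condensed, per condition, into six "super-metrics":

pre-apoptotic indicator, growth-arrested indicator, division rate,
mortality, motility, and variability of response.

Super-metrics are normalized to mean 1 across conditions, and conditions
are clustered hierarchically (Euclidean distance, average linkage) on
the four indicator/event metrics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.signal import savgol_filter

from .segmentation import SegmentedObject

logger = logging.getLogger(__name__)

__all__ = [
    "CellTrack",
    "ConditionSummary",
    "link_tracks",
    "track_probabilities",
    "smooth_probabilities",
    "condition_super_metrics",
    "normalize_super_metrics",
    "cluster_conditions",
    "linkage_to_newick",
    "rocket_export",
    "SUPER_METRICS",
    "CLUSTER_METRICS",
]

SUPER_METRICS = (
    "pre_apoptotic_indicator",
    "growth_arrested_indicator",
    "division_rate",
    "mortality",
    "motility",
    "variability_of_response",
)
#: The four metrics used for condition clustering by default.
CLUSTER_METRICS = (
    "pre_apoptotic_indicator",
    "growth_arrested_indicator",
    "mortality",
    "division_rate",
)


@dataclass
class CellTrack:
    """One cell followed through time."""

    track_id: int
    condition: str
    times: list[float] = field(default_factory=list)
    objects: list[SegmentedObject | None] = field(default_factory=list)
    centroids_um: list[tuple[float, float]] = field(default_factory=list)
    features: list[pd.Series | None] = field(default_factory=list)
    division_time: float | None = None
    death_time: float | None = None
    parent_id: int | None = None
    proba_raw: np.ndarray | None = None  # (T, K), NaN where missing
    proba_smooth: np.ndarray | None = None
    proba_classes: tuple[str, ...] | None = None

    @property
    def displacements_um(self) -> np.ndarray:
        """Microns moved since the previous hour (first entry 0)."""
        pos = np.asarray(self.centroids_um, dtype=float)
        if len(pos) < 2:
            return np.zeros(len(pos))
        d = np.linalg.norm(np.diff(pos, axis=0), axis=1)
        return np.concatenate([[0.0], d])

    @property
    def is_dead(self) -> bool:
        return self.death_time is not None

    @property
    def divided(self) -> bool:
        return self.division_time is not None


# ---------------------------------------------------------------------------
# tracking


def link_tracks(
    objects_by_frame: Sequence[Sequence[SegmentedObject]],
    frame_times: Sequence[float],
    max_step_um: float,
    condition: str = "",
) -> list[CellTrack]:
    """Greedy nearest-centroid linking under a maximum-step gate.

    Candidate (previous, next) pairs within ``max_step_um`` are taken in
    order of increasing distance (ties by object order) for one-to-one
    continuation links.  A leftover next-frame object whose nearest
    gated previous object already has a continuation turns that link
    into a division: the previous track ends, both next-frame objects
    start daughter tracks.  Leftover next-frame objects with no gated
    previous object start fresh tracks; previous tracks with no
    successor end as death/exit.
    """
    tracks: list[CellTrack] = []
    # active: list of (track, centroid)
    active: list[CellTrack] = []

    def start(t: float, obj: SegmentedObject, parent: int | None = None) -> CellTrack:
        tr = CellTrack(track_id=len(tracks), condition=condition, parent_id=parent)
        tracks.append(tr)
        append(tr, t, obj)
        return tr

    def append(tr: CellTrack, t: float, obj: SegmentedObject) -> None:
        tr.times.append(float(t))
        tr.objects.append(obj)
        tr.centroids_um.append(obj.centroid_um)

    for obj in objects_by_frame[0]:
        active.append(start(frame_times[0], obj))

    for f in range(1, len(objects_by_frame)):
        t = frame_times[f]
        new_objs = list(objects_by_frame[f])
        pairs = []
        for i, tr in enumerate(active):
            cx, cy = tr.centroids_um[-1]
            for j, obj in enumerate(new_objs):
                d = float(np.hypot(obj.centroid_um[0] - cx, obj.centroid_um[1] - cy))
                if d <= max_step_um:
                    pairs.append((d, i, j))
        pairs.sort()
        cont: dict[int, int] = {}  # prev index -> next index
        used_next: set[int] = set()
        for d, i, j in pairs:
            if i in cont or j in used_next:
                continue
            cont[i] = j
            used_next.add(j)

        # leftover objects are daughter candidates: assign them to gated
        # priors by ascending distance, at most one extra daughter each,
        # so simultaneous divisions of nearby cells stay disentangled
        divisions: dict[int, list[int]] = {}
        leftover = [j for j in range(len(new_objs)) if j not in used_next]
        cand = []
        for j in leftover:
            obj = new_objs[j]
            for i, tr in enumerate(active):
                cx, cy = tr.centroids_um[-1]
                d = float(np.hypot(obj.centroid_um[0] - cx, obj.centroid_um[1] - cy))
                if d <= max_step_um:
                    cand.append((d, j, i))
        cand.sort()
        assigned: set[int] = set()
        for d, j, i in cand:
            if j in assigned or i not in cont or i in divisions:
                continue
            divisions[i] = [j]
            assigned.add(j)
        orphans = [j for j in leftover if j not in assigned]

        next_active: list[CellTrack] = []
        for i, tr in enumerate(active):
            if i in divisions:
                tr.division_time = float(t)
                daughters = [cont[i]] + divisions[i][:1]
                extra = divisions[i][1:]  # >2-way splits: extras become orphans
                orphans.extend(extra)
                for j in daughters:
                    next_active.append(start(t, new_objs[j], parent=tr.track_id))
            elif i in cont:
                append(tr, t, new_objs[cont[i]])
                next_active.append(tr)
            else:
                tr.death_time = float(t)
        for j in orphans:
            next_active.append(start(t, new_objs[j]))
        active = next_active

    return tracks


def tracks_from_truth(truth_tracks, feature_names: Sequence[str]) -> list[CellTrack]:
    """Adapt simulated ground-truth tracks to :class:`CellTrack`.

    Used when studying the kinetics stage in isolation from
    segmentation/tracking error: observations, events, and feature
    vectors are taken verbatim from the simulator's truth.
    """
    out = []
    for tr in truth_tracks:
        ct = CellTrack(
            track_id=tr.track_id,
            condition=tr.condition,
            times=list(tr.times),
            centroids_um=list(tr.positions_um),
            objects=[None] * len(tr.times),
            features=[
                pd.Series(np.asarray(f), index=list(feature_names)) for f in tr.features
            ],
            division_time=tr.division_time,
            death_time=tr.death_time,
            parent_id=tr.parent_id,
        )
        out.append(ct)
    return out


# ---------------------------------------------------------------------------
# probabilities


def track_probabilities(
    classifier,
    track: CellTrack,
    feature_table: pd.DataFrame | None = None,
    missing: Sequence[int] = (),
) -> np.ndarray:
    """Raw per-hour class probabilities for one track.

    ``feature_table`` holds one row per observation (canonical feature
    columns); when None it is assembled from ``track.features``.
    Observation indices in ``missing`` (e.g. frames removed by the BgSD
    filter) are returned as NaN rows.
    """
    if feature_table is None:
        rows = [f for f in track.features if f is not None]
        if len(rows) != len(track.times):
            raise ValueError("track has missing features; pass feature_table")
        feature_table = pd.DataFrame(rows).reset_index(drop=True)
    proba = classifier.predict_proba(feature_table)
    proba = np.asarray(proba, dtype=float)
    for i in missing:
        proba[i, :] = np.nan
    track.proba_raw = proba
    track.proba_classes = tuple(str(c) for c in classifier.classes_)
    return proba


def _interp_nan_columns(series: np.ndarray) -> np.ndarray:
    out = series.copy()
    n = len(out)
    idx = np.arange(n)
    for k in range(out.shape[1]):
        col = out[:, k]
        good = ~np.isnan(col)
        if good.sum() == 0:
            raise ValueError("probability series entirely missing")
        if good.sum() < n:
            logger.info("interpolating %d missing time points", n - good.sum())
            out[:, k] = np.interp(idx, idx[good], col[good])
    return out


def smooth_probabilities(
    series: np.ndarray, degree: int = 2, window: int = 5
) -> np.ndarray:
    """Savitzky-Golay smoothing of a (T, K) probability series.

    Missing (NaN) time points are linearly interpolated first; after
    filtering each time point is clipped to [0, 1] and renormalized to
    sum to 1.  Series shorter than the window pass through unchanged
    (aside from interpolation of missing points).
    """
    series = np.asarray(series, dtype=float)
    if series.ndim != 2:
        raise ValueError("series must be (T, K)")
    filled = _interp_nan_columns(series)
    if len(filled) < window:
        logger.info("series shorter than window (%d < %d); passing through",
                    len(filled), window)
        smoothed = filled
    else:
        smoothed = savgol_filter(filled, window_length=window, polyorder=degree, axis=0)
    smoothed = np.clip(smoothed, 0.0, 1.0)
    totals = smoothed.sum(axis=1, keepdims=True)
    totals[totals == 0] = 1.0
    return smoothed / totals


def smooth_track(track: CellTrack, degree: int = 2, window: int = 5) -> np.ndarray:
    if track.proba_raw is None:
        raise ValueError("run track_probabilities first")
    track.proba_smooth = smooth_probabilities(track.proba_raw, degree, window)
    return track.proba_smooth


# ---------------------------------------------------------------------------
# super-metrics


@dataclass(frozen=True)
class ConditionSummary:
    """Six super-metrics condensing one condition's single-cell kinetics."""

    condition: str
    pre_apoptotic_indicator: float
    growth_arrested_indicator: float
    division_rate: float
    mortality: float
    motility: float
    variability_of_response: float
    n_cells: int

    def as_series(self) -> pd.Series:
        return pd.Series(
            {m: getattr(self, m) for m in SUPER_METRICS}, name=self.condition
        )


def _minmax(x: np.ndarray) -> np.ndarray:
    lo, hi = np.min(x), np.max(x)
    if hi == lo:
        return np.zeros_like(x)
    return (x - lo) / (hi - lo)


def condition_super_metrics(
    tracks: Sequence[CellTrack],
    *,
    st_class: str = "St",
    cdki_class: str = "CDKi",
    hypermotility_um: float | None = None,
    end_time: float | None = None,
    division_rate_per_cell_hour: bool = False,
) -> ConditionSummary:
    """Condense one condition's tracks into the six super-metrics.

    The pre-apoptotic indicator averages smoothed P(St) over cell-hours,
    forcing P(St) = 1 for every hour at or after a cell's death up to
    the end of the experiment.  Mortality is dead cells over (dead +
    alive at the final frame); tracks that end in division continue as
    their daughters and are excluded from that ratio.  Motility is the
    fraction of cell-hours with displacement above the hypermotility
    threshold (default: 2x the median hourly displacement over these
    tracks — pass the untreated condition's threshold for comparisons
    across conditions).
    """
    tracks = [tr for tr in tracks if len(tr.times) > 0]
    if not tracks:
        raise ValueError("need at least one non-empty track")
    for tr in tracks:
        if tr.proba_smooth is None:
            smooth_track(tr)
    classes = tracks[0].proba_classes or ()
    if st_class not in classes or cdki_class not in classes:
        raise ValueError(f"classifier classes {classes} lack {st_class!r}/{cdki_class!r}")
    i_st = classes.index(st_class)
    i_cdki = classes.index(cdki_class)

    if end_time is None:
        end_time = max(tr.times[-1] for tr in tracks)
    interval = 1.0
    for tr in tracks:
        if len(tr.times) > 1:
            interval = float(tr.times[1] - tr.times[0])
            break

    disp_parts = [tr.displacements_um[1:] for tr in tracks if len(tr.times) > 1]
    all_disp = np.concatenate(disp_parts) if disp_parts else np.array([])
    if hypermotility_um is None:
        hypermotility_um = 2.0 * float(np.median(all_disp)) if all_disp.size else np.inf

    st_hours: list[float] = []
    cdki_hours: list[float] = []
    per_cell_st, per_cell_cdki, per_cell_div, per_cell_mot = [], [], [], []
    hyper_hours = 0
    total_move_hours = 0

    for tr in tracks:
        p_st = list(tr.proba_smooth[:, i_st])
        p_cdki = list(tr.proba_smooth[:, i_cdki])
        if tr.is_dead:
            # death pins the pre-apoptotic probability at 1 from the death
            # hour to the end of the experiment
            p_st = [
                1.0 if t >= tr.death_time - 1e-9 else p
                for t, p in zip(tr.times, p_st)
            ]
            ext_start = max(tr.death_time, tr.times[-1] + interval)
            n_after = int(round((end_time - ext_start) / interval)) + 1
            p_st.extend([1.0] * max(n_after, 0))
        st_hours.extend(p_st)
        cdki_hours.extend(p_cdki)

        disp = tr.displacements_um[1:]
        hyper = int(np.sum(disp > hypermotility_um))
        hyper_hours += hyper
        total_move_hours += len(disp)

        per_cell_st.append(float(np.mean(p_st)))
        per_cell_cdki.append(float(np.mean(p_cdki)))
        per_cell_div.append(1.0 if tr.divided else 0.0)
        per_cell_mot.append(hyper / len(disp) if len(disp) else 0.0)

    n_cells = len(tracks)
    total_hours = sum(len(tr.times) for tr in tracks)
    n_divisions = sum(1 for tr in tracks if tr.divided)
    n_dead = sum(1 for tr in tracks if tr.is_dead)
    n_alive_end = sum(
        1 for tr in tracks if not tr.is_dead and not tr.divided and tr.times[-1] >= end_time - 1e-9
    )
    denom = n_dead + n_alive_end
    mortality = n_dead / denom if denom else 0.0

    variability = float(
        np.mean(
            [
                np.var(_minmax(np.asarray(per_cell_st))),
                np.var(_minmax(np.asarray(per_cell_cdki))),
                np.var(_minmax(np.asarray(per_cell_div))),
                np.var(_minmax(np.asarray(per_cell_mot))),
            ]
        )
    )

    return ConditionSummary(
        condition=tracks[0].condition,
        pre_apoptotic_indicator=float(np.mean(st_hours)),
        growth_arrested_indicator=float(np.mean(cdki_hours)),
        division_rate=(
            n_divisions / total_hours if division_rate_per_cell_hour
            else n_divisions / n_cells
        ),
        mortality=mortality,
        motility=hyper_hours / total_move_hours if total_move_hours else 0.0,
        variability_of_response=variability,
        n_cells=n_cells,
    )


def normalize_super_metrics(summaries: Sequence[ConditionSummary] | pd.DataFrame) -> pd.DataFrame:
    """Divide each metric column by its across-condition mean.

    After normalization every column averages exactly 1, making
    heterogeneous units comparable on one heatmap.  Zero-mean columns
    are left untouched (flagged in the log).
    """
    if isinstance(summaries, pd.DataFrame):
        df = summaries.copy()
    else:
        df = pd.DataFrame([s.as_series() for s in summaries])
    for col in df.columns:
        mean = df[col].mean()
        if mean == 0:
            logger.warning("metric %s has zero mean across conditions; not normalized", col)
            continue
        df[col] = df[col] / mean
    return df


def cluster_conditions(
    normalized: pd.DataFrame,
    metrics: Sequence[str] = CLUSTER_METRICS,
) -> np.ndarray:
    """UPGMA (average-linkage, Euclidean) clustering of conditions.

    Returns a scipy linkage matrix over the rows of ``normalized``
    restricted to ``metrics``.
    """
    if len(normalized) < 2:
        raise ValueError("need at least 2 conditions to cluster")
    X = normalized[list(metrics)].to_numpy(dtype=float)
    return hierarchy.linkage(X, method="average", metric="euclidean")


def linkage_to_newick(Z: np.ndarray, labels: Sequence[str]) -> str:
    """Render a scipy linkage matrix as a Newick tree string."""
    tree = hierarchy.to_tree(Z)

    def walk(node, parent_height: float) -> str:
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6g}"
        left = walk(node.left, node.dist)
        right = walk(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return walk(tree, tree.dist) + ";"


# ---------------------------------------------------------------------------
# rocket-plot export


def rocket_export(tracks: Sequence[CellTrack]) -> pd.DataFrame:
    """Long-format table behind a rocket plot: one row per track-hour.

    Columns: track id, time, displacement since the previous hour, the
    smoothed per-state probabilities, and the event at that hour
    (none / division / death; division and death are stamped on the
    track's final observed hour).
    """
    rows = []
    for tr in tracks:
        if tr.proba_smooth is None:
            smooth_track(tr)
        classes = tr.proba_classes or ()
        disp = tr.displacements_um
        for k, t in enumerate(tr.times):
            event = "none"
            if k == len(tr.times) - 1:
                if tr.divided:
                    event = "division"
                elif tr.is_dead:
                    event = "death"
            row = {
                "track_id": tr.track_id,
                "condition": tr.condition,
                "t": t,
                "displacement_um": float(disp[k]),
                "event": event,
            }
            for ci, cname in enumerate(classes):
                row[f"P({cname})"] = float(tr.proba_smooth[k, ci])
            rows.append(row)
    return pd.DataFrame(rows)
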