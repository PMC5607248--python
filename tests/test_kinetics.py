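import numpy as np
import pandas as pd
import pytest

import holocyte as hc
from holocyte import kinetics as kin
from holocyte.segmentation import SegmentedObject
from holocyte.synthetic import ConditionSpec, DriftModel, ExperimentDesign, simulate_timelapse


def _point_object(x_um, y_um, oid=0):
    return SegmentedObject(
        object_id=oid,
        pixel_set=np.array([[int(y_um), int(x_um)]]),
        centroid_um=(float(x_um), float(y_um)),
        boundary_um=np.zeros((2, 2)),
    )


def _track_with_proba(track_id, times, p, classes=("CDKi", "NT", "St"),
                      death_time=None, division_time=None, condition="c",
                      positions=None):
    """Hand-built CellTrack with fixed smoothed probabilities ``p`` (T, K)."""
    p = np.asarray(p, float)
    tr = kin.CellTrack(
        track_id=track_id,
        condition=condition,
        times=list(times),
        centroids_um=positions or [(0.0, 0.0)] * len(times),
        objects=[None] * len(times),
        features=[None] * len(times),
        death_time=death_time,
        division_time=division_time,
    )
    tr.proba_raw = p
    tr.proba_smooth = p
    tr.proba_classes = classes
    return tr


class TestLinkTracks:
    def test_stationary_object_single_track(self):
        frames = [[_point_object(10, 10)] for _ in range(6)]
        tracks = kin.link_tracks(frames, list(range(6)), max_step_um=5.0)
        assert len(tracks) == 1
        tr = tracks[0]
        assert len(tr.times) == 6
        assert np.allclose(tr.displacements_um, 0.0)
        assert tr.death_time is None and tr.division_time is None

    def test_two_distant_objects_never_cross(self):
        frames = [[_point_object(10, 10), _point_object(90, 90)] for _ in range(5)]
        tracks = kin.link_tracks(frames, list(range(5)), max_step_um=8.0)
        assert len(tracks) == 2
        assert all(len(tr.times) == 5 for tr in tracks)

    def test_disappearing_object_marked_dead(self):
        frames = [[_point_object(10, 10)], [_point_object(10, 10)], []]
        tracks = kin.link_tracks(frames, [0, 1, 2], max_step_um=5.0)
        assert tracks[0].death_time == 2.0

    def test_division_detected_when_two_objects_appear(self):
        frames = [
            [_point_object(50, 50)],
            [_point_object(46, 50, 0), _point_object(54, 50, 1)],
            [_point_object(45, 50, 0), _point_object(55, 50, 1)],
        ]
        tracks = kin.link_tracks(frames, [0, 1, 2], max_step_um=10.0)
        parent = tracks[0]
        assert parent.division_time == 1.0
        daughters = [t for t in tracks if t.parent_id == 0]
        assert len(daughters) == 2
        assert all(len(d.times) == 2 for d in daughters)

    def test_recovers_truth_links_on_simulated_geometry(self):
        # motility well below inter-cell spacing; no events
        models = hc.example_state_models(
            division_hazards={"NT": 0.0}, death_hazards={"NT": 0.0},
            motility_um={"NT": 1.0},
        )
        design = ExperimentDesign(
            conditions=(ConditionSpec("NT", ((0.0, "NT"),)),),
            n_cells=8, duration_h=15, image_shape_px=(512, 512), seed=21,
        )
        (_, truth), = simulate_timelapse(design, models, DriftModel(0.0, 0.0),
                                         render=False).values()
        times = design.frame_times
        frames = [[] for _ in times]
        for tr in truth:
            for t, (x, y) in zip(tr.times, tr.positions_um):
                frames[int(t)].append(_point_object(x, y, oid=tr.track_id))
        linked = kin.link_tracks(frames, list(times), max_step_um=12.0)
        # count recovered consecutive links (same truth id in consecutive hours)
        good = total = 0
        for tr in linked:
            for a, b in zip(tr.objects[:-1], tr.objects[1:]):
                total += 1
                good += a.object_id == b.object_id
        assert total > 0
        assert good / total >= 0.99


@pytest.fixture(scope="module")
def clf(models):
    rng = np.random.default_rng(0)
    parts = [hc.sample_feature_vectors(models[l], 300, rng) for l in ("NT", "St", "CDKi")]
    df = pd.concat(parts, ignore_index=True)
    y = df.pop("label")
    return hc.LDAGMMClassifier(random_state=0).fit(df, y)


class TestTrackProbabilities:
    def test_constant_features_constant_probabilities(self, clf, models):
        feats = pd.Series(models["NT"].feature_mean, index=list(hc.FEATURE_NAMES))
        tr = kin.CellTrack(0, "NT", times=[0.0, 1.0, 2.0],
                           centroids_um=[(0, 0)] * 3, objects=[None] * 3,
                           features=[feats] * 3)
        p = kin.track_probabilities(clf, tr)
        assert np.allclose(p, p[0])
        assert np.allclose(p.sum(axis=1), 1.0)

    def test_state_jump_switches_argmax(self, clf, models):
        nt = pd.Series(models["NT"].feature_mean, index=list(hc.FEATURE_NAMES))
        st = pd.Series(models["St"].feature_mean, index=list(hc.FEATURE_NAMES))
        tr = kin.CellTrack(0, "x", times=[0.0, 1.0, 2.0, 3.0],
                           centroids_um=[(0, 0)] * 4, objects=[None] * 4,
                           features=[nt, nt, st, st])
        p = kin.track_probabilities(clf, tr)
        idx = {c: i for i, c in enumerate(clf.classes_)}
        assert p[:2, idx["NT"]].min() > 0.5
        assert p[2:, idx["St"]].min() > 0.5

    def test_missing_frames_marked_nan(self, clf, models):
        feats = pd.Series(models["NT"].feature_mean, index=list(hc.FEATURE_NAMES))
        tr = kin.CellTrack(0, "NT", times=[0.0, 1.0, 2.0],
                           centroids_um=[(0, 0)] * 3, objects=[None] * 3,
                           features=[feats] * 3)
        p = kin.track_probabilities(clf, tr, missing=[1])
        assert np.isnan(p[1]).all() and not np.isnan(p[0]).any()


class TestSmoothing:
    def test_quadratic_series_reproduced_exactly(self):
        t = np.arange(11.0)
        q = 0.3 + 0.004 * (t - 5) ** 2  # stays inside [0, 1]
        series = np.column_stack([q, 1 - q])
        out = kin.smooth_probabilities(series)
        assert np.allclose(out, series, atol=1e-12)

    def test_constant_series_unchanged(self):
        series = np.tile([0.2, 0.3, 0.5], (8, 1))
        assert np.allclose(kin.smooth_probabilities(series), series, atol=1e-12)

    def test_noise_reduced_towards_quadratic(self, rng):
        t = np.arange(30.0)
        q = 0.4 + 0.001 * (t - 15) ** 2
        noisy = q + rng.normal(0, 0.05, size=30)
        series = np.clip(np.column_stack([noisy, 1 - noisy]), 0, 1)
        out = kin.smooth_probabilities(series)
        mse_in = np.mean((series[:, 0] - q) ** 2)
        mse_out = np.mean((out[:, 0] - q) ** 2)
        assert mse_out < mse_in

    def test_short_series_passes_through(self):
        series = np.array([[0.9, 0.1], [0.8, 0.2], [0.7, 0.3]])
        assert np.allclose(kin.smooth_probabilities(series, window=5), series)

    def test_missing_points_interpolated(self):
        series = np.array([[0.0, 1.0], [np.nan, np.nan], [1.0, 0.0]])
        out = kin.smooth_probabilities(series, window=5)
        assert np.allclose(out[1], [0.5, 0.5])

    def test_output_rows_renormalized(self, rng):
        series = np.clip(rng.random((12, 3)), 0, 1)
        series /= series.sum(axis=1, keepdims=True)
        out = kin.smooth_probabilities(series)
        assert np.allclose(out.sum(axis=1), 1.0, atol=1e-12)
        assert (out >= 0).all() and (out <= 1).all()


class TestSuperMetrics:
    def test_mortality_fraction(self):
        p = np.tile([0.2, 0.7, 0.1], (5, 1))
        tracks = [
            _track_with_proba(i, range(5), p,
                              death_time=4.0 if i < 3 else None)
            for i in range(10)
        ]
        # dead tracks end early at their death hour
        for tr in tracks[:3]:
            tr.times = [0.0, 1.0, 2.0, 3.0]
            tr.proba_raw = tr.proba_smooth = p[:4]
            tr.centroids_um = tr.centroids_um[:4]
        s = kin.condition_super_metrics(tracks, end_time=4.0)
        assert s.mortality == pytest.approx(0.3)

    def test_dead_from_start_pins_preapoptotic_indicator(self):
        p = np.array([[0.5, 0.5, 0.0]])
        tracks = [_track_with_proba(i, [0.0], p, death_time=0.0) for i in range(4)]
        s = kin.condition_super_metrics(tracks, end_time=0.0)
        assert s.pre_apoptotic_indicator == pytest.approx(1.0)

    def test_identical_tracks_zero_variability(self):
        p = np.tile([0.1, 0.6, 0.3], (6, 1))
        tracks = [_track_with_proba(i, range(6), p) for i in range(5)]
        s = kin.condition_super_metrics(tracks)
        assert s.variability_of_response == 0.0

    def test_division_rate_counts_events_per_cell(self):
        p = np.tile([0.1, 0.8, 0.1], (4, 1))
        tracks = [_track_with_proba(i, range(4), p,
                                    division_time=3.0 if i == 0 else None)
                  for i in range(4)]
        s = kin.condition_super_metrics(tracks)
        assert s.division_rate == pytest.approx(0.25)


class TestNormalization:
    @staticmethod
    def _summary(cond, **kw):
        base = dict(pre_apoptotic_indicator=0.2, growth_arrested_indicator=0.3,
                    division_rate=0.5, mortality=0.1, motility=0.2,
                    variability_of_response=0.05, n_cells=10)
        base.update(kw)
        return kin.ConditionSummary(condition=cond, **base)

    def test_column_means_one(self):
        out = kin.normalize_super_metrics([
            self._summary("a"), self._summary("b", mortality=0.5, division_rate=0.1),
        ])
        assert np.allclose(out.mean(axis=0), 1.0, atol=1e-12)

    def test_single_condition_all_ones(self):
        out = kin.normalize_super_metrics([self._summary("a")])
        assert np.allclose(out.to_numpy(), 1.0)

    def test_two_conditions_arithmetic(self):
        out = kin.normalize_super_metrics([
            self._summary("a", mortality=1.0), self._summary("b", mortality=3.0),
        ])
        assert list(out["mortality"]) == pytest.approx([0.5, 1.5])

    def test_idempotent(self):
        df = kin.normalize_super_metrics([
            self._summary("a"), self._summary("b", mortality=0.9),
        ])
        again = kin.normalize_super_metrics(df)
        pd.testing.assert_frame_equal(df, again)


class TestClustering:
    def test_identical_conditions_merge_first_at_zero(self):
        df = pd.DataFrame(
            [[1.0, 1, 1, 1], [2.0, 2, 2, 2], [1.0, 1, 1, 1]],
            columns=list(kin.CLUSTER_METRICS), index=["a", "b", "c"],
        )
        Z = kin.cluster_conditions(df)
        assert {int(Z[0, 0]), int(Z[0, 1])} == {0, 2}
        assert Z[0, 2] == 0.0

    def test_upgma_heights_on_a_line(self):
        df = pd.DataFrame(
            {m: [0.0, 1.0, 3.0] if m == "mortality" else [1.0, 1.0, 1.0]
             for m in kin.CLUSTER_METRICS},
            index=["a", "b", "c"],
        )
        Z = kin.cluster_conditions(df)
        assert Z[0, 2] == pytest.approx(1.0)  # a-b merge
        assert Z[1, 2] == pytest.approx(2.5)  # average of d(a,c)=3 and d(b,c)=2

    def test_newick_round_trips_through_skbio(self):
        import io

        from skbio import TreeNode

        df = pd.DataFrame(np.eye(4), columns=list(kin.CLUSTER_METRICS),
                          index=["w", "x", "y", "z"])
        Z = kin.cluster_conditions(df)
        nwk = kin.linkage_to_newick(Z, list(df.index))
        tree = TreeNode.read(io.StringIO(nwk))
        assert {t.name for t in tree.tips()} == {"w", "x", "y", "z"}


class TestRocketExport:
    def test_row_count_and_events(self):
        p = np.tile([0.1, 0.8, 0.1], (5, 1))
        t1 = _track_with_proba(0, range(5), p, division_time=4.0)
        t2 = _track_with_proba(1, range(5), p, death_time=4.0)
        out = kin.rocket_export([t1, t2])
        assert len(out) == 10
        assert out.loc[(out.track_id == 0) & (out.t == 4.0), "event"].item() == "division"
        assert out.loc[(out.track_id == 1) & (out.t == 4.0), "event"].item() == "death"
        assert np.allclose(out[["P(CDKi)", "P(NT)", "P(St)"]].iloc[0], [0.1, 0.8, 0.1])
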