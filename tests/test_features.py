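import math

import numpy as np
import pandas as pd
import pytest
from skimage.feature import graycomatrix, graycoprops

import holocyte as hc
from holocyte.features import (
    FEATURE_NAMES,
    masked_glcm,
    glcm_statistics,
    min_abs_correlation,
    morphology_features,
    optical_features,
    quantize_object,
    roughness_features,
    select_independent_features,
    texture_features,
)
from holocyte.segmentation import object_from_mask

from _oracles import glcm_stats_bruteforce
from conftest import make_image, random_blob_object


class TestMorphology:
    def test_square_closed_forms(self, square_patch):
        img, obj = square_patch
        f = morphology_features(obj, 1.0)
        assert f["Area (μm2)"] == pytest.approx(100.0)
        assert f["Perimeter length (μm)"] == pytest.approx(40.0)
        assert f["Boxed length (μm)"] == pytest.approx(10.0)
        assert f["Boxed breadth (μm)"] == pytest.approx(10.0)
        assert f["Shape convexity"] == pytest.approx(1.0)
        assert f["Hull convexity"] == pytest.approx(1.0)
        assert f["Eccentricity"] == pytest.approx(0.0, abs=1e-12)
        assert f["Irregularity"] == pytest.approx(40 / (2 * math.sqrt(100 * math.pi)) - 1)
        assert f["Irregularity"] == pytest.approx(0.1284, abs=2e-4)

    def test_rasterized_ellipse_eccentricity(self):
        yy, xx = np.mgrid[:90, :90]
        ell = ((xx - 45) / 40) ** 2 + ((yy - 45) / 20) ** 2 <= 1.0
        f = morphology_features(object_from_mask(ell), 1.0)
        assert f["Eccentricity"] == pytest.approx(math.sqrt(1 - 0.25), abs=0.02)
        assert f["Boxed length (μm)"] >= f["Boxed breadth (μm)"]

    def test_single_pixel_degeneracy(self):
        mask = np.zeros((5, 5), bool)
        mask[2, 2] = True
        f = morphology_features(object_from_mask(mask), 1.0)
        assert f["Eccentricity"] == 0.0
        assert f["Area (μm2)"] == 1.0
        assert f["Perimeter length (μm)"] == 4.0

    def test_rotation_90_invariance_within_rasterization(self):
        yy, xx = np.mgrid[:60, :60]
        ell = ((xx - 30) / 22) ** 2 + ((yy - 30) / 11) ** 2 <= 1.0
        f0 = morphology_features(object_from_mask(ell), 1.0)
        f90 = morphology_features(object_from_mask(ell.T), 1.0)
        for k, v in f0.items():
            assert f90[k] == pytest.approx(v, rel=0.02, abs=1e-9), k


class TestOptical:
    def test_thickness_closed_form_at_2pi(self, calib):
        mask = np.zeros((6, 6), bool)
        mask[2:4, 2:4] = True
        img = make_image(np.where(mask, 2 * math.pi, 0.0))
        f = optical_features(object_from_mask(mask), img, calib)
        # t = phi * lambda / (2 pi dn) = 0.635 / 0.04
        assert f["Thickness avg (μm)"] == pytest.approx(15.875)
        assert f["Thickness max (μm)"] == pytest.approx(15.875)

    def test_constant_patch_degeneracies(self, calib, square_patch):
        img, obj = square_patch
        f = optical_features(obj, img, calib)
        assert f["Phaseshift min"] == pytest.approx(2.0)
        assert f["Phaseshift std. dev."] == 0.0
        assert f["Thickness avg (μm)"] == f["Thickness max (μm)"]

    def test_volume_identity_on_random_objects(self, rng, calib):
        for _ in range(5):
            obj = random_blob_object(rng)
            img = make_image(rng.uniform(0.5, 3.0, size=(24, 24)))
            f = optical_features(obj, img, calib)
            assert f["Volume (μm3)"] == pytest.approx(
                f["Thickness avg (μm)"] * obj.n_pixels * 1.0, rel=1e-12
            )


class TestRoughness:
    def test_constant_patch_is_flat(self, calib, square_patch):
        img, obj = square_patch
        # use a constant image so no edge enters the 5x5 windows
        f = roughness_features(obj, make_image(np.full((30, 30), 2.0)))
        assert f == {"Roughness avg": 0.0, "Roughness skewness": 0.0, "Roughness kurtosis": 0.0}

    def test_linear_ramp_residual_zero(self):
        yy, xx = np.mgrid[:30, :30]
        img = make_image(0.3 * xx + 0.1 * yy)
        mask = np.zeros((30, 30), bool)
        mask[10:20, 10:20] = True  # interior: windows never cross the frame edge
        f = roughness_features(object_from_mask(mask), img)
        assert f["Roughness avg"] == pytest.approx(0.0, abs=1e-10)

    def test_checkerboard_residual_close_to_amplitude(self):
        yy, xx = np.mgrid[:30, :30]
        a = 0.7
        img = make_image(a * (-1.0) ** (xx + yy))
        mask = np.zeros((30, 30), bool)
        mask[10:20, 10:20] = True
        f = roughness_features(object_from_mask(mask), img)
        # 5x5 mean on a checkerboard is +-a/25, so |residual| = 24a/25
        assert f["Roughness avg"] == pytest.approx(24 * a / 25, rel=1e-9)
        assert f["Roughness avg"] == pytest.approx(a, rel=0.05)


class TestTexture:
    def test_constant_object_degenerate_glcm(self, square_patch):
        img, obj = square_patch
        f = texture_features(obj, img)
        assert f["Texture energy"] == 1.0
        assert f["Texture entropy"] == 0.0
        assert f["Texture contrast"] == 0.0
        assert f["Texture maxprob"] == 1.0
        assert f["Texture homogeneity"] == 1.0
        assert f["Texture correlation"] == 0.0

    def test_checkerboard_axis_contrast(self):
        yy, xx = np.mgrid[:12, :12]
        img = make_image(((xx + yy) % 2).astype(float))
        mask = np.ones((12, 12), bool)
        obj = object_from_mask(mask)
        levels = 32
        for offset in ((0, 1), (1, 0)):
            # along the axes every pair differs by the full level range
            P = masked_glcm(obj, img, levels=levels, offsets=(offset,))
            s = glcm_statistics(P)
            assert s["Texture contrast"] == pytest.approx((levels - 1) ** 2)
        # diagonal neighbours of a checkerboard are equal
        P = masked_glcm(obj, img, levels=levels, offsets=((1, 1),))
        assert glcm_statistics(P)["Texture contrast"] == 0.0

    def test_all_statistics_match_pair_enumeration_oracle(self, rng):
        for _ in range(10):
            obj = random_blob_object(rng)
            img = make_image(rng.normal(size=(24, 24)))
            mine = texture_features(obj, img)
            oracle = glcm_stats_bruteforce(obj, img)
            for k, v in oracle.items():
                assert mine[k] == pytest.approx(v, rel=1e-9, abs=1e-12), k

    def test_matches_skimage_on_rectangular_object(self, rng):
        """On full rectangles the masked GLCM must agree with skimage's."""
        vals = rng.normal(size=(16, 16))
        img = make_image(vals)
        obj = object_from_mask(np.ones((16, 16), bool))
        q = quantize_object(vals.ravel(), 8).reshape(16, 16).astype(np.uint8)
        sk = graycomatrix(q, [1], [0, np.pi / 4, np.pi / 2, 3 * np.pi / 4],
                          levels=8, symmetric=True, normed=True)
        sk_mean = sk[:, :, 0, :].mean(axis=2)
        mine = masked_glcm(obj, img, levels=8)
        assert np.allclose(mine, sk_mean, atol=1e-12)
        s = glcm_statistics(mine)
        # contrast/homogeneity are linear in P, so they commute with the
        # offset average and can be compared on the averaged matrix
        assert s["Texture contrast"] == pytest.approx(
            graycoprops(sk, "contrast").mean(), rel=1e-9
        )
        assert s["Texture homogeneity"] == pytest.approx(
            graycoprops(sk, "homogeneity").mean(), rel=1e-9
        )
        # correlation is not linear in P: compare per offset instead
        single = masked_glcm(obj, img, levels=8, offsets=((0, 1),))
        assert glcm_statistics(single)["Texture correlation"] == pytest.approx(
            float(graycoprops(sk, "correlation")[0, 0]), rel=1e-9
        )


class TestExtractTable:
    def test_empty_object_list(self, calib):
        table = hc.extract_table([], [], calib)
        assert len(table) == 0
        assert set(FEATURE_NAMES) <= set(table.columns)

    def test_five_truth_cells_five_rows_and_determinism(self, calib):
        from holocyte.synthetic import CellSpec, DriftModel, render_frame
        from holocyte.segmentation import segment_frame

        cells = [
            CellSpec("NT", (12.0 + 14 * i, 15.0 + 20 * (i % 3)), (6.0, 5.0), 0.2 * i)
            for i in range(5)
        ]
        img, truth = render_frame(cells, DriftModel(0.0, 0.0), 0.0,
                                  image_shape_px=(160, 160), pixel_size_um=0.5, rng=0)
        calib05 = hc.CalibrationParams(pixel_size_um=0.5)
        objs = segment_frame(img, 0.05)
        t1 = hc.extract_table([img], [objs], calib05)
        t2 = hc.extract_table([img], [objs], calib05)
        assert len(t1) == 5
        assert t1[list(FEATURE_NAMES)].notna().all().all()
        pd.testing.assert_frame_equal(t1, t2)

    def test_translation_leaves_features_unchanged(self, calib, rng):
        from holocyte.segmentation import segment_frame

        img = np.zeros((40, 40))
        img[8:16, 8:16] = 2.0 + rng.normal(0, 0.2, size=(8, 8))
        a = make_image(img)
        b = make_image(np.roll(np.roll(img, 11, 0), 7, 1))
        fa = hc.extract_features(segment_frame(a, 0.5)[0], a, calib)
        fb = hc.extract_features(segment_frame(b, 0.5)[0], b, calib)
        for k in FEATURE_NAMES:
            assert fb[k] == pytest.approx(fa[k], rel=1e-9, abs=1e-12), k


class TestFeatureSelection:
    @staticmethod
    def _tables(rng, n_tables=3, n_rows=200):
        """42-feature tables: 26 independent + 16 redundant copies."""
        base_names = [f"f{i:02d}" for i in range(26)]
        dup_names = [f"z_dup{i:02d}" for i in range(16)]  # later in canonical order
        tables = []
        for _ in range(n_tables):
            X = rng.normal(size=(n_rows, 26))
            dup = X[:, :16] * rng.uniform(0.5, 2.0) + rng.normal(0, 1e-4, size=(n_rows, 16))
            df = pd.DataFrame(np.hstack([X, dup]), columns=base_names + dup_names)
            tables.append(df)
        return tables, base_names, dup_names

    def test_42_to_26_reduction(self, rng):
        tables, base, dup = self._tables(rng)
        corrs = [min_abs_correlation([t]) for t in tables]
        kept = select_independent_features(corrs, cutoff=0.98)
        assert len(kept) == 26
        assert kept == base

    def test_pair_redundant_in_all_but_one_experiment_is_retained(self, rng):
        tables, base, dup = self._tables(rng, n_tables=3)
        # decorrelate one duplicate in one experiment only
        tables[1]["z_dup00"] = rng.normal(size=len(tables[1]))
        corrs = [min_abs_correlation([t]) for t in tables]
        kept = select_independent_features(corrs, cutoff=0.98)
        assert "z_dup00" in kept
        assert len(kept) == 27

    def test_exclusion_list(self, rng):
        tables, base, dup = self._tables(rng, n_tables=1)
        kept = select_independent_features(
            [min_abs_correlation([tables[0]])], exclude=("f00", "f01")
        )
        assert "f00" not in kept and "f01" not in kept


class TestMinAbsCorrelation:
    def test_single_table_matches_direct_formula(self, rng):
        df = pd.DataFrame(rng.normal(size=(50, 4)), columns=list("abcd"))
        M = min_abs_correlation([df])
        for i, fi in enumerate("abcd"):
            for j, fj in enumerate("abcd"):
                x, y = df[fi].to_numpy(), df[fj].to_numpy()
                r = np.mean((x - x.mean()) * (y - y.mean())) / (x.std() * y.std())
                assert M.iloc[i, j] == pytest.approx(abs(r), abs=1e-12)
        assert np.allclose(M, M.T)
        assert np.allclose(np.diag(M), 1.0)

    def test_constant_multiple_gives_unit_entry(self, rng):
        df = pd.DataFrame({"a": rng.normal(size=30)})
        df["b"] = 3.0 * df["a"]
        assert min_abs_correlation([df]).loc["a", "b"] == pytest.approx(1.0)

    def test_min_rule_across_tables(self, rng):
        x = rng.normal(size=100)
        t1 = pd.DataFrame({"a": x, "b": x + rng.normal(0, 0.05, 100)})  # |r| ~ 0.99
        t2 = pd.DataFrame({"a": x, "b": rng.normal(size=100)})  # |r| ~ 0
        M = min_abs_correlation([t1, t2])
        r1 = abs(t1.corr().loc["a", "b"])
        r2 = abs(t2.corr().loc["a", "b"])
        assert M.loc["a", "b"] == pytest.approx(min(r1, r2))
        assert r1 > 0.9 and r2 < 0.5
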