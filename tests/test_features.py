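"""Feature catalog: first-order statistics, 3D GLCM textures, tables."""

import numpy as np
import pandas as pd
import pytest

from dceus.features import (
    DISTANCES,
    FIRST_ORDER_NAMES,
    GLCM_PROPS,
    OFFSETS_13,
    extract_features,
    feature_catalog,
    first_order_features,
    glcm_3d,
    glcm_properties,
    percent_change,
    quantize_map,
    texture_features,
)


def brute_force_glcm(q, offset, L):
    """Triple-loop co-occurrence oracle (symmetric, normalized)."""
    dz, dy, dx = offset
    M = np.zeros((L, L))
    Z, Y, X = q.shape
    for z in range(Z):
        for y in range(Y):
            for x in range(X):
                z2, y2, x2 = z + dz, y + dy, x + dx
                if 0 <= z2 < Z and 0 <= y2 < Y and 0 <= x2 < X:
                    a, b = q[z, y, x], q[z2, y2, x2]
                    if a >= 0 and b >= 0:
                        M[a, b] += 1
                        M[b, a] += 1
    s = M.sum()
    return M / s if s else None


class TestCatalog:
    def test_catalog_has_1128_unique_ordered_names(self):
        cat = feature_catalog()
        assert len(cat) == 1128
        assert len(set(cat)) == 1128
        assert cat == feature_catalog()  # order is fixed

    def test_per_map_breakdown(self):
        cat = feature_catalog()
        per_map = [n for n in cat if n.startswith("PE_")]
        assert len(per_map) == 140
        assert len([n for n in cat if n.startswith("roi_")]) == 8
        assert len(OFFSETS_13) == 13 and len(DISTANCES) == 7


class TestQuantize:
    def test_identity_binning(self):
        vals = np.arange(32, dtype=float).reshape(2, 4, 4)
        q = quantize_map(vals, np.ones_like(vals, bool), 32)
        np.testing.assert_array_equal(q.ravel(), np.arange(32))

    def test_constant_map_single_level(self):
        vals = np.full((3, 3, 3), 5.0)
        q = quantize_map(vals, np.ones_like(vals, bool), 32)
        assert set(np.unique(q)) == {0}

    def test_positive_affine_invariance(self, rng):
        vals = rng.normal(size=(4, 4, 4))
        mask = np.ones_like(vals, bool)
        q1 = quantize_map(vals, mask)
        q2 = quantize_map(2.5 * vals + 17.0, mask)
        np.testing.assert_array_equal(q1, q2)

    def test_nan_stays_excluded(self, rng):
        vals = rng.normal(size=(4, 4, 4))
        vals[0, 0, 0] = np.nan
        q = quantize_map(vals, np.ones_like(vals, bool))
        assert q[0, 0, 0] == -1


class TestFirstOrder:
    def test_constant_map(self):
        vals = np.full((3, 3, 3), 7.0)
        fo = first_order_features(vals, np.ones_like(vals, bool))
        assert fo["mean"] == 7.0 and fo["std"] == 0.0 and fo["range"] == 0.0
        assert fo["uniformity"] == 1.0 and fo["entropy"] == 0.0

    def test_percentiles_linear_interpolation(self):
        vals = np.arange(1.0, 101.0).reshape(4, 5, 5)
        fo = first_order_features(vals, np.ones_like(vals, bool))
        assert fo["median"] == pytest.approx(50.5)
        assert fo["iqr"] == pytest.approx(49.5)

    def test_nan_padding_does_not_change_features(self, rng):
        vals = rng.normal(size=(4, 4, 4)) + 10.0
        mask = np.ones_like(vals, bool)
        fo1 = first_order_features(vals, mask)
        padded = np.full((6, 6, 6), np.nan)
        padded[1:5, 1:5, 1:5] = vals
        fo2 = first_order_features(padded, np.ones((6, 6, 6), bool))
        for k in FIRST_ORDER_NAMES:
            assert fo1[k] == pytest.approx(fo2[k], rel=1e-12)

    def test_too_few_voxels_flagged_missing(self):
        vals = np.full((2, 2, 2), np.nan)
        vals[0, 0, 0] = 1.0
        fo = first_order_features(vals, np.ones_like(vals, bool))
        assert all(np.isnan(v) for v in fo.values())


class TestGLCM:
    def test_two_voxel_hand_example(self):
        q = np.array([0, 1]).reshape(2, 1, 1)
        P = glcm_3d(q, None, (1, 0, 0), n_levels=2)
        assert P[0, 1] == 0.5 and P[1, 0] == 0.5
        props = glcm_properties(P)
        assert props["contrast"] == pytest.approx(1.0)
        assert props["energy"] == pytest.approx(0.5)

    def test_constant_volume_degenerate(self):
        q = np.zeros((3, 3, 3), dtype=int)
        P = glcm_3d(q, None, (0, 0, 1), n_levels=2)
        props = glcm_properties(P)
        assert props["contrast"] == 0.0
        assert props["energy"] == 1.0
        assert np.isnan(props["correlation"])

    def test_checkerboard_contrast_exactly_one(self):
        z, y, x = np.indices((8, 8, 8))
        q = ((z + y + x) % 2).astype(int)
        P = glcm_3d(q, None, (0, 0, 1), n_levels=2)
        assert glcm_properties(P)["contrast"] == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        q = rng.integers(0, 4, size=(5, 5, 5))
        q[rng.random((5, 5, 5)) < 0.2] = -1  # excluded voxels
        for off in [(0, 0, 1), (1, -1, 1), (1, 0, 0), (0, 1, -1)]:
            expected = brute_force_glcm(q, off, 4)
            got = glcm_3d(q, None, off, n_levels=4)
            np.testing.assert_array_equal(got, expected)

    def test_zero_offset_rejected(self):
        with pytest.raises(ValueError):
            glcm_3d(np.zeros((3, 3, 3), int), None, (0, 0, 0))


class TestTexture:
    def test_constant_map_textures(self):
        vals = np.full((9, 9, 9), 3.0)
        tex = texture_features(vals, np.ones_like(vals, bool))
        for off_name, v in tex.items():
            if off_name.endswith(("contrast", "dissimilarity")):
                assert v == 0.0
            if off_name.endswith("_energy"):
                assert v == 1.0

    def test_mirror_flip_preserves_direction_averaged(self, rng):
        vals = rng.normal(size=(9, 9, 9))
        mask = np.ones_like(vals, bool)
        t1 = texture_features(vals, mask)
        t2 = texture_features(vals[:, :, ::-1].copy(), mask)
        for k in t1:
            if "_avg_" in k:
                assert t1[k] == pytest.approx(t2[k], abs=1e-9)

    def test_axial_rotation_permutes_directions_fixes_averages(self, rng):
        vals = rng.normal(size=(9, 9, 9))
        mask = np.ones_like(vals, bool)
        t1 = texture_features(vals, mask)
        rot = np.rot90(vals, k=1, axes=(1, 2)).copy()  # 90 deg about z
        t2 = texture_features(rot, mask)
        avg1 = sorted(v for k, v in t1.items() if "_avg_" in k)
        avg2 = sorted(v for k, v in t2.items() if "_avg_" in k)
        np.testing.assert_allclose(avg1, avg2, atol=1e-9)
        # direction-specific multiset is permuted, not changed
        for prop in GLCM_PROPS:
            d1 = sorted(v for k, v in t1.items()
                        if k.startswith("glcm_d1") and k.endswith(prop))
            d2 = sorted(v for k, v in t2.items()
                        if k.startswith("glcm_d1") and k.endswith(prop))
            np.testing.assert_allclose(d1, d2, atol=1e-9)


@pytest.fixture(scope="module")
def mapset(noiseless_dataset):
    from dceus.bolus import roi_conventional_features
    from dceus.maps import compute_mapset

    vol, truth, spec = noiseless_dataset
    ms = compute_mapset(vol, truth.mask, spec.frame_times_s)
    roi = roi_conventional_features(vol, truth.mask, spec.frame_times_s)
    return ms, roi


class TestExtract:
    def test_vector_has_catalog_order_and_length(self, mapset):
        ms, roi = mapset
        v = extract_features(ms, roi)
        assert len(v) == 1128
        assert list(v.index) == feature_catalog()

    def test_extraction_is_deterministic(self, mapset):
        ms, roi = mapset
        pd.testing.assert_series_equal(extract_features(ms, roi),
                                       extract_features(ms, roi))

    def test_all_nan_map_yields_exactly_140_missing(self, mapset):
        import copy

        ms, roi = mapset
        ms2 = copy.deepcopy(ms)
        ms2.maps["MaxIP"] = np.full_like(ms2.maps["MaxIP"], np.nan)
        v = extract_features(ms2, roi)
        missing = v[v.isna()]
        assert len(missing) == 140
        assert all(n.startswith("MaxIP_") for n in missing.index)


class TestPercentChange:
    @pytest.fixture()
    def table(self):
        return pd.DataFrame({
            "subject": ["s1", "s1", "s2", "s2", "s3"],
            "day": [0, 1, 0, 1, 1],
            "replicate": 1,
            "cohort": "A",
            "arm": "treated",
            "f1": [50.0, 40.0, 10.0, 15.0, 3.0],
            "f2": [0.0, 5.0, 2.0, 2.0, 1.0],
        })

    def test_arithmetic_and_baseline_removal(self, table):
        pc = percent_change(table)
        assert set(pc["day"]) == {1}
        s1 = pc[pc["subject"] == "s1"].iloc[0]
        assert s1["f1"] == pytest.approx(-20.0)

    def test_zero_baseline_gives_missing(self, table):
        pc = percent_change(table)
        assert np.isnan(pc[pc["subject"] == "s1"].iloc[0]["f2"])

    def test_subject_without_baseline_dropped(self, table):
        pc = percent_change(table)
        assert "s3" not in set(pc["subject"])

    def test_day_equal_baseline_is_zero_percent(self):
        t = pd.DataFrame({"subject": ["a", "a"], "day": [0, 3],
                          "replicate": 1, "cohort": "A", "arm": "control",
                          "f": [8.0, 8.0]})
        pc = percent_change(t)
        assert pc.iloc[0]["f"] == 0.0
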