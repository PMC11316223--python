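"""Shape descriptors, the 40-feature catalog, two-point normalization."""

import numpy as np
import pandas as pd
import pytest

from fibromorph import (
    FEATURE_NAMES,
    LabelMap,
    ValidationError,
    assemble_feature_matrix,
    measure_objects,
    normalize_to_anchors,
)
from fibromorph.morphometry import boundary_chain_length


def square_map(side=10, pad=4, px=1.0, level="cell"):
    lbl = np.zeros((side + 2 * pad, side + 2 * pad), dtype=np.int32)
    lbl[pad : pad + side, pad : pad + side] = 1
    return LabelMap(lbl, level, px)


def ellipse_mask(a, b, theta_deg=0.0, pad=6):
    n = int(2 * max(a, b)) + 2 * pad
    rr, cc = np.mgrid[0:n, 0:n]
    x = cc - n / 2
    y = -(rr - n / 2)
    th = np.deg2rad(theta_deg)
    u = x * np.cos(th) + y * np.sin(th)
    v = -x * np.sin(th) + y * np.cos(th)
    return ((u / a) ** 2 + (v / b) ** 2 <= 1).astype(np.int32)


class TestMeasureObjects:
    def test_square_area_extent_solidity(self):
        row = measure_objects(square_map()).iloc[0]
        assert row["area_um2"] == 100.0
        assert row["extent"] == 1.0
        assert row["solidity"] == 1.0

    def test_square_perimeter_matches_boundary_walk_oracle(self):
        # oracle: explicit walk around a 10x10 square visits 36 boundary
        # pixels with unit axial steps
        side = 10
        expected = 4 * (side - 1)
        row = measure_objects(square_map(side)).iloc[0]
        assert row["perimeter_um"] == pytest.approx(expected)
        mask = np.zeros((14, 14), dtype=bool)
        mask[2:12, 2:12] = True
        assert boundary_chain_length(mask) == pytest.approx(expected)

    def test_disk_eccentricity_near_zero(self):
        lbl = LabelMap(ellipse_mask(30, 30), "cell", 1.0)
        assert measure_objects(lbl).iloc[0]["eccentricity"] < 0.05

    def test_ellipse_eccentricity_matches_closed_form(self):
        # semi-axes 40 and 20 px: e = sqrt(1 - (20/40)^2) = sqrt(3)/2
        lbl = LabelMap(ellipse_mask(40, 20), "cell", 1.0)
        row = measure_objects(lbl).iloc[0]
        assert row["eccentricity"] == pytest.approx(np.sqrt(3) / 2, abs=0.01)
        # pixel-moment oracle on the same mask
        coords = np.argwhere(lbl.labels == 1).astype(float)
        x = coords[:, 1] - coords[:, 1].mean()
        y = coords[:, 0] - coords[:, 0].mean()
        cov = np.cov(np.stack([x, y]), bias=True)
        lams = np.linalg.eigvalsh(cov)
        assert row["eccentricity"] == pytest.approx(np.sqrt(1 - lams[0] / lams[1]), abs=1e-9)

    def test_orientation_recovered_for_rotated_ellipse(self):
        lbl = LabelMap(ellipse_mask(40, 15, theta_deg=25.0), "cell", 1.0)
        row = measure_objects(lbl).iloc[0]
        assert row["orientation_deg"] == pytest.approx(25.0, abs=1.0)

    def test_rotation_changes_eccentricity_little(self):
        e0 = measure_objects(LabelMap(ellipse_mask(40, 20, 0), "cell", 1.0)).iloc[0][
            "eccentricity"
        ]
        e30 = measure_objects(LabelMap(ellipse_mask(40, 20, 30), "cell", 1.0)).iloc[0][
            "eccentricity"
        ]
        assert abs(e30 - e0) < 0.02

    def test_scale_equivariance(self):
        lbl1 = LabelMap(ellipse_mask(30, 12), "cell", 1.0)
        lbl2 = LabelMap(ellipse_mask(30, 12), "cell", 2.0)
        r1 = measure_objects(lbl1).iloc[0]
        r2 = measure_objects(lbl2).iloc[0]
        assert r2["area_um2"] == pytest.approx(4 * r1["area_um2"], rel=1e-12)
        for k in ("perimeter_um", "major_axis_um", "minor_axis_um", "feret_max_um"):
            assert r2[k] == pytest.approx(2 * r1[k], rel=1e-12)
        for k in ("eccentricity", "solidity", "extent", "form_factor"):
            assert r2[k] == pytest.approx(r1[k], rel=1e-12)

    def test_feret_diameters_of_square(self):
        row = measure_objects(square_map()).iloc[0]
        assert row["feret_max_um"] == pytest.approx(10 * np.sqrt(2), rel=1e-9)
        assert row["feret_min_um"] == pytest.approx(10.0, rel=1e-9)

    def test_form_factor_of_disk_near_one_and_bounded(self):
        row = measure_objects(LabelMap(ellipse_mask(40, 40), "cell", 1.0)).iloc[0]
        assert 0.85 < row["form_factor"] <= 1.0 + 1e-9

    def test_empty_map_gives_empty_table(self):
        lbl = LabelMap(np.zeros((8, 8), dtype=np.int32), "cell", 1.0)
        assert measure_objects(lbl).empty

    def test_parameter_recovery_on_default_scene(self, default_scene, processed_scene):
        from conftest import match_objects

        spec, _, gt = default_scene
        labels, tables = processed_scene
        for level in ("cell", "nucleus", "fa"):
            tsub = gt.level_table(level)
            tsub = tsub[~tsub["clipped"]]
            msub = tables[tables["level"] == level].set_index("label")
            for _, row in tsub.iterrows():
                r = match_objects(gt.label_maps[level], labels[level].labels, row["label"])
                m = msub.loc[r]
                assert m["area_um2"] == pytest.approx(row["area_um2"], rel=0.02)
                assert m["major_axis_um"] == pytest.approx(
                    2 * row["semi_major_um"], rel=0.03
                )
                assert m["eccentricity"] == pytest.approx(row["eccentricity"], abs=0.02)
                cent_err = np.hypot(
                    m["centroid_row"] - row["centroid_row"],
                    m["centroid_col"] - row["centroid_col"],
                )
                assert cent_err < 0.5


def toy_tables(n_fa=3, identical_fas=True):
    cell = dict(level="cell", label=1, parent=0, centroid_row=10.0, centroid_col=10.0)
    nuc = dict(level="nucleus", label=1, parent=1, centroid_row=10.0, centroid_col=10.0)
    desc = dict(
        area_um2=100.0, perimeter_um=36.0, eccentricity=0.5, major_axis_um=12.0,
        minor_axis_um=9.0, aspect_ratio=12 / 9, orientation_deg=0.0, solidity=1.0,
        extent=1.0, form_factor=0.9, compactness=1.1, feret_max_um=14.0, feret_min_um=10.0,
    )
    rows = [dict(**cell, **desc), dict(**nuc, **desc)]
    for i in range(n_fa):
        fa_desc = dict(desc)
        fa_desc["area_um2"] = 2.0 if identical_fas else 2.0 + i
        rows.append(
            dict(level="fa", label=10 + i, parent=1, centroid_row=5.0, centroid_col=5.0, **fa_desc)
        )
    return pd.DataFrame(rows)


class TestFeatureMatrix:
    def test_identical_fas_have_zero_sd_and_count(self):
        m = assemble_feature_matrix(toy_tables(3))
        row = m.iloc[0]
        assert row["fa_count"] == 3.0
        assert row["fa_area_um2_sd"] == 0.0
        assert row["fa_area_um2_mean"] == 2.0

    def test_zero_fa_cell_flagged_with_zero_aggregates(self):
        m = assemble_feature_matrix(toy_tables(0))
        row = m.iloc[0]
        assert row["zero_fa"]
        assert row["fa_count"] == 0.0
        assert row["fa_area_um2_mean"] == 0.0

    def test_catalog_has_40_stable_columns(self):
        assert len(FEATURE_NAMES) == 40
        m1 = assemble_feature_matrix(toy_tables(2))
        m2 = assemble_feature_matrix(toy_tables(5))
        assert list(m1.columns) == list(m2.columns)
        assert [c for c in m1.columns if c in FEATURE_NAMES] == list(FEATURE_NAMES)

    def test_nucleus_without_cell_raises(self):
        t = toy_tables(1)
        t.loc[t["level"] == "nucleus", "parent"] = 99
        with pytest.raises(ValidationError):
            assemble_feature_matrix(t)


def synthetic_matrix(rng, condition, n, shift=0.0):
    data = rng.normal(size=(n, 40)) + shift
    df = pd.DataFrame(data, columns=FEATURE_NAMES)
    df.insert(0, "zero_fa", False)
    df.insert(0, "cell_id", range(n))
    df.insert(0, "day", 2)
    df.insert(0, "condition", condition)
    df.insert(0, "image_id", condition)
    return df


class TestNormalization:
    def test_anchors_map_to_zero_and_one(self):
        rng = np.random.default_rng(0)
        mat = pd.concat(
            [
                synthetic_matrix(rng, "control", 20, 0.0),
                synthetic_matrix(rng, "myo", 20, 2.0),
                synthetic_matrix(rng, "lines", 20, 1.0),
            ],
            ignore_index=True,
        )
        out = normalize_to_anchors(mat, "control", "myo")
        ctrl = out[(out["condition"] == "control") & out["defined"]]
        myo = out[(out["condition"] == "myo") & out["defined"]]
        np.testing.assert_allclose(ctrl["value"], 0.0, atol=1e-12)
        np.testing.assert_allclose(myo["value"], 1.0, atol=1e-12)

    def test_midpoint_condition_maps_to_half(self):
        rows = []
        for cond, val in (("control", 0.0), ("myo", 4.0), ("mid", 2.0)):
            df = synthetic_matrix(np.random.default_rng(1), cond, 5, 0.0)
            df[list(FEATURE_NAMES)] = val
            rows.append(df)
        mat = pd.concat(rows, ignore_index=True)
        # give anchors a gap on one feature only; rest undefined
        out = normalize_to_anchors(mat, "control", "myo")
        mid = out[(out["condition"] == "mid") & out["defined"]]
        np.testing.assert_allclose(mid["value"], 0.5, atol=1e-12)

    def test_zero_anchor_gap_flagged_not_dropped(self):
        rng = np.random.default_rng(2)
        mat = pd.concat(
            [synthetic_matrix(rng, "control", 10), synthetic_matrix(rng, "myo", 10)],
            ignore_index=True,
        )
        mat["cell_area_um2"] = 7.0  # identical in both anchors
        out = normalize_to_anchors(mat, "control", "myo")
        flagged = out[out["feature"] == "cell_area_um2"]
        assert not flagged["defined"].any()
        assert flagged["value"].isna().all()
        assert len(flagged) > 0

    def test_insufficient_anchor_cells_rejected(self):
        rng = np.random.default_rng(3)
        mat = pd.concat(
            [synthetic_matrix(rng, "control", 1), synthetic_matrix(rng, "myo", 10)],
            ignore_index=True,
        )
        with pytest.raises(ValidationError, match="anchor"):
            normalize_to_anchors(mat, "control", "myo")
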