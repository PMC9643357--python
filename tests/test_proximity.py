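import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from mifquant.proximity import (
    EmptyGroupError,
    build_proximity_table,
    categorize,
    categorize_array,
    contact_comparison_cd8_vs_noncd8,
    nearest_neutrophil,
    normalize_per_patient,
    touching_vs_near,
    ttest_groups,
)


def cells(points, start_id=1):
    return pd.DataFrame(
        {
            "cell_id": np.arange(start_id, start_id + len(points)),
            "centroid_x_um": [p[0] for p in points],
            "centroid_y_um": [p[1] for p in points],
        }
    )


class TestCategorize:
    @pytest.mark.parametrize(
        "d,expected",
        [
            (5.0, "touching"),
            (9.99, "touching"),
            (10.0, "near"),
            (15.0, "near"),
            (19.999, "near"),
            (20.0, "excluded"),
            (25.0, "excluded"),
            (0.0, "touching"),
            (None, "excluded"),
            (float("nan"), "excluded"),
        ],
    )
    def test_binning(self, d, expected):
        assert categorize(d) == expected

    def test_negative_distance_is_an_error(self):
        with pytest.raises(ValueError, match=">= 0"):
            categorize(-1.0)
        with pytest.raises(ValueError):
            categorize_array(np.array([1.0, -0.5]))

    def test_array_agrees_with_scalar(self):
        d = np.array([0.0, 5.0, 10.0, 19.9, 20.0, np.nan])
        got = categorize_array(d)
        expected = [categorize(x) for x in d]
        assert list(got) == expected


class TestNearestNeutrophil:
    def test_simple_geometry(self):
        cd8 = cells([(0.0, 0.0)])
        neut = cells([(5.0, 0.0), (30.0, 0.0)], start_id=10)
        out = nearest_neutrophil(cd8, neut)
        assert out.loc[0, "distance_um"] == pytest.approx(5.0)
        assert out.loc[0, "nearest_neutrophil_id"] == 10

    def test_no_neutrophils_gives_absent_distance(self):
        out = nearest_neutrophil(cells([(1.0, 1.0)]), cells([], start_id=10))
        assert math.isnan(out.loc[0, "distance_um"])
        assert pd.isna(out.loc[0, "nearest_neutrophil_id"])
        assert categorize(out.loc[0, "distance_um"]) == "excluded"

    def test_matches_brute_force_on_random_field(self):
        rng = np.random.default_rng(17)
        q = cells(rng.uniform(0, 300, (120, 2)).tolist())
        n = cells(rng.uniform(0, 300, (80, 2)).tolist(), start_id=1000)
        out = nearest_neutrophil(q, n)
        npts = n[["centroid_x_um", "centroid_y_um"]].to_numpy()
        for i in range(len(q)):
            p = q.loc[i, ["centroid_x_um", "centroid_y_um"]].to_numpy(float)
            d = np.hypot(npts[:, 0] - p[0], npts[:, 1] - p[1])
            assert out.loc[i, "distance_um"] == pytest.approx(d.min(), abs=1e-9)
            assert out.loc[i, "nearest_neutrophil_id"] \
                == n.loc[int(np.argmin(d)), "cell_id"]

    def test_distance_ties_break_to_smaller_id(self):
        cd8 = cells([(0.0, 0.0)])
        neut = cells([(3.0, 0.0), (-3.0, 0.0), (0.0, 3.0)], start_id=7)
        out = nearest_neutrophil(cd8, neut)
        assert out.loc[0, "distance_um"] == pytest.approx(3.0)
        assert out.loc[0, "nearest_neutrophil_id"] == 7

    @settings(max_examples=25, deadline=None)
    @given(
        dx=st.floats(-50, 50), dy=st.floats(-50, 50),
        theta=st.floats(0, 2 * math.pi), scale=st.floats(0.1, 10),
    )
    def test_rigid_motion_invariance_and_scaling(self, dx, dy, theta, scale):
        rng = np.random.default_rng(5)
        qp = rng.uniform(0, 100, (15, 2))
        np_ = rng.uniform(0, 100, (10, 2))
        base = nearest_neutrophil(cells(qp.tolist()),
                                  cells(np_.tolist(), start_id=100))
        rot = np.array([[math.cos(theta), -math.sin(theta)],
                        [math.sin(theta), math.cos(theta)]])
        qp2 = scale * (qp @ rot.T) + [dx, dy]
        np2 = scale * (np_ @ rot.T) + [dx, dy]
        moved = nearest_neutrophil(cells(qp2.tolist()),
                                   cells(np2.tolist(), start_id=100))
        np.testing.assert_allclose(
            moved["distance_um"], scale * base["distance_um"], rtol=1e-9
        )


def make_proximity_df(rows):
    return pd.DataFrame(
        rows,
        columns=["cell_id", "patient_id", "field_id", "is_cd8",
                 "nearest_neutrophil_id", "distance_um", "category", "gzmk_mean"],
    )


class TestNormalization:
    def test_worked_example(self):
        # near cells {2, 4}, touching cell 6 -> near mean 3 -> {0.667, 1.333, 2}
        df = make_proximity_df(
            [
                (1, "P1", "F0", True, 9, 12.0, "near", 2.0),
                (2, "P1", "F0", True, 9, 14.0, "near", 4.0),
                (3, "P1", "F0", True, 9, 5.0, "touching", 6.0),
            ]
        )
        out = normalize_per_patient(df).set_index("cell_id")
        assert out.loc[1, "gzmk_norm"] == pytest.approx(2 / 3)
        assert out.loc[2, "gzmk_norm"] == pytest.approx(4 / 3)
        assert out.loc[3, "gzmk_norm"] == pytest.approx(2.0)

    def test_all_equal_values_normalize_to_one(self):
        df = make_proximity_df(
            [(i, "P1", "F0", True, 9, 11.0 if i % 2 else 5.0,
              "near" if i % 2 else "touching", 7.5) for i in range(1, 9)]
        )
        out = normalize_per_patient(df)
        np.testing.assert_allclose(out["gzmk_norm"], 1.0)

    def test_near_mean_is_exactly_one_per_patient(self):
        rng = np.random.default_rng(3)
        rows = []
        for pid in ("P1", "P2"):
            for i in range(20):
                cat = rng.choice(["touching", "near", "excluded"])
                d = {"touching": 5.0, "near": 15.0, "excluded": 30.0}[cat]
                rows.append((i, pid, "F0", True, 99, d, cat,
                             float(rng.uniform(10, 100))))
        out = normalize_per_patient(make_proximity_df(rows))
        for pid, grp in out.groupby("patient_id"):
            near = grp[grp["category"] == "near"]
            assert near["gzmk_norm"].mean() == pytest.approx(1.0, abs=1e-12)

    def test_patient_without_near_cells_flagged_and_warned(self, caplog):
        df = make_proximity_df(
            [
                (1, "P1", "F0", True, 9, 5.0, "touching", 6.0),
                (2, "P2", "F0", True, 9, 15.0, "near", 4.0),
            ]
        )
        with caplog.at_level("WARNING"):
            out = normalize_per_patient(df).set_index("cell_id")
        assert out.loc[1, "norm_excluded"]
        assert np.isnan(out.loc[1, "gzmk_norm"])
        assert not out.loc[2, "norm_excluded"]
        assert "P1" in caplog.text


class TestTtest:
    def test_hand_computed_pooled_t(self):
        a = [1.0, 2.0, 3.0, 4.0, 5.0]
        b = [2.0, 4.0, 6.0, 8.0, 10.0]
        # closed form: mean diff -3; pooled var (4*2.5 + 4*10)/8 = 6.25;
        # se = 2.5*sqrt(2/5); t = -3 / 1.5811388... = -1.8973665961
        res = ttest_groups(a, b)
        assert res.t == pytest.approx(-1.8973665961010275, rel=1e-12)
        assert res.p == pytest.approx(2 * stats.t.sf(1.8973665961010275, 8),
                                      rel=1e-12)
        assert res.n1 == res.n2 == 5
        assert res.mean1 == 3.0 and res.mean2 == 6.0

    def test_identical_groups_give_zero_t(self):
        res = ttest_groups([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.t == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    def test_empty_group_error_names_group(self):
        with pytest.raises(EmptyGroupError, match="near"):
            ttest_groups([1.0], [], "touching", "near")

    def test_welch_flag(self):
        a = np.r_[1.0:6.0]
        b = np.r_[2.0:20.0:2.0]
        res = ttest_groups(a, b, welch=True)
        expected = stats.ttest_ind(a, b, equal_var=False)
        assert res.t == pytest.approx(float(expected.statistic))
        assert res.welch


def synthetic_cohort(fold, noise_sd, seed, n_fields=4, n_patients=2):
    """Feature-level cohort via the generative model (no rasterization)."""
    from mifquant.simulate import TissueSpec, sample_cell_table
    from mifquant.classify import classify_markers  # noqa: F401  (not needed here)

    spec = TissueSpec(
        field_size_um=(150.0, 150.0), n_cells=120,
        fraction_cd8=0.35, fraction_neutrophil=0.3,
        gzmk_base=100.0, gzmk_contact_fold=fold, noise_sd=noise_sd, seed=seed,
    )
    rng = np.random.default_rng(seed)
    rows = []
    for p in range(n_patients):
        for f in range(n_fields):
            rows.append(
                sample_cell_table(spec, rng, patient_id=f"P{p}", field_id=f"F{f}")
            )
    return pd.concat(rows, ignore_index=True)


def cohort_to_proximity(table):
    """Ground-truth types -> proximity rows (bypasses image classification)."""
    frames = []
    for (pid, fid), grp in table.groupby(["patient_id", "field_id"]):
        cd8 = grp[grp["cell_type"] == "cd8"]
        neut = grp[grp["cell_type"] == "neutrophil"]
        nn = nearest_neutrophil(cd8, neut)
        block = cd8[["cell_id", "patient_id", "field_id", "gzmk_mean"]].merge(
            nn, on="cell_id"
        )
        block["is_cd8"] = True
        frames.append(block)
    out = pd.concat(frames, ignore_index=True)
    out["category"] = categorize_array(out["distance_um"].to_numpy())
    return out


class TestTouchingVsNear:
    def test_category_counts_partition_cd8_cells(self):
        table = synthetic_cohort(fold=1.0, noise_sd=10.0, seed=21)
        prox = cohort_to_proximity(table)
        n_cd8 = (table["cell_type"] == "cd8").sum()
        counts = prox["category"].value_counts()
        assert counts.sum() == n_cd8 == len(prox)

    def test_fold_two_recovered_exactly_without_noise(self):
        table = synthetic_cohort(fold=2.0, noise_sd=0.0, seed=22)
        prox = cohort_to_proximity(table)
        normed = normalize_per_patient(prox)
        res = touching_vs_near(normed)
        assert res.mean1 / res.mean2 == pytest.approx(2.0, abs=1e-12)
        assert res.p < 1e-10

    def test_fold_one_gives_ratio_one(self):
        table = synthetic_cohort(fold=1.0, noise_sd=10.0, seed=23,
                                 n_fields=6, n_patients=3)
        prox = cohort_to_proximity(table)
        res = touching_vs_near(normalize_per_patient(prox))
        assert res.mean1 / res.mean2 == pytest.approx(1.0, abs=0.05)

    def test_empty_category_raises(self):
        df = make_proximity_df(
            [(1, "P1", "F0", True, 9, 15.0, "near", 4.0),
             (2, "P1", "F0", True, 9, 16.0, "near", 5.0)]
        )
        with pytest.raises(EmptyGroupError, match="touching"):
            touching_vs_near(normalize_per_patient(df))


class TestCd8VsNonCd8:
    def test_identical_distributions_give_null_result(self):
        rows = []
        vals = [10.0, 12.0, 14.0, 16.0, 18.0]
        for i, v in enumerate(vals):
            rows.append((i, "P1", "F0", True, 99, 5.0, "touching", v))
            rows.append((100 + i, "P1", "F0", False, 99, 5.0, "touching", v))
        res = contact_comparison_cd8_vs_noncd8(make_proximity_df(rows))
        assert res.t == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    def test_only_sub_10um_cells_enter(self):
        rows = [
            (1, "P1", "F0", True, 9, 5.0, "touching", 10.0),
            (2, "P1", "F0", True, 9, 12.0, "near", 99.0),  # excluded by the rule
            (3, "P1", "F0", False, 9, 6.0, "touching", 5.0),
            (4, "P1", "F0", False, 9, 8.0, "touching", 5.0),
        ]
        res = contact_comparison_cd8_vs_noncd8(make_proximity_df(rows))
        assert res.n1 == 1 and res.n2 == 2
        assert res.mean1 == 10.0

    def test_empty_group_named(self):
        rows = [(1, "P1", "F0", True, 9, 5.0, "touching", 10.0)]
        with pytest.raises(EmptyGroupError, match="non_cd8_close"):
            contact_comparison_cd8_vs_noncd8(make_proximity_df(rows))


class TestBuildProximityTable:
    def _features_and_calls(self):
        # 1 cd8 at origin, neutrophils at 5 and 30, 1 double-negative at (8, 0)
        feats = pd.DataFrame(
            {
                "cell_id": [1, 2, 3, 4],
                "patient_id": "P0",
                "field_id": "F0",
                "centroid_x_um": [0.0, 5.0, 30.0, 8.0],
                "centroid_y_um": [0.0, 0.0, 0.0, 0.0],
                "mean_farred": [50.0, 1.0, 1.0, 7.0],
            }
        )
        calls = []
        pos = {1: "cd8", 2: "cd66b", 3: "cd66b"}
        for cid in feats["cell_id"]:
            for marker in ("cd8", "cd66b"):
                positive = pos.get(cid) == marker
                calls.append(
                    {"cell_id": cid, "patient_id": "P0", "field_id": "F0",
                     "marker": marker, "positive": positive,
                     "reason": "pass" if positive else "ratio_fail"}
                )
        return feats, pd.DataFrame(calls)

    def test_cd8_rows_with_distances_and_category(self):
        feats, calls = self._features_and_calls()
        prox = build_proximity_table(feats, calls)
        assert len(prox) == 1
        r = prox.iloc[0]
        assert r["cell_id"] == 1
        assert r["distance_um"] == pytest.approx(5.0)
        assert r["category"] == "touching"
        assert r["gzmk_mean"] == 50.0

    def test_include_non_cd8_adds_double_negatives(self):
        feats, calls = self._features_and_calls()
        prox = build_proximity_table(feats, calls, include_non_cd8=True)
        assert set(prox["cell_id"]) == {1, 4}
        assert not prox.set_index("cell_id").loc[4, "is_cd8"]

    def test_bad_cutoffs_rejected(self):
        feats, calls = self._features_and_calls()
        with pytest.raises(ValueError, match="cutoff"):
            build_proximity_table(feats, calls, touching_max_um=20, near_max_um=10)
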