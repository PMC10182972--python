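"""COPA scaling, threshold fitting, the filter cascade and evaluability."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hpaudit.matrix import VafMatrix
from hpaudit.outlier_model import (
    DegenerateScaleError,
    FilterConstants,
    call_outliers,
    copa_scale,
    fit_thresholds,
    sample_evaluability,
    validated_calls,
)
from hpaudit.synthetic_data import preset, simulate_vaf_cohort


def _sorted_median(values):
    # independent sort-based median for cross-checking
    s = sorted(values)
    n = len(s)
    return s[n // 2] if n % 2 else 0.5 * (s[n // 2 - 1] + s[n // 2])


class TestCopaScale:
    def test_hand_computed_values(self):
        x = [0.01, 0.02, 0.02, 0.03, 0.20]
        med = _sorted_median(x)
        mad = _sorted_median([abs(v - med) for v in x])
        assert med == pytest.approx(0.02) and mad == pytest.approx(0.01)
        z = copa_scale(x)
        expected = [(v - 0.02) / (1.4826 * 0.01) for v in x]
        np.testing.assert_allclose(z, expected)
        assert z[-1] == pytest.approx(12.1408, abs=1e-3)

    def test_degenerate_and_short_inputs(self):
        with pytest.raises(DegenerateScaleError):
            copa_scale([0.05, 0.05, 0.05, 0.05])
        with pytest.raises(ValueError):
            copa_scale([0.1, 0.2])

    def test_nan_propagates(self):
        z = copa_scale([0.01, 0.02, np.nan, 0.03, 0.2])
        assert np.isnan(z[2]) and np.isfinite(z[0])

    @settings(max_examples=200, derandomize=True, deadline=None)
    @given(
        values=st.lists(
            st.integers(0, 1000).map(lambda n: n / 1000), min_size=4, max_size=30
        ),
        a=st.integers(1, 100).map(lambda n: n / 10),
        b=st.integers(-50, 50).map(lambda n: n / 10),
    )
    def test_affine_invariance_and_permutation_equivariance(self, values, a, b):
        x = np.asarray(values, dtype=float)
        if np.median(np.abs(x - np.median(x))) == 0:
            return  # degenerate scale, covered elsewhere
        z = copa_scale(x)
        np.testing.assert_allclose(copa_scale(a * x + b), z, rtol=1e-7, atol=1e-7)
        perm = np.random.RandomState(0).permutation(len(x))
        np.testing.assert_allclose(copa_scale(x[perm]), z[perm])


def _matrix_from_values(control_vals, study_vals, region="R1", depth=1000):
    rows = []
    labels = {}
    for i, v in enumerate(control_vals):
        s = f"c{i:02d}"
        labels[s] = "control"
        rows.append({"sample_id": s, "region_id": region, "depth": depth,
                     "vaf_ins": 0.01, "vaf_del": v})
    for i, (v, d) in enumerate(study_vals):
        s = f"s{i:02d}"
        labels[s] = "study"
        rows.append({"sample_id": s, "region_id": region, "depth": d,
                     "vaf_ins": 0.01, "vaf_del": v})
    return VafMatrix(pd.DataFrame(rows), labels)


class TestFitThresholds:
    def test_max_control_is_maximum(self):
        m = _matrix_from_values([0.01, 0.012, 0.011, 0.05], [])
        ts = fit_thresholds(m)
        assert ts.cells.loc[("R1", "del"), "max_control_vaf"] == pytest.approx(0.05)

    def test_robust_threshold_vs_fragile_maximum(self):
        """An extreme control value jumps the raw maximum to itself, while the
        median/MAD centre and scale (breakdown point 50%) barely move and the
        mu+3*sigma threshold shifts only by its 1/n share of the outlier."""
        base = [0.010, 0.011, 0.012, 0.013, 0.014, 0.015, 0.016, 0.017]
        ts1 = fit_thresholds(_matrix_from_values(base, []))
        ts2 = fit_thresholds(_matrix_from_values(base + [0.40], []))
        t1 = ts1.cells.loc[("R1", "del")]
        t2 = ts2.cells.loc[("R1", "del")]
        assert t2["center"] == pytest.approx(t1["center"], abs=1e-3)
        assert t2["scale"] == pytest.approx(t1["scale"], rel=0.5)
        z_of_outlier = (0.40 - t2["center"]) / t2["scale"]
        assert abs(t2["z_threshold"] - t1["z_threshold"]) < 0.2 * z_of_outlier
        assert t2["max_control_vaf"] - t1["max_control_vaf"] > 0.3

    def test_empty_controls_is_error(self):
        m = _matrix_from_values([], [(0.2, 1000)])
        with pytest.raises(ValueError, match="control"):
            fit_thresholds(m)

    def test_degenerate_cell_falls_back_to_raw_filters(self):
        m = _matrix_from_values([0.02] * 6, [(0.5, 1000), (0.1, 1000)])
        ts = fit_thresholds(m)
        assert bool(ts.cells.loc[("R1", "del"), "degenerate"])
        audit = call_outliers(m, ts)
        big = audit[audit["vaf"] == 0.5].iloc[0]
        assert np.isnan(big["z_score"]) and big["passed_z"]
        assert big["validated"]
        small = audit[(audit["vaf"] == 0.1) & (audit["kind"] == "del")].iloc[0]
        assert not small["validated"]


class TestCallOutliers:
    def test_min_vaf_filter_beats_huge_z(self):
        m = _matrix_from_values(
            [0.0101, 0.0102, 0.0103, 0.0104, 0.0105], [(0.10, 1000)]
        )
        audit = call_outliers(m, fit_thresholds(m))
        row = audit[audit["kind"] == "del"].iloc[0]
        assert row["z_score"] > 100
        assert row["passed_z"] and not row["passed_min_vaf"]
        assert not row["validated"]

    def test_low_depth_never_validates(self):
        m = _matrix_from_values(
            [0.0101, 0.0102, 0.0103, 0.0104, 0.0105], [(0.60, 90)]
        )
        audit = call_outliers(m, fit_thresholds(m))
        row = audit[audit["kind"] == "del"].iloc[0]
        assert not row["passed_depth"] and not row["validated"]

    def test_validated_implies_all_filters(self, benchmark):
        ts = fit_thresholds(benchmark.matrix)
        audit = call_outliers(benchmark.matrix, ts)
        val = validated_calls(audit)
        assert (val["vaf"] >= 0.15).all()
        assert (val["vaf"] > val["max_control_vaf"]).all()
        assert (val["depth"] >= 100).all()
        flags = val[["passed_z", "passed_min_vaf", "passed_max_control",
                     "passed_depth"]].all(axis=1)
        assert flags.all()
        assert list(val["vaf"]) == sorted(val["vaf"], reverse=True)

    def test_rank_int_mode_agrees_on_clear_outliers(self):
        cfg = preset("clean", n_carriers=2, seed=9)
        matrix, truth = simulate_vaf_cohort(cfg)
        v_rob = validated_calls(
            call_outliers(matrix, fit_thresholds(matrix, normalization="robust-z"))
        )
        v_int = validated_calls(
            call_outliers(matrix, fit_thresholds(matrix, normalization="rank-int"))
        )
        keys = lambda df: set(zip(df.sample_id, df.region_id, df.kind))
        strong = truth[(truth.true_vaf >= 0.5) & (truth.depth >= 100)]
        want = set(zip(strong.sample_id, strong.region_id, strong.kind))
        assert want <= keys(v_rob) and want <= keys(v_int)

    def test_mismatched_catalogue_rejected(self):
        m1 = _matrix_from_values([0.01, 0.02, 0.03, 0.02], [(0.3, 1000)])
        m2 = _matrix_from_values([0.01, 0.02, 0.03, 0.02], [(0.3, 1000)],
                                 region="OTHER")
        with pytest.raises(ValueError, match="fitted"):
            call_outliers(m2, fit_thresholds(m1))


class TestFilterConstants:
    def test_invalid_constants_rejected(self):
        with pytest.raises(ValueError):
            FilterConstants(min_vaf=1.1)
        with pytest.raises(ValueError):
            FilterConstants(k_sigma=0)


class TestSampleEvaluability:
    def _matrix(self, depth_rows):
        rows, labels = [], {}
        for sample, depths in depth_rows.items():
            labels[sample] = "study"
            for j, d in enumerate(depths):
                rows.append({"sample_id": sample, "region_id": f"R{j}",
                             "depth": d, "vaf_ins": 0.01 if d else np.nan,
                             "vaf_del": 0.01 if d else np.nan})
        return VafMatrix(pd.DataFrame(rows), labels)

    def test_depth_failure_exclusions(self):
        m = self._matrix({
            "ok": [150] * 29,
            "fail9": [150] * 20 + [90] * 9,
            "fail16": [150] * 13 + [80] * 16,
        })
        ev = sample_evaluability(m)
        assert ev["ok"] == "evaluable"
        assert ev["fail9"] == "excluded"
        assert ev["fail16"] == "excluded"
        assert (sample_evaluability(m, max_failed_regions=29) == "evaluable").all()

    def test_monotone_in_max_failed_regions(self):
        m = self._matrix({"a": [150] * 28 + [50], "b": [50] * 3 + [150] * 26})
        ev0 = sample_evaluability(m, max_failed_regions=0)
        ev1 = sample_evaluability(m, max_failed_regions=1)
        ev3 = sample_evaluability(m, max_failed_regions=3)
        assert list(ev0) == ["excluded", "excluded"]
        assert list(ev1) == ["evaluable", "excluded"]
        assert list(ev3) == ["evaluable", "evaluable"]
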