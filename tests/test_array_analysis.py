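import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from oryzarray import (
    AnalysisParams,
    ArraySample,
    SpotMeasurement,
    average_replicates,
    call_specific,
    detection_call,
    differential_expression,
    log2_ratio_ew,
    median_scale,
    replicate_correlation,
    select_de,
)


def make_array(array_id, tissue, values, bg=0.0, flags=None):
    """Array whose background-subtracted values are exactly ``values``."""
    flags = flags or ["good"] * len(values)
    spots = tuple(
        SpotMeasurement(f"p{i}", foreground=v + bg, background=bg, flag=f)
        for i, (v, f) in enumerate(zip(values, flags))
    )
    return ArraySample(array_id, tissue, spots)


def arrays_from_log2(log2_matrix, tissues, bg=0.0):
    return [
        make_array(f"a{j}", tissues[j], list(np.exp2(log2_matrix[:, j])), bg=bg)
        for j in range(log2_matrix.shape[1])
    ]


class TestDetectionCall:
    def test_bad_flag_never_detected(self):
        assert not detection_call(SpotMeasurement("p", 9999, 1, flag="bad"))

    def test_snr_threshold(self):
        assert detection_call(SpotMeasurement("p", 3000, 100), snr_min=2)
        s = SpotMeasurement("p", 150, 100)
        assert not detection_call(s, snr_min=2)
        assert detection_call(s, snr_min=1.2)

    def test_zero_background_good_flag_detected(self):
        assert detection_call(SpotMeasurement("p", 10, 0))


class TestMedianScale:
    def test_two_arrays_meet_at_reference_median(self):
        a = make_array("a", "shoot", [500, 1000, 1500])
        b = make_array("b", "root", [1000, 2000, 3000])
        m = median_scale([a, b])
        med_a = m.values.loc[m.detected["a"], "a"].median()
        med_b = m.values.loc[m.detected["b"], "b"].median()
        assert med_a == pytest.approx(1500)
        assert med_b == pytest.approx(1500)

    def test_single_array_unchanged(self):
        a = make_array("a", "shoot", [10, 100, 1000])
        m = median_scale([a])
        assert list(m.values["a"]) == [10, 100, 1000]

    def test_identical_arrays_identity(self):
        vals = [30, 300, 3000]
        arrays = [make_array(f"a{i}", "shoot", vals) for i in range(3)]
        m = median_scale(arrays)
        for c in m.values.columns:
            assert list(m.values[c]) == vals

    def test_equal_median_invariant(self, rng):
        log2 = rng.normal(10, 1.5, size=(500, 4)) + rng.normal(0, 1, size=(1, 4))
        arrays = arrays_from_log2(log2, ["shoot"] * 2 + ["root"] * 2, bg=100.0)
        m = median_scale(arrays)
        meds = [
            m.values.loc[m.detected[c], c].median() for c in m.values.columns
        ]
        assert max(meds) / min(meds) - 1 < 1e-9

    def test_no_detected_spots_errors_naming_array(self):
        a = make_array("dark", "shoot", [10, 10], flags=["bad", "bad"])
        with pytest.raises(ValueError, match="dark"):
            median_scale([a])


class TestReplicateCorrelation:
    def test_duplicated_array_r_one(self, rng):
        vals = list(np.exp2(rng.normal(10, 1, 100)))
        arrays = [make_array("a", "shoot", vals), make_array("b", "shoot", vals)]
        r = replicate_correlation(median_scale(arrays))
        assert r.loc["a", "b"] == pytest.approx(1.0)

    def test_scaled_copy_r_one_on_log_scale(self, rng):
        vals = np.exp2(rng.normal(10, 1, 100))
        arrays = [
            make_array("a", "shoot", list(vals)),
            make_array("b", "shoot", list(2.0 * vals)),
        ]
        r = replicate_correlation(median_scale(arrays))
        assert r.loc["a", "b"] == pytest.approx(1.0)

    def test_additive_noise_matches_closed_form(self, rng):
        # log2 values x + e_i with var(x)=1.5^2, sd(e)=0.1:
        # corr = var / (var + sigma^2)
        n, sigma, var = 5000, 0.1, 1.5**2
        x = rng.normal(10, math.sqrt(var), n)
        log2 = np.stack([x + rng.normal(0, sigma, n) for _ in range(2)], axis=1)
        arrays = arrays_from_log2(log2, ["shoot", "shoot"])
        r = replicate_correlation(median_scale(arrays)).iloc[0, 1]
        assert r == pytest.approx(var / (var + sigma**2), abs=0.003)

    def test_few_common_spots_reported_missing(self):
        a = make_array("a", "shoot", [10, 20, 30], flags=["good", "bad", "bad"])
        b = make_array("b", "shoot", [10, 20, 30])
        r = replicate_correlation(median_scale([a, b]))
        assert math.isnan(r.loc["a", "b"])


class TestAverageReplicates:
    def test_equal_values_mean_v_se_zero(self):
        arrays = [make_array(f"a{i}", "shoot", [1024.0]) for i in range(5)]
        s = average_replicates(median_scale(arrays), "shoot")
        assert s.loc["p0", "mean"] == pytest.approx(10.0)
        assert s.loc["p0", "se"] == pytest.approx(0.0)
        assert s.loc["p0", "n_detected"] == 5

    def test_never_detected_marked(self):
        arrays = [
            make_array("a1", "shoot", [1000.0, 1000.0], flags=["good", "bad"]),
            make_array("a2", "shoot", [1000.0, 1000.0], flags=["good", "bad"]),
        ]
        s = average_replicates(median_scale(arrays), "shoot")
        assert math.isnan(s.loc["p1", "mean"])
        assert s.loc["p1", "n_detected"] == 0

    def test_mean_se_match_bruteforce(self, rng):
        log2 = rng.normal(10, 1, size=(50, 4))
        arrays = arrays_from_log2(log2, ["shoot"] * 4)
        m = median_scale(arrays)
        s = average_replicates(m, "shoot")
        probe = "p7"
        vals = np.log2(m.values.loc[probe].to_numpy())
        assert s.loc[probe, "mean"] == pytest.approx(vals.mean())
        assert s.loc[probe, "se"] == pytest.approx(
            vals.std(ddof=1) / math.sqrt(len(vals))
        )


class TestLog2RatioAndWelch:
    def test_identical_sets_ratio_zero(self):
        r, _ = log2_ratio_ew([10, 10.5, 11], [10, 10.5, 11])
        assert r == pytest.approx(0.0)

    def test_exact_fourfold(self):
        a = np.array([12.0, 13.0, 12.5])
        r, _ = log2_ratio_ew(a, a - 2.0)
        assert r == pytest.approx(2.0)

    def test_welch_matches_textbook_formula(self, rng):
        a = rng.normal(10, 0.5, 5)
        b = rng.normal(9, 0.7, 5)
        _, p = log2_ratio_ew(a, b)
        # independent route: explicit Welch statistic and Satterthwaite df
        va, vb = a.var(ddof=1) / 5, b.var(ddof=1) / 5
        t = (a.mean() - b.mean()) / math.sqrt(va + vb)
        df = (va + vb) ** 2 / (va**2 / 4 + vb**2 / 4)
        p_ref = 2 * stats.t.sf(abs(t), df)
        assert p == pytest.approx(p_ref, rel=1e-10)

    def test_single_replicate_side_has_no_p(self):
        r, p = log2_ratio_ew([10.0], [8.0, 8.1, 8.2])
        assert r == pytest.approx(10.0 - 8.1)
        assert math.isnan(p)


class TestSelectDe:
    def test_threshold_semantics(self):
        df = pd.DataFrame(
            {
                "log2_ratio": [1.0, 0.99, 2.0, -1.0, -0.5],
                "p_value": [0.049, 0.001, 0.05, 0.049, 0.001],
            },
            index=[f"p{i}" for i in range(5)],
        )
        out = select_de(df)
        assert out.loc["p0", "direction"] == "up"  # log2 >= 1 inclusive
        assert out.loc["p1", "direction"] == "not_de"  # below fold threshold
        assert out.loc["p2", "direction"] == "not_de"  # p < 0.05 strict
        assert out.loc["p3", "direction"] == "down"
        assert out.loc["p4", "direction"] == "not_de"

    def test_partition_exhaustive_and_disjoint(self, rng):
        df = pd.DataFrame(
            {
                "log2_ratio": rng.normal(0, 2, 200),
                "p_value": rng.uniform(0, 1, 200),
            }
        )
        df.loc[rng.choice(200, 20, replace=False), "p_value"] = np.nan
        out = select_de(df)
        counts = out["direction"].value_counts()
        assert counts.sum() == 200
        assert set(out["direction"]).issubset({"up", "down", "not_de"})
        assert (out["significant"] == (out["direction"] != "not_de")).all()


class TestCallSpecific:
    def _row(self, direction, sig, det_a, det_b, n=5):
        return pd.Series(
            {
                "direction": direction,
                "significant": sig,
                "det_a": det_a,
                "det_b": det_b,
                "n_a": n,
                "n_b": n,
            }
        )

    def test_shoot_specific(self):
        assert call_specific(self._row("up", True, 5, 0)) == "shoot_specific"

    def test_partially_detected_in_root_is_shared(self):
        assert call_specific(self._row("up", True, 5, 2)) == "shared"

    def test_not_significant_is_shared(self):
        assert call_specific(self._row("not_de", False, 5, 5)) == "shared"

    def test_root_specific_symmetric(self):
        assert call_specific(self._row("down", True, 0, 5)) == "root_specific"

    def test_undetected(self):
        assert call_specific(self._row("not_de", False, 0, 0)) == "undetected"


class TestOneSidedDetection:
    def test_probe_detected_in_one_tissue_flagged_and_callable(self):
        # probe p0 detected in all shoot arrays, never in root
        shoot = [
            make_array(f"s{i}", "shoot", [2**10 + d, 2**9], bg=100.0)
            for i, d in enumerate([0.0, 1.0, 2.0])
        ]
        root = [
            make_array(
                f"r{i}", "root", [2**10, 2**9], bg=100.0,
                flags=["bad", "good"],
            )
            for i in range(3)
        ]
        de = differential_expression(median_scale(shoot + root), "shoot", "root")
        row = de.loc["p0"]
        assert row["one_sided_detection"]
        assert row["det_b"] == 0
        assert row["log2_ratio"] > 5  # vs the intensity floor
        assert row["p_value"] < 0.05

    def test_detected_in_neither_tissue(self):
        arrays = [
            make_array(f"a{i}", t, [50.0, 5000.0], bg=100.0, flags=["bad", "good"])
            for i, t in enumerate(["shoot", "shoot", "root", "root"])
        ]
        de = differential_expression(median_scale(arrays), "shoot", "root")
        assert math.isnan(de.loc["p0", "log2_ratio"])
        assert math.isnan(de.loc["p0", "p_value"])
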