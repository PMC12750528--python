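"""Quota/metallome comparison statistics."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from metallome.compare import (
    QuotaTable,
    correlate,
    differential_expression,
    differential_table,
    metal_rollup_test,
    read_quota_table,
    strain_ratio,
    write_quota_table,
)
from metallome.homology import ProteinMetalAnnotation
from metallome.quant import QuantTable
from metallome.reconstruct import MetallomeProfile


def _profile(abundance, sd=None, group="OA1", reps=None):
    return MetallomeProfile(group=group, abundance=dict(abundance),
                            sd=dict(sd or {m: 0.0 for m in abundance}),
                            n_replicates=len(reps) if reps else 1,
                            replicate_profiles=reps)


def _quota(data, strain="OA1"):
    return QuotaTable(strain=strain, data=data)


class TestCorrelate:
    def test_proportional_profile_gives_perfect_fit(self):
        quota = _quota({m: (q, 0.1, 3) for m, q in
                        zip("ABCDEF", (1, 3, 10, 40, 200, 1000))})
        profile = _profile({m: 0.003 * q[0] for m, q in quota.data.items()})
        result = correlate(quota, profile)
        assert result.r_squared == pytest.approx(1.0, abs=1e-12)
        assert result.n_points == 6

    def test_matches_least_squares_oracle_on_hand_points(self):
        """r^2 equals 1 - SSres/SStot from an independent line fit."""
        quota = _quota({"Fe": (1.0, 0, 3), "Zn": (10.0, 0, 3),
                        "Mn": (100.0, 0, 3), "Cu": (1000.0, 0, 3)})
        profile = _profile({"Fe": 2.0, "Zn": 15.0, "Mn": 350.0, "Cu": 1800.0})
        x = np.log10([1.0, 10.0, 100.0, 1000.0])
        y = np.log10([2.0, 15.0, 350.0, 1800.0])
        slope, intercept = np.polyfit(x, y, 1)
        ss_res = float(np.sum((y - (slope * x + intercept)) ** 2))
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        expected = 1.0 - ss_res / ss_tot
        result = correlate(quota, profile)
        assert result.r_squared == pytest.approx(expected, abs=1e-12)

    def test_invariant_to_profile_rescaling(self):
        quota = _quota({m: (q, 0, 3) for m, q in zip("ABCD", (1, 7, 30, 400))})
        profile = _profile({"A": 0.5, "B": 2.0, "C": 20.0, "D": 100.0})
        r1 = correlate(quota, profile).r_squared
        r2 = correlate(quota, profile.scaled(37.5)).r_squared
        assert r1 == pytest.approx(r2, abs=1e-12)

    def test_unpaired_metals_excluded_and_reported(self):
        quota = _quota({"Fe": (1, 0, 3), "Zn": (2, 0, 3), "Mn": (3, 0, 3),
                        "Ca": (500, 0, 3)})
        profile = _profile({"Fe": 1.0, "Zn": 2.0, "Mn": 3.0, "Mo": 0.4})
        result = correlate(quota, profile)
        assert result.n_points == 3
        assert set(result.excluded) == {"Ca", "Mo"}

    def test_fewer_than_three_pairs_rejected(self):
        quota = _quota({"Fe": (1, 0, 3), "Zn": (2, 0, 3)})
        profile = _profile({"Fe": 1.0, "Zn": 2.0})
        with pytest.raises(ValueError, match="3"):
            correlate(quota, profile)

    def test_linear_mode_differs_from_log_mode(self):
        quota = _quota({m: (q, 0, 3) for m, q in zip("ABCD", (1, 10, 100, 1000))})
        profile = _profile({"A": 1.2, "B": 8.0, "C": 130.0, "D": 900.0})
        log_r2 = correlate(quota, profile, log_space=True).r_squared
        lin_r2 = correlate(quota, profile, log_space=False).r_squared
        assert log_r2 != pytest.approx(lin_r2, abs=1e-6)


class TestStrainRatio:
    def test_identical_profiles_give_unit_ratios(self):
        profile = _profile({"Fe": 2.0, "Zn": 1.0}, sd={"Fe": 0.2, "Zn": 0.1})
        result = strain_ratio(profile, profile)
        for metal, (ratio, _) in result.ratios.items():
            assert ratio == pytest.approx(1.0)

    def test_exact_means_give_exact_ratio_and_zero_sd(self):
        a = _quota({"Fe": (2.0, 0.0, 3)}, strain="OA1")
        b = _quota({"Fe": (4.0, 0.0, 3)}, strain="OA16")
        result = strain_ratio(a, b)
        assert result.ratios["Fe"] == (pytest.approx(2.0), pytest.approx(0.0))
        assert result.numerator == "OA16"
        assert result.denominator == "OA1"

    def test_propagated_sd_against_monte_carlo(self):
        """Delta-method SD tracks a 1e5-draw Monte-Carlo ratio distribution
        (first-order propagation truncates ~3% low at CV 0.1)."""
        a = _quota({"Fe": (10.0, 1.0, 3)}, strain="OA1")
        b = _quota({"Fe": (20.0, 2.0, 3)}, strain="OA16")
        ratio, sd = strain_ratio(a, b).ratios["Fe"]
        assert ratio == pytest.approx(2.0)
        assert sd == pytest.approx(2.0 * math.sqrt(0.01 + 0.01), abs=1e-12)
        rng = np.random.default_rng(42)
        draws = rng.normal(20, 2, 100_000) / rng.normal(10, 1, 100_000)
        mc_sd = float(np.std(draws, ddof=1))
        assert abs(sd - mc_sd) / mc_sd < 0.05

    def test_metal_missing_on_either_side_skipped(self, caplog):
        a = _profile({"Fe": 1.0, "Zn": 0.0})
        b = _profile({"Fe": 2.0, "Cu": 1.0}, group="OA16")
        with caplog.at_level("WARNING"):
            result = strain_ratio(a, b)
        assert set(result.ratios) == {"Fe"}
        assert set(result.skipped) == {"Zn", "Cu"}


def _de_table():
    """Target protein P1 with groups (1,2,3) vs (4,5,6); P2/P3 pin every
    sample's median to 10 so median normalization scales all columns
    equally and the pooled t statistic is unchanged."""
    data = pd.DataFrame({
        "A_1": [1.0, 10.0, 100.0], "A_2": [2.0, 10.0, 100.0],
        "A_3": [3.0, 10.0, 100.0], "B_1": [4.0, 10.0, 100.0],
        "B_2": [5.0, 10.0, 100.0], "B_3": [6.0, 10.0, 100.0],
    }, index=pd.Index(["P1", "P2", "P3"], name="protein_id"))
    return QuantTable(data)


class TestDifferentialExpression:
    def test_identical_groups_give_zero_fc_and_p_one(self):
        data = pd.DataFrame({
            "A_1": [1.0, 5.0], "A_2": [2.0, 5.0], "B_1": [1.0, 5.0],
            "B_2": [2.0, 5.0],
        }, index=pd.Index(["P1", "P2"], name="protein_id"))
        results = differential_expression(QuantTable(data), "A", "B")
        for r in results:
            assert r.log2_fold_change == pytest.approx(0.0)
            assert r.p_value == pytest.approx(1.0)
            assert not r.significant

    def test_pooled_t_matches_textbook_closed_form(self):
        """(1,2,3) vs (4,5,6): t = 3 / sqrt(1 * (1/3 + 1/3)), df = 4."""
        results = differential_expression(_de_table(), "A", "B")
        target = next(r for r in results if r.protein_id == "P1")
        t_hand = 3.0 / math.sqrt(1.0 * (1 / 3 + 1 / 3))
        p_hand = 2.0 * stats.t.sf(t_hand, df=4)
        assert target.p_value == pytest.approx(p_hand, abs=1e-10)
        assert target.log2_fold_change == pytest.approx(math.log2(5.0 / 2.0))
        assert target.significant  # p ~= 0.021 < 0.05

    def test_swapping_groups_negates_fc_and_keeps_p(self):
        fwd = differential_expression(_de_table(), "A", "B")
        rev = differential_expression(_de_table(), "B", "A")
        for f, r in zip(fwd, rev):
            assert f.log2_fold_change == pytest.approx(-r.log2_fold_change)
            assert f.p_value == pytest.approx(r.p_value, abs=1e-12)

    def test_single_replicate_gives_undefined_p(self):
        data = pd.DataFrame({
            "A_1": [1.0, 2.0], "B_1": [2.0, 4.0], "B_2": [3.0, 6.0],
        }, index=pd.Index(["P1", "P2"], name="protein_id"))
        results = differential_expression(QuantTable(data), "A", "B")
        assert all(math.isnan(r.p_value) for r in results)
        assert all(not r.significant for r in results)
        assert all(not math.isnan(r.log2_fold_change) for r in results)

    def test_welch_variant_differs_under_unequal_variance(self):
        data = pd.DataFrame({
            "A_1": [1.0, 10.0], "A_2": [1.1, 10.0], "A_3": [0.9, 10.0],
            "B_1": [5.0, 10.0], "B_2": [9.0, 10.0], "B_3": [1.0, 10.0],
        }, index=pd.Index(["P1", "P2"], name="protein_id"))
        student = differential_expression(QuantTable(data), "A", "B")[0]
        welch = differential_expression(QuantTable(data), "A", "B",
                                        equal_var=False)[0]
        assert student.p_value != pytest.approx(welch.p_value, abs=1e-6)

    def test_benjamini_hochberg_adjustment_is_monotone(self):
        rng = np.random.default_rng(3)
        data = pd.DataFrame(
            rng.lognormal(0, 0.2, size=(50, 6)),
            index=pd.Index([f"P{i}" for i in range(50)], name="protein_id"),
            columns=["A_1", "A_2", "A_3", "B_1", "B_2", "B_3"],
        )
        results = differential_expression(QuantTable(data), "A", "B", adjust="bh")
        for r in results:
            assert r.p_adjusted >= r.p_value - 1e-12

    def test_metal_labels_attached_from_annotations(self):
        anns = [ProteinMetalAnnotation("P1", {"Cu": 1, "Zn": 2})]
        results = differential_expression(_de_table(), "A", "B", annotations=anns)
        assert next(r for r in results if r.protein_id == "P1").metals == ["Cu", "Zn"]
        table = differential_table(results)
        assert table.loc[table.protein_id == "P1", "metals"].iloc[0] == "Cu;Zn"

    def test_unknown_group_rejected(self):
        with pytest.raises(KeyError):
            differential_expression(_de_table(), "A", "Z")


class TestMetalRollup:
    def test_identical_groups_give_p_one(self):
        reps = [{"Co": 1.0}, {"Co": 2.0}, {"Co": 3.0}]
        a = _profile({"Co": 2.0}, reps=reps)
        b = _profile({"Co": 2.0}, group="OA16", reps=list(reps))
        result = metal_rollup_test(a, b, "Co")
        assert result.p_value == pytest.approx(1.0)
        assert result.ratio == pytest.approx(1.0)

    def test_planted_twofold_difference_detected(self):
        rng = np.random.default_rng(11)
        reps_a = [{"Cu": float(v)} for v in rng.lognormal(0.0, 0.05, 4)]
        reps_b = [{"Cu": float(2 * v)} for v in rng.lognormal(0.0, 0.05, 4)]
        a = _profile({"Cu": 1.0}, reps=reps_a)
        b = _profile({"Cu": 2.0}, group="OA16", reps=reps_b)
        result = metal_rollup_test(a, b, "Cu")
        assert result.p_value < 0.05
        assert result.ratio == pytest.approx(2.0, rel=0.15)

    def test_single_replicate_reports_ratio_with_undefined_p(self):
        a = _profile({"Co": 1.5}, reps=[{"Co": 1.5}])
        b = _profile({"Co": 3.0}, group="OA16", reps=[{"Co": 3.0}])
        result = metal_rollup_test(a, b, "Co")
        assert result.ratio == pytest.approx(2.0)
        assert math.isnan(result.p_value)

    def test_profile_without_replicates_rejected(self):
        a = _profile({"Co": 1.0})
        with pytest.raises(ValueError, match="per-replicate"):
            metal_rollup_test(a, a, "Co")


def test_quota_table_round_trip(tmp_path):
    tables = {
        "OA1": _quota({"Fe": (4.0, 0.5, 3), "Zn": (2.0, 0.1, 3)}, strain="OA1"),
        "OA16": _quota({"Fe": (8.0, 1.0, 3)}, strain="OA16"),
    }
    path = tmp_path / "quotas.tsv"
    write_quota_table(tables, path)
    loaded = read_quota_table(path)
    assert loaded.keys() == tables.keys()
    assert loaded["OA1"].data == tables["OA1"].data
    assert loaded["OA16"].data["Fe"] == (8.0, 1.0, 3)


def test_quota_validation():
    with pytest.raises(ValueError):
        _quota({"Fe": (0.0, 0.1, 3)})
    with pytest.raises(ValueError):
        _quota({"Fe": (1.0, -0.1, 3)})
    with pytest.raises(ValueError):
        _quota({"Fe": (1.0, 0.1, 0)})
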