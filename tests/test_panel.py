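import math

import numpy as np
import pandas as pd
import pytest

import bioage as b
from conftest import make_cohort

# the published women's five-marker panel: weights and inverse coefficients
WOMEN = {
    "PWVe": (0.83, -44.384, 0.1235),
    "A": (0.65, -7.0318, 0.333),
    "APs": (0.58, -118.760, 1.328),
    "WT": (0.54, 204.880, -2.8573),
    "LC": (0.54, 226.860, -0.0662),
}


def women_panel(divisor="count"):
    members = list(WOMEN)
    weights = {m: WOMEN[m][0] for m in members}
    inverses = {m: b.RegressionModel.from_inverse_linear(WOMEN[m][1], WOMEN[m][2])
                for m in members}
    return b.PanelModel(members=members, weights=weights, inverses=inverses,
                        divisor_convention=divisor)


class TestComputeBA:
    def test_exact_age_identity_under_both_conventions(self):
        # values chosen so each member's BAp equals CA exactly
        ca = np.array([30.0, 50.0])
        cols = {}
        for name, (_, a_p, b_p) in WOMEN.items():
            cols[name] = (ca - a_p) / b_p
        table = make_cohort(ca, cols)
        for divisor in ("count", "weight_sum"):
            result = b.compute_ba(table, women_panel(divisor))
            assert np.allclose(result.ba_minus_ca, 0.0, atol=1e-9)

    def test_printed_womens_formula_hand_evaluation(self):
        # independent longhand arithmetic of the printed expression at
        # PWVe=800, A=150, APs=120, WT=50, LC=2500, CA=50
        table = make_cohort([50.0, 50.0], {
            "PWVe": [800.0, 800.0], "A": [150.0, 150.0], "APs": [120.0, 120.0],
            "WT": [50.0, 50.0], "LC": [2500.0, 2500.0]})
        expected = (0.83 * ((-44.384 + 0.1235 * 800) - 50)
                    + 0.65 * ((-7.0318 + 0.333 * 150) - 50)
                    + 0.58 * ((-118.760 + 1.328 * 120) - 50)
                    + 0.54 * ((204.880 - 2.8573 * 50) - 50)
                    + 0.54 * ((226.860 - 0.0662 * 2500) - 50)) / 5
        result = b.compute_ba(table, women_panel())
        assert result.ba_minus_ca.iloc[0] == pytest.approx(expected, abs=1e-9)
        assert result.ba.iloc[0] == pytest.approx(50 + expected, abs=1e-9)

    def test_unit_weights_count_divisor_is_plain_mean(self):
        ca = np.array([40.0, 60.0])
        cols = {name: (ca + shift - WOMEN[name][1]) / WOMEN[name][2]
                for shift, name in zip((2.0, -4.0, 6.0, 1.0, -5.0), WOMEN)}
        table = make_cohort(ca, cols)
        panel = women_panel()
        panel.weights = {m: 1.0 for m in panel.members}
        result = b.compute_ba(table, panel)
        assert np.allclose(result.ba_minus_ca.to_numpy(),
                           np.mean([2.0, -4.0, 6.0, 1.0, -5.0]), atol=1e-6)

    def test_missing_member_divides_by_available_count(self):
        ca = np.array([50.0, 50.0, 50.0])
        cols = {name: list((ca - WOMEN[name][1]) / WOMEN[name][2]) for name in WOMEN}
        cols["PWVe"][0] = np.nan
        cols["A"][0] = np.nan  # subject 0 has 3 of 5 members (>= 0.5)
        table = make_cohort(ca, cols)
        result = b.compute_ba(table, women_panel())
        assert result.n_available.iloc[0] == 3
        assert result.ba_minus_ca.iloc[0] == pytest.approx(0.0, abs=1e-9)

    def test_low_availability_subject_has_no_ba(self):
        ca = np.array([50.0, 50.0, 50.0])
        cols = {name: list((ca - WOMEN[name][1]) / WOMEN[name][2]) for name in WOMEN}
        for name in list(WOMEN)[:4]:
            cols[name][0] = np.nan  # 1 of 5 members < min_availability 0.5
        table = make_cohort(ca, cols)
        result = b.compute_ba(table, women_panel())
        assert math.isnan(result.ba.iloc[0])
        assert result.n_excluded == 1


class TestCohortStatistics:
    def _result(self, ca, ba):
        idx = pd.Index([f"S{i}" for i in range(len(ca))])
        ca = pd.Series(np.asarray(ca, float), index=idx)
        ba = pd.Series(np.asarray(ba, float), index=idx)
        return b.BAResult(bap=pd.DataFrame(index=idx), ba=ba, ba_minus_ca=ba - ca,
                          ca=ca, n_available=pd.Series(1, index=idx),
                          extrapolated=pd.DataFrame(index=idx))

    def test_perfect_clock(self):
        ca = [30.0, 40.0, 50.0, 60.0]
        stats = b.cohort_statistics(self._result(ca, ca))
        assert stats.mean == 0 and stats.sigma == 0
        assert stats.r_ba_ca == pytest.approx(1.0)
        assert stats.sigma_ok

    def test_constant_shift(self):
        ca = np.array([30.0, 40.0, 50.0, 60.0])
        stats = b.cohort_statistics(self._result(ca, ca + 7.5))
        assert stats.mean == pytest.approx(7.5)
        assert stats.sigma == pytest.approx(0.0, abs=1e-12)
        assert stats.r_ba_ca == pytest.approx(1.0)

    def test_r_invariant_to_constant_ba_shift(self):
        rng = np.random.default_rng(4)
        ca = rng.uniform(20, 70, 50)
        ba = ca + rng.normal(0, 5, 50)
        r0 = b.cohort_statistics(self._result(ca, ba)).r_ba_ca
        r1 = b.cohort_statistics(self._result(ca, ba + 100.0)).r_ba_ca
        assert r1 == pytest.approx(r0, abs=1e-12)

    def test_trim_applies_to_statistics_only(self):
        ca = np.array([30.0, 40.0, 50.0, 60.0, 35.0])
        ba = ca + np.array([0.0, 0.0, 0.0, 0.0, 40.0])
        result = self._result(ca, ba)
        stats = b.cohort_statistics(result, trim=1)
        assert stats.n == 3
        assert stats.sigma == pytest.approx(0.0, abs=1e-12)
        assert len(result.ba.dropna()) == 5  # individual BAs kept

    def test_too_few_subjects_error(self):
        with pytest.raises(ValueError, match="fewer than 3"):
            b.cohort_statistics(self._result([30.0, 40.0], [30.0, 40.0]))

    def test_variance_propagation_closed_form(self):
        # four markers with known noise; BAp_i = CA + eps_i / slope_i, so under
        # the count divisor sigma^2(BA-CA) = sum (w_i sd_i / slope_i)^2 / m^2
        rng = np.random.default_rng(12)
        n = 500
        ca = rng.uniform(20, 70, n)
        slopes = {"M1": 2.0, "M2": -1.5, "M3": 14.0, "M4": 0.5}
        sds = {"M1": 4.0, "M2": 3.0, "M3": 40.0, "M4": 1.2}
        weights = {"M1": 0.8, "M2": 0.6, "M3": 0.9, "M4": 0.5}
        cols, inverses = {}, {}
        for m, slope in slopes.items():
            intercept = 100.0
            cols[m] = intercept + slope * ca + rng.normal(0, sds[m], n)
            inverses[m] = b.RegressionModel.from_inverse_linear(
                -intercept / slope, 1.0 / slope)
        table = make_cohort(ca, cols)
        panel = b.PanelModel(members=list(slopes), weights=weights,
                             inverses=inverses, divisor_convention="count")
        result = b.compute_ba(table, panel)
        stats = b.cohort_statistics(result)
        m = len(slopes)
        expected = math.sqrt(sum((weights[k] * sds[k] / abs(slopes[k])) ** 2
                                 for k in slopes)) / m
        assert stats.sigma == pytest.approx(expected, rel=0.15)


class TestWeights:
    def _report(self, rs):
        cols = list(rs)
        empty = pd.DataFrame(np.nan, index=cols, columns=cols)
        return b.CorrelationReport(r_with_ca=dict(rs), n_with_ca={k: 9 for k in rs},
                                   pair_r=empty, n_pairs=empty)

    def test_rounding_rule(self):
        w = b.default_weights(self._report({"X": 0.823}), ["X"])
        assert w["X"] == 0.82

    def test_magnitude_used_for_negative_slopes(self):
        w = b.default_weights(self._report({"X": -0.53}), ["X"])
        assert w["X"] == 0.53

    def test_printed_overrides_echoed_verbatim(self):
        overrides = {m: WOMEN[m][0] for m in WOMEN}
        report = self._report({m: 0.1 for m in WOMEN})
        w = b.default_weights(report, list(WOMEN), overrides=overrides)
        assert w == overrides
        panel = women_panel()
        text = b.render_formula(panel)
        assert "0.83 ×" in text and text.strip().endswith("/5")

    def test_undefined_r_is_error(self):
        with pytest.raises(ValueError, match="weight"):
            b.default_weights(self._report({"X": float("nan")}), ["X"])


class TestRenderFormula:
    def test_singleton(self):
        model = b.RegressionModel.from_inverse_linear(12.5, 0.4)
        panel = b.PanelModel(members=["NAME"], weights={"NAME": 1.0},
                             inverses={"NAME": model})
        assert b.render_formula(panel) == "BA-CA = (1.00 × [12.5 + 0.4 × NAME - CA])/1"

    def test_five_member_panel_has_five_terms_and_divisor_five(self):
        text = b.render_formula(women_panel())
        assert text.count("[") == 5 and text.strip().endswith("/5")

    def test_render_parse_evaluate_round_trip(self):
        panel = women_panel()
        parsed = b.parse_formula(b.render_formula(panel))
        assert parsed.members == panel.members
        table = make_cohort([50.0, 62.0], {
            "PWVe": [800.0, 760.0], "A": [150.0, 140.0], "APs": [120.0, 135.0],
            "WT": [50.0, 44.0], "LC": [2500.0, 2100.0]})
        direct = b.compute_ba(table, panel).ba_minus_ca
        via_text = b.compute_ba(table, parsed).ba_minus_ca
        assert np.allclose(direct.to_numpy(), via_text.to_numpy(), atol=1e-9)


def test_panel_model_validation():
    model = b.RegressionModel.from_inverse_linear(0.0, 1.0)
    with pytest.raises(ValueError):
        b.PanelModel(members=[], weights={}, inverses={})
    with pytest.raises(ValueError, match="weight"):
        b.PanelModel(members=["X"], weights={"X": 1.5}, inverses={"X": model})
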