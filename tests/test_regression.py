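import math

import numpy as np
import pytest

import bioage as b


def normal_equations(x, y):
    """Closed-form simple least squares (the independent oracle)."""
    n = len(x)
    sx, sy = sum(x), sum(y)
    sxx, sxy = sum(v * v for v in x), sum(a * c for a, c in zip(x, y))
    slope = (n * sxy - sx * sy) / (n * sxx - sx * sx)
    intercept = (sy - slope * sx) / n
    return intercept, slope


class TestFit:
    def test_noiseless_line_exact(self):
        ca = np.linspace(20, 70, 20)
        model = b.fit_regression(ca, 10 + 2 * ca, "linear")
        a, slope = model.coefficients
        assert a == pytest.approx(10.0, abs=1e-9)
        assert slope == pytest.approx(2.0, abs=1e-12)
        assert model.r2 == pytest.approx(1.0)

    def test_five_points_match_normal_equations(self):
        ca = [20.0, 30.0, 40.0, 50.0, 60.0]
        bm = [1.0, 3.0, 2.0, 5.0, 4.0]
        model = b.fit_regression(ca, bm, "linear")
        a0, b0 = normal_equations(ca, bm)
        assert model.coefficients[0] == pytest.approx(a0, rel=1e-9)
        assert model.coefficients[1] == pytest.approx(b0, rel=1e-9)

    def test_exponential_rate_recovered(self):
        rng = np.random.default_rng(11)
        ca = rng.uniform(20, 70, 200)
        bm = 50 * np.exp(0.02 * ca) * (1 + rng.normal(0, 0.01, 200))
        model = b.fit_regression(ca, bm, "exponential")
        assert model.coefficients[1] == pytest.approx(0.02, rel=0.1)
        assert model.coefficients[0] == pytest.approx(50, rel=0.1)

    def test_degenerate_design_rejected(self):
        with pytest.raises(b.RegressionError, match="degenerate"):
            b.fit_regression([40, 40, 40], [1, 2, 3], "linear")

    def test_exponential_sign_violation(self):
        with pytest.raises(b.RegressionError, match="one sign"):
            b.fit_regression([20, 30, 40], [1.0, -2.0, 3.0], "exponential")

    def test_missing_pairs_excluded(self):
        ca = [20, 30, 40, 50, np.nan]
        bm = [50, 70, np.nan, 110, 130]
        model = b.fit_regression(ca, bm, "linear")
        assert model.coefficients[1] == pytest.approx(2.0, abs=1e-9)


class TestSelectFamily:
    def _model(self, family, r2):
        return b.RegressionModel(family=family, coefficients=(1.0, 1.0),
                                 rounded_coefficients=(1.0, 1.0), r2=r2,
                                 residual_se=0.0, ca_range=(20.0, 70.0))

    def test_singleton(self):
        m = self._model("linear", 0.4)
        assert b.select_family({"linear": m}) is m

    def test_small_improvement_keeps_linear(self):
        models = {"linear": self._model("linear", 0.50),
                  "polynomial2": self._model("polynomial2", 0.51)}
        assert b.select_family(models, 0.02).family == "linear"

    def test_large_improvement_switches(self):
        models = {"linear": self._model("linear", 0.50),
                  "exponential": self._model("exponential", 0.60)}
        assert b.select_family(models, 0.02).family == "exponential"


class TestInvert:
    def test_printed_pulse_wave_term(self):
        # women's elastic-artery term: BAp = -44.384 + 0.1235 x PWVe
        model = b.RegressionModel.from_inverse_linear(-44.384, 0.1235)
        assert model.invert(600.0) == pytest.approx(29.716, abs=1e-9)

    def test_round_trip_identity(self):
        ca = np.linspace(20, 70, 20)
        model = b.fit_regression(ca, 10 + 2 * ca, "linear", decimals=8)
        assert model.invert(model.predict(np.array([40.0]))[0]) == \
            pytest.approx(40.0, abs=1e-4)

    def test_vertex_inside_range_refused(self):
        ca = np.linspace(20, 70, 30)
        bm = (ca - 45.0) ** 2  # vertex at 45, inside the observed range
        model = b.fit_regression(ca, bm, "polynomial2")
        assert not model.is_monotone()
        with pytest.raises(b.RegressionError, match="monotone"):
            model.invert(100.0)

    def test_monotone_quadratic_inverts_in_range(self):
        ca = np.linspace(20, 70, 30)
        bm = 5 + 0.5 * ca + 0.01 * ca ** 2  # vertex at -25, monotone on range
        model = b.fit_regression(ca, bm, "polynomial2", decimals=8)
        value = 5 + 0.5 * 50 + 0.01 * 2500
        assert model.invert(value) == pytest.approx(50.0, abs=1e-3)

    def test_extrapolation_flagged_not_clamped(self):
        model = b.RegressionModel.from_inverse_linear(0.0, 1.0, ca_range=(20, 70))
        bap, flag = model.invert(90.0, with_flag=True)
        assert bap == 90.0 and flag is True
        bap, flag = model.invert(40.0, with_flag=True)
        assert flag is False

    def test_exponential_out_of_domain_is_nan(self):
        ca = np.linspace(20, 70, 30)
        model = b.fit_regression(ca, 50 * np.exp(0.02 * ca), "exponential")
        assert math.isnan(model.invert(-5.0))

    def test_zero_slope_refused(self):
        model = b.RegressionModel(family="linear", coefficients=(5.0, 0.0),
                                  rounded_coefficients=(5.0, 0.0), r2=0.0,
                                  residual_se=0.0, ca_range=(20.0, 70.0))
        with pytest.raises(b.RegressionError):
            model.invert(5.0)


class TestRoundTripAcrossRange:
    @pytest.mark.parametrize("family,curve", [
        ("linear", lambda ca: 10 + 2 * ca),
        ("linear", lambda ca: 300 - 1.7 * ca),
        ("exponential", lambda ca: 50 * np.exp(0.02 * ca)),
        ("polynomial2", lambda ca: 5 + 0.5 * ca + 0.01 * ca ** 2),
    ])
    def test_inverse_recovers_age_within_rounding_error(self, family, curve):
        ca = np.linspace(20, 70, 40)
        model = b.fit_regression(ca, curve(ca), family, decimals=4)
        recovered = np.array([model.invert(v) for v in curve(ca)])
        assert np.max(np.abs(recovered - ca)) < 0.5  # 4-decimal rounding bound

    def test_rounding_perturbation_bounded(self):
        ca = np.linspace(20, 70, 40)
        bm = 220 + 14 * ca
        exact = b.fit_regression(ca, bm, "linear", decimals=10)
        rounded = b.fit_regression(ca, bm, "linear", decimals=4)
        delta = max(abs(exact.invert(v) - rounded.invert(v)) for v in bm)
        assert delta < 0.5


class TestBiomarkerAgeModel:
    def test_sklearn_fit_predict(self):
        rng = np.random.default_rng(5)
        ca = rng.uniform(20, 70, 120)
        bm = 220 + 14 * ca + rng.normal(0, 30, 120)
        est = b.BiomarkerAgeModel(family="auto").fit(bm.reshape(-1, 1), ca)
        assert est.family_ == "linear"
        pred = est.predict((220 + 14 * ca).reshape(-1, 1))
        assert np.corrcoef(pred, ca)[0, 1] > 0.999

    def test_get_params_round_trip(self):
        est = b.BiomarkerAgeModel(decimals=6)
        params = est.get_params()
        assert params["decimals"] == 6
        est.set_params(family="linear")
        assert est.family == "linear"
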