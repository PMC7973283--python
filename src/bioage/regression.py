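"""Biomarker-vs-age regressions and their inversion to partial biological age.

Each biomarker is regressed on chronological age (BM on CA, not CA on BM)
with one of three families:

* linear        BM = a + b*CA
* exponential   BM = a*exp(b*CA)          (all BM values of one sign)
* polynomial2   BM = a + b*CA + c*CA**2

and the fitted curve is inverted algebraically to map a measured biomarker
value back to a partial biological age (BAp).  Coefficients are stored both
raw and rounded to a configured number of decimal places; inversion uses
the rounded coefficients, because published formulas are applied in their
printed (rounded) form.  Inversion is only defined where the fitted curve
is strictly monotone on the observed age range; a BAp outside that range is
returned unclamped but flagged as an extrapolation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin

logger = logging.getLogger("bioage")

__all__ = [
    "RegressionModel", "RegressionError", "fit_regression", "fit_candidates",
    "select_family", "invert", "BiomarkerAgeModel", "FAMILIES",
]

FAMILIES = ("linear", "exponential", "polynomial2")


class RegressionError(ValueError):
    """Raised for degenerate designs or refused inversions."""


def _round(values: Sequence[float], decimals: int) -> tuple[float, ...]:
    return tuple(float(np.round(v, decimals)) for v in values)


@dataclass(frozen=True)
class RegressionModel:
    """A fitted biomarker-on-age regression with its algebraic inverse.

    ``coefficients`` are the raw least-squares estimates in the family's
    parameter order; ``rounded_coefficients`` are the same at ``decimals``
    places.  For the linear family ``inverse_coefficients`` holds the
    printed-form inverse (a', b') with BAp = a' + b' * BM, also rounded.
    """

    family: str
    coefficients: tuple[float, ...]
    rounded_coefficients: tuple[float, ...]
    r2: float
    residual_se: float
    ca_range: tuple[float, float]
    decimals: int = 4
    inverse_coefficients: tuple[float, float] | None = None

    @classmethod
    def from_inverse_linear(cls, a_prime: float, b_prime: float,
                            ca_range: tuple[float, float] = (20.0, 70.0),
                            decimals: int = 4) -> "RegressionModel":
        """Build a linear model directly from printed inverse coefficients.

        Published panels give BAp = a' + b' * BM; the forward coefficients
        are recovered as b = 1/b', a = -a'/b'.
        """
        if b_prime == 0:
            raise RegressionError("inverse slope must be nonzero")
        b = 1.0 / b_prime
        a = -a_prime / b_prime
        return cls(family="linear", coefficients=(a, b),
                   rounded_coefficients=(a, b), r2=float("nan"),
                   residual_se=float("nan"), ca_range=ca_range,
                   decimals=decimals, inverse_coefficients=(a_prime, b_prime))

    # -- forward -------------------------------------------------------

    def predict(self, ca) -> np.ndarray:
        ca = np.asarray(ca, dtype=float)
        c = self.coefficients
        if self.family == "linear":
            return c[0] + c[1] * ca
        if self.family == "exponential":
            return c[0] * np.exp(c[1] * ca)
        return c[0] + c[1] * ca + c[2] * ca * ca

    # -- inversion -----------------------------------------------------

    def is_monotone(self) -> bool:
        """Strict monotonicity of the fitted curve on the observed age range."""
        c = self.rounded_coefficients
        if self.family == "linear":
            return c[1] != 0
        if self.family == "exponential":
            return c[0] != 0 and c[1] != 0
        a, b, q = c
        if q == 0:
            return b != 0
        vertex = -b / (2.0 * q)
        lo, hi = self.ca_range
        return not (lo < vertex < hi)

    def invert(self, bm_value: float, with_flag: bool = False):
        """Map a biomarker value to partial biological age (years).

        Raises :class:`RegressionError` when the model is structurally
        non-invertible (non-monotone, zero slope).  Returns NaN when the
        particular value is outside the curve's reachable range (wrong sign
        for an exponential, negative discriminant for a quadratic).  With
        ``with_flag`` a (BAp, extrapolated) pair is returned; BAp is never
        clamped to the observed age range.
        """
        if not self.is_monotone():
            raise RegressionError(
                f"{self.family} fit is not strictly monotone on {self.ca_range}; "
                "inversion refused")
        bap = self._invert_value(float(bm_value))
        if not with_flag:
            return bap
        lo, hi = self.ca_range
        extrapolated = bool(math.isnan(bap) or bap < lo or bap > hi)
        return bap, extrapolated

    def _invert_value(self, v: float) -> float:
        c = self.rounded_coefficients
        if self.family == "linear":
            a_p, b_p = self.inverse_linear()
            return a_p + b_p * v
        if self.family == "exponential":
            ratio = v / c[0]
            if ratio <= 0:
                return float("nan")
            return math.log(ratio) / c[1]
        a, b, q = c
        if q == 0:
            return (v - a) / b
        disc = b * b - 4.0 * q * (a - v)
        if disc < 0:
            return float("nan")
        root = math.sqrt(disc)
        roots = ((-b + root) / (2.0 * q), (-b - root) / (2.0 * q))
        lo, hi = self.ca_range
        inside = [x for x in roots if lo <= x <= hi]
        if inside:
            return inside[0]
        mid = 0.5 * (lo + hi)
        return min(roots, key=lambda x: abs(x - mid))

    def inverse_linear(self) -> tuple[float, float]:
        """Rounded (a', b') of the printed inverse form BAp = a' + b' * BM."""
        if self.family != "linear":
            raise RegressionError("inverse_linear only defined for the linear family")
        if self.inverse_coefficients is not None:
            return self.inverse_coefficients
        a, b = self.coefficients
        if b == 0:
            raise RegressionError("zero slope; inversion refused")
        return (float(np.round(-a / b, self.decimals)),
                float(np.round(1.0 / b, self.decimals)))

    # -- rendering -------------------------------------------------------

    def render_inverse(self, name: str) -> str:
        """The inverse formula as printed text, e.g. '-44.384 + 0.1235 x PWVe'."""
        fmt = lambda x: _trim(x, self.decimals)
        if self.family == "linear":
            a_p, b_p = self.inverse_linear()
            sign = "-" if b_p < 0 else "+"
            return f"{fmt(a_p)} {sign} {fmt(abs(b_p))} × {name}"
        c = self.rounded_coefficients
        if self.family == "exponential":
            return f"ln({name}/{fmt(c[0])})/{fmt(c[1])}"
        return f"quadratic-root({fmt(c[0])} + {fmt(c[1])} × CA + {fmt(c[2])} × CA² = {name})"


def _trim(x: float, decimals: int) -> str:
    s = f"{x:.{decimals}f}"
    return s.rstrip("0").rstrip(".") if "." in s else s


def fit_regression(ca, values, family: str = "linear", decimals: int = 4,
                   ) -> RegressionModel:
    """Least-squares fit of one family on complete (CA, BM) pairs.

    The exponential family is fitted by ordinary least squares on
    log-transformed biomarker values and therefore requires all values of
    one sign.  ``r2`` is always evaluated on the original biomarker scale so
    the families are comparable.
    """
    ca = np.asarray(ca, dtype=float)
    values = np.asarray(values, dtype=float)
    mask = np.isfinite(ca) & np.isfinite(values)
    ca, values = ca[mask], values[mask]
    need = 4 if family == "polynomial2" else 3
    if len(ca) < need:
        raise RegressionError(f"{family} fit needs >= {need} complete pairs, got {len(ca)}")
    if np.ptp(ca) == 0:
        raise RegressionError("degenerate design: all chronological ages equal")

    if family == "linear":
        b, a = np.polyfit(ca, values, 1)
        coef = (float(a), float(b))
    elif family == "exponential":
        if np.any(values == 0) or (np.any(values > 0) and np.any(values < 0)):
            raise RegressionError(
                "exponential family requires all biomarker values of one sign")
        sign = 1.0 if values[0] > 0 else -1.0
        b, loga = np.polyfit(ca, np.log(sign * values), 1)
        coef = (float(sign * np.exp(loga)), float(b))
    elif family == "polynomial2":
        c2, c1, c0 = np.polyfit(ca, values, 2)
        coef = (float(c0), float(c1), float(c2))
    else:
        raise RegressionError(f"unknown family {family!r}")

    model = RegressionModel(
        family=family, coefficients=coef, rounded_coefficients=_round(coef, decimals),
        r2=0.0, residual_se=0.0, ca_range=(float(ca.min()), float(ca.max())),
        decimals=decimals)
    pred = model.predict(ca)
    resid = values - pred
    ss_res = float((resid * resid).sum())
    ss_tot = float(((values - values.mean()) ** 2).sum())
    r2 = 1.0 if ss_tot == 0 and ss_res == 0 else (
        0.0 if ss_tot == 0 else max(0.0, min(1.0, 1.0 - ss_res / ss_tot)))
    dof = max(len(ca) - len(coef), 1)
    return replace(model, r2=r2, residual_se=float(np.sqrt(ss_res / dof)))


def fit_candidates(ca, values, families: Sequence[str] = FAMILIES,
                   decimals: int = 4) -> dict[str, RegressionModel]:
    """Fit every requested family, skipping the ones the data cannot support."""
    out: dict[str, RegressionModel] = {}
    for family in families:
        try:
            out[family] = fit_regression(ca, values, family, decimals)
        except RegressionError as exc:
            logger.info("family %s unavailable: %s", family, exc)
    return out


def select_family(models: Mapping[str, RegressionModel],
                  improvement_threshold: float = 0.02) -> RegressionModel:
    """Pick linear unless another family improves r2 by more than the threshold."""
    if not models:
        raise RegressionError("no candidate model was fitted")
    linear = models.get("linear")
    if linear is None:
        best = max(models.values(), key=lambda m: m.r2)
        logger.info("no linear candidate; selected %s (r2 = %.4f)", best.family, best.r2)
        return best
    challengers = [m for f, m in models.items()
                   if f != "linear" and m.r2 > linear.r2 + improvement_threshold]
    if not challengers:
        return linear
    best = max(challengers, key=lambda m: m.r2)
    logger.info("selected %s over linear (r2 %.4f vs %.4f)", best.family, best.r2, linear.r2)
    return best


def invert(model: RegressionModel, bm_value: float) -> float:
    """Functional form of :meth:`RegressionModel.invert`."""
    return model.invert(bm_value)


class BiomarkerAgeModel(RegressorMixin, BaseEstimator):
    """Inverse-regression age calibration for a single biomarker.

    scikit-learn-style estimator: ``fit(X, y)`` regresses the biomarker
    (single column of ``X``) on chronological age ``y`` and stores the
    selected family; ``predict(X)`` inverts the fit, returning the partial
    biological age implied by each measurement.

    Parameters
    ----------
    family : str
        One of ``linear``, ``exponential``, ``polynomial2`` or ``auto``
        (fit all three, keep linear unless another family improves r2 by
        more than ``improvement_threshold``).
    decimals : int
        Coefficient rounding used by the published/inverted form.
    """

    def __init__(self, family: str = "auto", improvement_threshold: float = 0.02,
                 decimals: int = 4):
        self.family = family
        self.improvement_threshold = improvement_threshold
        self.decimals = decimals

    def fit(self, X, y) -> "BiomarkerAgeModel":
        values = np.asarray(X, dtype=float).reshape(len(y), -1)
        if values.shape[1] != 1:
            raise ValueError("BiomarkerAgeModel handles exactly one biomarker column")
        ca = np.asarray(y, dtype=float)
        if self.family == "auto":
            candidates = fit_candidates(ca, values[:, 0], decimals=self.decimals)
            self.model_ = select_family(candidates, self.improvement_threshold)
            self.candidates_ = candidates
        else:
            self.model_ = fit_regression(ca, values[:, 0], self.family, self.decimals)
            self.candidates_ = {self.family: self.model_}
        self.family_ = self.model_.family
        self.n_features_in_ = 1
        return self

    def predict(self, X) -> np.ndarray:
        values = np.asarray(X, dtype=float).reshape(-1)
        return np.array([self.model_.invert(v) for v in values])

    def estimate_age(self, values) -> tuple[np.ndarray, np.ndarray]:
        """Like predict, also returning the per-value extrapolation flags."""
        pairs = [self.model_.invert(v, with_flag=True) for v in np.asarray(values, float).ravel()]
        bap = np.array([p[0] for p in pairs])
        flags = np.array([p[1] for p in pairs], dtype=bool)
        return bap, flags
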