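"""Achievable per-biomarker accuracy of a partial-biological-age estimate.

A biomarker can only date a subject as finely as its measurement method can
resolve its age-related change.  If a marker changes by ``change`` units
over a ``reference_interval`` of years and the instrument resolves
``instrument_accuracy`` units, then ``change / instrument_accuracy`` units
are resolvable across the interval, and the interval divided by that count
is the accuracy, in years, of the partial biological age read off this
marker.  Example: systolic pressure rising 40 mmHg over 50 years measured
to 5 mmHg resolves 40/5 = 8 units, i.e. 50/8 = 6.25 -> displayed 6.2 years.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence, TYPE_CHECKING

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .cohort import BiomarkerSpec, CohortTable, specs_by_name

if TYPE_CHECKING:  # pragma: no cover
    from .regression import RegressionModel

logger = logging.getLogger("bioage")

__all__ = [
    "AccuracyReport", "accuracy_in_years", "display_accuracy",
    "empirical_change", "accuracy_report", "screen_by_accuracy",
    "AccuracyScreen",
]


@dataclass
class AccuracyReport:
    """Per-biomarker resolvable units and accuracy-in-years.

    ``units_resolved[bm] = reference_change / instrument_accuracy`` and
    ``accuracy_years[bm] = reference_interval / units_resolved[bm]``;
    ``source`` records whether the change came from metadata or was
    estimated empirically from a fitted age regression.
    """

    units_resolved: dict[str, float] = field(default_factory=dict)
    accuracy_years: dict[str, float] = field(default_factory=dict)
    source: dict[str, str] = field(default_factory=dict)
    rejected: list[tuple[str, float]] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        names = sorted(set(self.units_resolved) | set(self.accuracy_years))
        return pd.DataFrame({
            "units_resolved": [self.units_resolved.get(n, float("nan")) for n in names],
            "accuracy_years": [self.accuracy_years.get(n, float("nan")) for n in names],
            "source": [self.source.get(n, "") for n in names],
        }, index=pd.Index(names, name="biomarker"))

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path)


def accuracy_in_years(change: float, interval: float,
                      instrument_accuracy: float) -> tuple[float, float]:
    """Resolvable units across the interval and the accuracy in years.

    All three inputs must be positive (in the biomarker's own units for
    ``change``/``instrument_accuracy``, years for ``interval``).  Full
    precision is returned; use :func:`display_accuracy` for the one-decimal
    display form.
    """
    if change <= 0 or interval <= 0 or instrument_accuracy <= 0:
        raise ValueError("change, interval and instrument_accuracy must all be > 0")
    units_resolved = change / instrument_accuracy
    return units_resolved, interval / units_resolved


def display_accuracy(accuracy_years: float) -> float:
    """Truncate to one decimal place for display (6.25 -> 6.2).

    Screening always uses the full-precision value; truncation is display
    only.
    """
    return math.floor(accuracy_years * 10.0) / 10.0


def empirical_change(table: CohortTable, biomarker: str,
                     model: "RegressionModel | None" = None,
                     window: tuple[float, float] | None = None,
                     ) -> tuple[float, float]:
    """Estimate a biomarker's change over an age window from its regression.

    The change is |f(end) - f(start)| of the fitted biomarker-vs-age curve;
    the window defaults to the observed chronological-age range.
    """
    if model is None:
        raise ValueError(
            f"no age regression available for {biomarker}; supply reference_change "
            "metadata or fit a regression first")
    ca, v = table.complete_pairs(biomarker)
    if window is None:
        window = (float(ca.min()), float(ca.max()))
    lo, hi = window
    inside = (ca >= lo) & (ca <= hi)
    if inside.sum() < 2:
        raise ValueError(f"fewer than 2 observations of {biomarker} in {window}")
    change = abs(float(model.predict(np.array([hi]))[0] - model.predict(np.array([lo]))[0]))
    return change, hi - lo


def accuracy_report(specs: Sequence[BiomarkerSpec] | Mapping[str, BiomarkerSpec] | None,
                    table: CohortTable | None = None,
                    models: Mapping[str, "RegressionModel"] | None = None,
                    biomarkers: Sequence[str] | None = None) -> AccuracyReport:
    """Build the accuracy table from metadata, falling back to empirical change.

    A biomarker with full metadata (instrument accuracy + reference change +
    interval) is scored from metadata.  With instrument accuracy only, the
    change over the observed age range is taken from its fitted regression
    when one is supplied.  Without instrument accuracy the biomarker stays
    unscored (accuracy metadata is optional).
    """
    by_name = specs_by_name(specs)
    names = list(biomarkers) if biomarkers is not None else (
        table.biomarkers if table is not None else list(by_name))
    report = AccuracyReport()
    for name in names:
        spec = by_name.get(name)
        if spec is None or spec.instrument_accuracy is None:
            continue
        if spec.reference_change is not None:
            change, interval = spec.reference_change, spec.reference_interval
            source = "metadata"
        elif table is not None and models is not None and name in models:
            try:
                change, interval = empirical_change(table, name, models[name])
            except ValueError:
                continue
            source = "empirical"
        else:
            continue
        # a flat marker resolves (numerically) zero units; unusable, flagged
        if change <= 1e-9 * spec.instrument_accuracy:
            logger.warning("accuracy: %s has no age-related change; flagged", name)
            report.source[name] = source
            continue
        units, years = accuracy_in_years(change, interval, spec.instrument_accuracy)
        report.units_resolved[name] = units
        report.accuracy_years[name] = years
        report.source[name] = source
    return report


def screen_by_accuracy(report: AccuracyReport, max_years: float,
                       candidates: Sequence[str] | None = None) -> list[str]:
    """Reject biomarkers whose accuracy-in-years exceeds ``max_years``.

    The comparison is strict and uses full precision.  Biomarkers with no
    defined accuracy pass with a warning, because metadata is optional.
    """
    if max_years <= 0:
        raise ValueError("max_years must be > 0")
    names = list(candidates) if candidates is not None else sorted(report.accuracy_years)
    retained = []
    for name in names:
        years = report.accuracy_years.get(name)
        if years is None:
            logger.warning("accuracy: no accuracy defined for %s; retained", name)
            retained.append(name)
        elif years > max_years:
            report.rejected.append((name, years))
            logger.info("step 3: rejected %s (accuracy %.2f y > %.2f y)",
                        name, years, max_years)
        else:
            retained.append(name)
    return retained


class AccuracyScreen(TransformerMixin, BaseEstimator):
    """Transformer dropping biomarkers that cannot date a subject finely enough.

    ``specs`` is the biomarker metadata (list of :class:`BiomarkerSpec` or a
    name -> spec mapping); columns without metadata are retained.
    """

    def __init__(self, specs=None, max_years: float = 10.0):
        self.specs = specs
        self.max_years = max_years

    def fit(self, X: pd.DataFrame, y=None) -> "AccuracyScreen":
        X = pd.DataFrame(X)
        self.report_ = accuracy_report(self.specs, biomarkers=list(X.columns))
        self.retained_ = screen_by_accuracy(self.report_, self.max_years,
                                            candidates=list(X.columns))
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return pd.DataFrame(X)[self.retained_]
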