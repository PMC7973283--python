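"""Panel assembly: weighted biological age and cohort quality statistics.

Each panel member contributes a partial biological age BAp (its measured
value pushed through the member's inverted age regression).  The panel's
biological age offset for a subject is the weighted mean of the available
member deviations:

    BA - CA = ( sum_i  w_i * (BAp_i - CA) ) / D

where the divisor D is, by default, the count of available members
(published panel formulas divide by the member count, e.g. /5 for a
five-marker panel) or optionally the sum of the available weights — the
statistically conventional weighted mean.  Weights w lie in (0, 1]; by
default w_i = |r(BM_i, CA)| rounded to two decimals.

Cohort quality is summarised by the mean and sample standard deviation of
BA - CA and the Pearson correlation of BA with CA, computed after trimming
the configured number of extreme BA values; sigma below 10 years is the
conventional acceptability gate.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import CohortTable
from .correlation import CorrelationReport
from .outliers import OutlierPolicy, trim_extreme_ba
from .regression import RegressionModel, _trim

logger = logging.getLogger("bioage")

__all__ = ["PanelModel", "BAResult", "CohortStats", "compute_ba",
           "cohort_statistics", "default_weights", "render_formula",
           "parse_formula"]


@dataclass
class PanelModel:
    """Selected biomarkers with weights and inverse age regressions."""

    members: list[str]
    weights: dict[str, float]
    inverses: dict[str, RegressionModel]
    divisor_convention: str = "count"  # "count" (printed form) or "weight_sum"
    min_availability: float = 0.5

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("a panel needs at least one member")
        for name in self.members:
            w = self.weights.get(name)
            if w is None or not 0 < w <= 1:
                raise ValueError(f"weight for {name} must be in (0, 1], got {w}")
            model = self.inverses.get(name)
            if model is None:
                raise ValueError(f"no inverse regression for {name}")
            if not model.is_monotone():
                raise ValueError(f"inverse for {name} is not monotone; unusable")
        if self.divisor_convention not in ("count", "weight_sum"):
            raise ValueError("divisor_convention must be 'count' or 'weight_sum'")


@dataclass
class BAResult:
    """Per-subject partial and aggregate biological ages.

    ``bap`` is subjects x members (NaN where the biomarker was missing or
    not invertible at that value); ``ba`` is NaN for subjects below the
    panel's minimum availability.  ``cohort_stats`` is attached by
    :func:`cohort_statistics`.
    """

    bap: pd.DataFrame
    ba: pd.Series
    ba_minus_ca: pd.Series
    ca: pd.Series
    n_available: pd.Series
    extrapolated: pd.DataFrame
    n_excluded: int = 0
    cohort_stats: "CohortStats | None" = None

    def to_frame(self) -> pd.DataFrame:
        frame = self.bap.add_prefix("BAp_")
        frame.insert(0, "CA", self.ca)
        frame["n_available"] = self.n_available
        frame["BA"] = self.ba
        frame["BA_minus_CA"] = self.ba_minus_ca
        return frame


@dataclass(frozen=True)
class CohortStats:
    mean: float
    sigma: float
    r_ba_ca: float
    n: int
    sigma_limit: float = 10.0

    @property
    def sigma_ok(self) -> bool:
        return self.sigma < self.sigma_limit

    def as_dict(self) -> dict:
        return {"mean_ba_minus_ca": self.mean, "sigma_ba_minus_ca": self.sigma,
                "r_ba_ca": self.r_ba_ca, "n": self.n,
                "sigma_limit": self.sigma_limit, "sigma_ok": self.sigma_ok}


def compute_ba(table: CohortTable, panel: PanelModel) -> BAResult:
    """Per-subject BAp for every panel member and the weighted BA.

    A subject's BA is defined only when the fraction of available members
    reaches the panel's ``min_availability``; subjects with no BA are
    excluded from cohort statistics (their count is logged).
    """
    members = panel.members
    bap = pd.DataFrame(index=table.subjects, columns=members, dtype=float)
    flags = pd.DataFrame(False, index=table.subjects, columns=members)
    for name in members:
        values = table.values(name)
        pairs = [panel.inverses[name].invert(v, with_flag=True) if np.isfinite(v)
                 else (np.nan, False) for v in values.to_numpy()]
        bap[name] = [p[0] for p in pairs]
        flags[name] = [p[1] for p in pairs]

    w = np.array([panel.weights[m] for m in members])
    available = bap.notna().to_numpy()
    n_avail = available.sum(axis=1)
    dev = (bap.to_numpy() - table.ca.to_numpy()[:, None])
    weighted = np.where(available, dev * w[None, :], 0.0).sum(axis=1)
    if panel.divisor_convention == "count":
        divisor = n_avail.astype(float)
    else:
        divisor = np.where(available, w[None, :], 0.0).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        ba_minus_ca = np.where(n_avail > 0, weighted / np.where(divisor > 0, divisor, np.nan),
                               np.nan)
    enough = n_avail >= panel.min_availability * len(members)
    ba_minus_ca = np.where(enough & (n_avail > 0), ba_minus_ca, np.nan)

    ba = pd.Series(table.ca.to_numpy() + ba_minus_ca, index=table.subjects, name="BA")
    n_excluded = int(np.isnan(ba_minus_ca).sum())
    if n_excluded:
        logger.info("compute_ba: %d subject(s) without a defined BA", n_excluded)
    return BAResult(
        bap=bap, ba=ba,
        ba_minus_ca=pd.Series(ba_minus_ca, index=table.subjects, name="BA_minus_CA"),
        ca=table.ca.copy(),
        n_available=pd.Series(n_avail, index=table.subjects, name="n_available"),
        extrapolated=flags, n_excluded=n_excluded)


def cohort_statistics(result: BAResult, trim: OutlierPolicy | int = 0,
                      sigma_limit: float = 10.0) -> CohortStats:
    """Mean/σ of BA−CA and r(BA, CA) after trimming extreme BA values.

    Trimming affects only these statistics — each subject keeps their
    individual BA in the result.  Requires at least 3 subjects with a
    defined BA after trimming.
    """
    n_trim = trim.n_trim_ba if isinstance(trim, OutlierPolicy) else int(trim)
    defined = result.ba.dropna()
    if len(defined) - 2 * n_trim < 3:
        raise ValueError("fewer than 3 subjects with defined BA after trimming")
    kept = trim_extreme_ba(defined, n_trim)
    ba = result.ba.loc[kept]
    ca = result.ca.loc[kept]
    diff = ba - ca
    sigma = float(diff.std(ddof=1))
    if np.ptp(ba.to_numpy()) == 0 or np.ptp(ca.to_numpy()) == 0:
        r = float("nan")
    else:
        r = float(stats.pearsonr(ba.to_numpy(), ca.to_numpy())[0])
    stats_ = CohortStats(mean=float(diff.mean()), sigma=sigma, r_ba_ca=r,
                         n=len(kept), sigma_limit=sigma_limit)
    result.cohort_stats = stats_
    return stats_


def default_weights(report: CorrelationReport, members: Sequence[str],
                    overrides: Mapping[str, float] | None = None) -> dict[str, float]:
    """w_i = |r(BM_i, CA)| rounded to 2 decimals, floored at 0.01.

    User-supplied ``overrides`` take precedence member by member.  An
    undefined correlation with no override is an error.
    """
    weights: dict[str, float] = {}
    for name in members:
        if overrides is not None and name in overrides:
            weights[name] = float(overrides[name])
            continue
        r = report.r_with_ca.get(name, float("nan"))
        if np.isnan(r):
            raise ValueError(f"no defined r(CA) for {name}; supply a weight")
        weights[name] = max(0.01, float(np.round(abs(r), 2)))
    return weights


# -- formula rendering / parsing ---------------------------------------


def render_formula(panel: PanelModel, decimals: int | None = None) -> str:
    """Render the panel in the printed style::

        BA-CA = (0.83 × [-44.384 + 0.1235 × PWVe - CA] + ...)/5
    """
    terms = []
    for name in panel.members:
        model = panel.inverses[name]
        terms.append(f"{panel.weights[name]:.2f} × [{model.render_inverse(name)} - CA]")
    if panel.divisor_convention == "count":
        divisor = str(len(panel.members))
    else:
        divisor = _trim(sum(panel.weights[m] for m in panel.members), 4)
    return "BA-CA = (" + " +\n".join(terms) + f")/{divisor}"


_TERM = re.compile(
    r"(?P<w>[-+]?\d+(?:\.\d+)?)\s*×\s*\[\s*(?P<a>[-+]?\d+(?:\.\d+)?)\s*"
    r"(?P<sign>[-+])\s*(?P<b>\d+(?:\.\d+)?)\s*×\s*(?P<name>[A-Za-z_][\w]*)\s*-\s*CA\s*\]")


def parse_formula(text: str, ca_range: tuple[float, float] = (20.0, 70.0),
                  ) -> PanelModel:
    """Parse a rendered linear-panel formula back into a PanelModel.

    Supports linear terms only (the printed form); used to round-trip
    rendered formulas against :func:`compute_ba`.
    """
    m = re.search(r"BA-CA\s*=\s*\((?P<body>.*)\)\s*/\s*(?P<div>[\d.]+)\s*$",
                  text.replace("\n", " "), flags=re.S)
    if not m:
        raise ValueError("unrecognised formula layout")
    members, weights, inverses = [], {}, {}
    for t in _TERM.finditer(m.group("body")):
        name = t.group("name")
        b = float(t.group("b")) * (-1.0 if t.group("sign") == "-" else 1.0)
        members.append(name)
        weights[name] = float(t.group("w"))
        inverses[name] = RegressionModel.from_inverse_linear(
            float(t.group("a")), b, ca_range=ca_range)
    if not members:
        raise ValueError("no recognisable terms in formula")
    divisor = float(m.group("div"))
    convention = "count" if abs(divisor - len(members)) < 1e-9 else "weight_sum"
    return PanelModel(members=members, weights=weights, inverses=inverses,
                      divisor_convention=convention)
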