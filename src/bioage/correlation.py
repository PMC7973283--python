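"""Correlation screening and redundancy pruning.

Biomarkers of aging are screened on the magnitude of their Pearson
correlation with chronological age (so markers that decrease with age, such
as lung capacity or static balancing, are retained), and candidate panels
are pruned of redundant members using the biomarker-by-biomarker
cross-correlation matrix.  All correlations are computed on
pairwise-complete observations, with the per-pair count recorded, because a
cohort row need not carry a value for every biomarker.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .cohort import CohortTable

logger = logging.getLogger("bioage")

__all__ = [
    "CorrelationReport", "correlation_report", "correlate_with_ca",
    "cross_correlations", "reject_low_correlation", "prune_redundant",
    "CorrelationAgeScreen", "RedundancyPruner",
]


@dataclass
class CorrelationReport:
    """Pairwise-complete correlation summary for one cohort.

    ``r_with_ca`` maps biomarker -> Pearson r with chronological age (NaN
    when undefined); ``pair_r`` / ``n_pairs`` are the symmetric biomarker
    cross-correlation matrix and its per-pair complete-observation counts.
    Rejections performed against this report are appended to
    ``rejected_low`` / ``rejected_redundant``.
    """

    r_with_ca: dict[str, float]
    n_with_ca: dict[str, int]
    pair_r: pd.DataFrame
    n_pairs: pd.DataFrame
    rejected_low: list[tuple[str, float]] = field(default_factory=list)
    rejected_redundant: list[tuple[str, str, float]] = field(default_factory=list)

    def to_csv(self, path: str | Path) -> None:
        """Export the square, labeled, symmetric cross-correlation matrix."""
        self.pair_r.to_csv(path)


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson r; NaN when fewer than 2 points or zero variance."""
    if len(x) < 2:
        return float("nan")
    xc, yc = x - x.mean(), y - y.mean()
    den = np.sqrt((xc * xc).sum() * (yc * yc).sum())
    if den == 0:
        return float("nan")
    return float(np.clip((xc * yc).sum() / den, -1.0, 1.0))


def correlate_with_ca(table: CohortTable) -> dict[str, tuple[float, int]]:
    """Pearson correlation of each biomarker with chronological age.

    Computed over pairwise-complete observations.  Biomarkers with fewer
    than 2 complete pairs or zero variance are reported as undefined (NaN),
    never as 0 and never silently dropped.
    """
    out: dict[str, tuple[float, int]] = {}
    for name in table.biomarkers:
        ca, v = table.complete_pairs(name)
        out[name] = (_pearson(ca, v), len(v))
    return out


def cross_correlations(table: CohortTable) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise-complete biomarker cross-correlation matrix and pair counts."""
    r = table.data.corr(method="pearson", min_periods=2)
    notna = table.data.notna().astype(int)
    n = notna.T @ notna
    return r, n


def correlation_report(table: CohortTable) -> CorrelationReport:
    with_ca = correlate_with_ca(table)
    pair_r, n_pairs = cross_correlations(table)
    return CorrelationReport(
        r_with_ca={k: v[0] for k, v in with_ca.items()},
        n_with_ca={k: v[1] for k, v in with_ca.items()},
        pair_r=pair_r, n_pairs=n_pairs)


def reject_low_correlation(report: CorrelationReport, threshold: float,
                           candidates: Sequence[str] | None = None) -> list[str]:
    """Reject biomarkers with |r(BM, CA)| below ``threshold`` or undefined r.

    Returns the retained biomarkers in input order; removals are logged on
    the report with their r values.
    """
    if not 0 <= threshold <= 1:
        raise ValueError("threshold must be in [0, 1]")
    names = list(candidates) if candidates is not None else list(report.r_with_ca)
    retained = []
    for name in names:
        r = report.r_with_ca[name]
        if np.isnan(r) or abs(r) < threshold:
            report.rejected_low.append((name, r))
            logger.info("step 1: rejected %s (r with CA = %.3f)", name, r)
        else:
            retained.append(name)
    return retained


def prune_redundant(report: CorrelationReport, retained: Sequence[str],
                    cross_threshold: float,
                    accuracy: Mapping[str, float] | None = None) -> list[str]:
    """Drop one member of each highly cross-correlated biomarker pair.

    Pairs with |r| >= ``cross_threshold`` are processed in descending |r|.
    From each pair still fully retained, the dropped member is the one with
    the worse (larger) accuracy-in-years when both accuracies are known,
    otherwise the one with the smaller |r with CA|; remaining ties are broken
    lexicographically (the later name is dropped).
    """
    if not 0 < cross_threshold <= 1:
        raise ValueError("cross_threshold must be in (0, 1]")
    keep = list(retained)
    pairs = []
    for i, a in enumerate(keep):
        for b in keep[i + 1:]:
            r = report.pair_r.at[a, b] if a in report.pair_r.index and b in report.pair_r.columns else float("nan")
            if not np.isnan(r) and abs(r) >= cross_threshold:
                pairs.append((a, b, float(r)))
    pairs.sort(key=lambda p: (-abs(p[2]), p[0], p[1]))

    dropped: set[str] = set()
    for a, b, r in pairs:
        if a in dropped or b in dropped:
            continue
        loser = _pick_loser(a, b, report, accuracy)
        winner = b if loser == a else a
        dropped.add(loser)
        report.rejected_redundant.append((loser, winner, r))
        logger.info("step 2: dropped %s (redundant with %s, r = %.3f)", loser, winner, r)
    return [name for name in keep if name not in dropped]


def _pick_loser(a: str, b: str, report: CorrelationReport,
                accuracy: Mapping[str, float] | None) -> str:
    if accuracy is not None:
        aa, ab = accuracy.get(a), accuracy.get(b)
        if aa is not None and ab is not None and not np.isnan(aa) and not np.isnan(ab) and aa != ab:
            return a if aa > ab else b  # worse accuracy = more years per unit
    ra, rb = report.r_with_ca.get(a, float("nan")), report.r_with_ca.get(b, float("nan"))
    if not np.isnan(ra) and not np.isnan(rb) and abs(ra) != abs(rb):
        return a if abs(ra) < abs(rb) else b
    return max(a, b)


class CorrelationAgeScreen(TransformerMixin, BaseEstimator):
    """Feature selector keeping biomarkers well correlated with age.

    scikit-learn-style transformer: ``fit(X, y)`` computes pairwise-complete
    Pearson correlations of each column of ``X`` (a biomarker DataFrame,
    NaN = missing) with ``y`` (chronological age); ``transform`` keeps the
    columns with |r| >= ``threshold``.
    """

    def __init__(self, threshold: float = 0.3):
        self.threshold = threshold

    def fit(self, X: pd.DataFrame, y) -> "CorrelationAgeScreen":
        X = pd.DataFrame(X)
        table = CohortTable(X, pd.Series(np.asarray(y, float), index=X.index))
        self.report_ = correlation_report(table)
        self.retained_ = reject_low_correlation(self.report_, self.threshold)
        self.rejected_ = list(self.report_.rejected_low)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return pd.DataFrame(X)[self.retained_]

    def get_support(self) -> list[str]:
        return list(self.retained_)


class RedundancyPruner(TransformerMixin, BaseEstimator):
    """Drop one member of every biomarker pair with |cross-r| >= threshold."""

    def __init__(self, cross_threshold: float = 0.7,
                 accuracy: Mapping[str, float] | None = None):
        self.cross_threshold = cross_threshold
        self.accuracy = accuracy

    def fit(self, X: pd.DataFrame, y) -> "RedundancyPruner":
        X = pd.DataFrame(X)
        table = CohortTable(X, pd.Series(np.asarray(y, float), index=X.index))
        self.report_ = correlation_report(table)
        self.retained_ = prune_redundant(self.report_, list(X.columns),
                                         self.cross_threshold, self.accuracy)
        self.rejected_ = list(self.report_.rejected_redundant)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return pd.DataFrame(X)[self.retained_]
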