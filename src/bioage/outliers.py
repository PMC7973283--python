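"""Bin-wise sigma rejection of unrepresentative biomarker values.

Extreme biomarker values distort the age regressions, so within each
10-year age bin, values further than k standard deviations from the bin
mean are masked (treated as missing downstream).  Bins are half-open
[lo, lo+10) intervals anchored at multiples of 10 years; bin statistics use
the sample (n-1) standard deviation because bins are small.  Exactly one
pass is applied — recomputing bin statistics after masking and filtering
again would not be reproducible.  Chronological age itself is never masked.

Separately, the n largest and n smallest biological-age values can be
trimmed from the cohort-level statistics (not from individual reports).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .cohort import CohortTable

logger = logging.getLogger("bioage")

__all__ = ["OutlierPolicy", "reject_bm_outliers", "trim_extreme_ba",
           "AgeBinOutlierMasker", "BIN_WIDTH"]

BIN_WIDTH = 10.0


@dataclass(frozen=True)
class OutlierPolicy:
    """Sigma thresholds per 10-year age bin plus the BA trim count.

    ``sigmas_per_bin`` is either one k for every bin or a mapping from the
    bin's lower edge (a multiple of 10) to k; every k must be positive.
    ``n_trim_ba`` is the count of maximum AND minimum biological-age values
    excluded from cohort statistics.
    """

    sigmas_per_bin: float | Mapping[int, float] = 3.0
    n_trim_ba: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.sigmas_per_bin, Mapping):
            if any(k <= 0 for k in self.sigmas_per_bin.values()):
                raise ValueError("every per-bin sigma multiplier must be > 0")
        elif self.sigmas_per_bin <= 0:
            raise ValueError("sigma multiplier must be > 0")
        if self.n_trim_ba < 0:
            raise ValueError("n_trim_ba must be >= 0")

    def k_for_bin(self, bin_lo: float) -> float:
        if isinstance(self.sigmas_per_bin, Mapping):
            return float(self.sigmas_per_bin.get(int(bin_lo), 3.0))
        return float(self.sigmas_per_bin)


def bin_lower_edges(ca: np.ndarray) -> np.ndarray:
    return np.floor(np.asarray(ca, float) / BIN_WIDTH) * BIN_WIDTH


def reject_bm_outliers(table: CohortTable,
                       biomarkers: Sequence[str] | None = None,
                       policy: OutlierPolicy | None = None,
                       ) -> tuple[CohortTable, pd.DataFrame]:
    """Mask bin-wise extreme values of the given biomarkers (single pass).

    Within each 10-year bin holding at least 3 non-missing values, cells
    with |value - bin mean| > k * bin SD are set to missing.  Returns the
    masked cohort and a mask report with one row per masked cell:
    (subject, biomarker, value, bin, bin_mean, bin_sd, k, decision).
    """
    policy = policy or OutlierPolicy()
    names = list(biomarkers) if biomarkers is not None else table.biomarkers
    data = table.data.copy()
    edges = bin_lower_edges(table.ca.to_numpy())
    rows = []
    for name in names:
        col = data[name]
        for lo in np.unique(edges):
            in_bin = (edges == lo) & col.notna().to_numpy()
            if in_bin.sum() < 3:
                continue
            vals = col.to_numpy()[in_bin]
            mean, sd = float(vals.mean()), float(vals.std(ddof=1))
            k = policy.k_for_bin(lo)
            bad = np.abs(vals - mean) > k * sd
            if not bad.any():
                continue
            subjects = col.index.to_numpy()[in_bin][bad]
            for subj, value in zip(subjects, vals[bad]):
                rows.append({"subject": subj, "biomarker": name, "value": value,
                             "bin": f"[{lo:g}, {lo + BIN_WIDTH:g})",
                             "bin_mean": mean, "bin_sd": sd, "k": k,
                             "decision": "masked"})
            data.loc[subjects, name] = np.nan
            logger.info("outliers: masked %d cell(s) of %s in bin [%g, %g)",
                        int(bad.sum()), name, lo, lo + BIN_WIDTH)
    report = pd.DataFrame(rows, columns=["subject", "biomarker", "value", "bin",
                                         "bin_mean", "bin_sd", "k", "decision"])
    return table.with_data(data), report


def trim_extreme_ba(ba: pd.Series, n_trim: int) -> pd.Index:
    """Subjects retained after dropping the n largest and n smallest BA values.

    Ties are broken by subject order (stable sort).  Requires
    2 * n_trim < number of defined BA values.
    """
    ba = ba.dropna()
    if 2 * n_trim >= len(ba):
        raise ValueError(f"cannot trim {n_trim} from both ends of {len(ba)} values")
    if n_trim == 0:
        return ba.index
    order = np.argsort(ba.to_numpy(), kind="stable")
    keep = order[n_trim:len(ba) - n_trim]
    return ba.index[np.sort(keep)]


class AgeBinOutlierMasker(TransformerMixin, BaseEstimator):
    """Transformer form of the bin-wise sigma mask.

    ``fit(X, y)`` records the age bins and bin statistics of the training
    cohort; ``transform(X)`` masks the same-shaped table (the mask is
    computed once from the fitted statistics, never iterated).
    """

    def __init__(self, sigmas_per_bin: float | Mapping[int, float] = 3.0):
        self.sigmas_per_bin = sigmas_per_bin

    def fit(self, X: pd.DataFrame, y) -> "AgeBinOutlierMasker":
        X = pd.DataFrame(X)
        table = CohortTable(X, pd.Series(np.asarray(y, float), index=X.index))
        policy = OutlierPolicy(sigmas_per_bin=self.sigmas_per_bin)
        masked, report = reject_bm_outliers(table, policy=policy)
        self.mask_report_ = report
        self._masked = masked.data
        self._index = X.index
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        X = pd.DataFrame(X)
        if not X.index.equals(self._index):
            raise ValueError("AgeBinOutlierMasker masks the cohort it was fitted on")
        return self._masked.copy()
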