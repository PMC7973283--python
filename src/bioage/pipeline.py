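"""Seven-step optimization of an aging-biomarker panel.

Step order is fixed for reproducibility:

1. reject biomarkers poorly correlated with chronological age;
2. prune redundant (highly cross-correlated) biomarkers;
3. reject biomarkers whose achievable accuracy-in-years is too coarse;
4. fit/select the age regressions, mask bin-wise outlier values, refit,
   round coefficients, and drop non-invertible fits;
5. compute the weighted biological age, trim extreme BA values, and check
   sigma(BA-CA) and r(BA, CA) against the configured limits;
6. apply researcher-supplied criteria (built-in: an interindividual-range
   limit per biomarker, the classical reason to drop body weight);
7. assemble and render the final panel, recomputing the statistics when
   step 6 changed the membership.

Every removal is logged as a step-attributed record, so each biomarker
absent from the final panel is explained by at least one record.  A panel
whose statistics violate the step-5 limits is reported as rejected, not
silently replaced; combinatorial search over alternative subsets is out of
scope by design.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from typing import Any, Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin

from .accuracy import AccuracyReport, accuracy_report, screen_by_accuracy
from .cohort import BiomarkerSpec, CohortTable, specs_by_name
from .correlation import (CorrelationReport, correlation_report,
                          prune_redundant, reject_low_correlation)
from .outliers import OutlierPolicy, reject_bm_outliers
from .panel import (BAResult, CohortStats, PanelModel, cohort_statistics,
                    compute_ba, default_weights, render_formula)
from .regression import RegressionModel, fit_candidates, select_family

logger = logging.getLogger("bioage")

__all__ = ["PipelineConfig", "StepLog", "PipelineResult", "EmptyPanelError",
           "run", "run_stratified", "apply_user_criterion", "PanelOptimizer"]


class EmptyPanelError(RuntimeError):
    """Every biomarker was rejected; carries the step log explaining why."""

    def __init__(self, message: str, log: "StepLog"):
        super().__init__(message)
        self.log = log


@dataclass
class PipelineConfig:
    """Thresholds mirroring the optimizer's dialog parameters.

    ``task`` chooses the default accuracy gate: population cross-sectional
    studies tolerate 10 years, longitudinal follow-up of one person needs
    5 years (interindividual dispersion cancels there, so only instrument
    resolution limits the estimate).
    """

    ca_correlation_threshold: float = 0.3
    cross_correlation_threshold: float = 0.7
    max_accuracy_years: float | None = None
    task: str = "cross_sectional"  # or "longitudinal"
    sigma_policy: OutlierPolicy = field(default_factory=OutlierPolicy)
    coefficient_decimals: int = 4
    ba_ca_sigma_limit: float = 10.0
    ba_ca_r_limits: tuple[float, float] = (0.5, 1.0)  # not stated in print; config default
    improvement_threshold: float = 0.02
    divisor_convention: str = "count"
    min_availability: float = 0.5
    weights: Mapping[str, float] | None = None
    range_limits: Mapping[str, float] | None = None
    mode: str = "automatic"  # or "interactive" (CLI prompts produce a config)
    group_stratify: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.ca_correlation_threshold <= 1:
            raise ValueError("ca_correlation_threshold must be in [0, 1]")
        if not 0 < self.cross_correlation_threshold <= 1:
            raise ValueError("cross_correlation_threshold must be in (0, 1]")
        if self.max_accuracy_years is not None and self.max_accuracy_years <= 0:
            raise ValueError("max_accuracy_years must be > 0")
        if self.task not in ("cross_sectional", "longitudinal"):
            raise ValueError("task must be 'cross_sectional' or 'longitudinal'")
        if self.coefficient_decimals < 0:
            raise ValueError("coefficient_decimals must be >= 0")

    @property
    def accuracy_gate(self) -> float:
        if self.max_accuracy_years is not None:
            return self.max_accuracy_years
        return 5.0 if self.task == "longitudinal" else 10.0

    def as_dict(self) -> dict[str, Any]:
        d = asdict(self)
        d["sigma_policy"] = {"sigmas_per_bin": self.sigma_policy.sigmas_per_bin
                             if not isinstance(self.sigma_policy.sigmas_per_bin, Mapping)
                             else dict(self.sigma_policy.sigmas_per_bin),
                             "n_trim_ba": self.sigma_policy.n_trim_ba}
        d["max_accuracy_years"] = self.accuracy_gate
        d["weights"] = None if self.weights is None else dict(self.weights)
        d["range_limits"] = None if self.range_limits is None else dict(self.range_limits)
        d["ba_ca_r_limits"] = list(self.ba_ca_r_limits)
        return d


@dataclass
class StepLog:
    """Ordered, auditable record of every pipeline action."""

    records: list[dict[str, Any]] = field(default_factory=list)

    def record(self, step: int, action: str, target: str | None = None,
               evidence: Mapping[str, Any] | None = None,
               threshold: Any = None) -> None:
        self.records.append({
            "step": step, "action": action, "target": target,
            "evidence": dict(evidence or {}), "threshold": threshold,
        })

    def rejections(self) -> dict[str, int]:
        """Biomarker -> step at which it was rejected (first attribution)."""
        out: dict[str, int] = {}
        for rec in self.records:
            if rec["action"].startswith("reject") and rec["target"] is not None:
                out.setdefault(rec["target"], rec["step"])
        return out

    def to_list(self) -> list[dict[str, Any]]:
        return [dict(r) for r in self.records]


@dataclass
class PipelineResult:
    panel: PanelModel | None
    result: BAResult | None
    log: StepLog
    accepted: bool
    stats: CohortStats | None
    correlation: CorrelationReport
    accuracy: AccuracyReport
    models: dict[str, RegressionModel]
    formula: str | None
    config: PipelineConfig
    n_input_biomarkers: int = 0

    def report(self) -> dict[str, Any]:
        """Machine-readable report; deterministic for fixed inputs and config."""
        panel = None
        if self.panel is not None:
            panel = {
                "members": list(self.panel.members),
                "weights": {m: self.panel.weights[m] for m in self.panel.members},
                "divisor_convention": self.panel.divisor_convention,
                "models": {m: {"family": self.panel.inverses[m].family,
                               "coefficients": list(self.panel.inverses[m].coefficients),
                               "rounded_coefficients":
                                   list(self.panel.inverses[m].rounded_coefficients),
                               "r2": self.panel.inverses[m].r2}
                           for m in self.panel.members},
            }
        return {
            "status": ("no panel" if self.panel is None
                       else "accepted" if self.accepted else "rejected"),
            "config": self.config.as_dict(),
            "steps": self.log.to_list(),
            "panel": panel,
            "formula": self.formula,
            "statistics": None if self.stats is None else self.stats.as_dict(),
            "r_with_ca": dict(self.correlation.r_with_ca),
            "accuracy_years": dict(self.accuracy.accuracy_years),
        }


def apply_user_criterion(retained: Sequence[str],
                         predicate: Callable[[str, dict[str, Any]], bool],
                         evidence: Mapping[str, dict[str, Any]],
                         log: StepLog | None = None,
                         description: str = "user criterion") -> list[str]:
    """Keep the biomarkers for which ``predicate(name, evidence)`` is true.

    The predicate must be total over the retained set; removals are logged
    as step-6 rejections.
    """
    kept = []
    for name in retained:
        ev = dict(evidence.get(name, {}))
        if predicate(name, ev):
            kept.append(name)
        else:
            if log is not None:
                log.record(6, "reject_user_criterion", name, ev, description)
            logger.info("step 6: rejected %s (%s)", name, description)
    return kept


def _range_evidence(table: CohortTable, names: Sequence[str]) -> dict[str, dict]:
    out = {}
    for name in names:
        v = table.values(name).dropna()
        out[name] = {"min": float(v.min()), "max": float(v.max()),
                     "range": float(v.max() - v.min())} if len(v) else {"range": float("nan")}
    return out


def run(table: CohortTable,
        specs: Sequence[BiomarkerSpec] | Mapping[str, BiomarkerSpec] | None = None,
        config: PipelineConfig | None = None,
        user_criterion: Callable[[str, dict[str, Any]], bool] | None = None,
        ) -> PipelineResult:
    """Execute the seven optimization steps on one cohort."""
    config = config or PipelineConfig()
    log = StepLog()
    by_name = specs_by_name(specs)

    # step 1: correlation with chronological age
    corr = correlation_report(table)
    retained = reject_low_correlation(corr, config.ca_correlation_threshold)
    for name, r in corr.rejected_low:
        log.record(1, "reject_low_correlation", name, {"r_with_ca": r},
                   config.ca_correlation_threshold)
    _check_nonempty(retained, 1, log)

    # metadata-based accuracy, needed both as the step-2 tie-break and at step 3
    acc = accuracy_report(by_name, biomarkers=table.biomarkers)

    # step 2: redundancy pruning
    retained = prune_redundant(corr, retained, config.cross_correlation_threshold,
                               accuracy=acc.accuracy_years)
    for dropped, kept, r in corr.rejected_redundant:
        log.record(2, "reject_redundant", dropped,
                   {"kept": kept, "cross_r": r}, config.cross_correlation_threshold)
    _check_nonempty(retained, 2, log)

    # step 3: accuracy-in-years gate
    retained = screen_by_accuracy(acc, config.accuracy_gate, candidates=retained)
    for name, years in acc.rejected:
        log.record(3, "reject_accuracy", name, {"accuracy_years": years},
                   config.accuracy_gate)
    _check_nonempty(retained, 3, log)

    # step 4: outlier masking, regression fits, rounding, invertibility
    masked, mask_report = reject_bm_outliers(table, retained, config.sigma_policy)
    log.record(4, "mask_outliers", None,
               {"n_masked_cells": int(len(mask_report))},
               config.sigma_policy.sigmas_per_bin
               if not isinstance(config.sigma_policy.sigmas_per_bin, Mapping)
               else dict(config.sigma_policy.sigmas_per_bin))
    models: dict[str, RegressionModel] = {}
    invertible = []
    for name in retained:
        ca, v = masked.complete_pairs(name)
        candidates = fit_candidates(ca, v, decimals=config.coefficient_decimals)
        # step 4 exists to produce inverse formulas, so only strictly
        # monotone (invertible) fits compete in the family selection
        invertible_fits = {f: m for f, m in candidates.items() if m.is_monotone()}
        if not invertible_fits:
            log.record(4, "reject_non_monotone" if candidates else "reject_unfittable",
                       name,
                       {f: m.r2 for f, m in candidates.items()}, None)
            continue
        model = select_family(invertible_fits, config.improvement_threshold)
        models[name] = model
        invertible.append(name)
        log.record(4, "fit", name, {"family": model.family, "r2": model.r2,
                                    "coefficients": list(model.rounded_coefficients)},
                   config.coefficient_decimals)
    retained = invertible
    _check_nonempty(retained, 4, log)

    # step 5: biological age, trimming, sigma and r gates
    weights = default_weights(corr, retained, overrides=config.weights)
    panel = PanelModel(members=list(retained), weights=weights,
                       inverses={m: models[m] for m in retained},
                       divisor_convention=config.divisor_convention,
                       min_availability=config.min_availability)
    result = compute_ba(masked, panel)
    stats = cohort_statistics(result, config.sigma_policy, config.ba_ca_sigma_limit)
    log.record(5, "cohort_statistics", None, stats.as_dict(), config.ba_ca_sigma_limit)

    # step 6: researcher criteria (built-in interindividual-range limit + hook)
    evidence = _range_evidence(masked, retained)
    if config.range_limits:
        limits = dict(config.range_limits)
        retained = apply_user_criterion(
            retained,
            lambda name, ev: name not in limits or ev.get("range", 0.0) <= limits[name],
            evidence, log, description="interindividual range limit")
    if user_criterion is not None:
        retained = apply_user_criterion(retained, user_criterion, evidence, log)
    _check_nonempty(retained, 6, log)

    # step 7: final assembly (recompute when step 6 changed the membership)
    if list(retained) != panel.members:
        weights = default_weights(corr, retained, overrides=config.weights)
        panel = PanelModel(members=list(retained), weights=weights,
                           inverses={m: models[m] for m in retained},
                           divisor_convention=config.divisor_convention,
                           min_availability=config.min_availability)
        result = compute_ba(masked, panel)
        stats = cohort_statistics(result, config.sigma_policy, config.ba_ca_sigma_limit)
    r_lo, r_hi = config.ba_ca_r_limits
    r_ok = (not np.isnan(stats.r_ba_ca)) and r_lo <= stats.r_ba_ca <= r_hi
    accepted = stats.sigma_ok and r_ok
    formula = render_formula(panel)
    log.record(7, "assemble_panel", None,
               {"members": list(panel.members), "accepted": accepted,
                "sigma": stats.sigma, "r_ba_ca": stats.r_ba_ca},
               {"sigma_limit": config.ba_ca_sigma_limit,
                "r_limits": list(config.ba_ca_r_limits)})
    if not accepted:
        logger.warning("panel rejected by step-5 limits: sigma=%.2f r=%.3f",
                       stats.sigma, stats.r_ba_ca)

    return PipelineResult(panel=panel, result=result, log=log, accepted=accepted,
                          stats=stats, correlation=corr, accuracy=acc, models=models,
                          formula=formula, config=config,
                          n_input_biomarkers=len(table.biomarkers))


def run_stratified(table: CohortTable, specs=None, config: PipelineConfig | None = None,
                   user_criterion=None) -> dict[str, PipelineResult]:
    """Run the pipeline independently inside each group stratum."""
    return {label: run(sub, specs, config, user_criterion)
            for label, sub in table.split_groups().items()}


def _check_nonempty(retained: Sequence[str], step: int, log: StepLog) -> None:
    if not retained:
        raise EmptyPanelError(
            f"every biomarker was rejected by step {step}; see the step log", log)


class PanelOptimizer(RegressorMixin, BaseEstimator):
    """scikit-learn estimator form of the seven-step panel optimizer.

    ``fit(X, y)`` takes a biomarker DataFrame ``X`` (NaN = missing) and
    chronological ages ``y``, selects the panel and calibrates the inverse
    regressions.  ``predict(X)`` returns each subject's biological age; under
    the printed ``count`` divisor convention BA depends on CA, so ``X`` must
    then carry the chronological-age column named ``ca_column`` (under
    ``weight_sum`` the weighted mean of partial ages is CA-free and the
    column is optional).

    Fitted attributes: ``panel_``, ``result_``, ``stats_``, ``step_log_``,
    ``accepted_``, ``report_``.
    """

    def __init__(self, ca_correlation_threshold: float = 0.3,
                 cross_correlation_threshold: float = 0.7,
                 max_accuracy_years: float | None = None,
                 task: str = "cross_sectional",
                 sigmas_per_bin: float = 3.0, n_trim_ba: int = 0,
                 coefficient_decimals: int = 4,
                 ba_ca_sigma_limit: float = 10.0,
                 ba_ca_r_limits: tuple[float, float] = (0.5, 1.0),
                 improvement_threshold: float = 0.02,
                 divisor_convention: str = "count",
                 min_availability: float = 0.5,
                 weights: Mapping[str, float] | None = None,
                 range_limits: Mapping[str, float] | None = None,
                 specs: Sequence[BiomarkerSpec] | None = None,
                 ca_column: str = "CA", seed: int = 0):
        self.ca_correlation_threshold = ca_correlation_threshold
        self.cross_correlation_threshold = cross_correlation_threshold
        self.max_accuracy_years = max_accuracy_years
        self.task = task
        self.sigmas_per_bin = sigmas_per_bin
        self.n_trim_ba = n_trim_ba
        self.coefficient_decimals = coefficient_decimals
        self.ba_ca_sigma_limit = ba_ca_sigma_limit
        self.ba_ca_r_limits = ba_ca_r_limits
        self.improvement_threshold = improvement_threshold
        self.divisor_convention = divisor_convention
        self.min_availability = min_availability
        self.weights = weights
        self.range_limits = range_limits
        self.specs = specs
        self.ca_column = ca_column
        self.seed = seed

    def _config(self) -> PipelineConfig:
        return PipelineConfig(
            ca_correlation_threshold=self.ca_correlation_threshold,
            cross_correlation_threshold=self.cross_correlation_threshold,
            max_accuracy_years=self.max_accuracy_years, task=self.task,
            sigma_policy=OutlierPolicy(self.sigmas_per_bin, self.n_trim_ba),
            coefficient_decimals=self.coefficient_decimals,
            ba_ca_sigma_limit=self.ba_ca_sigma_limit,
            ba_ca_r_limits=tuple(self.ba_ca_r_limits),
            improvement_threshold=self.improvement_threshold,
            divisor_convention=self.divisor_convention,
            min_availability=self.min_availability,
            weights=self.weights, range_limits=self.range_limits, seed=self.seed)

    def fit(self, X: pd.DataFrame, y) -> "PanelOptimizer":
        X = pd.DataFrame(X)
        if self.ca_column in X.columns:
            X = X.drop(columns=[self.ca_column])
        table = CohortTable(X, pd.Series(np.asarray(y, float), index=X.index))
        out = run(table, self.specs, self._config())
        self.pipeline_result_ = out
        self.panel_ = out.panel
        self.result_ = out.result
        self.stats_ = out.stats
        self.step_log_ = out.log
        self.accepted_ = out.accepted
        self.report_ = out.report()
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        X = pd.DataFrame(X)
        if self.ca_column in X.columns:
            ca = pd.to_numeric(X[self.ca_column]).astype(float)
            data = X.drop(columns=[self.ca_column])
        elif self.panel_.divisor_convention == "weight_sum":
            ca = pd.Series(1.0, index=X.index)  # cancels under weight_sum
            data = X
        else:
            raise ValueError(
                f"the 'count' divisor convention needs a {self.ca_column!r} column "
                "to compute BA = CA + weighted deviation")
        table = CohortTable(data.reindex(columns=self.panel_.members),
                            pd.Series(np.asarray(ca, float), index=X.index))
        return compute_ba(table, self.panel_).ba.to_numpy()
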