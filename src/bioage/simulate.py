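"""Synthetic aging cohorts with controllable planted structure.

The generator produces cohorts with exactly the statistical features the
panel optimizer screens for: biomarkers with known linear or exponential
age trajectories plus Gaussian noise, redundant biomarkers built as noisy
copies of another marker (inducing a chosen cross-correlation), uniformly
missing cells, and planted within-bin outliers.  Chronological age is drawn
uniformly over the cohort's age range.  Every cohort is emitted together
with a ground-truth record so tests never re-derive expectations from the
generator's internals, and generation is fully deterministic under the
spec's seed.

``paper_like_preset`` mirrors the structure of the classical Soviet
15-row biomarker screening panel (13 named markers + chronological age,
160 women): systolic/diastolic/pulse arterial pressure, elastic- and
muscular-artery pulse wave velocity, lung capacity, breath-hold time, eye
accommodation, hearing acuity, static balancing, body weight, health
self-assessment and the Wechsler test — with two near-zero age slopes
(BHT, SAH), redundant pressure and pulse-wave pairs, a moderately
LC-coupled body weight, and body weight's large interindividual dispersion
(roughly 45-135 kg).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort import BiomarkerSpec, CohortTable

__all__ = ["BiomarkerSim", "RedundancyLink", "OutlierPlan", "SyntheticSpec",
           "generate", "paper_like_preset", "paper_like_metadata"]


@dataclass(frozen=True)
class BiomarkerSim:
    """One independent biomarker: value = family(coefficients)(CA) + N(0, noise_sd)."""

    name: str
    coefficients: tuple[float, ...]  # linear: (a, b); exponential: (a, b)
    noise_sd: float
    family: str = "linear"

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError(f"{self.name}: noise_sd must be >= 0")
        if self.family not in ("linear", "exponential"):
            raise ValueError(f"{self.name}: unsupported family {self.family!r}")

    def mean_curve(self, ca: np.ndarray) -> np.ndarray:
        a, b = self.coefficients
        if self.family == "linear":
            return a + b * ca
        return a * np.exp(b * ca)


@dataclass(frozen=True)
class RedundancyLink:
    """A marker coupled to another: target = offset + scale*source + ca_slope*CA + noise.

    With ``ca_slope = 0`` this is a plain noisy copy (high cross-correlation);
    a nonzero ``ca_slope`` lets the target keep its own age trend while the
    coupling strength controls the pair's cross-correlation.
    """

    source: str
    target: str
    noise_sd: float
    scale: float = 1.0
    offset: float = 0.0
    ca_slope: float = 0.0


@dataclass(frozen=True)
class OutlierPlan:
    """Plant ``count`` values at bin mean + offset_sigmas * bin SD in one age bin."""

    biomarker: str
    bin_lo: float
    offset_sigmas: float
    count: int = 1


@dataclass
class SyntheticSpec:
    """Everything needed to generate one synthetic cohort deterministically."""

    n_subjects: int = 160
    ca_range: tuple[float, float] = (20.0, 70.0)
    biomarkers: list[BiomarkerSim] = field(default_factory=list)
    links: list[RedundancyLink] = field(default_factory=list)
    missing_fraction: float = 0.0
    outliers: list[OutlierPlan] = field(default_factory=list)
    groups: Mapping[str, float] | None = None
    seed: int = 0
    expected: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        lo, hi = self.ca_range
        if not (0 < lo < hi):
            raise ValueError("ca_range must satisfy 0 < min < max")
        if not 0 <= self.missing_fraction < 1:
            raise ValueError("missing_fraction must be in [0, 1)")
        if self.n_subjects < 2:
            raise ValueError("need at least 2 subjects")


def generate(spec: SyntheticSpec) -> tuple[CohortTable, dict]:
    """Generate a cohort and its ground-truth record.

    Order of construction: base biomarkers from their age trajectories,
    then redundancy links, then planted outliers (against the pre-planting
    bin statistics), then missingness.  All randomness comes from one
    ``numpy`` Generator seeded with ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_subjects
    lo, hi = spec.ca_range
    ca = rng.uniform(lo, hi, size=n)
    index = pd.Index([f"S{i + 1:04d}" for i in range(n)], name="subject")

    data: dict[str, np.ndarray] = {}
    for bm in spec.biomarkers:
        data[bm.name] = bm.mean_curve(ca) + rng.normal(0.0, bm.noise_sd, size=n)
    for link in spec.links:
        if link.source not in data:
            raise ValueError(f"redundancy link source {link.source!r} not generated")
        data[link.target] = (link.offset + link.scale * data[link.source]
                             + link.ca_slope * ca
                             + rng.normal(0.0, link.noise_sd, size=n))
    frame = pd.DataFrame(data, index=index)

    planted: list[tuple[str, str]] = []
    edges = np.floor(ca / 10.0) * 10.0
    for plan in spec.outliers:
        in_bin = np.flatnonzero(edges == plan.bin_lo)
        if len(in_bin) < max(plan.count, 3):
            raise ValueError(f"bin [{plan.bin_lo}, {plan.bin_lo + 10}) too small "
                             f"for outlier plan on {plan.biomarker}")
        vals = frame[plan.biomarker].to_numpy()[in_bin]
        mean, sd = float(vals.mean()), float(vals.std(ddof=1))
        chosen = rng.choice(in_bin, size=plan.count, replace=False)
        frame.iloc[chosen, frame.columns.get_loc(plan.biomarker)] = (
            mean + plan.offset_sigmas * sd)
        planted.extend((str(index[i]), plan.biomarker) for i in chosen)

    n_missing = 0
    if spec.missing_fraction > 0:
        mask = rng.random(frame.shape) < spec.missing_fraction
        frame = frame.mask(mask)
        n_missing = int(mask.sum())

    group = None
    if spec.groups:
        labels = list(spec.groups)
        probs = np.array([spec.groups[k] for k in labels], dtype=float)
        probs = probs / probs.sum()
        group = pd.Series(rng.choice(labels, size=n, p=probs), index=index, name="group")

    table = CohortTable(frame, pd.Series(ca, index=index, name="CA"), group)
    truth = {
        "seed": spec.seed,
        "n_subjects": n,
        "ca_range": list(spec.ca_range),
        "biomarkers": {bm.name: {"family": bm.family,
                                 "coefficients": list(bm.coefficients),
                                 "noise_sd": bm.noise_sd}
                       for bm in spec.biomarkers},
        "links": [asdict(link) for link in spec.links],
        "planted_outliers": planted,
        "n_missing_cells": n_missing,
        "expected": dict(spec.expected),
    }
    return table, truth


def paper_like_preset(n_subjects: int = 160, seed: int = 1) -> SyntheticSpec:
    """The classical 13-marker screening panel with its known pathologies.

    Planted structure (targets chosen to match the panel's reported
    behaviour on real cohorts):

    * BHT and SAH correlate with age near 0 / ~0.23 — rejected by the
      correlation screen at the default 0.3 threshold;
    * APd and APp are noisy copies of APs (cross-r ~0.80), PWVm of PWVe
      (cross-r ~0.99) — pruned as redundant at the default 0.7 threshold;
    * BW is coupled to LC at cross-r ~0.66 (below the pruning threshold)
      but spans roughly 45-135 kg — excluded only by the interindividual
      range criterion (threshold 60 kg) at the user-criteria step;
    * the remaining seven markers (APs, PWVe, LC, A, HA, SB, WT) survive.
    """
    # Age is the single latent factor here, so two markers with age
    # correlations r1, r2 are incidentally cross-correlated at r1*r2.  The
    # strongest marker (PWVe) keeps its reported r ~0.82; the other
    # survivors sit near 0.62-0.67 so every incidental pair stays clearly
    # below the 0.7 pruning gate and only the planted pairs exceed it.
    biomarkers = [
        # systolic pressure: 110 -> 150 mmHg over ages 20-70
        BiomarkerSim("APs", (94.0, 0.8), 12.8),
        # elastic-artery pulse wave velocity: 500 -> 1200 over 50 y (r~0.82)
        BiomarkerSim("PWVe", (220.0, 14.0), 138.0),
        # lung capacity declines ~30 ml/y
        BiomarkerSim("LC", (4600.0, -30.0), 500.0),
        # eye accommodation (distance to nearest clear point) grows ~3/y
        BiomarkerSim("A", (-7.0, 3.0), 48.0),
        # hearing threshold at 4 kHz rises ~0.5 dB/y
        BiomarkerSim("HA", (5.0, 0.5), 9.1),
        # static balancing declines ~0.7 s/y
        BiomarkerSim("SB", (75.0, -0.7), 11.2),
        # Wechsler test score declines ~0.35/y
        BiomarkerSim("WT", (88.0, -0.35), 5.75),
        # breath-hold time: essentially flat (planted near-zero correlation)
        BiomarkerSim("BHT", (45.0, -0.02), 9.0),
        # health self-assessment: weak trend, r ~ 0.23 (below the screen)
        BiomarkerSim("SAH", (10.0, 0.12), 7.3),
    ]
    links = [
        # diastolic and pulse pressure shadow systolic pressure (cross-r ~0.8)
        RedundancyLink("APs", "APd", noise_sd=12.2, scale=1.0, offset=-50.0),
        RedundancyLink("APs", "APp", noise_sd=12.0, scale=1.0, offset=-80.0),
        # the two pulse-wave velocities are nearly interchangeable
        RedundancyLink("PWVe", "PWVm", noise_sd=42.0, scale=1.0, offset=80.0),
        # body weight loosely tracks lung capacity (cross-r ~0.66, below the
        # pruning threshold) and declines mildly with age; huge spread (~45-135 kg)
        RedundancyLink("LC", "BW", noise_sd=12.7, scale=0.0148, offset=46.4,
                       ca_slope=-0.145),
    ]
    expected = {
        "reject_low_correlation": ["BHT", "SAH"],
        "prune_redundant": ["APd", "APp", "PWVm"],
        "user_criterion_range_limits": {"BW": 60.0},
        "reject_user_criterion": ["BW"],
        "final_panel": ["APs", "PWVe", "LC", "A", "HA", "SB", "WT"],
    }
    return SyntheticSpec(n_subjects=n_subjects, ca_range=(20.0, 70.0),
                         biomarkers=biomarkers, links=links, seed=seed,
                         expected=expected)


def paper_like_metadata() -> list[BiomarkerSpec]:
    """Instrument accuracies and reference changes for the classical panel.

    Values follow the instruments' customary resolutions (5 mmHg cuff,
    10 m/s pulse-wave timing, ~2-3% spirometry) and each marker's typical
    change between ages 20 and 70.  These make the redundancy tie-breaks
    deterministic: the worse-accuracy member of each correlated pair (APd,
    APp, PWVm) is the one dropped.
    """
    it = 50.0  # reference interval, years (ages 20-70)
    return [
        BiomarkerSpec("APs", "mmHg", instrument_accuracy=5.0,
                      reference_change=40.0, reference_interval=it),
        BiomarkerSpec("APd", "mmHg", instrument_accuracy=5.0,
                      reference_change=20.0, reference_interval=it),
        BiomarkerSpec("APp", "mmHg", instrument_accuracy=5.0,
                      reference_change=20.0, reference_interval=it),
        BiomarkerSpec("PWVe", "m/s", instrument_accuracy=10.0,
                      reference_change=700.0, reference_interval=it),
        BiomarkerSpec("PWVm", "m/s", instrument_accuracy=10.0,
                      reference_change=300.0, reference_interval=it),
        BiomarkerSpec("LC", "ml", instrument_accuracy=80.0,
                      reference_change=1500.0, reference_interval=it),
        BiomarkerSpec("A", "diopters", instrument_accuracy=5.0,
                      reference_change=150.0, reference_interval=it),
        BiomarkerSpec("HA", "dB", instrument_accuracy=2.0,
                      reference_change=25.0, reference_interval=it),
        BiomarkerSpec("SB", "s", instrument_accuracy=2.0,
                      reference_change=35.0, reference_interval=it),
        BiomarkerSpec("WT", "scores", instrument_accuracy=1.0,
                      reference_change=17.5, reference_interval=it),
        BiomarkerSpec("BW", "kg", instrument_accuracy=0.5,
                      reference_change=5.0, reference_interval=it),
    ]
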