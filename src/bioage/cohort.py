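"""Core cohort containers.

A cohort is a rectangular table of subjects (rows) by biomarkers of aging
(columns) plus one designated chronological-age (CA) column.  Missing
biomarker values are allowed and are represented as NaN; chronological age
must be present, finite and positive for every retained subject.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = ["CohortTable", "BiomarkerSpec", "CohortError"]


class CohortError(ValueError):
    """Raised when a cohort table violates its structural invariants."""


@dataclass
class CohortTable:
    """Subjects x biomarkers matrix with a designated chronological-age column.

    Parameters
    ----------
    data : pandas.DataFrame
        One row per subject, one float column per biomarker.  Missing cells
        are NaN and are distinct from zero.
    ca : pandas.Series
        Chronological age in years, aligned with ``data`` on the index.
    group : pandas.Series, optional
        Optional stratum label per subject (e.g. sex).
    """

    data: pd.DataFrame
    ca: pd.Series
    group: pd.Series | None = None

    def __post_init__(self) -> None:
        if not self.data.index.equals(self.ca.index):
            raise CohortError("data and ca must share the same subject index")
        ca = pd.to_numeric(self.ca, errors="coerce").astype(float)
        if not np.isfinite(ca.to_numpy()).all():
            raise CohortError("chronological age must be finite for every subject")
        if (ca.to_numpy() <= 0).any():
            raise CohortError("chronological age must be positive")
        if len(self.data) < 2:
            raise CohortError("a cohort needs at least 2 subjects")
        if self.data.shape[1] < 1:
            raise CohortError("a cohort needs at least 1 biomarker column")
        object.__setattr__(self, "ca", ca)
        object.__setattr__(self, "data", self.data.astype(float))
        if self.group is not None and not self.group.index.equals(self.data.index):
            raise CohortError("group labels must share the subject index")

    # -- basic views ---------------------------------------------------

    @property
    def biomarkers(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_subjects(self) -> int:
        return len(self.data)

    @property
    def subjects(self) -> pd.Index:
        return self.data.index

    def values(self, biomarker: str) -> pd.Series:
        return self.data[biomarker]

    def complete_pairs(self, biomarker: str) -> tuple[np.ndarray, np.ndarray]:
        """Pairwise-complete (CA, value) arrays for one biomarker."""
        v = self.data[biomarker]
        mask = v.notna()
        return self.ca[mask].to_numpy(), v[mask].to_numpy()

    # -- derived tables ------------------------------------------------

    def select(self, biomarkers: Sequence[str]) -> "CohortTable":
        return CohortTable(self.data[list(biomarkers)].copy(), self.ca.copy(),
                           None if self.group is None else self.group.copy())

    def with_data(self, data: pd.DataFrame) -> "CohortTable":
        return CohortTable(data, self.ca.copy(),
                           None if self.group is None else self.group.copy())

    def split_groups(self) -> dict[str, "CohortTable"]:
        """Stratify by the group column; subjects never mix across strata."""
        if self.group is None:
            raise CohortError("cohort has no group column")
        out: dict[str, CohortTable] = {}
        for label, idx in self.group.groupby(self.group).groups.items():
            out[str(label)] = CohortTable(
                self.data.loc[idx].copy(), self.ca.loc[idx].copy(),
                self.group.loc[idx].copy())
        return out

    def to_frame(self, ca_column: str = "CA", group_column: str = "group") -> pd.DataFrame:
        frame = self.data.copy()
        frame.insert(0, ca_column, self.ca)
        if self.group is not None:
            frame[group_column] = self.group
        return frame


@dataclass(frozen=True)
class BiomarkerSpec:
    """Per-biomarker metadata used by the accuracy screen.

    ``instrument_accuracy`` is the measurement-method resolution in the
    biomarker's own units; ``reference_change`` is how much the biomarker
    changes over ``reference_interval`` years in a reference population.
    Units are opaque labels and are never converted.
    """

    name: str
    units: str = ""
    instrument_accuracy: float | None = None
    reference_change: float | None = None
    reference_interval: float | None = None

    def __post_init__(self) -> None:
        if self.instrument_accuracy is not None and self.instrument_accuracy <= 0:
            raise ValueError(f"{self.name}: instrument_accuracy must be > 0")
        if self.reference_change is not None:
            if self.reference_interval is None:
                raise ValueError(
                    f"{self.name}: reference_change requires reference_interval")
            if self.reference_change <= 0 or self.reference_interval <= 0:
                raise ValueError(
                    f"{self.name}: reference change and interval must be > 0")


def specs_by_name(specs: Iterable[BiomarkerSpec] | Mapping[str, BiomarkerSpec] | None,
                  ) -> dict[str, BiomarkerSpec]:
    if specs is None:
        return {}
    if isinstance(specs, Mapping):
        return dict(specs)
    return {s.name: s for s in specs}
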