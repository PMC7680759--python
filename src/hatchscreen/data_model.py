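"""Core domain types for well-level egg-hatch data.

The screen's unit of observation is a single well (plate format) or a
single female's vial (vial format): the number of eggs laid and the number
of those eggs that hatched, under a labelled cross/treatment condition.
Hatch rates are carried as proportions in [0, 1] at full precision;
percentages are a display concern only.
"""

from __future__ import annotations

import math
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from .exceptions import (
    MissingConditionError,
    UndefinedFoldChangeError,
    UndefinedRateError,
)

# Canonical condition labels.
CONTROL_CROSS = "control-cross"
CI_CONTROL = "ci-control"
RESCUE_CONTROL = "rescue-control"
CI_TREATED = "ci-treated"

#: Conditions carried by a screening plate, in canonical layout order.
PLATE_CONDITIONS = (CI_CONTROL, CI_TREATED, RESCUE_CONTROL)

CSV_COLUMNS = ["plate_id", "well_id", "condition", "treatment", "eggs_laid", "eggs_hatched"]


@dataclass(frozen=True)
class WellObservation:
    """Egg counts from one well (or one female's vial).

    Parameters
    ----------
    plate_id, well_id
        Identifiers; the pair must be unique within a dataset.
    condition
        Condition label, e.g. ``"ci-control"`` or ``"ci-treated"``.
    eggs_laid, eggs_hatched
        Non-negative counts with ``eggs_hatched <= eggs_laid``.
    treatment
        Optional chemical treatment name for treated conditions.
    """

    plate_id: str
    well_id: str
    condition: str
    eggs_laid: int
    eggs_hatched: int
    treatment: str | None = None

    def __post_init__(self) -> None:
        if self.eggs_laid < 0 or self.eggs_hatched < 0:
            raise ValueError("egg counts must be non-negative")
        if self.eggs_hatched > self.eggs_laid:
            raise ValueError(
                f"eggs_hatched ({self.eggs_hatched}) exceeds eggs_laid ({self.eggs_laid})"
            )

    @property
    def hatch_fraction(self) -> float:
        """Per-well hatch proportion; NaN when no eggs were laid."""
        if self.eggs_laid == 0:
            return math.nan
        return self.eggs_hatched / self.eggs_laid


@dataclass
class ScreenDataset:
    """A collection of wells plus free-form metadata.

    Enforces uniqueness of ``(plate_id, well_id)`` pairs.  Metadata is a
    free mapping (strain label, assay format, provenance, ...).
    """

    wells: list[WellObservation]
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set[tuple[str, str]] = set()
        for w in self.wells:
            key = (w.plate_id, w.well_id)
            if key in seen:
                raise ValueError(f"duplicate (plate_id, well_id) pair: {key}")
            seen.add(key)

    def __len__(self) -> int:
        return len(self.wells)

    def conditions(self) -> list[str]:
        """Distinct condition labels, in order of first appearance."""
        return list(dict.fromkeys(w.condition for w in self.wells))

    def plate_ids(self) -> list[str]:
        """Distinct plate identifiers, in order of first appearance."""
        return list(dict.fromkeys(w.plate_id for w in self.wells))

    def subset(
        self, condition: str | None = None, plate_id: str | None = None
    ) -> "ScreenDataset":
        wells = [
            w
            for w in self.wells
            if (condition is None or w.condition == condition)
            and (plate_id is None or w.plate_id == plate_id)
        ]
        return ScreenDataset(wells, dict(self.metadata))

    def per_well_rates(self, condition: str) -> np.ndarray:
        """Per-well hatch proportions for one condition, ordered by (plate, well)."""
        wells = sorted(
            (w for w in self.wells if w.condition == condition and w.eggs_laid > 0),
            key=lambda w: (w.plate_id, w.well_id),
        )
        if not wells:
            raise MissingConditionError(f"no wells with eggs under condition {condition!r}")
        return np.array([w.hatch_fraction for w in wells])

    def has_scoring_conditions(self, plate_id: str) -> bool:
        """True if the plate carries all three conditions needed for hit scoring."""
        present = {w.condition for w in self.wells if w.plate_id == plate_id}
        return set(PLATE_CONDITIONS) <= present

    # ---- tabular I/O -------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "plate_id": w.plate_id,
                    "well_id": w.well_id,
                    "condition": w.condition,
                    "treatment": w.treatment if w.treatment is not None else "",
                    "eggs_laid": w.eggs_laid,
                    "eggs_hatched": w.eggs_hatched,
                }
                for w in self.wells
            ],
            columns=CSV_COLUMNS,
        )

    @classmethod
    def from_frame(
        cls, frame: pd.DataFrame, metadata: Mapping[str, Any] | None = None
    ) -> "ScreenDataset":
        missing = set(CSV_COLUMNS) - {"treatment"} - set(frame.columns)
        if missing:
            raise ValueError(f"missing required columns: {sorted(missing)}")
        wells = []
        for row in frame.itertuples(index=False):
            treatment = getattr(row, "treatment", "")
            if treatment is None or (isinstance(treatment, float) and math.isnan(treatment)):
                treatment = ""
            wells.append(
                WellObservation(
                    plate_id=str(row.plate_id),
                    well_id=str(row.well_id),
                    condition=str(row.condition),
                    eggs_laid=int(row.eggs_laid),
                    eggs_hatched=int(row.eggs_hatched),
                    treatment=str(treatment) or None,
                )
            )
        return cls(wells, dict(metadata or {}))

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path: str | Path, metadata: Mapping[str, Any] | None = None) -> "ScreenDataset":
        return cls.from_frame(pd.read_csv(Path(path)), metadata)


@dataclass(frozen=True)
class ConditionSummary:
    """Per-condition summary used by tests and by the Z' machinery.

    ``pooled_hatch_rate`` pools eggs across wells; ``mean_rate``/``sd_rate``
    treat the per-well proportions as the replicate sample (sample sd,
    n - 1 denominator).  ``sd_rate`` is NaN for a single well.
    """

    condition: str
    n_wells: int
    pooled_hatch_rate: float
    per_well_rates: tuple[float, ...]
    mean_rate: float
    sd_rate: float


def hatch_rate(wells: Iterable[WellObservation]) -> float:
    """Pooled hatch rate: total hatched / total laid over the given wells."""
    laid = 0
    hatched = 0
    for w in wells:
        laid += w.eggs_laid
        hatched += w.eggs_hatched
    if laid == 0:
        raise UndefinedRateError("hatch rate undefined: zero eggs laid in total")
    return hatched / laid


def fold_change(
    treated: Iterable[WellObservation], control: Iterable[WellObservation]
) -> float:
    """Ratio of pooled hatch rates, treated over control."""
    r_control = hatch_rate(control)
    r_treated = hatch_rate(treated)
    if r_control == 0:
        raise UndefinedFoldChangeError("fold change undefined: control hatch rate is zero")
    return r_treated / r_control


def summarize_condition(dataset: ScreenDataset, condition: str) -> ConditionSummary:
    """Summarise one condition: pooled rate plus per-well mean and sample sd."""
    wells = sorted(
        (w for w in dataset.wells if w.condition == condition),
        key=lambda w: (w.plate_id, w.well_id),
    )
    if not wells:
        raise MissingConditionError(f"condition {condition!r} absent from dataset")
    pooled = hatch_rate(wells)
    rates = tuple(w.hatch_fraction for w in wells if w.eggs_laid > 0)
    arr = np.array(rates)
    sd = float(np.std(arr, ddof=1)) if len(rates) >= 2 else math.nan
    return ConditionSummary(
        condition=condition,
        n_wells=len(rates),
        pooled_hatch_rate=pooled,
        per_well_rates=rates,
        mean_rate=float(arr.mean()),
        sd_rate=sd,
    )


def reconstruct_hatched(rate: float, total: int) -> int:
    """Hatched count from a printed (rate, egg total) pair: round(rate * total)."""
    return int(round(rate * total))
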