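"""Plate QC gating and dose-response tolerability scoring.

Two gate-keeping steps precede hit scoring.  First, a screening plate is
only scored when its CI-control condition pooled hatch rate is at or
below 12% — a plate whose negative control drifts upward cannot
distinguish treatment effects from assay failure.  Second, each chemical's
feeding dose is chosen from a vial-format dose-response series: the
highest dose with no adverse developmental effect, where "adverse" means
a loss of 40% or more of eggs, larvae or pupae relative to the matched
control.  Losses confined to the late half of the 12-day series (days
7-12, the second treatment vial) are graded "some"; consistent losses in
both windows are graded "-"; anything else is tolerated ("+").
"""

from __future__ import annotations

from collections.abc import Mapping, Sequence
from dataclasses import dataclass

from .data_model import CI_CONTROL, ScreenDataset, hatch_rate
from .exceptions import (
    MissingControlError,
    NoToleratedDoseError,
    UndefinedLossError,
)

#: Pooled CI-control hatch rate above which a plate is excluded (inclusive bound).
QC_MAX_CI_CONTROL_RATE = 0.12

#: Relative loss versus control at or above which a stage counts as defective.
DOSE_LOSS_THRESHOLD = 0.40

STAGES = ("eggs", "larvae", "pupae")
WINDOWS = ("early", "late")

GRADE_TOLERATED = "+"
GRADE_SOME = "some"
GRADE_DEFECT = "-"


def qc_gate(dataset: ScreenDataset, plate_id: str) -> bool:
    """Pass/fail screen-inclusion gate for one plate.

    Passes iff the plate's pooled CI-control hatch rate is <= 12%
    (boundary inclusive).
    """
    wells = [
        w
        for w in dataset.wells
        if w.plate_id == plate_id and w.condition == CI_CONTROL
    ]
    if not wells or sum(w.eggs_laid for w in wells) == 0:
        raise MissingControlError(
            f"plate {plate_id!r} has no CI-control wells with eggs"
        )
    return hatch_rate(wells) <= QC_MAX_CI_CONTROL_RATE


@dataclass(frozen=True)
class DoseSeriesRecord:
    """One dose of a vial-format dose-response series.

    ``treated`` and ``control`` map window -> stage -> count, with windows
    ``"early"`` (days 1-6) and ``"late"`` (days 7-12) and stages eggs,
    larvae, pupae.
    """

    dose: float
    unit: str
    treated: Mapping[str, Mapping[str, int]]
    control: Mapping[str, Mapping[str, int]]

    def __post_init__(self) -> None:
        for side, table in (("treated", self.treated), ("control", self.control)):
            for window in WINDOWS:
                if window not in table:
                    raise ValueError(f"{side} counts missing window {window!r}")
                for stage in STAGES:
                    if stage not in table[window]:
                        raise ValueError(
                            f"{side} counts missing stage {stage!r} in window {window!r}"
                        )
                    if table[window][stage] < 0:
                        raise ValueError("counts must be non-negative")


@dataclass(frozen=True)
class DoseScore:
    dose: float
    grade: str

    def __post_init__(self) -> None:
        if self.grade not in (GRADE_TOLERATED, GRADE_SOME, GRADE_DEFECT):
            raise ValueError(f"invalid grade {self.grade!r}")


def _window_defective(record: DoseSeriesRecord, window: str) -> bool:
    """True if any stage lost >= 40% versus its stage-matched control."""
    for stage in STAGES:
        control = record.control[window][stage]
        treated = record.treated[window][stage]
        if control == 0:
            raise UndefinedLossError(
                f"control count for stage {stage!r}, window {window!r} is zero"
            )
        if 1.0 - treated / control >= DOSE_LOSS_THRESHOLD:
            return True
    return False


def score_dose(record: DoseSeriesRecord) -> DoseScore:
    """Grade one dose: "-" (defects in both windows), "some" (late only), "+"."""
    early = _window_defective(record, "early")
    late = _window_defective(record, "late")
    if early and late:
        grade = GRADE_DEFECT
    elif late:
        grade = GRADE_SOME
    else:
        grade = GRADE_TOLERATED
    return DoseScore(dose=record.dose, grade=grade)


def select_dose(series: Sequence[tuple[float, DoseScore]]) -> float:
    """Highest dose graded "+" in an ascending dose series."""
    doses = [dose for dose, _ in series]
    if doses != sorted(doses):
        raise ValueError("dose series must be sorted by ascending dose")
    tolerated = [dose for dose, score in series if score.grade == GRADE_TOLERATED]
    if not tolerated:
        raise NoToleratedDoseError("no dose in the series was tolerated ('+')")
    return max(tolerated)
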