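"""Z' assay-quality scoring and normalized hit-range positioning.

The Z' factor summarises how well a plate's two control conditions are
separated relative to their replicate noise:

    Z' = 1 - 3 (sigma_CI + sigma_R) / |mu_R - mu_CI|

computed over per-well hatch proportions of the CI control (negative
control, low hatch) and rescue control (positive control, high hatch).
Z' is positive exactly when the two controls' 3-sd envelopes do not
overlap; values above ~0.5 mark an excellent screening assay.  Negative
values are reported as-is — they diagnose failed plates.

A treatment's plate mean is positioned on the normalized scale
``(mu_T - mu_CI) / (mu_R - mu_CI)`` (0 at the CI control, 1 at rescue);
it falls in the "hit range" when it clears the CI-control boundary
``mu_CI + 3 sigma_CI`` without entering the rescue envelope
``mu_R - 3 sigma_R``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .data_model import (
    CI_CONTROL,
    CI_TREATED,
    RESCUE_CONTROL,
    ConditionSummary,
    ScreenDataset,
    summarize_condition,
)
from .exceptions import InsufficientReplicationError, UndefinedZPrimeError


@dataclass(frozen=True)
class ZPrimeResult:
    plate_id: str
    z_prime: float
    mu_ci: float
    sd_ci: float
    mu_rescue: float
    sd_rescue: float
    #: (mu_CI + 3 sd_CI, mu_R - 3 sd_R) — the unnormalized hit window.
    hit_range: tuple[float, float]


@dataclass(frozen=True)
class NormalizedScore:
    position: float
    in_hit_range: bool


def _check_controls(ci: ConditionSummary, rescue: ConditionSummary) -> None:
    for summary in (ci, rescue):
        if summary.n_wells < 2:
            raise InsufficientReplicationError(
                f"condition {summary.condition!r} has {summary.n_wells} well(s); "
                "Z' needs at least 2 replicate wells per control"
            )
    if math.isclose(ci.mean_rate, rescue.mean_rate, rel_tol=0.0, abs_tol=0.0):
        raise UndefinedZPrimeError("control means coincide; Z' is undefined")


def zprime(
    ci: ConditionSummary, rescue: ConditionSummary, plate_id: str = ""
) -> ZPrimeResult:
    """Z' factor from the two control-condition summaries of one plate."""
    _check_controls(ci, rescue)
    separation = abs(rescue.mean_rate - ci.mean_rate)
    z = 1.0 - 3.0 * (ci.sd_rate + rescue.sd_rate) / separation
    return ZPrimeResult(
        plate_id=plate_id or "",
        z_prime=z,
        mu_ci=ci.mean_rate,
        sd_ci=ci.sd_rate,
        mu_rescue=rescue.mean_rate,
        sd_rescue=rescue.sd_rate,
        hit_range=(
            ci.mean_rate + 3.0 * ci.sd_rate,
            rescue.mean_rate - 3.0 * rescue.sd_rate,
        ),
    )


def normalized_score(
    treatment: ConditionSummary,
    ci: ConditionSummary,
    rescue: ConditionSummary,
) -> NormalizedScore:
    """Treatment mean on the CI->rescue normalized scale, plus hit flag.

    The flag applies the 3-sd rule to the treatment *mean* (the plate-level
    summary), not to individual wells.
    """
    _check_controls(ci, rescue)
    span = rescue.mean_rate - ci.mean_rate
    position = (treatment.mean_rate - ci.mean_rate) / span
    lower = 3.0 * ci.sd_rate / abs(span)
    upper = 1.0 - 3.0 * rescue.sd_rate / abs(span)
    return NormalizedScore(position=position, in_hit_range=bool(lower < position < upper))


def plate_zprime(dataset: ScreenDataset, plate_id: str) -> ZPrimeResult:
    """Z' of one plate from its CI-control and rescue-control wells."""
    plate = dataset.subset(plate_id=plate_id)
    return zprime(
        summarize_condition(plate, CI_CONTROL),
        summarize_condition(plate, RESCUE_CONTROL),
        plate_id=plate_id,
    )


def screen_zprimes(plates: list[ScreenDataset]) -> list[ZPrimeResult]:
    """Z' per plate for a list of single-plate datasets."""
    results = []
    for plate in plates:
        (pid,) = plate.plate_ids()
        results.append(plate_zprime(plate, pid))
    return results


def plate_normalized_score(dataset: ScreenDataset, plate_id: str) -> NormalizedScore:
    """Normalized position of the treated condition on one plate."""
    plate = dataset.subset(plate_id=plate_id)
    return normalized_score(
        summarize_condition(plate, CI_TREATED),
        summarize_condition(plate, CI_CONTROL),
        summarize_condition(plate, RESCUE_CONTROL),
    )
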