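"""Synthetic well-level egg-hatch data.

The generator reproduces the statistical structure of a plate screen, not
the biology: each well holds ten females laying for roughly a day, so the
egg count is modelled as Poisson with mean ``mean_eggs`` (zero-egg wells
are redrawn, since a well without eggs carries no rate information), and
the hatched count follows a beta-binomial law with per-condition mean
hatch probability ``p`` and intraclass correlation ``rho``.  The
beta-binomial captures between-well heterogeneity (female age, feeding,
local food quality): with ``rho = 0`` it degenerates to a plain binomial,
and for ``rho > 0`` the per-well rate variance is inflated to
``p (1 - p) (1 + (n - 1) rho) / n`` for a well with ``n`` eggs.

Calibrations mirror the screen's operating points: cytoplasmic-
incompatibility (CI) control wells hatch around 12%, CI wells under an
effective suppressing treatment around 25%, rescue-control wells around
92%, and uninfected control crosses around 90%.
"""

from __future__ import annotations

from collections.abc import Mapping
from dataclasses import dataclass, replace

import numpy as np

from .data_model import (
    CI_CONTROL,
    CI_TREATED,
    CONTROL_CROSS,
    PLATE_CONDITIONS,
    RESCUE_CONTROL,
    ScreenDataset,
    WellObservation,
)
from .exceptions import LayoutError, ParameterError

#: Wells on the physical plate (Corning 24-well format).
PLATE_CAPACITY = 24

_ROWS = "ABCD"
_COLS = range(1, 7)
#: Well identifiers of the 24-well plate in row-major order (A1..D6).
WELL_IDS = tuple(f"{r}{c}" for r in _ROWS for c in _COLS)

SCENARIOS = ("ci-null", "nabu-effect", "rescue-vs-ci")


@dataclass(frozen=True)
class SimulationParams:
    """Parameters of the plate-screen generator.

    Parameters
    ----------
    means
        Mapping from condition label to mean hatch probability ``p`` in (0, 1).
        May carry more conditions than are laid out on a plate (e.g. a
        vial-format control cross).
    rho
        Intraclass correlation of the beta-binomial hatch law, in [0, 1).
    mean_eggs
        Poisson mean of eggs per well (lambda), > 0.
    n_wells_per_condition, n_plates
        Replication; the plate layout must fit ``PLATE_CAPACITY``.
    seed
        Root seed; identical parameters and seed give bit-identical data.
    plate_conditions
        Conditions laid out on each simulated plate, in order.
    """

    means: Mapping[str, float]
    rho: float = 0.002
    mean_eggs: float = 150.0
    n_wells_per_condition: int = 8
    n_plates: int = 1
    seed: int | None = None
    plate_conditions: tuple[str, ...] = PLATE_CONDITIONS

    def __post_init__(self) -> None:
        for cond, p in self.means.items():
            if not 0.0 < p < 1.0:
                raise ParameterError(f"hatch mean for {cond!r} must be in (0,1), got {p}")
        if not 0.0 <= self.rho < 1.0:
            raise ParameterError(f"rho must be in [0,1), got {self.rho}")
        if self.mean_eggs <= 0:
            raise ParameterError(f"mean_eggs must be positive, got {self.mean_eggs}")
        if self.n_wells_per_condition < 1 or self.n_plates < 1:
            raise ParameterError("n_wells_per_condition and n_plates must be >= 1")
        missing = [c for c in self.plate_conditions if c not in self.means]
        if missing:
            raise ParameterError(f"plate conditions without a hatch mean: {missing}")


def _draw_eggs(mean_eggs: float, rng: np.random.Generator) -> int:
    """Poisson egg count, redrawn until positive."""
    n = int(rng.poisson(mean_eggs))
    while n == 0:
        n = int(rng.poisson(mean_eggs))
    return n


def _draw_hatched(n: int, p: float, rho: float, rng: np.random.Generator) -> int:
    if rho == 0.0:
        return int(rng.binomial(n, p))
    # Beta(a, b) with mean p and intraclass correlation rho.
    a = p * (1.0 - rho) / rho
    b = (1.0 - p) * (1.0 - rho) / rho
    return int(rng.binomial(n, rng.beta(a, b)))


def simulate_well(
    condition: str,
    params: SimulationParams,
    rng: np.random.Generator,
    plate_id: str = "plate-1",
    well_id: str = "A1",
) -> WellObservation:
    """Draw one well under `condition` from the beta-binomial hatch law."""
    if condition not in params.means:
        raise ParameterError(f"no hatch mean configured for condition {condition!r}")
    n = _draw_eggs(params.mean_eggs, rng)
    hatched = _draw_hatched(n, params.means[condition], params.rho, rng)
    return WellObservation(
        plate_id=plate_id,
        well_id=well_id,
        condition=condition,
        eggs_laid=n,
        eggs_hatched=hatched,
        treatment="treated" if condition == CI_TREATED else None,
    )


def simulate_screen_plate(
    params: SimulationParams,
    rng: np.random.Generator,
    plate_id: str = "plate-1",
) -> ScreenDataset:
    """Simulate one screening plate (all ``plate_conditions``, one plate)."""
    n_wells = len(params.plate_conditions) * params.n_wells_per_condition
    if n_wells > PLATE_CAPACITY:
        raise LayoutError(
            f"{len(params.plate_conditions)} conditions x "
            f"{params.n_wells_per_condition} wells = {n_wells} exceeds the "
            f"{PLATE_CAPACITY}-well plate"
        )
    wells = []
    slot = iter(WELL_IDS)
    for condition in params.plate_conditions:
        for _ in range(params.n_wells_per_condition):
            wells.append(
                simulate_well(condition, params, rng, plate_id=plate_id, well_id=next(slot))
            )
    return ScreenDataset(wells, {"plate_id": plate_id, "simulated": True})


def simulate_screen(params: SimulationParams) -> list[ScreenDataset]:
    """Simulate ``params.n_plates`` plates, one child random stream per plate.

    The root seed is expanded with :class:`numpy.random.SeedSequence` so the
    same seed always yields the same plates, independent of how many are
    consumed downstream.
    """
    ss = np.random.SeedSequence(params.seed)
    children = ss.spawn(params.n_plates)
    return [
        simulate_screen_plate(params, np.random.default_rng(child), plate_id=f"plate-{i + 1}")
        for i, child in enumerate(children)
    ]


def simulate_screen_dataset(params: SimulationParams) -> ScreenDataset:
    """Like :func:`simulate_screen` but pooled into a single dataset."""
    plates = simulate_screen(params)
    wells = [w for plate in plates for w in plate.wells]
    return ScreenDataset(wells, {"n_plates": params.n_plates, "simulated": True})


def default_calibration(scenario: str, seed: int | None = None) -> SimulationParams:
    """Calibrated parameters for a named screen scenario.

    Condition means sit at the midpoints of the screen's operating ranges:
    CI control 0.12, effectively treated CI 0.25, rescue control 0.92,
    uninfected control cross 0.90.  Scenarios:

    - ``"ci-null"``: treated wells share the CI-control mean (no effect).
    - ``"nabu-effect"``: treated mean 0.25, the suppression effect size.
    - ``"rescue-vs-ci"``: same plate, used when the quantity of interest is
      the CI-control / rescue-control separation (assay quality).
    """
    if scenario not in SCENARIOS:
        raise ParameterError(f"unknown scenario {scenario!r}; expected one of {SCENARIOS}")
    means = {
        CI_CONTROL: 0.12,
        CI_TREATED: 0.12 if scenario == "ci-null" else 0.25,
        RESCUE_CONTROL: 0.92,
        CONTROL_CROSS: 0.90,
    }
    return SimulationParams(means=means, rho=0.002, mean_eggs=150.0, seed=seed)


def with_seed(params: SimulationParams, seed: int | None) -> SimulationParams:
    """Copy of `params` with a different root seed."""
    return replace(params, seed=seed)
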