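"""Packaged summary tables from the source screen, plus reconstruction helpers.

Five CSV fixtures transcribe the screen's printed summary tables:

- ``crosses_control_food``: pooled hatch rates and egg totals of the
  baseline crosses (uninfected control, CI, rescue) on control food.
- ``crosses_nabu_food``: the same crosses under sodium-butyrate feeding.
- ``screen_wri`` / ``screen_wmel``: the plate-screen hit tables for the
  natural (wRi) and transinfected (wMel) infections — 24 and 8 chemical
  treatments with printed hit grades and p-values.
- ``screen_combinations``: the 7 dual-treatment combinations.

Only percentages and egg totals are printed for the crosses, so hatched
counts are reconstructed as ``round(rate * total)``.  Censored p-values
("<0.001") are parsed to a representative value just inside the bound.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .data_model import WellObservation, reconstruct_hatched

#: Stand-in for censored "<0.001" entries: just inside the printed bound.
P_BELOW_DETECTION = 0.0009


def _load(name: str) -> pd.DataFrame:
    with resources.files("hatchscreen.data").joinpath(name).open("r") as fh:
        return pd.read_csv(fh)


def load_cross_table() -> pd.DataFrame:
    """Baseline crosses on control food (hatch %, egg totals, female counts)."""
    return _load("crosses_control_food.csv")


def load_nabu_table() -> pd.DataFrame:
    """CI-related crosses under NaBu versus regular food."""
    return _load("crosses_nabu_food.csv")


def load_screen_table(strain: str = "wRi") -> pd.DataFrame:
    """Plate-screen hit table for one strain ("wRi" or "wMel")."""
    if strain == "wRi":
        return _load("screen_wri.csv")
    if strain == "wMel":
        return _load("screen_wmel.csv")
    raise ValueError(f"unknown strain {strain!r}; expected 'wRi' or 'wMel'")


def load_combination_table() -> pd.DataFrame:
    """Dual-treatment combination screen hit table."""
    return _load("screen_combinations.csv")


def parse_p_value(printed: str | float) -> float:
    """Parse a printed p-value, mapping censored "<x" entries below the bound."""
    if isinstance(printed, (int, float)):
        return float(printed)
    text = printed.strip()
    if text.startswith("<"):
        bound = float(text[1:])
        if bound == 0.001:
            return P_BELOW_DETECTION
        return 0.9 * bound
    return float(text)


def pooled_observation(
    hatch_pct: float, eggs: int, label: str, condition: str
) -> WellObservation:
    """One pooled pseudo-well from a printed (hatch %, egg total) pair."""
    return WellObservation(
        plate_id=label,
        well_id=label,
        condition=condition,
        eggs_laid=int(eggs),
        eggs_hatched=reconstruct_hatched(hatch_pct / 100.0, int(eggs)),
    )


def nabu_mass_mating_groups(strain: str = "wRi") -> tuple[list[WellObservation], list[WellObservation]]:
    """(treated, control) pooled groups from the NaBu mass-mating rows.

    Hatched counts are reconstructed from the printed rate and egg total;
    the returned groups feed directly into pooled-rate fold change.
    """
    table = load_nabu_table()
    rows = table[(table["assay"] == "mass") & (table["strain"] == strain)]
    control_row = rows[rows["condition"] == "ci-regular"].iloc[0]
    treated_row = rows[rows["condition"] == "ci-nabu"].iloc[0]
    control = [
        pooled_observation(control_row.hatch_pct, control_row.eggs, "ci-regular", "ci-control")
    ]
    treated = [
        pooled_observation(treated_row.hatch_pct, treated_row.eggs, "ci-nabu", "ci-treated")
    ]
    return treated, control
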