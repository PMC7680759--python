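from dataclasses import replace

import numpy as np
import pytest

import hatchscreen as hs


def make_wells(counts, condition="ci-control", plate_id="p1", prefix="w"):
    """Wells from a list of (hatched, laid) pairs."""
    return [
        hs.WellObservation(
            plate_id=plate_id,
            well_id=f"{prefix}{i}",
            condition=condition,
            eggs_laid=laid,
            eggs_hatched=hatched,
        )
        for i, (hatched, laid) in enumerate(counts)
    ]


@pytest.fixture
def rng():
    return np.random.default_rng(20201109)


@pytest.fixture(scope="session")
def nabu_plates():
    """Five screening plates at the suppression-effect calibration."""
    params = replace(hs.default_calibration("nabu-effect"), n_plates=5, seed=1)
    return hs.simulate_screen(params)


@pytest.fixture(scope="session")
def rescue_plates():
    """Five screening plates at the control-separation calibration."""
    params = replace(hs.default_calibration("rescue-vs-ci"), n_plates=5, seed=1)
    return hs.simulate_screen(params)
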