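import numpy as np
import pandas as pd
import pytest

from clscreen import pipeline
from clscreen import synthetic_data as sd

SEED = 1234


@pytest.fixture(scope="session")
def noiseless_screen():
    """Small zero-noise screen with planted effects: closed forms hold exactly."""
    truths, cfg = sd.make_screen_scenario(
        24, fraction_short=0.25, fraction_long=0.25, seed=SEED,
        cv_fluor=0.0, cv_od=0.0, batch_offset_sd=0.0)
    readings, layout, truth = sd.simulate_plate_set(truths, cfg, seed=SEED)
    return readings, layout, truth, cfg


@pytest.fixture(scope="session")
def noisy_screen():
    """96 strains at default noise (5% CV) with batch offsets, as screened."""
    truths, cfg = sd.make_screen_scenario(
        96, fraction_short=0.3, fraction_long=0.3, seed=SEED + 1)
    readings, layout, truth = sd.simulate_plate_set(truths, cfg, seed=SEED + 1)
    return readings, layout, truth, cfg


@pytest.fixture(scope="session")
def noisy_screen_result(noisy_screen):
    readings, layout, truth, cfg = noisy_screen
    res = pipeline.analyze_screen(readings, layout, call=False)
    return res, truth, cfg


@pytest.fixture()
def tiny_layout():
    return pd.DataFrame({
        "plate_id": ["P1"] * 4,
        "well": ["A01", "A02", "A03", "A04"],
        "strain_id": ["mutX", "WT", "", ""],
        "fluorophore": ["RFP", "RFP", "RFP", "CFP"],
        "role": ["mutant", "wt_control", "rfp_only", "cfp_only"],
        "batch_id": ["B1"] * 4,
    })


def make_readings(layout, ages=(0.0,), times=(3.0, 6.0, 9.0, 12.0, 15.0),
                  rfp=100.0, cfp=100.0, od=0.5):
    rows = []
    for _, w in layout.iterrows():
        for age in ages:
            for t in times:
                rows.append((w["plate_id"], w["well"], age, t, rfp, cfp, od))
    return pd.DataFrame(rows, columns=["plate_id", "well", "age_days", "time_h",
                                       "rfp_raw", "cfp_raw", "od600"])
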