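import numpy as np
import pandas as pd
import pytest

import ccteval as cc
from ccteval.io import COVARIATE_COLUMNS


@pytest.fixture(scope="session")
def sim_config():
    return cc.SimConfig(n_municipalities=80, seed=123)


@pytest.fixture(scope="session")
def panel_and_truth(sim_config):
    return cc.generate_panel(sim_config)


@pytest.fixture(scope="session")
def panel(panel_and_truth):
    return panel_and_truth[0]


@pytest.fixture(scope="session")
def truth(panel_and_truth):
    return panel_and_truth[1]


@pytest.fixture(scope="session")
def prepared(panel):
    """Panel with exposure levels and dichotomised covariates, plus the
    fitted transformers (needed downstream for frozen cut-points)."""
    expo = cc.ExposureTransformer().fit(panel)
    out = expo.transform(panel)
    dich = cc.CovariateDichotomizer(columns=COVARIATE_COLUMNS).fit(out)
    return dich.transform(out), expo, dich


@pytest.fixture(scope="session")
def fitted(prepared):
    df, _, _ = prepared
    return cc.FixedEffectsPoisson(
        covariates=tuple(COVARIATE_COLUMNS)).fit(df)


@pytest.fixture()
def two_by_two():
    """Saturated 2-municipality x 2-period fixture with a known RR.

    Municipality A: 100 -> 90 never exposed; B: 100 -> 72 exposed in
    period 2; equal offsets.  The saturated closed form gives exposure
    RR = (72/100) / (90/100) = 0.8 exactly.
    """
    return pd.DataFrame({
        "municipality": ["A", "A", "B", "B"],
        "year": [2000, 2001, 2000, 2001],
        "deaths": [100, 90, 100, 72],
        "population": [1000, 1000, 1000, 1000],
        "exposed": [0.0, 0.0, 0.0, 1.0],
    })
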