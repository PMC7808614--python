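"""Shared fixtures: measured-endpoint series and synthetic scenarios."""

import numpy as np
import pandas as pd
import pytest

from sulfiso import (
    CultureTimeSeries,
    NoiseModel,
    ethanol_scenario,
    methanol_scenario,
    simulate_batch,
)

#: final-timepoint chemistry and isotope compositions of the three
#: alcohol-fed cultures (21 mM initial sulfate, measured at 140 h):
#: remaining sulfate (mM), its δ34S (‰), produced sulfide (mM), its δ34S (‰),
#: and the reported per-culture enrichment factor (‰ ± ‰).
ALCOHOL_ENDPOINTS = {
    "ethanol": (10.9, 6.9, 9.5, -6.6, 9.8, 0.6),
    "n_propanol": (10.5, 6.8, 9.5, -6.6, 9.7, 0.6),
    "n_butanol": (11.0, 7.3, 9.6, -6.8, 10.2, 0.6),
}


def endpoint_series(remaining, d_so4, sulfide, d_hs, initial=21.0):
    """Two-row series: time zero plus one measured endpoint."""
    df = pd.DataFrame(
        {
            "time_h": [0.0, 140.0],
            "sulfate_mM": [initial, remaining],
            "sulfide_mM": [0.0, sulfide],
            "d34S_sulfate_permil": [0.0, d_so4],
            "d34S_sulfide_permil": [np.nan, d_hs],
        }
    )
    return CultureTimeSeries(df, {"initial_sulfate_mM": initial})


@pytest.fixture(scope="session")
def noiseless_methanol():
    """Noiseless slow culture driven to f ≈ 0.3 (19.6 mM methanol, 6 e⁻)."""
    cfg = methanol_scenario(methanol_mM=19.6, n_samples=12)
    return simulate_batch(cfg, NoiseModel.zero())


@pytest.fixture(scope="session")
def noiseless_ethanol():
    cfg = ethanol_scenario()
    return simulate_batch(cfg, NoiseModel.zero())
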