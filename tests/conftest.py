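"""Shared fixtures: the study sampling grid and reference PK truths."""
import numpy as np
import pytest

from mdpkpd import Pk1CParams, Pk2CParams, SampleSeries, interval_average_conc

#: collection-window width (min) and post-dose horizon (min) of the design
INTERVAL = 20.0
HORIZON = 480.0
DOSE = 100000.0


@pytest.fixture(scope="session")
def grid_mid():
    """Midpoints of the 24 post-dose collection windows."""
    return np.arange(INTERVAL / 2, HORIZON, INTERVAL)


@pytest.fixture(scope="session")
def bateman_truth():
    """Reference one-compartment truth: ka=0.05, ke=0.01 /min, V/F=1000."""
    return Pk1CParams(ka=0.05, ke=0.01, v_f=1000.0)


@pytest.fixture(scope="session")
def biphasic_truth():
    """Reference two-compartment truth with well-separated phases."""
    return Pk2CParams(ka=0.1, alpha=0.2, beta=0.01, a_coef=40.0, b_coef=20.0)


@pytest.fixture(scope="session")
def clean_interval_series(grid_mid, bateman_truth):
    """Noise-free interval-averaged dialysate series of the Bateman truth."""
    conc = interval_average_conc(bateman_truth, grid_mid - INTERVAL / 2,
                                 grid_mid + INTERVAL / 2, dose=DOSE)
    return SampleSeries("lignan", grid_mid, conc, interval=INTERVAL)


def replicate_rng(base: int, replicate: int) -> np.random.Generator:
    """Package-wide convention for independent replicate streams."""
    return np.random.default_rng(np.random.SeedSequence([base, replicate]))
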