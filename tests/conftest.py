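import numpy as np
import pandas as pd
import pytest

import stemwc as sw


@pytest.fixture(scope="session")
def registry():
    return sw.default_registry()


@pytest.fixture(scope="session")
def ttc(registry):
    return registry.calibrations["TTC"]


@pytest.fixture(scope="session")
def osc(registry):
    return registry.calibrations["OSC"]


@pytest.fixture(scope="session")
def bucket_model(registry):
    return registry.temperature_model("water-bucket")


@pytest.fixture(scope="session")
def teros12(registry):
    return registry.transform("teros12")


@pytest.fixture(scope="session")
def calib_records():
    """One paper-scale synthetic calibration experiment (8 x 3 x 11)."""
    records, truth = sw.generate_calibration_experiment(sw.CalibGenConfig(seed=11))
    return records, truth


@pytest.fixture(scope="session")
def noiseless_records():
    """Records lying exactly on the common line (all spreads zero)."""
    cfg = sw.CalibGenConfig(
        seed=12, sd_species_intercept=0.0, sd_individual_intercept=0.0,
        sd_residual=0.0, sd_wood_density=0.0,
    )
    records, truth = sw.generate_calibration_experiment(cfg)
    return records, truth
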