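"""Shared fixtures: published median parameters and reusable simulations."""

import numpy as np
import pytest

from ventpkpd import (
    HCVRParameters,
    PhysiologyConstants,
    PKParameters,
    calibrate_vco2,
    simulate_run,
)


@pytest.fixture(scope="session")
def median_hcvr() -> HCVRParameters:
    """Population median pre-drug HCVR parameter set."""
    return HCVRParameters(baseline_ve=8.3, resting_petco2=41.0, vrt=44.0,
                          slope_s=2.5)


@pytest.fixture(scope="session")
def calibrated_constants(median_hcvr) -> PhysiologyConstants:
    cons = PhysiologyConstants()
    return cons.with_vco2(calibrate_vco2(median_hcvr.baseline_ve,
                                         median_hcvr.resting_petco2, cons))


@pytest.fixture(scope="session")
def median_pk() -> PKParameters:
    return PKParameters(v1=90.0, v2=557.0, cl=197.0, cl2=726.0, tabs=1.2)


@pytest.fixture(scope="session")
def median_run(median_hcvr, calibrated_constants):
    """Noise-free forced HCVR run at the median parameters."""
    return simulate_run(median_hcvr, calibrated_constants)
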