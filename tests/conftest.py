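"""Shared fixtures: the calibrated model is expensive, so build it once."""

from __future__ import annotations

import numpy as np
import pytest

from vildapbpk import (DrugParameters, SimulationConfig, VildagliptinPBPK,
                       build_reference_individual)


@pytest.fixture(scope="session")
def drug() -> DrugParameters:
    return DrugParameters.default()


@pytest.fixture(scope="session")
def reference_phys(drug):
    return build_reference_individual(68.1, "M", 30,
                                      fu_plasma=drug.fu_plasma)


@pytest.fixture(scope="session")
def fitted_results(drug):
    """Model calibrated once against the reference IV clearance."""
    model = VildagliptinPBPK(drug=drug)
    return model.fit()


@pytest.fixture(scope="session")
def fast_config() -> SimulationConfig:
    """Coarser output grid for tests that only need NCA-level accuracy."""
    return SimulationConfig(duration_h=24.0, output_interval_h=0.1)
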