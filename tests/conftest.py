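"""Shared fixtures: small synthetic fields, reused across the suite."""

import numpy as np
import pytest

from trogoquant import (
    NucleiLabels,
    PipelineConfig,
    SyntheticParams,
    generate_coculture_field,
    generate_ffpe_field,
)

# a compact FFPE layout used wherever a full-size field is unnecessary
SMALL_FFPE = dict(shape=(320, 320), n_tumor_cells=25, n_stromal_cells=5)


@pytest.fixture(scope="session")
def ffpe_noiseless():
    """Noiseless FFPE field, planted coverages spanning [0, 1], 100 cells."""
    params = SyntheticParams(
        seed=11, expressing_fraction=1.0, expressing_coverage_range=(0.0, 1.0)
    ).noiseless()
    return generate_ffpe_field(params)


@pytest.fixture(scope="session")
def ffpe_small_noiseless():
    """Small noiseless FFPE field with three fixed planted coverages."""
    coverages = tuple([0.3, 0.6, 0.95] * 8 + [0.3])
    params = SyntheticParams(
        seed=21, coverage_values=coverages, **SMALL_FFPE
    ).noiseless()
    return generate_ffpe_field(params)


@pytest.fixture(scope="session")
def coculture_grid():
    """Noiseless co-culture field with one planted ring per listed diameter."""
    params = SyntheticParams.coculture(
        shape=(480, 480), n_tumor_cells=16, trog_diameters_um=(2.0, 4.0, 5.5, 8.0),
        seed=31,
    ).noiseless()
    return generate_coculture_field(params)


@pytest.fixture()
def coculture_config():
    """Pipeline config for co-culture fields (the monolayer fills the frame)."""
    return PipelineConfig(tumor_threshold_method="fixed", tumor_threshold_value=0.0)


@pytest.fixture()
def gt_nuclei(ffpe_noiseless):
    _, truth = ffpe_noiseless
    return NucleiLabels(truth.nuclei_labels)
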