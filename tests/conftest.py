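"""Shared fixtures: small synthetic fields rendered once per session."""

import numpy as np
import pytest

import pillarmyelin as pm

#: coverage classes exercised across tests, cycled over the grid
COVERAGE_CYCLE = (0.0, 0.25, 0.5, 0.75, 1.0)


@pytest.fixture(scope="session")
def small_spec():
    """4x4 grid of 5 µm mold pillars at 10 µm spacing, 26% swelling."""
    return pm.make_array_spec(5.0, 10.0, 22.0, 0.26, rows=4, cols=4)


@pytest.fixture(scope="session")
def mixed_truth(small_spec):
    cov = np.resize(np.asarray(COVERAGE_CYCLE), small_spec.n_sites)
    return pm.make_field_truth(small_spec, coverage=cov, thickness_um=0.66,
                               n_nuclei=8, seed=3)


@pytest.fixture(scope="session")
def clean_field(small_spec, mixed_truth):
    """Noiseless, blur-free render of the mixed-coverage field."""
    stack, truth = pm.render_field(small_spec, mixed_truth,
                                   pm.NoiseModel.none(), seed=3)
    return stack, truth


@pytest.fixture(scope="session")
def noisy_field(small_spec, mixed_truth):
    """Same field with the default blur/background/read-noise model."""
    stack, truth = pm.render_field(small_spec, mixed_truth,
                                   pm.NoiseModel(), seed=3)
    return stack, truth


@pytest.fixture(scope="session")
def clean_grid(small_spec, clean_field):
    stack, _ = clean_field
    pil = pm.max_project(stack, "PILLAR")
    return pm.detect_pillars(pil, small_spec.pitch_um,
                             small_spec.realized_diameter_um,
                             mold_diameter_um=small_spec.mold_diameter_um)


@pytest.fixture(scope="session")
def clean_measurements(clean_field, clean_grid):
    stack, _ = clean_field
    mbp = pm.max_project(stack, "MBP", z_lo=4.0)
    return pm.quantify_field(mbp, clean_grid)
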