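"""Shared fixtures: small phantoms and cached full-field pipeline runs."""

from __future__ import annotations

import numpy as np
import pytest

from myocap3d import (
    PhantomSpec,
    compute_morphometry,
    generate_capillary_network,
    rasterise_network,
    reconstruct_graph,
)


@pytest.fixture
def small_spec() -> PhantomSpec:
    """A fast, low-density field for unit tests (not the study geometry)."""
    return PhantomSpec(
        field_size=(120.0, 120.0, 60.0),
        target_LVm=700e-6,
        target_NV=2.0e-6,
        n_fibres=4,
        fibre_diameter_mean=45.0,
        seed=42,
    )


def run_field_pipeline(spec: PhantomSpec):
    """Generate, rasterise and reconstruct one field; return truth + measured."""
    graph, truth = generate_capillary_network(spec)
    stack = rasterise_network(graph, spec)
    z_cal = 1.0 / spec.z_shrinkage
    rec = reconstruct_graph(stack, z_calibration=z_cal)
    measured = compute_morphometry(rec, stack.world_volume * z_cal)
    return truth, measured


@pytest.fixture(scope="session")
def dia_field_run():
    """Full-resolution field at the control-diaphragm LVm/Br_dens setpoints."""
    spec = PhantomSpec(target_LVm=598.75e-6, target_NV=1.37e-6, seed=11)
    return run_field_pipeline(spec)


@pytest.fixture(scope="session")
def meancap_vl_field_run():
    """Full field with densities chosen for the control-diaphragm MeanCap and
    perturbation amplitude calibrated to the control-VL tortuosity."""
    from myocap3d import calibrate_tortuosity_amplitude, nv_for_meancap

    base = PhantomSpec(
        target_LVm=598.75e-6, target_NV=nv_for_meancap(598.75e-6, 373.76), seed=12
    )
    amp = calibrate_tortuosity_amplitude(base, 42.12e-3)
    spec = PhantomSpec(
        target_LVm=base.target_LVm,
        target_NV=base.target_NV,
        tortuosity_amplitude=amp,
        seed=12,
    )
    return run_field_pipeline(spec)


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
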