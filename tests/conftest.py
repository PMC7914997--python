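"""Shared simulation fixtures.

The expensive PDE/ODE runs are session-scoped so the whole suite reuses one
transport solve per flow protocol.
"""

from __future__ import annotations

import numpy as np
import pytest

from atpcal import (
    ChannelGeometry,
    FlowProgram,
    Grid,
    SinusoidalFlow,
    SteadyFlow,
    TransportParams,
    WallStimulus,
    chip_config,
    default_params,
    frequency_sweep,
    run_chip_experiment,
    simulate_calcium,
    simulate_transport,
)


@pytest.fixture(scope="session")
def shallow_geometry():
    return ChannelGeometry.reference_shallow()


@pytest.fixture(scope="session")
def params():
    return default_params()


@pytest.fixture(scope="session")
def steady_field(shallow_geometry):
    """Reference chip with equal steady streams, from an empty channel."""
    program = FlowProgram(q1=1.5e-10, q2=SteadyFlow(1.5e-10))
    grid = Grid(nx=48, nz=160, t_end=10.0, output_dt=0.05)
    return simulate_transport(shallow_geometry, TransportParams(), program, grid)


@pytest.fixture(scope="session")
def pulsatile_field(shallow_geometry):
    """Reference chip with 50 % perfusion modulation at 0.1 Hz, 60 s."""
    program = FlowProgram(q1=1.5e-10, q2=SinusoidalFlow(1.5e-10, 0.5, 0.1))
    grid = Grid(nx=48, nz=160, t_end=60.0, output_dt=0.05)
    return simulate_transport(shallow_geometry, TransportParams(), program, grid)


@pytest.fixture(scope="session")
def chip_result():
    """Full coupled protocol at 0.1 Hz for 200 s (four outlet cells)."""
    return run_chip_experiment(chip_config(frequency=0.1, t_end=200.0))


@pytest.fixture(scope="session")
def chip_result_f05():
    """Same protocol with the perfusion modulated at 0.5 Hz."""
    return run_chip_experiment(chip_config(frequency=0.5, t_end=200.0))


@pytest.fixture(scope="session")
def validation_stimulus():
    """Raised-cosine ATP peaking at 10 uM at 0.1 Hz, constant 0.3 Pa shear."""
    t = np.arange(0.0, 300.0 + 1e-9, 0.05)
    atp = 5.0 * (1.0 - np.cos(2.0 * np.pi * 0.1 * t))
    return WallStimulus(t=t, atp=atp, shear=np.full_like(t, 0.3), position=(0.0, 0.0))


@pytest.fixture(scope="session")
def validation_trajectory(params, validation_stimulus):
    return simulate_calcium(params, validation_stimulus, output_dt=0.05)


@pytest.fixture(scope="session")
def lowpass_sweep():
    """ATP peak-to-peak at the outlet across drive frequencies at delta=0.5."""
    return frequency_sweep(
        chip_config(), frequencies=[0.05, 0.1, 0.2, 0.5, 1.0], deltas=[0.5]
    )


@pytest.fixture(scope="session")
def amplitude_sweep():
    """ATP peak-to-peak across pulsatile amplitudes at 0.1 Hz, including
    the steady-flow (delta=0) column."""
    return frequency_sweep(
        chip_config(), frequencies=[0.1], deltas=[0.0, 0.1, 0.3, 0.5, 0.8]
    )
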