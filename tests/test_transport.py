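import numpy as np
import pytest

from atpcal.transport import (
    Grid,
    StabilityError,
    TransportParams,
    WallStimulus,
    effective_diffusivity,
    inlet_profile,
    mean_velocity,
    sample_wall_stimulus,
    settling_time,
    simulate_transport,
)
from atpcal.waveforms import ChannelGeometry, FlowProgram, SinusoidalFlow, SteadyFlow


def steady_program():
    return FlowProgram(q1=1.5e-10, q2=SteadyFlow(1.5e-10))


class TestDispersion:
    def test_taylor_aris_reference_value(self):
        # Nominal deep section, ubar = Q/(H W) = 3e-10/(1e-3*5e-5) = 6e-3 m/s:
        # Pe = 600, Deff = D (1 + Pe^2/210 * (H/W)^2) = 3.428576e-4 m^2/s.
        geom = ChannelGeometry()
        params = TransportParams()
        ubar = mean_velocity(steady_program(), geom, 0.0)
        assert ubar == pytest.approx(6e-3)
        deff = effective_diffusivity(ubar, geom, params)
        assert deff == pytest.approx(5e-10 * (1 + 600.0**2 / 210.0 * 400.0), rel=1e-12)

    def test_molecular_variant_disables_enhancement(self):
        geom = ChannelGeometry()
        params = TransportParams(dispersion="molecular")
        assert effective_diffusivity(6e-3, geom, params) == pytest.approx(5e-10)

    def test_dispersion_grows_without_bound_in_velocity(self):
        geom = ChannelGeometry.reference_shallow()
        params = TransportParams()
        lo = effective_diffusivity(1e-3, geom, params)
        hi = effective_diffusivity(1e-2, geom, params)
        assert hi > lo > params.diffusivity


class TestInletProfile:
    def test_linear_ramp_and_zero_beyond_interface(self):
        x = np.linspace(0.0, 1e-3, 11)
        prof = inlet_profile(x, eps=0.5, phi0=10.0, width=1e-3)
        assert prof[0] == pytest.approx(10.0)
        assert prof[5] == pytest.approx(0.0, abs=1e-12)  # x = eps*W
        assert np.all(prof[6:] == 0.0)
        # linear in the ATP stream
        np.testing.assert_allclose(prof[:6], 10.0 * (1 - x[:6] / 0.5e-3), atol=1e-12)

    def test_zero_fraction_means_no_atp(self):
        assert np.all(inlet_profile(np.linspace(0, 1e-3, 5), 0.0, 10.0, 1e-3) == 0.0)


class TestSimulation:
    def test_maximum_principle(self, steady_field):
        assert steady_field.values.min() >= 0.0
        assert steady_field.values.max() <= steady_field.phi0 + 1e-12

    def test_maximum_principle_pulsatile(self, pulsatile_field):
        assert pulsatile_field.values.min() >= 0.0
        assert pulsatile_field.values.max() <= pulsatile_field.phi0 + 1e-12

    def test_transverse_mean_is_advected_conservatively(self, steady_field):
        # Side walls are no-flux and the axial flow is plug-like after depth
        # averaging, so at steady state the transverse mean concentration is
        # the same at the outlet as at the inlet (eps*phi0/2 = 2.5 uM).
        final = steady_field.values[-1]
        x = steady_field.x
        mean_in = np.trapezoid(final[:, 0], x) / (x[-1] - x[0])
        mean_out = np.trapezoid(final[:, -1], x) / (x[-1] - x[0])
        assert mean_in == pytest.approx(2.5, rel=0.02)
        assert mean_out == pytest.approx(mean_in, rel=0.02)

    def test_settling_time_near_four_seconds(self, steady_field):
        ts = settling_time(steady_field)
        assert 3.0 < ts < 5.0

    def test_grid_convergence_below_one_percent(self, shallow_geometry):
        params = TransportParams()
        prog = steady_program()
        vals = []
        for nx, nz in ((24, 80), (48, 160)):
            field = simulate_transport(
                shallow_geometry, params, prog, Grid(nx=nx, nz=nz, t_end=10.0, output_dt=0.5)
            )
            vals.append(field.sample(shallow_geometry.width / 5.0, shallow_geometry.length)[-1])
        assert abs(vals[1] - vals[0]) / vals[1] < 0.01

    def test_advection_dominated_steady_front(self, shallow_geometry):
        # Without dispersion enhancement the solute is nearly frozen across
        # streamlines: the perfusion side of the outlet stays essentially
        # ATP-free while the stock side stays near phi0.
        params = TransportParams(dispersion="molecular")
        field = simulate_transport(
            shallow_geometry, params, steady_program(),
            Grid(nx=48, nz=160, t_end=10.0, output_dt=0.5),
        )
        W, L = shallow_geometry.width, shallow_geometry.length
        assert field.sample(0.9 * W, L)[-1] < 0.05 * field.phi0
        assert field.sample(0.05 * W, L)[-1] > 0.8 * field.phi0

    def test_explicit_step_beyond_cfl_rejected(self, shallow_geometry):
        # dz = L/(nz-1) ~ 6.3e-5 m, ubar = 6e-3/20... compute inside
        grid = Grid(nx=16, nz=160, t_end=1.0, dt=1.0, output_dt=1.0)
        with pytest.raises(StabilityError):
            simulate_transport(shallow_geometry, TransportParams(), steady_program(), grid)

    def test_unsettled_field_raises(self, shallow_geometry):
        field = simulate_transport(
            shallow_geometry, TransportParams(), steady_program(),
            Grid(nx=16, nz=32, t_end=1.0, output_dt=0.05),
        )
        with pytest.raises(RuntimeError):
            settling_time(field)


class TestSampling:
    def test_sample_outside_channel_rejected(self, steady_field):
        with pytest.raises(ValueError):
            steady_field.sample(2e-3, 1e-2)

    def test_wall_stimulus_pairs_atp_and_shear(self, steady_field, shallow_geometry):
        stim = sample_wall_stimulus(
            steady_field, steady_program(), shallow_geometry, 1e-3,
            shallow_geometry.width / 5.0, shallow_geometry.length,
        )
        assert stim.t.shape == stim.atp.shape == stim.shear.shape
        np.testing.assert_allclose(stim.shear, 0.72, rtol=1e-12)  # steady flow
        assert stim.atp[-1] == pytest.approx(5.94, abs=0.3)

    def test_stimulus_csv_roundtrip(self, tmp_path):
        t = np.arange(0.0, 1.0, 0.1)
        stim = WallStimulus(t=t, atp=np.linspace(0, 5, t.size),
                            shear=np.full_like(t, 0.3), position=(0.0, 0.0))
        path = tmp_path / "stim.csv"
        stim.to_csv(path)
        back = WallStimulus.from_csv(path)
        np.testing.assert_allclose(back.t, stim.t)
        np.testing.assert_allclose(back.atp, stim.atp)
        np.testing.assert_allclose(back.shear, stim.shear)
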