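import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from atpcal.calcium import (
    calcium_rhs,
    default_params,
    gate_p1,
    gate_p2,
    gate_p3,
    initial_state,
    q_in_p2x4,
    q_in_trp,
    q_out,
    resting_passive_influx,
    resting_store,
    simulate_calcium,
    strain_energy,
)
from atpcal.transport import WallStimulus


def constant_stimulus(atp: float, shear: float, t_end: float) -> WallStimulus:
    t = np.array([0.0, t_end])
    return WallStimulus(
        t=t, atp=np.full(2, atp), shear=np.full(2, shear), position=(0.0, 0.0)
    )


class TestRestingState:
    def test_rest_is_an_exact_equilibrium(self, params):
        rhs = calcium_rhs(initial_state(params), 0.0, 0.0, params)
        assert np.max(np.abs(rhs)) < 1e-9

    def test_store_balance_at_rest(self, params):
        # restore and leak cancel at (C0, Cs0)
        from atpcal.calcium import q_res

        cs0 = resting_store(params)
        assert q_res(params.C0, cs0, params) == pytest.approx(0.0, abs=1e-12)

    def test_buffer_below_capacity(self, params):
        assert 0.0 < initial_state(params).Cb < params.BT

    def test_zero_stimulus_holds_rest_for_ten_minutes(self, params):
        traj = simulate_calcium(params, constant_stimulus(0.0, 0.0, 600.0))
        assert np.max(np.abs(traj.C - params.C0)) < 1e-3 * params.C0

    def test_shear_alone_cannot_perturb_rest(self, params):
        # TRP influx is proportional to store depletion, which is zero at
        # rest, so pure shear with no agonist leaves the cell quiescent.
        traj = simulate_calcium(params, constant_stimulus(0.0, 1.0, 120.0))
        assert np.max(np.abs(traj.C - params.C0)) < 1e-3 * params.C0


class TestGatesAndFluxes:
    def test_strain_energy_vanishes_at_zero_shear(self, params):
        assert strain_energy(0.0, params) == pytest.approx(0.0, abs=1e-18)

    def test_strain_energy_monotone_and_sign_symmetric(self, params):
        taus = np.linspace(0.0, 5.0, 50)
        w = strain_energy(taus, params)
        assert np.all(np.diff(w) > 0)
        np.testing.assert_allclose(strain_energy(-taus, params), w)

    def test_shear_gate_bounds(self, params):
        taus = np.linspace(0.0, 100.0, 200)
        p1 = gate_p1(taus, params)
        # strictly below 1 mathematically; saturates to 1.0 in float
        assert np.all((p1 > 0) & (p1 <= 1))
        assert p1[0] == pytest.approx(1.0 / (1.0 + params.alpha))
        assert np.all(np.diff(p1) >= 0)

    def test_ip3_gate_bounds(self, params):
        i = np.linspace(0.0, 10.0, 100)
        p2 = gate_p2(i, params)
        assert p2[0] == pytest.approx(params.b1)
        assert np.all(p2 <= params.b1 * (1 + params.a1) + 1e-12)

    def test_calcium_gate_bounds(self, params):
        C = np.linspace(0.0, 5.0, 100)
        p3 = gate_p3(C, params)
        assert p3[0] == pytest.approx(params.c1 + params.c2)
        assert np.all(p3 > params.c1)
        assert np.all(np.diff(p3) < 0)

    def test_p2x4_influx_saturates_with_atp(self, params):
        lo = q_in_p2x4(1.0, params.C0, params)
        hi = q_in_p2x4(100.0, params.C0, params)
        cap = params.kp2x4 * (params.Cex - params.C0)
        assert 0 < lo < hi < cap

    def test_trp_influx_vanishes_at_full_store(self, params):
        cs0 = resting_store(params)
        assert q_in_trp(params.C0, cs0, 0.1, 1.0, params) == pytest.approx(0.0, abs=1e-15)
        assert q_in_trp(params.C0, 0.5 * cs0, 0.1, 1.0, params) > 0.0

    @settings(max_examples=200, deadline=None)
    @given(
        C=st.floats(1e-4, 5.0),
        Cs=st.floats(1.0, 1000.0),
        Cb=st.floats(0.0, 119.0),
        i=st.floats(0.0, 10.0),
        phi=st.floats(0.0, 20.0),
        tau=st.floats(0.0, 5.0),
    )
    def test_flux_bookkeeping_identity(self, C, Cs, Cb, i, phi, tau):
        # dC/dt + dCb/dt + dCs/dt / (Vc/Vs) == influx - efflux exactly:
        # store exchange and buffering only move Ca2+ between compartments.
        p = default_params()
        d = calcium_rhs(np.array([C, Cs, Cb, i]), phi, tau, p)
        qin = (
            q_in_p2x4(phi, C, p)
            + q_in_trp(C, Cs, i, tau, p)
            + resting_passive_influx(p)
        )
        lhs = d[0] + d[2] + d[1] / p.Vc_over_Vs
        rhs = qin - q_out(C, p)
        # rounding floor set by the largest cancelled term (store release can
        # reach ~1e4 uM/s, so machine precision here is ~1e-11)
        scale = max(1.0, abs(d[0]), abs(d[1]))
        assert abs(lhs - rhs) < 1e-10 * scale


class TestDynamics:
    def test_state_invariants_under_validation_drive(self, validation_trajectory, params):
        traj = validation_trajectory
        for arr in (traj.C, traj.Cs, traj.Cb, traj.i):
            assert np.all(arr >= -1e-9)
        assert np.all(traj.Cb <= params.BT)

    def test_peak_response_grows_with_atp_step(self, params):
        peaks = []
        for atp in (1.0, 5.0, 10.0):
            traj = simulate_calcium(params, constant_stimulus(atp, 0.3, 120.0))
            peaks.append(traj.C.max())
        assert peaks[0] < peaks[1] < peaks[2]

    def test_return_to_rest_after_perturbation(self, params):
        from atpcal.calcium import CalciumState

        rest = initial_state(params)
        for factor in (0.9, 1.1):
            start = CalciumState(C=factor * rest.C, Cs=rest.Cs, Cb=rest.Cb, i=rest.i)
            traj = simulate_calcium(
                params, constant_stimulus(0.0, 0.0, 120.0), state0=start
            )
            assert abs(traj.C[-1] - params.C0) < 0.01 * params.C0

    def test_validation_first_peak_latency(self, validation_trajectory):
        from atpcal.waveforms import TimeSeries, signal_metrics

        m = signal_metrics(TimeSeries(validation_trajectory.t, validation_trajectory.C))
        assert m.first_peak_time is not None
        assert 15.0 < m.first_peak_time < 35.0

    def test_validation_entrains_to_drive(self, validation_trajectory):
        from atpcal.waveforms import TimeSeries, signal_metrics

        m = signal_metrics(TimeSeries(validation_trajectory.t, validation_trajectory.C))
        assert m.dominant_frequency == pytest.approx(0.1, abs=0.01)

    def test_stimulus_must_cover_horizon(self, params):
        with pytest.raises(ValueError):
            simulate_calcium(params, constant_stimulus(1.0, 0.3, 10.0), t_end=20.0)


class TestParameters:
    def test_overrides_apply(self):
        p = default_params(k1=0.1)
        assert p.k1 == 0.1
        assert p.k2 == default_params().k2

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            default_params(k1=-1.0)

    def test_passive_influx_balances_efflux_at_rest(self, params):
        # with the TRP and release terms zero at rest, the calibrated passive
        # influx is essentially the resting efflux
        assert resting_passive_influx(params) == pytest.approx(
            q_out(params.C0, params), rel=1e-6
        )
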