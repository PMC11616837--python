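"""Electrostatics, channel gating, membrane relaxation, Hebbian plasticity."""

import numpy as np
import pytest
from scipy.constants import Boltzmann as K_B

import protospike as ps
from protospike import mechanism as mech


class TestPoissonBoltzmann:
    def _system(self, sigma, n_debye=12.0):
        base = mech.ElectrolyteSystem(surface_charge=sigma)
        lam = mech.debye_length(base)
        a = base.inner_radius
        return mech.ElectrolyteSystem(
            inner_radius=a, outer_radius=a + n_debye * lam, surface_charge=sigma
        )

    def test_uncharged_system_flat_potential(self):
        system = self._system(0.0)
        r, psi = mech.solve_pb_radial(system, 500)
        np.testing.assert_allclose(psi, 0.0, atol=1e-15)

    def test_linear_regime_matches_debye_huckel(self):
        system = self._system(2e-5)  # e psi / kT ~ 1e-3
        r, psi = mech.solve_pb_radial(system, 3000)
        dh = mech.debye_huckel_profile(system, r)
        kt_over_e = K_B * system.temperature / 1.602176634e-19
        assert np.max(np.abs(psi)) < 0.1 * kt_over_e
        mask = dh > dh[0] * 1e-3  # skip the outer tail dominated by the BC
        rel = np.abs(psi[mask] - dh[mask]) / np.abs(dh[mask])
        assert np.max(rel) < 0.01

    def test_outer_boundary_insensitive_when_screened(self):
        near = self._system(1e-4, n_debye=12.0)
        far = self._system(1e-4, n_debye=24.0)
        r1, psi1 = mech.solve_pb_radial(near, 3000)
        r2, psi2 = mech.solve_pb_radial(far, 6000)
        half = r1 < near.inner_radius + 6 * mech.debye_length(near)
        interp = np.interp(r1[half], r2, psi2)
        assert np.max(np.abs(psi1[half] - interp)) < 1e-3 * np.abs(psi1[0])

    def test_nonlinear_solution_below_linear_prediction(self):
        # counterion crowding: the full PB potential at the surface lies
        # below the Debye-Hueckel extrapolation at high surface charge
        system = self._system(0.05)
        r, psi = mech.solve_pb_radial(system, 3000)
        dh = mech.debye_huckel_profile(system, r)
        assert 0 < psi[0] < dh[0]

    def test_non_electroneutral_bulk_rejected(self):
        with pytest.raises(ValueError, match="electroneutral"):
            mech.ElectrolyteSystem(ions=((1.0, 100.0), (-1.0, 50.0)))


class TestChannelGating:
    def test_zero_energy_half_open(self):
        assert ps.channel_open_probability(0.0, 298.0) == 0.5

    def test_kt_ln3_closed_form(self):
        dg = K_B * 298.0 * np.log(3.0)
        assert ps.channel_open_probability(dg, 298.0) == pytest.approx(0.25)

    def test_saturating_limits(self):
        assert ps.channel_open_probability(1e-18, 298.0) < 1e-30
        assert ps.channel_open_probability(-1e-18, 298.0) == pytest.approx(1.0)

    def test_strictly_decreasing_onto_unit_interval(self):
        dgs = np.linspace(-30, 30, 101) * K_B * 298.0
        p = [ps.channel_open_probability(d, 298.0) for d in dgs]
        assert all(a > b for a, b in zip(p, p[1:]))
        assert all(0 < x < 1 for x in p)


class TestMembrane:
    def test_leak_relaxation_time_constant(self):
        g, e = 0.1, -65.0
        model = mech.MembraneModel(channels=(mech.Channel(g, e),))
        t, v = mech.simulate_membrane(model, 0.0, 100.0, 0.01)
        tau = model.c_m / g
        v_at_tau = np.interp(tau, t, v)
        assert v_at_tau == pytest.approx(e * (1 - np.exp(-1)), rel=0.01)
        assert v[-1] == pytest.approx(e, rel=0.01)

    def test_two_conductance_steady_state(self):
        model = mech.MembraneModel(
            channels=(mech.Channel(0.3, -80.0), mech.Channel(0.1, 20.0))
        )
        expected = (0.3 * -80 + 0.1 * 20) / 0.4
        assert mech.membrane_steady_state(model) == pytest.approx(expected)
        t, v = mech.simulate_membrane(model, 0.0, 200.0, 0.05)
        assert v[-1] == pytest.approx(expected, abs=1e-6)

    def test_pure_capacitor_linear_ramp(self):
        model = mech.MembraneModel(c_m=2.0, i_ext=4.0)
        t, v = mech.simulate_membrane(model, -10.0, 50.0, 0.5)
        np.testing.assert_allclose(v, -10.0 + 2.0 * t, rtol=1e-12)

    def test_resting_state_conserved(self):
        model = mech.MembraneModel(
            channels=(mech.Channel(0.2, -70.0), mech.Channel(0.05, 0.0))
        )
        v_star = mech.membrane_steady_state(model)
        tau = model.c_m / model.effective_conductances().sum()
        t, v = mech.simulate_membrane(model, v_star, 10 * tau, tau / 50)
        assert np.max(np.abs(v - v_star)) < 1e-6

    def test_gating_scales_conductance(self):
        # a channel at dG = 0 contributes half its maximal conductance
        open_ch = mech.MembraneModel(channels=(mech.Channel(0.2, -65.0),))
        gated = mech.MembraneModel(channels=(mech.Channel(0.4, -65.0, 0.0),))
        np.testing.assert_allclose(
            gated.effective_conductances(), open_ch.effective_conductances()
        )


class TestHebbian:
    def _network(self, eta, cs=1.0, w=None, x=(1.0, 1.0), y=(1.0,)):
        w = np.zeros((len(x), len(y))) if w is None else w
        return mech.PlasticNetwork(
            weights=w, cs=cs, x=np.asarray(x), y=np.asarray(y),
            learning_rate=eta,
        )

    def test_zero_learning_rate_null_update(self, rng):
        w0 = rng.normal(size=(3, 2))
        net = mech.PlasticNetwork(
            weights=w0, cs=2.0, x=rng.normal(size=3), y=rng.normal(size=2),
            learning_rate=lambda cs: np.zeros_like(cs),
        )
        np.testing.assert_array_equal(mech.hebbian_step(net, 1.0), w0)

    def test_constant_rate_arithmetic(self):
        net = self._network(lambda cs: np.full_like(cs, 0.1), x=(1.0,), y=(1.0,))
        w = net.weights
        for _ in range(10):
            net = mech.PlasticNetwork(
                weights=w, cs=net.cs, x=net.x, y=net.y,
                learning_rate=net.learning_rate,
            )
            w = mech.hebbian_step(net, 1.0)
        assert w[0, 0] == pytest.approx(1.0)

    def test_bilinear_in_activities(self, rng):
        x = rng.normal(size=4)
        y = rng.normal(size=3)
        eta = mech.michaelis_learning_rate(0.2, 1.0)
        up = mech.hebbian_step(self._network(eta, cs=2.0, x=x, y=y), 0.5)
        down = mech.hebbian_step(self._network(eta, cs=2.0, x=-x, y=y), 0.5)
        np.testing.assert_allclose(down, -up)

    def test_saturating_rate_monotone_in_cs(self):
        eta = mech.michaelis_learning_rate(0.5, 2.0)
        cs = np.asarray([0.0, 0.5, 2.0, 10.0, 100.0])
        vals = eta(cs)
        assert np.all(np.diff(vals) > 0)
        assert np.all(vals < 0.5)
        deltas = [
            mech.hebbian_step(self._network(eta, cs=c, x=(1.0,), y=(1.0,)), 1.0)[0, 0]
            for c in cs[1:]
        ]
        assert all(a < b for a, b in zip(deltas, deltas[1:]))

    def test_non_finite_activity_rejected(self):
        eta = mech.michaelis_learning_rate(0.1, 1.0)
        net = self._network(eta, x=(np.nan, 1.0), y=(1.0,))
        with pytest.raises(ValueError, match="finite"):
            mech.hebbian_step(net, 1.0)

    def test_clipping(self):
        net = mech.PlasticNetwork(
            weights=np.asarray([[0.9]]), cs=1e9, x=[1.0], y=[1.0],
            learning_rate=lambda cs: np.ones_like(cs),
            clip=(-1.0, 1.0),
        )
        assert mech.hebbian_step(net, 10.0)[0, 0] == 1.0
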