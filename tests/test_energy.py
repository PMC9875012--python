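from dataclasses import replace

import numpy as np
import pytest

from neuroenergy.dynamics import (
    HHParameters,
    SimulationSettings,
    ionic_currents,
    simulate_network,
    simulate_single,
    steady_state_gating,
)
from neuroenergy.energy import (
    alpha_power_series,
    energy_identity_residual,
    ion_channel_power_peak,
    negative_energy_ratio,
    nernst_passive_split,
    network_energy_rate,
    power_decomposition,
)
from neuroenergy.graphs import DirectedGraph, StimulusVector


class TestDecomposition:
    def test_rest_state_arithmetic(self):
        # clamp-like check on the recorded initial sample: V = -65, I = 20
        traj = simulate_single(20.0, SimulationSettings(duration=1.0))
        d = power_decomposition(traj)
        assert d.W_I[0, 0] == pytest.approx(-65.0 * 20.0)  # -1300 nJ/s
        # leak term alone at rest: -0.3 * (-10.5)^2 = -33.075 nJ/s
        p = traj.params
        leak = -p.g_l * (-65.0 - p.E_l) ** 2
        assert leak == pytest.approx(-33.075)
        assert d.W_ion[0, 0] < leak  # the other channels only add drain

    def test_w_ion_pointwise_nonpositive(self, single_traj):
        d = power_decomposition(single_traj)
        assert (d.W_ion <= 0).all()

    def test_total_rate_is_sum_of_parts(self, single_traj):
        d = power_decomposition(single_traj)
        total = d.W_I + d.W_ion + d.gap_drive + d.amp_supply
        np.testing.assert_allclose(d.total_rate, total, rtol=1e-9)

    def test_per_channel_square_identity(self, single_traj):
        # -g (V-E)^2 == E i - V i with i = g (V-E), at every sample
        p = single_traj.params
        V = single_traj.V
        i_Na, i_K, i_l = ionic_currents(
            V, single_traj.m, single_traj.n, single_traj.h, p
        )
        for i, E, g_term in [
            (i_Na, p.E_Na, p.g_Na * single_traj.m**3 * single_traj.h),
            (i_K, p.E_K, p.g_K * single_traj.n**4),
            (i_l, p.E_l, p.g_l),
        ]:
            np.testing.assert_allclose(
                -g_term * (V - E) ** 2, E * i - V * i, rtol=1e-9, atol=1e-9
            )

    def test_pairwise_coupling_identity(self):
        # gap_drive + amp_supply telescopes to k C_ij (V_i^2 - V_j^2)
        g = DirectedGraph.from_edges(2, [(0, 1), (1, 0)])
        stim = StimulusVector(np.array([9.0, 26.0]))
        traj = simulate_network(
            g, stim, k=0.8, settings=SimulationSettings(duration=30.0)
        )
        d = power_decomposition(traj)
        V0, V1 = traj.V[:, 0], traj.V[:, 1]
        np.testing.assert_allclose(
            d.gap_drive[:, 1] + d.amp_supply[:, 1],
            0.8 * (V0**2 - V1**2),
            rtol=1e-9, atol=1e-7,
        )

    def test_fig1_steady_regime_magnitudes(self, single_traj):
        steady = single_traj.times >= 20.0
        d = power_decomposition(single_traj)
        WI = d.W_I[steady, 0]
        assert abs(WI.min()) == pytest.approx(1400.0, rel=0.20)
        assert WI.max() == pytest.approx(500.0, rel=0.20)
        peak = np.abs(d.W_ion[steady, 0]).max()
        assert peak == pytest.approx(90_000.0, rel=0.15)

    def test_ion_peak_helper_and_conductance_scaling(self, single_traj):
        peak = ion_channel_power_peak(single_traj)
        assert peak.shape == (1,)
        assert peak[0] == pytest.approx(
            np.abs(power_decomposition(single_traj).W_ion).max()
        )
        # passive trace (gates forced closed): |W_ion| linear in g_l
        p1 = HHParameters()
        fake = replace(
            single_traj,
            m=np.zeros_like(single_traj.m),
            n=np.zeros_like(single_traj.n),
            h=np.zeros_like(single_traj.h),
        )
        w1 = power_decomposition(fake, p1).W_ion
        p2 = replace(p1, g_l=0.6)
        w2 = power_decomposition(fake, p2).W_ion
        np.testing.assert_allclose(w2, 2.0 * w1, rtol=1e-12)


class TestEnergyRate:
    def test_constant_rate_closed_form(self, single_traj):
        d = power_decomposition(single_traj)
        const = replace(
            d,
            W_I=np.full_like(d.W_I, -250.0),
            W_ion=np.zeros_like(d.W_ion),
            gap_drive=np.zeros_like(d.W_I),
            amp_supply=np.zeros_like(d.W_I),
        )
        s = network_energy_rate(const, 100.0)
        assert s.E_N == pytest.approx(250.0, rel=1e-9)
        zero = replace(const, W_I=np.zeros_like(d.W_I))
        assert network_energy_rate(zero, 100.0).E_N == 0.0

    def test_window_beyond_trajectory_rejected(self, single_traj):
        d = power_decomposition(single_traj)
        with pytest.raises(ValueError, match="window"):
            network_energy_rate(d, 500.0)

    def test_decoupled_network_energy_equals_isolated_sum(self):
        g = DirectedGraph.from_edges(4, [(0, 1), (1, 2), (2, 3), (3, 0)])
        stim = StimulusVector(np.array([8.0, 14.0, 21.0, 28.0]))
        settings = SimulationSettings(duration=100.0)
        net = network_energy_rate(
            power_decomposition(
                simulate_network(g, stim, 0.0, settings)
            ),
            100.0,
        )
        iso_sum = sum(
            network_energy_rate(
                power_decomposition(simulate_single(I, settings)), 100.0
            ).E_N
            for I in stim.currents
        )
        assert net.E_N == pytest.approx(iso_sum, rel=1e-9)


class TestEnergyIdentity:
    def test_circuit_energy_matches_rate_form(self):
        traj = simulate_single(20.0, SimulationSettings(dt=0.01, duration=100.0))
        res = energy_identity_residual(traj)
        assert res < 1e-3

    def test_residual_shrinks_quadratically(self):
        r1 = energy_identity_residual(
            simulate_single(20.0, SimulationSettings(dt=0.01, duration=50.0))
        )
        r2 = energy_identity_residual(
            simulate_single(20.0, SimulationSettings(dt=0.005, duration=50.0))
        )
        assert r2 < r1 / 2.5  # ~4x expected for an O(dt^2) scheme


class TestNernstSplit:
    def test_split_reconstructs_channel_power(self, single_traj):
        # sign-consistent source power + passive power == negated squares
        p = single_traj.params
        i_Na, i_K, i_l = ionic_currents(
            single_traj.V, single_traj.m, single_traj.n, single_traj.h, p
        )
        raw_nernst = i_Na * p.E_Na + i_K * p.E_K + i_l * p.E_l
        _, passive = nernst_passive_split(single_traj)
        w_ion = power_decomposition(single_traj).W_ion
        np.testing.assert_allclose(
            raw_nernst - passive, w_ion, rtol=1e-9, atol=1e-6
        )

    def test_pump_power_with_sodium_closed(self):
        # h = 0 closes the sodium channel: P reduces to |i_K E_K| + |i_l E_l|
        traj = simulate_single(5.0, SimulationSettings(duration=5.0))
        fake = replace(traj, h=np.zeros_like(traj.h))
        P, _ = nernst_passive_split(fake)
        p = traj.params
        _, i_K, i_l = ionic_currents(fake.V, fake.m, fake.n, fake.h, p)
        np.testing.assert_allclose(
            P, np.abs(i_K * p.E_K) + np.abs(i_l * p.E_l), rtol=1e-12
        )


class TestNegativeEnergyRatio:
    def test_strictly_positive_power_gives_zero(self):
        t = np.linspace(0.0, 100.0, 1001)
        P = np.full((1001, 3), 5.0)
        assert negative_energy_ratio(P, t).alpha == 0.0

    def test_balanced_square_wave_gives_fifty_percent(self):
        t = np.arange(0.0, 100.0, 0.1)
        P = np.where((t // 10) % 2 == 0, 3.0, -3.0)[:, None]
        r = negative_energy_ratio(P, t)
        assert r.alpha == pytest.approx(50.0, abs=1.0)  # edges are trapezoids

    def test_zero_power_is_undefined(self):
        t = np.linspace(0.0, 10.0, 11)
        with pytest.raises(ValueError, match="zero power"):
            negative_energy_ratio(np.zeros((11, 2)), t)

    def test_alpha_modes_differ_and_stay_in_range(self, single_traj):
        for mode in ("nernst", "nernst_full", "raw"):
            P = alpha_power_series(single_traj, mode=mode)
            a = negative_energy_ratio(P, single_traj.times, 100.0).alpha
            assert 0.0 <= a <= 100.0
        with pytest.raises(ValueError, match="mode"):
            alpha_power_series(single_traj, mode="bogus")
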