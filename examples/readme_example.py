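import numpy as np
from neuroenergy import (
    SimulationSettings, simulate_single, detect_spikes,
    power_decomposition, network_energy_rate,
    generate_ba, draw_stimulus, simulate_network,
    network_information_rate, energy_efficiency,
    alpha_power_series, negative_energy_ratio,
)

# -- one neuron, 20 uA, 100 ms ------------------------------------------
traj = simulate_single(20.0, SimulationSettings(dt=0.01, duration=100.0))
raster = detect_spikes(traj)
steady = traj.times >= 20.0
decomp = power_decomposition(traj)
print(f"spikes in 100 ms: {raster.counts()[0]}")
print(f"steady-state spike peak: {traj.V[steady, 0].max():.1f} mV")
print(f"|W_ion| peak: {np.abs(decomp.W_ion[steady, 0]).max():.0f} nJ/s")
print(f"W_I range: [{decomp.W_I[steady, 0].min():.0f}, "
      f"{decomp.W_I[steady, 0].max():.0f}] nJ/s")
print(f"E_N (single neuron): {network_energy_rate(decomp, 100.0).E_N:.0f} nJ/s")

# -- a scale-free network at the reference scale ------------------------
graph = generate_ba(n=297, attach=8, target_edges=2345, seed=1)
stim = draw_stimulus(n=297, lo=7.0, hi=30.0, seed=2)
net = simulate_network(
    graph, stim, k=1.5,
    settings=SimulationSettings(duration=1500.0, record_stride=10),
)
E_N = network_energy_rate(power_decomposition(net), 1000.0).E_N
I_N = network_information_rate(detect_spikes(net), dt_bin=3.0, T=30.0,
                               duration=1500.0)
eff = energy_efficiency(I_N, E_N)
alpha = negative_energy_ratio(alpha_power_series(net), net.times, 100.0)
print(f"network E_N = {E_N:.3e} nJ/s, I_N = {I_N:.0f} bits/s")
print(f"efficiency eps_N = {eff.epsilon_N:.5f} bits/nJ")
print(f"negative-energy ratio alpha = {alpha.alpha:.3f} %")
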