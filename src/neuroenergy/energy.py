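"""Power and energy accounting for HH networks via the equivalent circuit.

For a 1 cm^2 membrane patch every current-times-voltage product is a power
in nJ/s.  The instantaneous energy rate of neuron j in a gap-junction
network is

    dE_j/dt = V_j I_j
              - g_Na m^3 h (V_j - E_Na)^2 - g_K n^4 (V_j - E_K)^2
              - g_l (V_j - E_l)^2
              + sum_i k C_ij V_j (V_i - V_j)      (junction current)
              + sum_i k C_ij V_i (V_i - V_j)      (amplifier supply)

The three squared terms are the ion-channel power W_ion (pointwise <= 0).
The channel power can equivalently be split into the power of the Nernst
voltage sources, i_Na E_Na + i_K E_K + i_l E_l, plus the passive
field-driven part -V_j (i_Na + i_K + i_l); the pump-power variant used by
the negative-energy-ratio synchronization index rewrites the Nernst block
with magnitudes, counting the reverse-polarity potassium/leak sources as
consuming and the sodium source as storing:

    P_j = |i_K E_K| + |i_l E_l| - |i_Na E_Na|.

Consumption is reported positive: integrated energies flip the sign of
the raw rate (whose dominant terms are negative squares).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dynamics import HHParameters, NetworkTrajectory, ionic_currents

__all__ = [
    "PowerDecomposition",
    "EnergySummary",
    "NegativeEnergyRatio",
    "power_decomposition",
    "ion_channel_power_peak",
    "network_energy_rate",
    "nernst_passive_split",
    "negative_energy_ratio",
    "energy_identity_residual",
]


@dataclass(frozen=True)
class PowerDecomposition:
    """Per-sample, per-neuron power terms (nJ/s), shape (samples, neurons).

    ``total_rate`` is the raw signed energy rate dE_j/dt; its negative
    integral is the energy consumed.
    """

    times: np.ndarray
    W_I: np.ndarray           # stimulus power V * I
    W_ion: np.ndarray         # channel power, three negated squares
    gap_drive: np.ndarray     # sum_i k C_ij V_j (V_i - V_j)
    amp_supply: np.ndarray    # sum_i k C_ij V_i (V_i - V_j)
    P_nernst: np.ndarray      # pump power |i_K E_K| + |i_l E_l| - |i_Na E_Na|
    P_passive: np.ndarray     # V (i_Na + i_K + i_l)

    @property
    def total_rate(self) -> np.ndarray:
        return self.W_I + self.W_ion + self.gap_drive + self.amp_supply

    @property
    def n_neurons(self) -> int:
        return self.W_I.shape[1]


@dataclass(frozen=True)
class EnergySummary:
    """Integrated consumption (positive) over a window.

    ``E_j`` per-neuron energy in nJ; ``E_N`` the network consumption rate
    sum_j E_j / t in nJ/s.
    """

    E_j: np.ndarray
    E_N: float
    window_ms: float


@dataclass(frozen=True)
class NegativeEnergyRatio:
    """Share of integrated power that is negative (energy-storing), %."""

    alpha: float
    E_negative: float
    E_positive: float
    window_ms: float


def _window_slice(times: np.ndarray, window_ms: float) -> slice:
    if window_ms > times[-1] + 1e-9:
        raise ValueError(
            f"window {window_ms} ms exceeds trajectory span {times[-1]} ms"
        )
    stop = int(np.searchsorted(times, window_ms + 1e-9, side="right"))
    return slice(0, stop)


def power_decomposition(
    traj: NetworkTrajectory, params: HHParameters | None = None
) -> PowerDecomposition:
    """Evaluate every power term sample-wise from the recorded states.

    With an empty graph (or k = 0) the coupling terms vanish and the
    decomposition reduces to the isolated-neuron energy rate.  When noise
    was enabled its recorded realization is included in the stimulus term.
    """
    p = params or traj.params
    V = traj.V
    i_Na, i_K, i_l = ionic_currents(V, traj.m, traj.n, traj.h, p)
    W_I = V * traj.applied_current()
    W_ion = -(
        p.g_Na * traj.m**3 * traj.h * (V - p.E_Na) ** 2
        + p.g_K * traj.n**4 * (V - p.E_K) ** 2
        + p.g_l * (V - p.E_l) ** 2
    )
    A = traj.graph.adjacency.astype(np.float64)
    if traj.k != 0.0 and A.any():
        S1 = V @ A              # (samples, n): sum of presynaptic V
        S2 = (V * V) @ A        # sum of presynaptic V^2
        indeg = A.sum(axis=0)
        gap_drive = traj.k * (V * S1 - indeg * V * V)
        amp_supply = traj.k * (S2 - V * S1)
    else:
        gap_drive = np.zeros_like(V)
        amp_supply = np.zeros_like(V)
    P_nernst = (
        np.abs(i_K * p.E_K) + np.abs(i_l * p.E_l) - np.abs(i_Na * p.E_Na)
    )
    P_passive = V * (i_Na + i_K + i_l)
    return PowerDecomposition(
        times=traj.times, W_I=W_I, W_ion=W_ion,
        gap_drive=gap_drive, amp_supply=amp_supply,
        P_nernst=P_nernst, P_passive=P_passive,
    )


def ion_channel_power_peak(
    traj: NetworkTrajectory, params: HHParameters | None = None
) -> np.ndarray:
    """Per-neuron max over time of |W_ion|, nJ/s."""
    decomp = power_decomposition(traj, params)
    return np.abs(decomp.W_ion).max(axis=0)


def network_energy_rate(
    decomp: PowerDecomposition, window_ms: float | None = None
) -> EnergySummary:
    """Integrate the signed rate over [0, window], sign-flipped.

    E_j = -integral of dE_j/dt (trapezoidal rule, ms converted to s), so
    consumption comes out positive; E_N = sum_j E_j / t in nJ/s.
    """
    t = decomp.times
    window_ms = float(window_ms if window_ms is not None else t[-1])
    sl = _window_slice(t, window_ms)
    tt = t[sl]
    E_j = -np.trapezoid(decomp.total_rate[sl], tt * 1e-3, axis=0)
    E_N = float(E_j.sum() / (tt[-1] * 1e-3))
    return EnergySummary(E_j=E_j, E_N=E_N, window_ms=window_ms)


def nernst_passive_split(
    traj: NetworkTrajectory, params: HHParameters | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """(P_nernst, P_passive) series; see the module docstring.

    The sign-consistent Nernst form i_Na E_Na + i_K E_K + i_l E_l plus
    P_passive reproduces the negated squared channel terms exactly; the
    returned P_nernst uses the magnitude (pump-power) convention.
    """
    decomp = power_decomposition(traj, params)
    return decomp.P_nernst, decomp.P_passive


def negative_energy_ratio(
    P: np.ndarray,
    times: np.ndarray,
    window_ms: float | None = None,
) -> NegativeEnergyRatio:
    """Negative-energy ratio of a power series, in percent.

    ``P`` is (samples, neurons) in nJ/s.  E_positive integrates
    P * sgn(P), E_negative integrates P * sgn(-P) (reported in
    magnitude), and

        alpha = |E_negative| / (E_positive + |E_negative|) * 100.

    Strong network synchronization shows up as a shift of this ratio; it
    is evaluated on the pump-power series P_j by default in the pipeline.
    """
    t = np.asarray(times, dtype=np.float64)
    P = np.atleast_2d(np.asarray(P, dtype=np.float64))
    if P.shape[0] != t.shape[0]:
        P = P.T
    window_ms = float(window_ms if window_ms is not None else t[-1])
    sl = _window_slice(t, window_ms)
    Pw = P[sl]
    tw = t[sl] * 1e-3
    if not Pw.any():
        raise ValueError("identically zero power: ratio undefined")
    pos = np.trapezoid(np.where(Pw > 0, Pw, 0.0), tw, axis=0).sum()
    neg = np.trapezoid(np.where(Pw < 0, Pw, 0.0), tw, axis=0).sum()
    alpha = abs(neg) / (pos + abs(neg)) * 100.0
    return NegativeEnergyRatio(
        alpha=float(alpha),
        E_negative=float(abs(neg)),
        E_positive=float(pos),
        window_ms=window_ms,
    )


def alpha_power_series(
    traj: NetworkTrajectory,
    params: HHParameters | None = None,
    mode: str = "nernst",
) -> np.ndarray:
    """Power series entering the negative-energy ratio.

    mode "nernst" (default): the pump power P_j = |i_K E_K| + |i_l E_l|
    - |i_Na E_Na| alone — the quantity the synchronization index is
    defined on.  mode "nernst_full": the full energy rate with the
    channel block replaced by the pump power (stimulus, passive and
    coupling terms included).  mode "raw": the unmodified signed rate.
    """
    decomp = power_decomposition(traj, params)
    if mode == "nernst":
        return decomp.P_nernst
    if mode == "nernst_full":
        return (
            decomp.W_I + decomp.P_nernst - decomp.P_passive
            + decomp.gap_drive + decomp.amp_supply
        )
    if mode == "raw":
        return decomp.total_rate
    raise ValueError(f"unknown mode {mode!r}")


def energy_identity_residual(
    traj: NetworkTrajectory, params: HHParameters | None = None
) -> float:
    """Max relative mismatch between the circuit energy and the rate form.

    The accumulated circuit energy is E(t) = C V^2 / 2 + H_Na + H_K + H_l
    with each source accumulator integrated as dH/dt = i E (trapezoidal).
    Its centered finite difference must match the isolated-neuron energy
    rate V I + W_ion along the trajectory to O(dt^2); the returned number
    is the max |mismatch| / max |rate|.  Only meaningful for k = 0.
    """
    p = params or traj.params
    V, t = traj.V, traj.times
    i_Na, i_K, i_l = ionic_currents(V, traj.m, traj.n, traj.h, p)
    source_rate = i_Na * p.E_Na + i_K * p.E_K + i_l * p.E_l
    dt_s = np.diff(t)[:, None]
    H = np.zeros_like(V)
    H[1:] = np.cumsum(0.5 * (source_rate[1:] + source_rate[:-1]) * dt_s, axis=0)
    E = 0.5 * p.C * V**2 + H
    dE = (E[2:] - E[:-2]) / (t[2:, None] - t[:-2, None])
    decomp = power_decomposition(traj, p)
    rate = (decomp.W_I + decomp.W_ion)[1:-1]
    return float(np.max(np.abs(dE - rate)) / np.max(np.abs(rate)))
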