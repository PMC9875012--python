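"""Hodgkin-Huxley single-neuron and gap-junction network dynamics.

The membrane model is the classical four-variable HH formulation: membrane
potential ``V`` (mV) plus gating variables ``m, n, h`` for the sodium and
potassium channels,

    C dV/dt = -g_Na m^3 h (V - E_Na) - g_K n^4 (V - E_K)
              - g_l (V - E_l) + I [+ I_noise] [+ I_gap],

with the standard voltage-dependent opening/closing rates.  Neurons are
coupled through gap junctions (electrical synapses): a directed edge
i -> j injects ``k (V_i - V_j)`` uA into neuron ``j``, where ``k`` is the
junction conductance in mS/cm^2.  All per-area quantities assume a 1 cm^2
membrane patch, so uA * mV products read directly as nJ/s.

Integration is fixed-step classical RK4 (forward Euler available for
cross-checks) with steady-state gating initial conditions, which avoids
startup transients dominating short analysis windows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _integrate
from .graphs import DirectedGraph, StimulusVector

__all__ = [
    "HHParameters",
    "SimulationSettings",
    "NoiseSpec",
    "NetworkTrajectory",
    "SpikeRaster",
    "gating_rates",
    "steady_state_gating",
    "hh_derivatives",
    "gap_junction_current",
    "simulate_network",
    "simulate_single",
    "detect_spikes",
    "IntegrationInstabilityError",
]


class IntegrationInstabilityError(RuntimeError):
    """The fixed-step integrator left the physical state region."""


@dataclass(frozen=True)
class HHParameters:
    """Membrane parameters; defaults are the squid-axon standard set.

    Units: C in uF/cm^2, conductances in mS/cm^2, potentials in mV.
    """

    C: float = 1.0
    g_Na: float = 120.0
    g_K: float = 36.0
    g_l: float = 0.3
    E_Na: float = 50.0
    E_K: float = -77.0
    E_l: float = -54.5
    V0: float = -65.0

    def __post_init__(self) -> None:
        if min(self.g_Na, self.g_K, self.g_l) <= 0 or self.C <= 0:
            raise ValueError("conductances and capacitance must be positive")


@dataclass(frozen=True)
class SimulationSettings:
    dt: float = 0.01            # integration step, ms
    duration: float = 100.0     # ms
    integrator: str = "rk4"     # "rk4" | "euler"
    record_stride: int = 1      # record every record_stride steps

    def __post_init__(self) -> None:
        if self.dt <= 0 or self.duration < self.dt:
            raise ValueError("require dt > 0 and duration >= dt")
        if self.integrator not in ("rk4", "euler"):
            raise ValueError(f"unknown integrator {self.integrator!r}")
        if self.record_stride < 1:
            raise ValueError("record_stride must be >= 1")

    @property
    def n_steps(self) -> int:
        return int(round(self.duration / self.dt))


@dataclass(frozen=True)
class NoiseSpec:
    """Gaussian white-noise current added to every neuron's stimulus.

    One independent draw N(mean, variance) per neuron per integration
    step, held constant within the step.  ``scale_by_sqrt_dt`` divides the
    standard deviation by sqrt(dt) instead, the Euler-Maruyama reading of
    unit-intensity white noise (the per-step reading is the default).
    """

    enabled: bool = False
    mean: float = 0.0
    variance: float = 1.0
    seed: int = 0
    scale_by_sqrt_dt: bool = False

    def __post_init__(self) -> None:
        if self.variance < 0:
            raise ValueError("variance must be >= 0")


@dataclass(frozen=True)
class NetworkTrajectory:
    """Recorded state of a network simulation.

    Arrays are (n_samples, n_neurons); ``noise`` holds the noise-current
    draw active on the step starting at each recorded time (zeros when
    noise is disabled).
    """

    times: np.ndarray
    V: np.ndarray
    m: np.ndarray
    n: np.ndarray
    h: np.ndarray
    stimulus: StimulusVector
    k: float
    graph: DirectedGraph
    params: HHParameters
    settings: SimulationSettings
    noise: np.ndarray | None = None

    @property
    def n_neurons(self) -> int:
        return self.V.shape[1]

    @property
    def duration(self) -> float:
        return float(self.times[-1])

    @property
    def sample_dt(self) -> float:
        return self.settings.dt * self.settings.record_stride

    def applied_current(self) -> np.ndarray:
        """Total applied current (stimulus + recorded noise), per sample."""
        I = np.broadcast_to(self.stimulus.currents, self.V.shape)
        if self.noise is not None:
            return I + self.noise
        return np.array(I)


@dataclass(frozen=True)
class SpikeRaster:
    """Per-neuron sorted spike times (ms) from threshold crossings."""

    spike_times: tuple[np.ndarray, ...]
    duration: float
    threshold: float

    @property
    def n_neurons(self) -> int:
        return len(self.spike_times)

    def counts(self) -> np.ndarray:
        return np.array([len(s) for s in self.spike_times])


# -- rate functions ---------------------------------------------------------

def gating_rates(V):
    """The six HH channel rates (alpha_m, beta_m, alpha_n, beta_n,
    alpha_h, beta_h) at potential ``V`` (mV), in 1/ms.

    Vectorized over ``V``.  The removable singularities of alpha_m at
    V = -40 and alpha_n at V = -55 are evaluated by their analytic limits
    (alpha_m -> 1, alpha_n -> 0.1).
    """
    V = np.asarray(V, dtype=np.float64)
    x = V + 40.0
    with np.errstate(divide="ignore", invalid="ignore"):
        am = np.where(
            np.abs(x) < 1e-7, 1.0, 0.1 * x / (1.0 - np.exp(-x / 10.0))
        )
    bm = 4.0 * np.exp(-(V + 65.0) / 18.0)
    y = V + 55.0
    with np.errstate(divide="ignore", invalid="ignore"):
        an = np.where(
            np.abs(y) < 1e-7, 0.1, 0.01 * y / (1.0 - np.exp(-y / 10.0))
        )
    bn = 0.125 * np.exp(-(V + 65.0) / 80.0)
    ah = 0.07 * np.exp(-(V + 65.0) / 20.0)
    bh = 1.0 / (1.0 + np.exp(-(V + 35.0) / 10.0))
    return am, bm, an, bn, ah, bh


def steady_state_gating(V):
    """Gating steady states (m_inf, n_inf, h_inf) at potential ``V``."""
    am, bm, an, bn, ah, bh = gating_rates(V)
    return am / (am + bm), an / (an + bn), ah / (ah + bh)


def ionic_currents(V, m, n, h, params: HHParameters = HHParameters()):
    """Channel currents (i_Na, i_K, i_l) in uA/cm^2; outward positive."""
    i_Na = params.g_Na * m**3 * h * (V - params.E_Na)
    i_K = params.g_K * n**4 * (V - params.E_K)
    i_l = params.g_l * (V - params.E_l)
    return i_Na, i_K, i_l


def hh_derivatives(V, m, n, h, I_total, params: HHParameters = HHParameters()):
    """Right-hand side (dV/dt, dm/dt, dn/dt, dh/dt) of the HH equations.

    ``I_total`` is the full applied current (stimulus + noise + coupling)
    in uA; dV/dt comes back in mV/ms.
    """
    i_Na, i_K, i_l = ionic_currents(V, m, n, h, params)
    am, bm, an, bn, ah, bh = gating_rates(V)
    dV = (I_total - i_Na - i_K - i_l) / params.C
    dm = am * (1.0 - m) - bm * m
    dn = an * (1.0 - n) - bn * n
    dh = ah * (1.0 - h) - bh * h
    return dV, dm, dn, dh


def gap_junction_current(k: float, V_i, V_j):
    """Gap-junction current k (V_i - V_j) in uA; positive depolarizes j."""
    return k * (np.asarray(V_i) - np.asarray(V_j))


# -- simulation -------------------------------------------------------------

def _csr_by_target(graph: DirectedGraph):
    A = graph.adjacency
    indptr = np.zeros(graph.n + 1, dtype=np.int64)
    cols = []
    for j in range(graph.n):
        src = np.nonzero(A[:, j])[0]
        cols.append(src)
        indptr[j + 1] = indptr[j] + len(src)
    indices = (
        np.concatenate(cols).astype(np.int64)
        if cols else np.zeros(0, dtype=np.int64)
    )
    return indptr, indices


def simulate_network(
    graph: DirectedGraph,
    stimulus: StimulusVector,
    k: float = 0.0,
    settings: SimulationSettings = SimulationSettings(),
    noise: NoiseSpec = NoiseSpec(),
    params: HHParameters = HHParameters(),
) -> NetworkTrajectory:
    """Integrate a gap-junction-coupled HH network.

    Every neuron starts at ``V0`` with gating at its steady state, receives
    its constant stimulus current (plus optional per-step Gaussian noise),
    and is driven by ``k (V_i - V_j)`` from each presynaptic neuron ``i``.
    Fully deterministic given ``noise.seed``.
    """
    if stimulus.n != graph.n:
        raise ValueError(
            f"stimulus length {stimulus.n} != graph size {graph.n}"
        )
    nn = graph.n
    V0 = np.full(nn, params.V0)
    m0, n0, h0 = (np.full(nn, g) for g in steady_state_gating(params.V0))
    indptr, indices = _csr_by_target(graph)

    times, V, m, n, h, noise_rec, status, bad_step = _integrate.integrate(
        V0, m0, n0, h0,
        np.ascontiguousarray(stimulus.currents, dtype=np.float64),
        float(k), indptr, indices,
        params.C, params.g_Na, params.g_K, params.g_l,
        params.E_Na, params.E_K, params.E_l,
        settings.dt, settings.n_steps, settings.record_stride,
        noise.enabled, noise.mean, float(np.sqrt(noise.variance)),
        noise.scale_by_sqrt_dt, np.uint32(noise.seed % (2**32)),
        settings.integrator == "euler",
    )
    if status != _integrate.STATUS_OK:
        t_bad = bad_step * settings.dt
        what = (
            "gating variable left [0, 1]"
            if status == _integrate.STATUS_GATING
            else "membrane potential became non-finite"
        )
        raise IntegrationInstabilityError(
            f"{what} at t = {t_bad:.4f} ms (dt = {settings.dt} ms too large?)"
        )
    return NetworkTrajectory(
        times=times, V=V, m=m, n=n, h=h,
        stimulus=stimulus, k=float(k), graph=graph,
        params=params, settings=settings,
        noise=noise_rec if noise.enabled else None,
    )


def simulate_single(
    I: float,
    settings: SimulationSettings = SimulationSettings(),
    noise: NoiseSpec = NoiseSpec(),
    params: HHParameters = HHParameters(),
) -> NetworkTrajectory:
    """Single isolated neuron under constant current ``I`` (uA)."""
    graph = DirectedGraph.empty(1)
    stim = StimulusVector(np.array([float(I)]))
    return simulate_network(graph, stim, 0.0, settings, noise, params)


def detect_spikes(
    traj: NetworkTrajectory,
    threshold: float = 0.0,
    min_separation: float = 2.0,
) -> SpikeRaster:
    """Spike times as upward threshold crossings of the recorded V.

    A spike is the first sample at or above ``threshold`` after the trace
    was below it; subsequent crossings within ``min_separation`` ms are
    suppressed (HH action potentials at the standard parameters are ~2 ms
    wide and overshoot 0 mV, so the defaults are robust).
    """
    if traj.sample_dt > 0.1 + 1e-12:
        raise ValueError(
            "spike detection needs <= 0.1 ms sampling; "
            f"got {traj.sample_dt} ms"
        )
    out = []
    for j in range(traj.n_neurons):
        v = traj.V[:, j]
        above = v >= threshold
        crossings = np.flatnonzero(above[1:] & ~above[:-1]) + 1
        t = traj.times[crossings]
        if len(t) > 1:
            keep = [0]
            for idx in range(1, len(t)):
                if t[idx] - t[keep[-1]] >= min_separation:
                    keep.append(idx)
            t = t[keep]
        out.append(t)
    return SpikeRaster(
        spike_times=tuple(out),
        duration=traj.duration,
        threshold=threshold,
    )
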