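"""Experiment orchestration: coupling sweeps, bin-length sweeps, noise runs.

Each condition (family, repeat, k, noise) generates or loads a graph,
draws a stimulus vector, integrates the coupled HH network once over the
longest window required, and derives every metric from that single
trajectory:

* E_N    — network energy-consumption rate over ``energy_window`` ms;
* I_N    — summed binned-word entropy rates over ``info_duration`` ms;
* eps_N  — I_N / E_N;
* alpha  — negative-energy ratio of the pump power over ``alpha_window`` ms.

The stimulus vector is reused across the k grid within a (family, repeat)
cell so the coupling strength is the only moving variable; repeats draw
fresh seeds (and, by default, fresh graphs).  Everything is a pure
function of the spec and ``base_seed``.
"""

from __future__ import annotations

import hashlib
import io
import json
import logging
import time
from dataclasses import asdict, dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .dynamics import (
    NoiseSpec,
    SimulationSettings,
    detect_spikes,
    simulate_network,
)
from .energy import (
    alpha_power_series,
    negative_energy_ratio,
    network_energy_rate,
    power_decomposition,
)
from .graphs import (
    CELEGANS_EDGES,
    CELEGANS_N,
    DirectedGraph,
    draw_stimulus,
    generate_ba,
    generate_er,
    generate_ws,
    load_connectome,
)
from .information import network_information_rate

__all__ = ["SweepSpec", "SweepResult", "run_sweep",
           "run_bin_length_sweep", "write_results", "read_results"]

log = logging.getLogger("neuroenergy")

DEFAULT_K_GRID = tuple(np.round(np.linspace(0.1, 2.0, 20), 4))


@dataclass(frozen=True)
class SweepSpec:
    """Full description of one sweep experiment.

    Defaults are the study conditions: 297 neurons, ~2,345 directed
    edges, stimulus ~ U[7, 30] uA, k spanning [0.1, 2] mS/cm^2, 1,000 ms
    energy window, 9,000 ms information record (dt_bin = 3 ms, T = 30 ms,
    300 words), 100 ms synchronization window.
    """

    families: tuple[str, ...] = ("BA", "ER", "WS")
    k_grid: tuple[float, ...] = DEFAULT_K_GRID
    n: int = CELEGANS_N
    target_edges: int = CELEGANS_EDGES
    ba_attach: int = 8
    ws_neighbors: int = 8
    ws_rewire_prob: float = 0.1
    connectome_path: str | None = None
    stimulus_range: tuple[float, float] = (7.0, 30.0)
    energy_window: float = 1000.0
    info_duration: float = 9000.0
    alpha_window: float = 100.0
    dt_bin: float = 3.0
    T: float = 30.0
    alpha_mode: str = "nernst"
    dt: float = 0.01
    record_stride: int = 10
    noise: NoiseSpec = NoiseSpec()
    repeats: int = 1
    base_seed: int = 0
    new_graph_per_repeat: bool = True

    def __post_init__(self) -> None:
        if not self.k_grid or min(self.k_grid) <= 0:
            raise ValueError("k_grid must be nonempty with all k > 0")
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")
        if "file" in self.families and not self.connectome_path:
            raise ValueError("family 'file' requires connectome_path")

    @property
    def duration(self) -> float:
        return max(self.energy_window, self.info_duration, self.alpha_window)

    def spec_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


@dataclass(frozen=True)
class SweepResult:
    """Tidy per-condition rows plus repeat summaries."""

    rows: pd.DataFrame
    summary: pd.DataFrame | None
    spec: SweepSpec

    def __eq__(self, other) -> bool:  # convenience for determinism checks
        return (
            isinstance(other, SweepResult)
            and self.rows.equals(other.rows)
            and self.spec == other.spec
        )


def _condition_seeds(base_seed: int, family_idx: int, repeat: int):
    """Three decorrelated child seeds (graph, stimulus, noise) < 2^31."""
    ss = np.random.SeedSequence(
        entropy=int(base_seed), spawn_key=(family_idx, repeat)
    )
    g, s, z = ss.generate_state(3)
    return int(g % 2**31), int(s % 2**31), int(z % 2**31)


def _make_graph(spec: SweepSpec, family: str, seed: int) -> DirectedGraph:
    if family == "BA":
        return generate_ba(spec.n, spec.ba_attach, spec.target_edges, seed)
    if family == "ER":
        return generate_er(spec.n, spec.target_edges, seed)
    if family == "WS":
        return generate_ws(
            spec.n, spec.ws_neighbors, spec.ws_rewire_prob, seed
        )
    if family == "file":
        return load_connectome(spec.connectome_path)
    raise ValueError(f"unknown family {family!r}")


def _run_condition(spec: SweepSpec, graph, stimulus, k, noise_seed):
    noise = replace(spec.noise, seed=noise_seed) if spec.noise.enabled \
        else spec.noise
    settings = SimulationSettings(
        dt=spec.dt, duration=spec.duration, record_stride=spec.record_stride
    )
    traj = simulate_network(graph, stimulus, k, settings, noise)
    decomp = power_decomposition(traj)
    E_N = network_energy_rate(decomp, spec.energy_window).E_N
    raster = detect_spikes(traj)
    I_N = network_information_rate(
        raster, spec.dt_bin, spec.T, spec.info_duration
    )
    P = alpha_power_series(traj, mode=spec.alpha_mode)
    alpha = negative_energy_ratio(P, traj.times, spec.alpha_window).alpha
    eps = I_N / E_N if E_N > 0 else np.nan
    return E_N, I_N, eps, alpha


def run_sweep(spec: SweepSpec) -> SweepResult:
    """Run the full (family x repeat x k) grid of conditions."""
    records = []
    for fi, family in enumerate(spec.families):
        for rep in range(spec.repeats):
            g_seed, s_seed, z_seed = _condition_seeds(
                spec.base_seed, fi, rep
            )
            if not spec.new_graph_per_repeat:
                g_seed, _, _ = _condition_seeds(spec.base_seed, fi, 0)
            graph = _make_graph(spec, family, g_seed)
            stimulus = draw_stimulus(
                spec.n if family != "file" else graph.n,
                *spec.stimulus_range, seed=s_seed,
            )
            for k in spec.k_grid:
                t0 = time.perf_counter()
                E_N, I_N, eps, alpha = _run_condition(
                    spec, graph, stimulus, float(k), z_seed
                )
                log.info(
                    "family=%s rep=%d k=%.3g done in %.1fs "
                    "(E_N=%.4g I_N=%.4g)",
                    family, rep, k, time.perf_counter() - t0, E_N, I_N,
                )
                records.append(
                    dict(
                        family=family, repeat=rep, seed=g_seed, k=float(k),
                        noise=bool(spec.noise.enabled), E_N=E_N, I_N=I_N,
                        epsilon_N=eps, alpha=alpha,
                        window_ms=spec.energy_window,
                    )
                )
    rows = pd.DataFrame.from_records(records)
    summary = None
    if spec.repeats >= 2:
        summary = (
            rows.groupby(["family", "k", "noise"])[
                ["E_N", "I_N", "epsilon_N", "alpha"]
            ]
            .agg(["mean", "std"])
            .reset_index()
        )
        summary.columns = [
            "_".join(c).rstrip("_") for c in summary.columns
        ]
    return SweepResult(rows=rows, summary=summary, spec=spec)


def run_bin_length_sweep(
    spec: SweepSpec,
    dt_bins: tuple[float, ...] = tuple(float(d) for d in range(1, 11)),
    word_length: int = 10,
    n_words: int = 300,
    k: float = 1.5,
) -> SweepResult:
    """Information rate versus bin width at fixed word length.

    For each bin width the window is ``T = word_length * dt_bin`` and the
    record is cut to exactly ``n_words`` windows (duration 300 T at the
    defaults), so every estimate rests on the same number of words.  One
    trajectory of the longest duration is simulated per (family, repeat)
    and truncated per bin width.
    """
    max_duration = n_words * word_length * max(dt_bins)
    records = []
    for fi, family in enumerate(spec.families):
        for rep in range(spec.repeats):
            g_seed, s_seed, z_seed = _condition_seeds(
                spec.base_seed, fi, rep
            )
            graph = _make_graph(spec, family, g_seed)
            stimulus = draw_stimulus(
                spec.n if family != "file" else graph.n,
                *spec.stimulus_range, seed=s_seed,
            )
            noise = replace(spec.noise, seed=z_seed) \
                if spec.noise.enabled else spec.noise
            settings = SimulationSettings(
                dt=spec.dt, duration=max_duration,
                record_stride=spec.record_stride,
            )
            traj = simulate_network(graph, stimulus, k, settings, noise)
            raster = detect_spikes(traj)
            for db in dt_bins:
                T = word_length * db
                I_N = network_information_rate(
                    raster, db, T, duration=n_words * T
                )
                records.append(
                    dict(
                        family=family, repeat=rep, seed=g_seed, k=k,
                        noise=bool(spec.noise.enabled),
                        dt_bin=db, T=T, I_N=I_N,
                    )
                )
    rows = pd.DataFrame.from_records(records)
    return SweepResult(rows=rows, summary=None, spec=spec)


def write_results(result: SweepResult, path: str | Path) -> None:
    """Tidy CSV with a commented provenance header; lossless round-trip."""
    path = Path(path)
    buf = io.StringIO()
    buf.write(f"# neuroenergy {__version__}\n")
    buf.write(f"# spec_hash {result.spec.spec_hash()}\n")
    buf.write(f"# base_seed {result.spec.base_seed}\n")
    result.rows.to_csv(buf, index=False)
    path.write_text(buf.getvalue())
    if result.summary is not None:
        spath = path.with_name(path.stem + "_summary" + path.suffix)
        result.summary.to_csv(spath, index=False)


def read_results(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")
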