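"""Spike-train information rates via the direct (binned-word) method.

A spike train is binarized into time bins of width dt_bin: a bin is 1 if
at least one spike falls in it.  Consecutive runs of ``l = T / dt_bin``
bins inside non-overlapping windows of length ``T`` form binary words;
the plug-in Shannon entropy of the word distribution, divided by the
window length in seconds, is the neuron's entropy rate

    H_T = -(1/T) sum_w p(w) log2 p(w)      [bits/s],

bounded by 0 <= H_T <= l/T.  The network information rate I_N sums the
per-neuron rates, and the energy efficiency is eps_N = I_N / E_N in
bits/nJ.

The plug-in estimator is applied exactly as stated — no bias correction.
With few words and many possible symbols it is downward-biased; the test
suite demonstrates convergence to the analytic rate on Bernoulli-bin
synthetic trains as the word count grows.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .dynamics import SpikeRaster

__all__ = [
    "BinnedSpikeMatrix",
    "EntropyEstimate",
    "EfficiencyResult",
    "binarize",
    "build_words",
    "entropy_rate",
    "network_information_rate",
    "energy_efficiency",
]


@dataclass(frozen=True)
class BinnedSpikeMatrix:
    """Binary (neurons x bins) matrix; half-open bins of width dt_bin ms."""

    bits: np.ndarray
    dt_bin: float
    origin: float = 0.0

    @property
    def n_neurons(self) -> int:
        return self.bits.shape[0]

    @property
    def n_bins(self) -> int:
        return self.bits.shape[1]


@dataclass(frozen=True)
class EntropyEstimate:
    H_T: float          # bits/s
    l: int              # word length, characters
    T: float            # window, ms
    dt_bin: float       # bin width, ms
    n_words: int


@dataclass(frozen=True)
class EfficiencyResult:
    I_N: float          # bits/s
    E_N: float          # nJ/s
    epsilon_N: float    # bits/nJ


def binarize(
    raster: SpikeRaster, dt_bin: float, duration: float | None = None
) -> BinnedSpikeMatrix:
    """Bin spike times into a binary matrix.

    A bin covers [b * dt_bin, (b+1) * dt_bin); a spike exactly on a
    boundary belongs to the bin it opens.  Multiple spikes in one bin
    still give 1.  A duration that is not a multiple of dt_bin is
    truncated with a warning.
    """
    if dt_bin <= 0:
        raise ValueError("dt_bin must be positive")
    duration = float(duration if duration is not None else raster.duration)
    n_bins = int(np.floor(duration / dt_bin + 1e-9))
    if abs(n_bins * dt_bin - duration) > 1e-9 * max(1.0, duration):
        warnings.warn(
            f"duration {duration} ms truncated to {n_bins} bins of "
            f"{dt_bin} ms",
            stacklevel=2,
        )
    bits = np.zeros((raster.n_neurons, n_bins), dtype=np.uint8)
    for j, spikes in enumerate(raster.spike_times):
        idx = np.floor(np.asarray(spikes) / dt_bin + 1e-9).astype(np.int64)
        idx = idx[(idx >= 0) & (idx < n_bins)]
        bits[j, idx] = 1
    return BinnedSpikeMatrix(bits=bits, dt_bin=float(dt_bin))


def build_words(binned: BinnedSpikeMatrix, T: float) -> np.ndarray:
    """Tile each neuron's bit sequence into non-overlapping l-bit words.

    Returns an integer array (neurons, n_words) with each word encoded as
    an integer (most significant bit first); ``l = T / dt_bin`` must be a
    whole number, and a trailing partial window is dropped with a warning.
    """
    ratio = T / binned.dt_bin
    l = int(round(ratio))
    if l < 1 or abs(ratio - l) > 1e-9:
        raise ValueError(
            f"window T={T} ms must be a positive multiple of "
            f"dt_bin={binned.dt_bin} ms"
        )
    if l > 62:
        raise ValueError(f"word length {l} exceeds the 62-bit encoding")
    n_words = binned.n_bins // l
    if n_words * l != binned.n_bins:
        warnings.warn(
            f"dropping {binned.n_bins - n_words * l} trailing bin(s) not "
            f"filling a window",
            stacklevel=2,
        )
    if n_words == 0:
        raise ValueError("record shorter than one window")
    usable = binned.bits[:, : n_words * l]
    powers = 1 << np.arange(l - 1, -1, -1, dtype=np.int64)
    return usable.reshape(binned.n_neurons, n_words, l).astype(np.int64) @ powers


def entropy_rate(words: np.ndarray, T: float, dt_bin: float | None = None) -> EntropyEstimate:
    """Plug-in entropy rate of one neuron's word sequence, bits/s.

    Word probabilities are the empirical frequencies; the window length T
    (ms) is converted to seconds so the rate is per second.
    """
    words = np.asarray(words).ravel()
    if words.size == 0:
        raise ValueError("empty word sequence")
    _, counts = np.unique(words, return_counts=True)
    p = counts / counts.sum()
    H_bits = float(-(p * np.log2(p)).sum())
    T_s = T * 1e-3
    l = int(round(T / dt_bin)) if dt_bin else 0
    return EntropyEstimate(
        H_T=H_bits / T_s, l=l, T=float(T),
        dt_bin=float(dt_bin or np.nan), n_words=int(words.size),
    )


def network_information_rate(
    raster: SpikeRaster,
    dt_bin: float,
    T: float,
    duration: float | None = None,
) -> float:
    """Sum of per-neuron plug-in entropy rates, bits/s."""
    binned = binarize(raster, dt_bin, duration)
    words = build_words(binned, T)
    return float(
        sum(
            entropy_rate(words[j], T, dt_bin).H_T
            for j in range(words.shape[0])
        )
    )


def energy_efficiency(I_N: float, E_N: float) -> EfficiencyResult:
    """Energy efficiency eps_N = I_N / E_N in bits/nJ."""
    if E_N <= 0:
        raise ValueError(f"efficiency undefined for E_N = {E_N} <= 0")
    return EfficiencyResult(I_N=float(I_N), E_N=float(E_N),
                            epsilon_N=float(I_N) / float(E_N))
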