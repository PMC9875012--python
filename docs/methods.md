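# Methods

## Model

Each neuron is a classical four-variable Hodgkin–Huxley membrane patch:

    C dV/dt = −g_Na m³h (V − E_Na) − g_K n⁴ (V − E_K) − g_l (V − E_l) + I + I_noise + I_gap
    dx/dt   = α_x(V)(1 − x) − β_x(V) x,   x ∈ {m, n, h}

with the standard squid-axon rate functions.  Defaults (per 1 cm² of
membrane): C = 1 µF/cm², g_Na = 120, g_K = 36, g_l = 0.3 mS/cm²,
E_Na = 50, E_K = −77, E_l = −54.5 mV, initial potential V₀ = −65 mV.
Because all quantities are per 1 cm², a current (µA) times a voltage (mV)
is a power in nJ/s with no unit conversion.

Neurons are coupled by gap junctions (electrical synapses).  The network
is a **directed binary graph** C with C_ij = 1 for an edge i → j; neuron
j receives the one-way current Σ_i k C_ij (V_i − V_j), with k in mS/cm²
the junction conductance ("coupling strength").  Directedness is taken
literally: a single directed edge influences only its target.

Assumptions worth making explicit:

* constant stimulus currents per neuron (no time structure beyond noise);
* identical membrane parameters across the network;
* every neuron starts at V₀ with gating at its steady state
  m∞(V₀), n∞(V₀), h∞(V₀) — no random initial phases;
* binary, unweighted synapses; chemical synapses are out of scope.

## Energy accounting

The equivalent circuit stores E(t) = ½CV² + H_Na + H_K + H_l, where each
ionic source accumulates Ḣ = i·E_rev.  Differentiating and substituting
the membrane equation gives the per-neuron energy rate

    dE_j/dt = V_j I_j − g_Na m³h (V_j−E_Na)² − g_K n⁴ (V_j−E_K)²
              − g_l (V_j−E_l)²
              + Σ_i k C_ij V_j (V_i−V_j)   (power absorbed at the junction)
              + Σ_i k C_ij V_i (V_i−V_j)   (power supplied by the driving side)

The three squared terms (the ion-channel power W_ion) are pointwise
non-positive; the raw integral of dE_j/dt is therefore negative, and the
package reports **consumption as positive**: E_j = −∫ dE_j/dt dt,
E_N = Σ_j E_j / t in nJ/s.  `energy_identity_residual` turns the
derivation itself into a regression test: the centered finite difference
of the accumulated circuit energy must match the rate form to O(dt²)
along any simulated trajectory (measured ≈ 3·10⁻⁴ at dt = 0.01 ms,
shrinking ≈ 4× when dt is halved).

The channel power can be rewritten as the power of the Nernst voltage
sources plus a passive, field-driven part V_j(i_Na + i_K + i_l).  The
**pump power** re-expresses the source block with magnitudes, counting
the reverse-polarity potassium and leak sources as consuming and the
sodium source as storing:

    P_j = |i_K E_K| + |i_l E_l| − |i_Na E_Na|.

### Negative-energy ratio

The synchronization index α is the share of integrated power that is
negative over a window [0, t]:

    α = |E_neg| / (E_pos + |E_neg|) × 100 %,

with E_pos and E_neg the positive- and negative-part integrals of a
per-neuron power series summed over the network.  Magnitudes are used
throughout so α ∈ [0, 100] (a literal signed reading would force
α ≤ 0).  Which power series enters α is a genuine design choice; the
package implements three (`alpha_mode`):

* `"nernst"` (default) — the pump power P_j alone.  This is the series
  the index is defined on, and at the reference network scale it yields
  ratios in the low-percent range (≈ 2–3 % over 100 ms windows), with
  brief negative excursions exactly during the sodium-dominated spike
  upstroke — the behaviour the index is meant to capture.
* `"nernst_full"` — the full rate with the channel block replaced by the
  pump power (stimulus, passive and coupling terms included).
* `"raw"` — the unmodified signed rate of the decomposition (dominated
  by the negative squared terms, so α saturates near 100 %; kept for
  completeness).

## Information rate

Spike trains (upward crossings of 0 mV with a 2 ms refractory guard) are
binarized into Δt-wide half-open bins, tiled into non-overlapping windows
of length T, and each window of l = T/Δt bins becomes a binary word.  The
per-neuron entropy rate is the plug-in Shannon entropy of the empirical
word distribution divided by T in seconds, H_T = −(1/T) Σ p(ω) log₂ p(ω)
bits/s, bounded by l/T.  The network information rate I_N sums per-neuron
rates (words are per neuron, not joint), and the efficiency is
ε_N = I_N / E_N in bits/nJ.

Defaults follow the study conditions: Δt = 3 ms, T = 30 ms (l = 10),
9,000 ms records giving 300 words per estimate; the bin-width sweep holds
l = 10 and cuts every record to the same word budget (300 T at the
defaults) so estimates are comparable across Δt.

**Estimator bias.**  The plug-in estimator is applied with no
correction.  With a few hundred words and up to 2¹⁰ symbols it is
downward-biased by roughly the first-order Miller–Madow term
(m−1)/(2N ln 2) per word (m = observed distinct words).  The test suite
demonstrates this on Bernoulli-bin trains: in the sparse regime typical
of ~80 Hz trains at 1–3 ms bins (bin probability ≈ 0.1) the bias is
negligible against sampling error and the estimate lands within 3 SE of
the analytic rate at 10⁴ words; at denser bins (p = 0.3) the shortfall
matches the first-order bias term.  Absolute I_N values at 300 words
should therefore be read as estimator-dependent; trends across k or Δt
are robust.

## Synthetic study conditions

The generator stage emulates the reference biological network's scale:
directed binary graphs with n = 297 nodes and ~2,345 edges, per-neuron
constant stimulus currents ~ U[7, 30] µA, and optional Gaussian noise
current of mean 0 and variance 1 µA² (one draw per neuron per step, held
within the step; a 1/√dt-scaled variant is available behind a flag since
a bandwidth-free "unit variance" prescription is discretization-
dependent).

* **ER** — directed G(n, m): exactly m uniform directed non-self edges.
* **WS** — classical rewired ring lattice (default neighbors = 8,
  rewire probability 0.1), symmetrized, giving n·neighbors = 2,376
  directed edges (within 1.3 % of the target).
* **BA** — classical preferential attachment (attach = 8, matching the
  target mean degree), each edge oriented uniformly at random, then
  uniform random directed edges added/removed to hit the target exactly.

What these graphs do **not** emulate: synaptic weights and signs,
chemical synapses, spatial structure, and the in/out-degree correlations
of a real connectome.  A real adjacency can be supplied as an edge list
or 0/1 CSV (self-loops are dropped with a warning); none ships with the
package.  Passing tests on the synthetic families therefore validates
the machinery and the qualitative coupling phenomenology, not any claim
about a particular organism's wiring.

## Numerics

* **Integrator**: fixed-step classical RK4, dt = 0.01 ms default
  (forward Euler available for cross-checks).  Halving dt moves spike
  times by < 0.1 ms and peak V by < 0.5 mV in the single-neuron
  benchmark.  Gating variables are checked against [0, 1] (tolerance
  10⁻⁶) each step; violations raise an error naming the offending time
  rather than silently clipping.
* **Rate-function singularities**: α_m at V = −40 and α_n at V = −55 are
  evaluated by their analytic limits within 10⁻⁷ mV of the singular
  point.
* **Recording**: every `record_stride` steps (default stride 10 →
  0.1 ms sampling in network runs, the resolution floor for spike
  detection); single-neuron benchmarks record every step.
* **Energy integrals**: trapezoidal rule on the recorded grid, O(dt²),
  consistent with the integrator's recording.
* **Settle window**: the quiescent start produces one overshooting first
  spike (peak ≈ 41 mV vs ≈ 25 mV in steady firing).  Figure-level
  single-neuron quantities (peak V, power extremes) are measured after a
  20 ms settle window, i.e. on the steady repetitive-firing regime.
* **Seeds**: every stochastic stage (graphs, stimulus, noise) takes an
  explicit seed; sweep-level seeds derive from a single `base_seed` via
  `numpy` SeedSequence spawning, so whole pipelines are bit-reproducible.
  The stimulus vector is reused across the k grid within a (family,
  repeat) cell, isolating the coupling effect.

## Problem sizes in the test suite

Heavy checks run at the full reference scale (297 neurons, ~2,345
edges) but with economical records, chosen so the default suite runs in
minutes on one core: three repeats per family, 1,500 ms information
records (the length the noise preset also uses) with 1,000 ms energy
windows and 100 ms synchronization windows; the bin-width sweep uses 30
words per estimate.  Unit tests use 20–40-neuron graphs at matched
density.  The library defaults remain the full study conditions (9,000
ms records, 300 words, 20-point k grid).

## Known limitations and observed behaviour

* With identical initial states and literal directed coupling, all three
  synthetic families **phase-lock completely** for k ≳ 0.3 at the
  reference density (per-neuron rates become identical); between-family
  differences in I_N at high k are then only ~5–10 % and comparable to
  the across-seed spread, so the ordering of the scale-free (BA) family
  against ER/WS at high k is seed-dependent rather than a large, robust
  separation.  The coupling-strength trends that are robust across seeds
  are:
  E_N decreasing in k, I_N decreasing in k, and α of the synthetic
  families decreasing mildly in k.
* The per-step noise convention makes the effective noise bandwidth
  depend on dt; comparisons across dt with noise enabled should use the
  1/√dt variant.
* Absolute entropy rates inherit the plug-in estimator's bias (above).
* Memory: network trajectories store four state variables per neuron per
  sample; a 9,000 ms, 297-neuron record at 0.1 ms sampling is ≈ 0.9 GB.
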