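# Methods

`spikesat` solves binary constraint satisfaction problems (CSPs) by simulating
a stochastic spiking neural network whose attractor structure mirrors the
constraint graph.  This note describes the model, the translation, the
numerical scheme, the parameter regimes each bundled problem family uses and
why, what the tests demonstrate, and the known limitations.

## Problem model

A CSP is the triple ⟨X, D, C⟩: N variables, one finite ordered value domain
per variable, and signed binary constraints.  A *negative* constraint forbids
its two variables from taking equal values; a *positive* constraint requires
equality.  This covers the three bundled families:

* **graph k-coloring** — one variable per vertex, k colors, a negative
  constraint per edge;
* **Sudoku** — 81 cells × 9 digits; 810 distinct negative constraints
  (324 row pairs + 324 column pairs + 162 box pairs that share neither row
  nor column); clues are metadata consumed by the compiler;
* **Ising spin systems** — one ±1 variable per lattice site.  With couplings
  J_ij ∈ {+U, −U} and field h, the energy is
  H = −Σ_bonds J_ij S_i S_j − h Σ_i S_i.  Ferromagnetic bonds (J > 0) map to
  positive constraints, antiferromagnetic (J < 0) to negative ones, so lower
  energy is exactly more satisfied constraints.  Random ±J lattices
  (Edwards–Anderson disorder, probability `p_af` of an AF bond) produce
  frustration: constraint sets no configuration satisfies completely.

Exact oracles (`brute_force_solve`, exhaustive Ising enumeration) back every
stochastic result on small instances; any solution the network reports is
re-verified symbolically before being trusted.

## Network translation

Each (variable, value) pair becomes a sub-population of `n` leaky
integrate-and-fire neurons.  Three projection classes:

1. **WTA** — all ordered pairs of a variable's sub-populations are connected
   with inhibition, a soft winner-take-all: on average one value stays active
   per variable, without hard mutual exclusion that would freeze the search.
2. **Constraint** — for every constraint and every value index, the
   equal-value sub-populations of the two variables are connected in both
   directions: inhibitory for negative constraints, excitatory for positive.
3. **Noise** — per sub-population Poisson sources: *stimulation* (excitatory)
   supplies the energy of the search, *dissipation* (inhibitory) drains it.
   Each source is a population of independent generators active over a
   scheduled pulse window; a source per (sub-population, pulse).

Connectivity is random: each neuron pair of a projection connects with
probability `p_conn` (default 0.5); weights are drawn per synapse uniformly
from a class-specific magnitude range (the class fixes the sign); delays
uniformly from [1, 2] ms.  Everything is a pure function of
(CSP, parameters, seed); identical compiles serialize byte-identically.

Clues (fixed cells) are encoded by exclusivity: a clued variable keeps
stimulation only on its clue value's sub-population, which also receives an
extra bias current.  Nothing else about the network changes, so clue cells
participate in constraint signalling exactly like free cells.

## Neuron and synapse model

Membrane dynamics (per neuron):  τ_m du/dt = −u + R·I_total(t), threshold
u_th, reset u_r, refractory period t_ref.  Each presynaptic spike arriving at
t₀ contributes an exponential post-synaptic current
J(t) = (q/τ_s)·e^(−(t−t₀)/τ_s)·Θ(t−t₀) scaled by the synaptic weight; noise
generator events enter the same way with strength Ω.

Constants are normalized: u_r = 0, u_th = 1, R = 1, q = 1, τ_m = 20 ms,
τ_s = 5 ms, t_ref = 2 ms.  Published current/weight settings are interpreted
on this scale (external currents are a fraction of threshold; unit-magnitude
weights produce ~0.1 u_th per spike after membrane filtering).

### Numerical scheme

Time is discrete with dt = 1 ms.  Integration is exponential-Euler with the
synaptic current held piecewise-constant over each step — exact for constant
input, so the constant-current trajectory and inter-spike interval match the
closed form u(t) = RI(1−e^(−t/τ_m)) to the grid.  Post-synaptic currents are
per-neuron exponential accumulators (decay e^(−dt/τ_s) per step, add ω·q/τ_s
on arrival), mathematically identical to summing kernels by linearity; a unit
test cross-checks the engine spike-for-spike against an explicit kernel-sum
reference implementation.  Poisson generators are per-step Bernoulli with
p = rate·dt (rates above 1/dt are rejected); each noise source owns an RNG
stream seeded by (master seed, source id), so adding sources never perturbs
existing streams, and noise is pre-sampled in fixed 1 s blocks so results do
not depend on how a run is chunked.  Synaptic delays round to whole steps
(minimum one).  A non-finite membrane aborts with the neuron and step named.

## Readout and observables

Spikes are binned into 200 ms windows.  Per bin and variable, the decoded
value is the sub-population with the strictly largest spike count; ties and
silence decode as *undecided*, so satisfaction is never granted on ambiguous
activity.  From the decoded microstate sequence ψ_t the package computes:

* Shannon entropy S(t) = −Σ p_i log₂ p_i of the empirical microstate
  distribution over a trailing window (default: full history, giving the
  cumulative estimate; a sliding window is selectable).  The estimator's
  support is the variable-level decoded state, not the 2^N per-neuron vector,
  which would be unestimable from one run;
* mean per-neuron firing rate ν(t) = spikes / (N · bin width);
* cumulative distinct-state count Ω(t) with new/revisit/change flags;
* per-bin satisfaction via the symbolic checker, and solve times — *first*
  (earliest satisfying bin) and *stable* (earliest satisfying bin after which
  every bin satisfies; hopping between distinct solutions is allowed).

Across repeated seeded runs (seed = master + run index),
`experiment_stats` reports the success ratio ξ over all runs and μ, σ,
adjusted Fisher–Pearson skewness γ₁ and t_min over successful runs;
undefined moments are NaN, never fabricated.

For end-of-run configurations (spin quenches), `final_state` decodes from
counts summed over the trailing five bins: frustrated sites fire too sparsely
for a single 200 ms bin, and the wider window resolves them without changing
the tie rule.

## Parameter regimes

The search temperature is set by the stimulation rate and weight against the
strength of the WTA/constraint projections.  Defaults per family were
calibrated once on the small bundled instances and frozen; they are the
package's study conditions, not per-run tuning knobs.

| family | n | WTA ω | constraint ω | I | stimulation | dissipation |
|---|---|---|---|---|---|---|
| coloring | 20 | 1.2–1.5 | 1.2–1.4 | 0.17–0.2 | 120 Hz, Ω=1.6, continuous | — |
| AF spins / glass | 20 | 1.2–1.5 | 1.6–2.0 (glass: 0.4–0.6) | 0 | 160 Hz, Ω=1.6, continuous | — |
| FM spins | 20 | 1.2–1.5 | 1.6–2.0 | 0 | 30 Hz, Ω=1.6, continuous | 800 Hz, Ω=4, 400 ms burst every 2 s |
| Sudoku | 10 | 1.2–1.5 | 3.0–4.0 | 0.95 | 15 Hz, Ω=1.6, continuous | — |

Why these shapes:

* **Coloring** uses the published weight ranges and currents; the noise level
  balances exploration (several states visited before settling) against the
  stability of the converged state.  Weight ranges are read as magnitudes —
  the published tables print signs inconsistently — with the projection class
  fixing the sign.
* **Antiferromagnets** are purely noise-driven (I = 0): all recurrent input
  is inhibitory, so sustained stimulation is required for any activity, and
  strong couplings let antiparallel order percolate.
* **Ferromagnets** invert the logic: excitatory bonds make activity
  self-sustaining, so ordering works by nucleation — at low noise the first
  sub-population to burst recruits its neighbors and one orientation sweeps
  the lattice.  When two opposite domains nucleate, the walls freeze; the
  periodic dissipation bursts wipe the configuration so the noise can re-seed
  it — the restart role of discontinuous noise.  A 1D FM chain has too few
  neighbors for the cascade, so the chain demonstration instead uses moderate
  noise (80 Hz) with softer couplings (0.8–1.2), letting single wall sites
  flip and the domains coarsen.
* **The ±J glass** uses weak couplings so that frustrated sites are biased
  rather than silenced and every site stays decodable; the lattice then
  freezes into a local minimum (quenched state) well below the random-state
  energy with visibly frustrated bonds, with no global-optimality claim.
* **Sudoku** (at the software-scale ensemble n = 10) runs cold and greedy:
  a just-sub-threshold current makes every neuron fire regularly, weak noise
  provides the stochastic flips, and strong conflict inhibition makes a
  single violated constraint decisive.  This deviates from the published
  Sudoku weight table (tiny weights at n = 50): at n = 10 those leave the
  network undecodable, and the regime here was recalibrated for the smaller
  ensembles.

Problem sizes in the default test and acceptance runs (Canada at its full
published scale of 20-neuron ensembles; Sudoku at n = 10; FM cube at 5³
sites) are the package's chosen software-scale study conditions; the full
37k-neuron Sudoku network compiles and simulates but is not exercised in the
default suites.

## What the demonstrations do and do not show

The bundled instances demonstrate: stable convergence on satisfiable
instances (triangle, Canada/Australia maps, AF chains, easy Sudoku with clue
preservation), honest failure on unsatisfiable ones (K4 with three colors
never reports satisfaction — every report is re-verified), ferromagnetic
ordering with restarts, and spin-glass quenching into frustrated local
minima.  Solve times are model (biological) time at 1 ms resolution and
depend on the frozen noise schedules; they characterize this software
configuration, not any hardware platform.  Harder Sudoku instances
(`sudoku-hard`, `ai-escargot`) are bundled for exploration; at the scaled
ensemble size their success ratio is markedly lower, consistent with
difficulty ordering by stochastic search.

## Known limitations

* Binary constraints only; no inequality/optimization constraints, so the
  solver samples satisfying states but cannot prefer one optimum among them.
* Constraint projections pair equal domain *indices*, so both variables of a
  constraint must have equal domain sizes.
* The entropy estimator uses decoded variable-level states from a single
  trajectory; it is a lower-dimensional summary of the network's true state
  distribution.
* Current-based synapses with a single exponential PSC; no conductances,
  plasticity, or event-driven simulation.
* The world-map fixture is a best-effort reconstruction of the UN land-border
  list (192 vertices); its published network-size figures are not
  reproducible and are not targeted by any test.
* Sudoku difficulty ratings are informal; the bundled easy/hard puzzles are
  labeled stand-ins chosen to represent their tiers (see `data/sudoku.txt`).
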