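# spikesat

Stochastic spiking neural networks that solve constraint satisfaction
problems.

`spikesat` is for computational neuroscientists and neuromorphic-computing
researchers who want to study how noisy winner-take-all spiking circuits
perform stochastic search.  It compiles a binary CSP ⟨X, D, C⟩ — variables,
finite value domains, and pairwise constraints that forbid (negative) or
require (positive) equal values — into a network of leaky integrate-and-fire
neurons, simulates it in discrete 1 ms time, and decodes the spiking activity
back into candidate assignments.  Bundled problem families: graph/map
coloring, Sudoku, and Ising spin systems (ferromagnets, antiferromagnets and
±J spin glasses, where energy minimization and constraint satisfaction
coincide).

## The model

Every (variable, value) pair becomes a sub-population of `n` LIF neurons

    τ_m du/dt = −u(t) + R·I(t),    spike and reset at u ≥ u_th,

coupled through exponential post-synaptic currents
J(t) = (q/τ)·e^(−t/τ)·Θ(t).  A variable's sub-populations inhibit each other
(a soft winner-take-all, so one value dominates per variable); negative
constraints inhibit, and positive constraints excite, the equal-value
sub-populations of their two variables.  Poisson noise populations stimulate
(and optionally dissipate) every sub-population over scheduled pulse windows:
the noise powers the search, and applied discontinuously it acts as a
restart.  Spikes are binned (200 ms), each bin decodes to a microstate ψ_t
(per-variable winner, ties undecided), and the package tracks the Shannon
entropy S = −Σ p_i log₂ p_i of visited states, mean firing rate ν, distinct
states Ω(t), satisfaction, and — over repeated seeded runs — the solve-time
statistics μ, σ, γ₁, success ratio ξ, and t_min.  Every solution the network
reports is re-verified against the constraints symbolically.

## Worked example

```sh
$ python examples/color_a_map.py
first satisfaction at 0.20 s of model time
stable satisfaction from 1.00 s
  YT  -> red
  NT  -> blue
  BC  -> green
  ...
```

The 13 Canadian provinces/territories are 3-colored by a network of 780
principal neurons (13 regions × 3 colors × 20 neurons): after 0.20 s of model
time every adjacency constraint holds, and from 1.00 s the network stays on
satisfying colorings to the end of the run.  All times are model time — the
network ran that many 1 ms steps.

```sh
$ python examples/solve_sudoku.py
solved in 1.00 s of model time (stable from 4.00 s)
 4  8 [3]| 9 [2] 1 |[6] 5  7
...
```

Clue cells (brackets) keep stimulation only on their clue digit, so the
search fills the free cells under the 810 row/column/box constraints.

```sh
$ python examples/spin_systems.py
AF chain: -+-+-+-+-+ energy -9U (ground state -9U), stable from 1.20 s
spin glass quench: E = -114U vs random mean +0.3U over 180 bonds
```

The antiferromagnetic chain reaches its alternating ground state (all 9 bonds
satisfied); the frustrated ±J glass freezes into a quenched local minimum far
below the random-configuration mean without claiming global optimality.

Other examples: `convergence_statistics.py` (μ, σ, γ₁, ξ, t_min over 20
runs), `network_anatomy.py` (exact structural counts and the per-bin
S/ν/Ω/satisfaction table).

A thin CLI wraps the same library:

```sh
spikesat fixtures                 # list bundled instances
spikesat solve canada --seed 1    # one run
spikesat experiment triangle-k3 --runs 20 --outdir out/
spikesat verify triangle-k3 "[0, 1, 2]"
spikesat inspect sudoku-easy      # network summary
```

## Layout

    src/spikesat/       csp, problems, compiler, simulate, analysis,
                        experiment, fixtures, io, plots, cli
    examples/           one narrative script per capability
    tests/              pytest suite (unit, property and acceptance tests)
    docs/methods.md     model, numerics, parameter regimes, limitations
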