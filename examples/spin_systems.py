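"""Ising spin systems as CSPs: antiferromagnetic order and spin-glass quench.

1. A 10-spin antiferromagnetic chain relaxes to the alternating ground state
   (energy −9U: all 9 bonds satisfied).
2. A 10×10 ±J spin glass (p_AF = 0.5) freezes into a quenched state whose
   energy is far below the mean of random configurations, but frustration
   keeps it above the (unknown) ground state.
"""

import numpy as np

from spikesat import ising_energy, load_fixture, run_single

# --- antiferromagnetic chain -------------------------------------------------
inst = load_fixture("af-ring-10")
r = run_single(inst, seed=1, duration_ms=30_000, stop="stable")
spins = np.array([1 if v == 0 else -1 for v in r.assignment.values])
print("AF chain:", "".join("+" if s > 0 else "-" for s in spins),
      f"energy {ising_energy(inst.spin_system, spins):+.0f}U "
      f"(ground state -9U), stable from {r.t_stable_ms / 1000:.2f} s")

# --- 2D spin glass quench ----------------------------------------------------
glass = load_fixture("lattice-2d")
r = run_single(glass, seed=1, duration_ms=10_000, stop="none")
state = r.trace.states[-1]
spins = np.array([1 if v == 0 else -1 for v in state.values])
e_quench = ising_energy(glass.spin_system, spins)

rng = np.random.default_rng(0)
random_energies = [ising_energy(glass.spin_system, rng.choice([-1, 1], 100))
                   for _ in range(1000)]
print(f"spin glass quench: E = {e_quench:+.0f}U vs random mean "
      f"{np.mean(random_energies):+.1f}U over {glass.spin_system.n_bonds} bonds")
# the quenched energy sits well below zero (the random-configuration mean)
# yet frustration keeps some bonds unsatisfied — no global optimum claimed.
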