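"""Solve an easy Sudoku with the stochastic spiking search.

Clue cells keep stimulation only on their clue digit (plus a bias current),
so the network searches the 45 free cells under the row/column/box
constraints.  Prints the solved grid; clues are wrapped in brackets.
"""

from spikesat import check_assignment, load_fixture, run_single

inst = load_fixture("sudoku-easy")
result = run_single(inst, seed=1, stop="stable")

if not result.solved:
    print(f"not converged within {result.duration_ms / 1000:.0f} s of model time")
    raise SystemExit(1)

print(f"solved in {result.t_first_ms / 1000:.2f} s of model time "
      f"(stable from {result.t_stable_ms / 1000:.2f} s)")
assert check_assignment(inst.csp, result.assignment).satisfied
digits = [v + 1 for v in result.assignment.values]
for r in range(9):
    row = ""
    for c in range(9):
        cell = r * 9 + c
        d = digits[cell]
        row += f"[{d}]" if cell in inst.clues else f" {d} "
        if c in (2, 5):
            row += "|"
    print(row)
    if r in (2, 5):
        print("-" * 29)
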