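"""Problem families: graph coloring, Sudoku / Latin squares, Ising spin systems.

Each generator maps its native formulation onto the signed binary CSP model:

* k-coloring — one variable per vertex, k colors, a negative (inequality)
  constraint per edge;
* Sudoku — 81 variables with 9-digit domains, negative constraints between
  every same-row, same-column and same-box cell pair (810 distinct pairs);
* Ising spins — one ±1 variable per site; ferromagnetic bonds (J>0) become
  positive (equality) constraints, antiferromagnetic bonds (J<0) negative ones.
"""

from __future__ import annotations

import itertools
import dataclasses
from dataclasses import dataclass

import numpy as np

from .csp import CSP, Assignment, Constraint

__all__ = [
    "csp_from_graph_coloring",
    "csp_from_sudoku",
    "sudoku_constraint_pairs",
    "SpinSystem",
    "make_spin_lattice",
    "make_spin_chain",
    "csp_from_spin_system",
    "ising_energy",
    "frustrated_bonds",
]


# ---------------------------------------------------------------------------
# graph coloring
# ---------------------------------------------------------------------------

def csp_from_graph_coloring(edges, k: int, vertices=None) -> CSP:
    """Build the k-coloring CSP of a graph given as an edge list.

    Vertices are ordered by first appearance in the edge list (then by the
    optional explicit ``vertices`` list, which may add isolated vertices).
    Each undirected edge becomes one negative constraint: adjacent vertices
    must not share a color.  Self-loops are rejected — a vertex cannot be
    required to differ from itself.
    """
    if k < 1:
        raise ValueError(f"color count must be >= 1, got {k}")
    order: dict = {}
    for u, v in edges:
        if u == v:
            raise ValueError(f"self-loop on vertex {u!r}: a vertex cannot differ from itself")
        for w in (u, v):
            if w not in order:
                order[w] = len(order)
    if vertices is not None:
        for w in vertices:
            if w not in order:
                order[w] = len(order)
    constraints = []
    seen = set()
    for u, v in edges:
        key = frozenset((order[u], order[v]))
        if key in seen:  # parallel edges collapse to one constraint
            continue
        seen.add(key)
        constraints.append(Constraint(order[u], order[v], sign=-1))
    names = [w for w, _ in sorted(order.items(), key=lambda kv: kv[1])]
    domains = [list(range(k)) for _ in names]
    return CSP(domains, constraints, metadata={"kind": "coloring", "vertices": names, "k": k})


# ---------------------------------------------------------------------------
# Sudoku
# ---------------------------------------------------------------------------

def sudoku_constraint_pairs() -> list[tuple[int, int]]:
    """The 810 distinct cell pairs constrained by Sudoku rules (row-major, 0-based).

    324 same-row + 324 same-column pairs, plus the 162 same-box pairs that
    share neither row nor column.
    """
    pairs = set()
    for r in range(9):
        for c1, c2 in itertools.combinations(range(9), 2):
            pairs.add((r * 9 + c1, r * 9 + c2))
    for c in range(9):
        for r1, r2 in itertools.combinations(range(9), 2):
            pairs.add((r1 * 9 + c, r2 * 9 + c))
    for br in range(3):
        for bc in range(3):
            cells = [(br * 3 + dr) * 9 + bc * 3 + dc for dr in range(3) for dc in range(3)]
            for a, b in itertools.combinations(cells, 2):
                pairs.add(tuple(sorted((a, b))))
    return sorted(pairs)


def parse_sudoku_clues(clues: str) -> list[int | None]:
    """Parse an 81-character row-major clue string; '0' or '.' mean blank."""
    s = "".join(clues.split())
    if len(s) != 81:
        raise ValueError(f"Sudoku clue string must have 81 cells, got {len(s)}")
    grid: list[int | None] = []
    for ch in s:
        if ch in "0.":
            grid.append(None)
        elif ch in "123456789":
            grid.append(int(ch))
        else:
            raise ValueError(f"invalid Sudoku cell character {ch!r}")
    return grid


def csp_from_sudoku(clues: str = "") -> CSP:
    """Build the CSP of a 9×9 Sudoku puzzle from an 81-char clue string.

    Cells are row-major variables 0..80 with digit domains 1..9.  The clue
    list is carried in ``metadata['clues']`` as ``{cell: digit}`` for the
    network compiler; two equal clue digits in one unit are rejected.
    An empty string yields the clue-free puzzle (still 810 constraints).
    """
    grid = parse_sudoku_clues(clues) if clues else [None] * 81
    constraints = [Constraint(u, v, sign=-1) for u, v in sudoku_constraint_pairs()]
    for c in constraints:
        du, dv = grid[c.u], grid[c.v]
        if du is not None and du == dv:
            raise ValueError(
                f"inconsistent clues: cells {c.u} and {c.v} share digit {du} within one row/column/box"
            )
    domains = [list(range(1, 10)) for _ in range(81)]
    clue_map = {i: d for i, d in enumerate(grid) if d is not None}
    return CSP(domains, constraints, metadata={"kind": "sudoku", "clues": clue_map})


# ---------------------------------------------------------------------------
# Ising spin systems
# ---------------------------------------------------------------------------

@dataclass
class SpinSystem:
    """An Ising system: ±1 spins on sites with signed nearest-neighbor bonds.

    ``couplings`` maps a site-index bond ``(i, j)`` (i < j) to J ∈ {+U, −U}.
    ``field`` is a uniform external field h favoring spin +1 when positive.
    Energy of a configuration S is  H = −Σ_bonds J_ij S_i S_j − h Σ_i S_i.
    """

    n_sites: int
    couplings: dict[tuple[int, int], float]
    field: float = 0.0
    lattice_shape: tuple[int, ...] | None = None
    metadata: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        mags = {abs(j) for j in self.couplings.values()}
        if len(mags) > 1:
            raise ValueError(f"all couplings must share one magnitude U, got magnitudes {sorted(mags)}")
        for (i, j) in self.couplings:
            if not (0 <= i < self.n_sites and 0 <= j < self.n_sites) or i >= j:
                raise ValueError(f"bad bond ({i}, {j}) for {self.n_sites} sites (need 0 <= i < j < n)")

    @property
    def coupling_magnitude(self) -> float:
        return abs(next(iter(self.couplings.values()))) if self.couplings else 0.0

    @property
    def n_bonds(self) -> int:
        return len(self.couplings)


def _grid_bonds(shape: tuple[int, ...]) -> list[tuple[int, int]]:
    """Nearest-neighbor bonds of an open-boundary grid, row-major site indices."""
    sites = np.arange(int(np.prod(shape))).reshape(shape)
    bonds: list[tuple[int, int]] = []
    for axis in range(len(shape)):
        a = np.moveaxis(sites, axis, 0)
        for i, j in zip(a[:-1].ravel(), a[1:].ravel()):
            bonds.append((int(i), int(j)))
    return sorted(tuple(sorted(b)) for b in bonds)


def make_spin_lattice(
    shape: tuple[int, ...],
    p_af: float,
    coupling: float = 1.0,
    h: float = 0.0,
    seed: int | None = 0,
) -> SpinSystem:
    """Random-bond Ising lattice on an open-boundary grid of 1–3 dimensions.

    Each nearest-neighbor bond independently takes J = −U (antiferromagnetic)
    with probability ``p_af`` and J = +U otherwise, under the given seed —
    the Edwards–Anderson ±J disorder model.  Identical (shape, p_af, coupling,
    h, seed) calls yield identical couplings.
    """
    if not (1 <= len(shape) <= 3) or any(s < 1 for s in shape):
        raise ValueError(f"lattice shape must have 1-3 positive dimensions, got {shape}")
    if not (0.0 <= p_af <= 1.0):
        raise ValueError(f"p_af must lie in [0, 1], got {p_af}")
    if coupling <= 0:
        raise ValueError(f"coupling magnitude U must be positive, got {coupling}")
    rng = np.random.default_rng(seed)
    bonds = _grid_bonds(tuple(shape))
    signs = np.where(rng.random(len(bonds)) < p_af, -1.0, 1.0)
    couplings = {b: float(s * coupling) for b, s in zip(bonds, signs)}
    n = int(np.prod(shape))
    return SpinSystem(n, couplings, field=h, lattice_shape=tuple(shape),
                      metadata={"p_af": p_af, "seed": seed})


def make_spin_chain(n: int, sign: int = -1, coupling: float = 1.0, h: float = 0.0) -> SpinSystem:
    """Open 1D chain of n spins with uniform FM (+1) or AF (−1) bonds."""
    if sign not in (-1, 1):
        raise ValueError("sign must be -1 (AF) or +1 (FM)")
    couplings = {(i, i + 1): float(sign * coupling) for i in range(n - 1)}
    return SpinSystem(n, couplings, field=h, lattice_shape=(n,))


def csp_from_spin_system(system: SpinSystem) -> CSP:
    """Map an Ising system to a CSP: one ±1 variable per site, one signed
    constraint per bond (FM → positive/equality, AF → negative/inequality)."""
    domains = [[+1, -1] for _ in range(system.n_sites)]
    constraints = [
        Constraint(i, j, sign=+1 if J > 0 else -1)
        for (i, j), J in sorted(system.couplings.items())
    ]
    return CSP(domains, constraints, metadata={"kind": "spin", "shape": system.lattice_shape,
                                               "field": system.field})


def ising_energy(system: SpinSystem, config) -> float:
    """Energy  H = −Σ J_ij S_i S_j − h Σ S_i  of a ±1 spin configuration."""
    config = np.asarray(config)
    if config.shape != (system.n_sites,):
        raise ValueError(f"configuration must have {system.n_sites} spins, got shape {config.shape}")
    if not np.all(np.isin(config, (-1, 1))):
        raise ValueError("spins must take values in {+1, -1}")
    e = -sum(J * config[i] * config[j] for (i, j), J in system.couplings.items())
    e -= system.field * float(config.sum())
    return float(e)


def frustrated_bonds(system: SpinSystem, config) -> list[tuple[int, int]]:
    """Bonds whose energy term is unsatisfied: J S_i S_j < 0."""
    config = np.asarray(config)
    return [b for b, J in system.couplings.items() if J * config[b[0]] * config[b[1]] < 0]


def spin_assignment(system: SpinSystem, config) -> Assignment:
    """Express a ±1 configuration as an assignment of the spin CSP
    (domain index 0 ↔ +1, 1 ↔ −1)."""
    return Assignment(tuple(0 if s == 1 else 1 for s in config))
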