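"""Bundled demo instances and their solver parameter presets.

The registry covers the three problem families: map/graph coloring
(australia, canada, world, triangle-k3, k4-k3), Sudoku (sudoku-easy,
sudoku-hard, ai-escargot) and Ising spin systems (af-ring-10, lattice-2d,
lattice-3d-fm, lattice-3d-af).  Each entry resolves to a
:class:`ProblemInstance` bundling the CSP, any clues, and parameter presets
tuned per family (weight ranges and external currents follow the published
per-problem settings; ensemble sizes and noise schedules are scaled for
single-CPU software runs).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

from .compiler import CompilerParams, NoisePulse
from .csp import CSP
from .io import read_dimacs_col
from .problems import (
    SpinSystem,
    csp_from_graph_coloring,
    csp_from_spin_system,
    csp_from_sudoku,
    make_spin_lattice,
)
from .simulate import LIFParams

__all__ = ["ProblemInstance", "FIXTURES", "load_fixture", "fixture_names"]


@dataclass
class ProblemInstance:
    """A CSP ready for the compile → simulate → analyze pipeline."""

    name: str
    kind: str  # coloring | sudoku | spin
    csp: CSP
    params: CompilerParams
    lif: LIFParams = field(default_factory=LIFParams)
    clues: dict[int, int] = field(default_factory=dict)  # variable -> domain index
    spin_system: SpinSystem | None = None
    duration_ms: float = 60_000.0
    metadata: dict = field(default_factory=dict)


def _data_text(name: str) -> str:
    return resources.files("spikesat.data").joinpath(name).read_text()


#: Dissipation pulse train used as a restart schedule: a strong inhibitory
#: burst every 2 s wipes the current configuration so the noise can re-seed a
#: fresh one — the discontinuous-noise restart mechanism.
def restart_pulses(period_ms: float = 2000.0, width_ms: float = 400.0,
                   horizon_ms: float = 120_000.0) -> tuple[NoisePulse, ...]:
    k = int(max(0, (horizon_ms - width_ms) // period_ms))
    return tuple(NoisePulse(period_ms - width_ms + period_ms * i, width_ms)
                 for i in range(k))


def _coloring_params(**over) -> CompilerParams:
    # published coloring settings: inhibition [1.2,1.5], constraints [1.2,1.4];
    # continuous stimulation at a rate balancing exploration and stability
    base = dict(n=20, p_conn=0.5, wta_weight=(1.2, 1.5), constraint_weight=(1.2, 1.4),
                current=0.17, stim_size=15, stim_rate_hz=120.0, stim_weight=1.6)
    base.update(over)
    return CompilerParams(**base)


def _spin_params(**over) -> CompilerParams:
    # antiferromagnet/glass default: purely noise-driven (no external current),
    # strong couplings so order percolates against the stochastic drive
    base = dict(n=20, p_conn=0.5, wta_weight=(1.2, 1.5), constraint_weight=(1.6, 2.0),
                current=0.0, stim_size=20, stim_rate_hz=160.0, stim_weight=1.6)
    base.update(over)
    return CompilerParams(**base)


def _fm_spin_params(**over) -> CompilerParams:
    # ferromagnet: very low noise so a single orientation nucleates and
    # percolates; periodic dissipation bursts restart failed (multi-domain)
    # cascades
    base = dict(stim_rate_hz=30.0, diss_size=40, diss_rate_hz=800.0,
                diss_weight=4.0, diss_pulses=restart_pulses())
    base.update(over)
    return _spin_params(**base)


def _sudoku_params(**over) -> CompilerParams:
    # near-threshold drive (regular firing) with weak noise and strong conflict
    # inhibition: a cold, greedy search that still escapes by stochastic flips
    base = dict(n=10, p_conn=0.5, wta_weight=(1.2, 1.5), constraint_weight=(3.0, 4.0),
                current=0.95, stim_size=10, stim_rate_hz=15.0, stim_weight=1.6,
                clue_bias_current=0.4)
    base.update(over)
    return CompilerParams(**base)


def _coloring_fixture(name, colfile, k, **over):
    def build() -> ProblemInstance:
        vertices, edges = read_dimacs_col(_data_text(colfile))
        csp = csp_from_graph_coloring(edges, k, vertices=vertices)
        return ProblemInstance(name, "coloring", csp, _coloring_params(**over),
                               metadata={"k": k, "vertices": csp.metadata["vertices"]})
    return build


def _graph_fixture(name, edges, k, satisfiable):
    def build() -> ProblemInstance:
        csp = csp_from_graph_coloring(edges, k)
        return ProblemInstance(name, "coloring", csp, _coloring_params(),
                               metadata={"k": k, "satisfiable": satisfiable})
    return build


def _sudoku_fixture(name):
    def build() -> ProblemInstance:
        for line in _data_text("sudoku.txt").splitlines():
            if line.startswith("#") or not line.strip():
                continue
            key, clues = line.split()
            if key == name:
                csp = csp_from_sudoku(clues)
                clue_idx = {cell: digit - 1 for cell, digit in csp.metadata["clues"].items()}
                return ProblemInstance(name, "sudoku", csp, _sudoku_params(),
                                       clues=clue_idx, duration_ms=120_000.0,
                                       metadata={"clue_string": clues})
        raise KeyError(name)
    return build


def _spin_fixture(name, shape, p_af, seed, ferro=False, **over):
    def build() -> ProblemInstance:
        system = make_spin_lattice(shape, p_af, coupling=1.0, h=0.0, seed=seed)
        csp = csp_from_spin_system(system)
        params = _fm_spin_params(**over) if ferro else _spin_params(**over)
        return ProblemInstance(name, "spin", csp, params, spin_system=system,
                               metadata={"shape": shape, "p_af": p_af, "seed": seed})
    return build


FIXTURES = {
    "triangle-k3": _graph_fixture("triangle-k3", [(0, 1), (1, 2), (0, 2)], 3, True),
    "k4-k3": _graph_fixture(
        "k4-k3", [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)], 3, False),
    "australia": _coloring_fixture("australia", "australia.col", 3, current=0.2),
    "canada": _coloring_fixture("canada", "canada.col", 3, current=0.17),
    "world": _coloring_fixture("world", "world.col", 4, n=15),
    "sudoku-easy": _sudoku_fixture("sudoku-easy"),
    "sudoku-hard": _sudoku_fixture("sudoku-hard"),
    "ai-escargot": _sudoku_fixture("ai-escargot"),
    # "AF ring": modeled as the open 10-spin chain of the 1D antiferromagnet
    # demo (alternating ground state, energy -9U over its 9 bonds)
    "af-ring-10": _spin_fixture("af-ring-10", (10,), 1.0, 0),
    # ±J glass: weak couplings (bias, not silencing) so frustrated sites stay
    # active and the whole lattice decodes; it quenches into a local minimum
    "lattice-2d": _spin_fixture("lattice-2d", (10, 10), 0.5, 1, constraint_weight=(0.4, 0.6)),
    "lattice-3d-fm": _spin_fixture("lattice-3d-fm", (10, 10, 10), 0.0, 2, ferro=True, n=10),
    "lattice-3d-af": _spin_fixture("lattice-3d-af", (10, 10, 10), 1.0, 3, n=10),
}


def fixture_names() -> list[str]:
    return sorted(FIXTURES)


def load_fixture(name: str) -> ProblemInstance:
    """Resolve a registry name to a fresh ProblemInstance.

    Unknown names raise ``KeyError`` listing the registry.
    """
    try:
        build = FIXTURES[name]
    except KeyError:
        raise KeyError(f"unknown fixture {name!r}; available: {', '.join(fixture_names())}") from None
    return build()
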