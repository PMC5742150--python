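"""Compile a binary CSP into a stochastic winner-take-all spiking network.

Every (variable, value) pair becomes a sub-population of excitable LIF
neurons.  Three projection classes shape the dynamics:

* *WTA* — mutual inhibition between all distinct value sub-populations of one
  variable, so that on average a single value stays active;
* *constraint* — inhibition (negative constraint) or excitation (positive
  constraint) between equal-value sub-populations of the two constrained
  variables, instantiated in both directions;
* *noise* — Poisson stimulation (excitatory) and dissipation (inhibitory)
  sources attached per sub-population, active over scheduled pulse windows.
  The noise supplies the energy for the stochastic search; pulses applied
  discontinuously act as restarts.

Connectivity is random: each neuron pair of a projection is connected with
probability ``p_conn``, weights are drawn per-synapse from a class-specific
uniform range, delays uniformly from the delay range.  Everything is a pure
function of (CSP, params, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np

from .csp import CSP

__all__ = [
    "NoisePulse",
    "CompilerParams",
    "Population",
    "Projection",
    "NoiseSource",
    "NetworkSpec",
    "compile_csp",
    "encode_clues",
    "network_summary",
]


@dataclass(frozen=True)
class NoisePulse:
    """An activation window of a noise source: (start, duration) in ms.

    ``duration=None`` keeps the source on until the end of the simulation.
    """

    start_ms: float = 0.0
    duration_ms: float | None = None

    def __post_init__(self) -> None:
        if self.start_ms < 0:
            raise ValueError("pulse start must be >= 0")
        if self.duration_ms is not None and self.duration_ms < 0:
            raise ValueError("pulse duration must be >= 0")

    def end_ms(self, horizon_ms: float) -> float:
        return horizon_ms if self.duration_ms is None else min(self.start_ms + self.duration_ms, horizon_ms)


def _as_magnitude_range(lo_hi) -> tuple[float, float]:
    """Weight ranges are magnitudes; accept either order and either sign."""
    a, b = abs(lo_hi[0]), abs(lo_hi[1])
    return (min(a, b), max(a, b))


@dataclass
class CompilerParams:
    """Knobs of the CSP→network translation.

    Weight ranges are interpreted as magnitude bounds; the projection class
    fixes the sign (WTA and negative constraints inhibitory, positive
    constraints excitatory).  ``n`` is the ensemble size per (variable, value)
    sub-population — large enough to average out single-spike stochasticity.
    """

    n: int = 25
    p_conn: float = 0.5
    wta_weight: tuple[float, float] = (1.2, 1.5)
    constraint_weight: tuple[float, float] = (1.2, 1.4)
    delay_ms: tuple[float, float] = (1.0, 2.0)
    current: float = 0.17
    # noise sources: one Poisson population per (target sub-population, pulse)
    stim_size: int = 20
    stim_rate_hz: float = 30.0
    stim_weight: float = 1.4
    stim_pulses: tuple[NoisePulse, ...] = (NoisePulse(0.0, None),)
    diss_size: int = 20
    diss_rate_hz: float = 30.0
    diss_weight: float = 1.4
    diss_pulses: tuple[NoisePulse, ...] = ()
    clue_bias_current: float = 0.3

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("ensemble size n must be >= 1")
        if not (0.0 < self.p_conn <= 1.0):
            raise ValueError("p_conn must lie in (0, 1]")
        lo, hi = self.delay_ms
        if lo < 1.0 or hi < lo:
            raise ValueError("delay range must be ordered and >= 1 ms (one time step)")
        self.wta_weight = _as_magnitude_range(self.wta_weight)
        self.constraint_weight = _as_magnitude_range(self.constraint_weight)


@dataclass(frozen=True)
class Population:
    """A principal sub-population coding one value of one variable."""

    index: int
    variable: int
    value: int  # domain index within the variable
    size: int
    offset: int  # global id of its first neuron

    @property
    def neuron_ids(self) -> np.ndarray:
        return np.arange(self.offset, self.offset + self.size)


@dataclass
class Projection:
    """A bundle of synapses between two sub-populations (global neuron ids)."""

    source: int  # population index
    target: int
    kind: Literal["wta", "constraint"]
    sign: int  # -1 inhibitory, +1 excitatory
    pre: np.ndarray
    post: np.ndarray
    weight: np.ndarray
    delay_ms: np.ndarray

    @property
    def n_synapses(self) -> int:
        return len(self.pre)


@dataclass
class NoiseSource:
    """A scheduled Poisson population wired onto one principal sub-population.

    Generator spikes are delivered as exogenous weighted synaptic events
    (strength Ω per event); the generators are not themselves LIF neurons.
    """

    index: int
    target: int  # population index
    kind: Literal["stimulation", "dissipation"]
    size: int
    rate_hz: float
    weight: float  # signed Ω: > 0 stimulation, < 0 dissipation
    pulse: NoisePulse
    pre: np.ndarray  # generator-local indices
    post: np.ndarray  # global principal neuron ids


@dataclass
class NetworkSpec:
    """A compiled network: populations, projections, noise sources, currents."""

    populations: list[Population]
    projections: list[Projection]
    noise_sources: list[NoiseSource]
    currents: np.ndarray  # constant external current per population
    domain_sizes: list[int]
    metadata: dict = field(default_factory=dict)

    @property
    def n_principal(self) -> int:
        return sum(p.size for p in self.populations)

    @property
    def n_variables(self) -> int:
        return len(self.domain_sizes)

    def population_index(self, variable: int, value: int) -> int:
        return self._pop_lookup[(variable, value)]

    def __post_init__(self) -> None:
        self._pop_lookup = {(p.variable, p.value): p.index for p in self.populations}


def _random_projection(rng: np.random.Generator, src: Population, tgt: Population,
                       p_conn: float, wrange: tuple[float, float], sign: int,
                       delay: tuple[float, float], kind: str) -> Projection:
    mask = rng.random((src.size, tgt.size)) < p_conn
    pre_loc, post_loc = np.nonzero(mask)
    m = len(pre_loc)
    w = sign * rng.uniform(wrange[0], wrange[1], size=m)
    d = rng.uniform(delay[0], delay[1], size=m)
    return Projection(src.index, tgt.index, kind, sign,
                      pre=src.offset + pre_loc, post=tgt.offset + post_loc,
                      weight=w, delay_ms=d)


def compile_csp(csp: CSP, params: CompilerParams, seed: int = 0) -> NetworkSpec:
    """Translate a CSP into a noisy winner-take-all spiking network.

    Creates one size-``n`` sub-population per (variable, value), attaches one
    scheduled Poisson stimulation source per (sub-population, pulse) (and
    dissipation sources when configured), builds the intra-variable WTA
    inhibition, and maps every constraint onto bidirectional projections
    between equal-value sub-populations — inhibitory for negative constraints,
    excitatory for positive ones.  Pure function of (csp, params, seed).

    Constraints whose two variables have different domain sizes are rejected:
    the equal-value pairing would be undefined.
    """
    for c in csp.constraints:
        if len(csp.domains[c.u]) != len(csp.domains[c.v]):
            raise ValueError(
                f"constraint {c.scope} links variables with different domain sizes "
                f"({len(csp.domains[c.u])} vs {len(csp.domains[c.v])}); equal-value pairing undefined"
            )
    rng = np.random.default_rng(seed)
    populations: list[Population] = []
    offset = 0
    for var, dom in enumerate(csp.domains):
        for val in range(len(dom)):
            populations.append(Population(len(populations), var, val, params.n, offset))
            offset += params.n

    net = NetworkSpec(populations, [], [], currents=np.full(len(populations), params.current),
                      domain_sizes=csp.domain_sizes,
                      metadata={"seed": seed, "kind": csp.metadata.get("kind")})

    # (b) winner-take-all: inhibition between all ordered pairs of a variable's values
    for var, dom in enumerate(csp.domains):
        for di in range(len(dom)):
            for dj in range(len(dom)):
                if di == dj:
                    continue
                src = populations[net.population_index(var, di)]
                tgt = populations[net.population_index(var, dj)]
                net.projections.append(_random_projection(
                    rng, src, tgt, params.p_conn, params.wta_weight, -1, params.delay_ms, "wta"))

    # (c) constraints: equal-value coupling in both directions
    for c in csp.constraints:
        wrange = params.constraint_weight
        for a, b in ((c.u, c.v), (c.v, c.u)):
            for val in range(len(csp.domains[a])):
                src = populations[net.population_index(a, val)]
                tgt = populations[net.population_index(b, val)]
                net.projections.append(_random_projection(
                    rng, src, tgt, params.p_conn, wrange, c.sign, params.delay_ms, "constraint"))

    # (a) noise: scheduled Poisson stimulation / dissipation per sub-population
    def _attach(kind: str, size: int, rate: float, weight: float, pulses) -> None:
        if size < 1 or rate <= 0 or not pulses:
            return
        for pop in populations:
            for pulse in pulses:
                mask = rng.random((size, pop.size)) < params.p_conn
                pre_loc, post_loc = np.nonzero(mask)
                net.noise_sources.append(NoiseSource(
                    len(net.noise_sources), pop.index, kind, size, rate, weight, pulse,
                    pre=pre_loc, post=pop.offset + post_loc))

    _attach("stimulation", params.stim_size, params.stim_rate_hz, abs(params.stim_weight), params.stim_pulses)
    _attach("dissipation", params.diss_size, params.diss_rate_hz, -abs(params.diss_weight), params.diss_pulses)
    return net


def encode_clues(network: NetworkSpec, clues: dict[int, int], params: CompilerParams) -> NetworkSpec:
    """Bias a compiled network toward fixed (variable → value-index) clues.

    For each clued variable only the clued value's sub-population keeps its
    stimulation sources; the sibling sub-populations lose theirs.  The clued
    sub-population additionally receives ``clue_bias_current``.  Dissipation
    sources are untouched.  Returns a new NetworkSpec; the input is unchanged.
    """
    for var, val in clues.items():
        if not (0 <= var < network.n_variables):
            raise ValueError(f"clue variable {var} outside range")
        if not (0 <= val < network.domain_sizes[var]):
            raise ValueError(f"clue value index {val} outside domain of variable {var}")
    clued_vars = set(clues)
    keep: list[NoiseSource] = []
    for src in network.noise_sources:
        pop = network.populations[src.target]
        if (src.kind == "stimulation" and pop.variable in clued_vars
                and pop.value != clues[pop.variable]):
            continue
        keep.append(replace(src, index=len(keep)))
    currents = network.currents.copy()
    for var, val in clues.items():
        currents[network.population_index(var, val)] += params.clue_bias_current
    return NetworkSpec(network.populations, network.projections, keep, currents,
                       network.domain_sizes,
                       metadata={**network.metadata, "clues": dict(clues)})


def network_summary(network: NetworkSpec) -> dict:
    """Exact structural counts: neurons, synapses, populations, domain sizes."""
    n_noise = sum(s.size for s in network.noise_sources)
    n_syn = sum(p.n_synapses for p in network.projections)
    n_noise_syn = sum(len(s.pre) for s in network.noise_sources)
    return {
        "n_variables": network.n_variables,
        "domain_sizes": sorted(set(network.domain_sizes)),
        "populations": len(network.populations),
        "principal_neurons": network.n_principal,
        "noise_neurons": n_noise,
        "neurons": network.n_principal + n_noise,
        "projections": len(network.projections),
        "synapses": n_syn,
        "noise_synapses": n_noise_syn,
        "noise_sources": len(network.noise_sources),
    }
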