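"""Discrete-time (1 ms) leaky integrate-and-fire network simulation.

The membrane of each neuron follows

    τ_m du/dt = −u(t) + R [ I + Σ_j ω_j Σ_f J(t − t_j^f − Δ_j) + Σ_k Ω_k J(t − T_k) ]

with the exponential post-synaptic current kernel

    J(t) = (q/τ) e^(−t/τ) Θ(t).

Integration uses an exponential-Euler step with the synaptic current held
piecewise-constant over each 1 ms step, which is exact for constant input.
Every synaptic arrival adds ω·q/τ to a per-neuron current accumulator that
decays by e^(−dt/τ) per step — mathematically identical to summing kernels,
by linear superposition.  Threshold crossing emits a spike, resets the
membrane to u_r and silences the neuron for the refractory period.

Poisson noise generators are exogenous event sources (strength Ω per event),
each source driven by its own RNG stream derived from (master seed, source
id) so that adding sources never perturbs existing streams.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse

from .compiler import NetworkSpec

__all__ = [
    "LIFParams",
    "SimConfig",
    "SpikeRecord",
    "psc_kernel",
    "poisson_events",
    "Simulation",
    "simulate",
]


@dataclass
class LIFParams:
    """LIF neuron and synapse constants, on a normalized membrane scale.

    Defaults: τ_m = 20 ms, R = 1, threshold 1, reset 0, PSC decay τ = 5 ms,
    unit charge per event, 2 ms refractory period.  The time step is fixed at
    1 ms — the network evolves as a discrete stochastic process on that grid.
    """

    tau_m: float = 20.0
    R: float = 1.0
    u_th: float = 1.0
    u_r: float = 0.0
    tau_syn: float = 5.0
    q_scale: float = 1.0
    t_ref: float = 2.0
    dt: float = 1.0

    def __post_init__(self) -> None:
        if self.tau_m <= 0 or self.tau_syn <= 0:
            raise ValueError("membrane and synaptic time constants must be positive")
        if self.u_th <= self.u_r:
            raise ValueError("threshold must exceed reset")
        if self.dt != 1.0:
            raise ValueError("the time step is fixed at 1 ms")
        if self.t_ref < 0:
            raise ValueError("refractory period must be >= 0")


@dataclass
class SimConfig:
    """Duration (a positive multiple of dt), master seed, optional membrane taps."""

    duration_ms: float
    seed: int = 0
    record_membrane: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.duration_ms <= 0 or self.duration_ms % 1.0 != 0:
            raise ValueError("duration must be a positive multiple of the 1 ms time step")


@dataclass
class SpikeRecord:
    """Spike events (neuron id, time) plus the population index table.

    ``times_ms`` and ``neurons`` are parallel arrays sorted by time;
    ``population_of`` maps each principal neuron to its population index.
    """

    times_ms: np.ndarray
    neurons: np.ndarray
    n_neurons: int
    duration_ms: float
    population_of: np.ndarray
    populations: list  # list[Population] from the compiled network
    membrane: dict[int, np.ndarray] = field(default_factory=dict)

    @property
    def n_events(self) -> int:
        return len(self.times_ms)

    def events(self) -> np.ndarray:
        """(time_ms, neuron, population) triples as a structured view."""
        return np.column_stack([self.times_ms, self.neurons, self.population_of[self.neurons]])


def psc_kernel(t_since_arrival, lif: LIFParams):
    """Exponential PSC kernel J(t) = (q/τ) e^(−t/τ) for t ≥ 0, else 0."""
    t = np.asarray(t_since_arrival, dtype=float)
    out = np.where(t >= 0, (lif.q_scale / lif.tau_syn) * np.exp(-np.clip(t, 0, None) / lif.tau_syn), 0.0)
    return float(out) if np.isscalar(t_since_arrival) else out


def poisson_events(rate_hz: float, window: tuple[float, float], seed: int = 0,
                   dt: float = 1.0) -> np.ndarray:
    """Spike times (ms) of a Poisson process discretized to per-step Bernoulli.

    Each step inside ``window = (start_ms, duration_ms)`` fires with
    probability rate·dt.  Rates with rate·dt > 1 cannot be represented by one
    event per step and are rejected.
    """
    if rate_hz < 0:
        raise ValueError("rate must be >= 0")
    p = rate_hz * dt / 1000.0
    if p > 1.0:
        raise ValueError(f"rate {rate_hz} Hz exceeds one event per {dt} ms step")
    start, duration = window
    n_steps = int(round(duration / dt))
    if n_steps <= 0 or p == 0.0:
        return np.array([], dtype=float)
    rng = np.random.default_rng(seed)
    hits = rng.random(n_steps) < p
    return start + dt * np.flatnonzero(hits)


class Simulation:
    """Stateful stepper over a compiled network; supports chunked running.

    Noise is pre-sampled in fixed internal blocks so results are independent
    of how callers split the run into chunks.
    """

    _NOISE_BLOCK = 1000  # steps per internal noise block

    def __init__(self, network: NetworkSpec, lif: LIFParams, cfg: SimConfig):
        self.network = network
        self.lif = lif
        self.cfg = cfg
        self.N = network.n_principal
        dt = lif.dt

        # principal synapses grouped by integer delay (>= 1 step)
        pre, post, w, d = [], [], [], []
        for proj in network.projections:
            pre.append(proj.pre)
            post.append(proj.post)
            w.append(proj.weight)
            d.append(np.maximum(1, np.rint(proj.delay_ms / dt)).astype(int))
        if pre:
            pre, post, w, d = (np.concatenate(x) for x in (pre, post, w, d))
        else:
            pre = post = np.array([], dtype=int)
            w = np.array([])
            d = np.array([], dtype=int)
        self.delay_steps = sorted(set(d.tolist())) if len(d) else []
        self.W = {}
        self.WT = {}
        for ds in self.delay_steps:
            m = d == ds
            self.W[ds] = sparse.csr_matrix(
                (w[m], (pre[m], post[m])), shape=(self.N, self.N))
            self.WT[ds] = self.W[ds].T.tocsr()  # for the dense-spiking path
        self.max_delay = max(self.delay_steps, default=1)

        # noise sources: weighted connection matrix (generators × principals)
        self.M = sum(s.size for s in network.noise_sources)
        gpre, gpost, gw = [], [], []
        g0 = 0
        self._src_slices = []
        starts, ends, rates = [], [], []
        horizon = cfg.duration_ms
        for s in network.noise_sources:
            gpre.append(g0 + s.pre)
            gpost.append(s.post)
            gw.append(np.full(len(s.pre), s.weight * lif.q_scale / lif.tau_syn))
            self._src_slices.append((g0, g0 + s.size))
            starts.append(s.pulse.start_ms)
            ends.append(s.pulse.end_ms(horizon))
            p = s.rate_hz * dt / 1000.0
            if p > 1.0:
                raise ValueError(f"noise source {s.index}: rate {s.rate_hz} Hz exceeds one event per step")
            rates.append(p)
            g0 += s.size
        if self.M:
            self.C = sparse.csr_matrix(
                (np.concatenate(gw), (np.concatenate(gpre), np.concatenate(gpost))),
                shape=(self.M, self.N)).T.tocsr()
        else:
            self.C = None
        self._src_start = np.array(starts)
        self._src_end = np.array(ends)
        self._src_p = np.array(rates)
        self._noise_rngs = [np.random.default_rng(np.random.SeedSequence((cfg.seed, s.index)))
                            for s in network.noise_sources]
        self._noise_block = None
        self._noise_block_t0 = -1

        # state
        self.u = np.full(self.N, lif.u_r, dtype=float)
        self.I_syn = np.zeros(self.N)
        self.ref_count = np.zeros(self.N, dtype=int)
        self.t_step = 0
        L = self.max_delay + 1
        self._pending = np.zeros((L, self.N))
        self._decay_m = math.exp(-dt / lif.tau_m)
        self._decay_s = math.exp(-dt / lif.tau_syn)
        self._psc0 = lif.q_scale / lif.tau_syn
        self._t_ref_steps = int(round(lif.t_ref / dt))
        self.I_ext = np.repeat(
            np.asarray(network.currents, dtype=float),
            [p.size for p in network.populations]) if network.populations else np.zeros(0)
        self._spike_t: list[np.ndarray] = []
        self._spike_id: list[np.ndarray] = []
        self._membrane = {i: [] for i in cfg.record_membrane}
        pop_of = np.empty(self.N, dtype=int)
        for p in network.populations:
            pop_of[p.offset:p.offset + p.size] = p.index
        self._pop_of = pop_of

    # -- noise ---------------------------------------------------------------

    def _noise_input(self, t_step: int) -> np.ndarray:
        """Summed exogenous PSC increments per principal neuron at this step."""
        if not self.M:
            return 0.0
        b0 = (t_step // self._NOISE_BLOCK) * self._NOISE_BLOCK
        if b0 != self._noise_block_t0:
            T = self._NOISE_BLOCK
            F = np.zeros((self.M, T), dtype=np.float64)
            t_ms = (b0 + np.arange(T)) * self.lif.dt
            for k, (g0, g1) in enumerate(self._src_slices):
                # draw the full block for stream stability, then gate by window
                draws = self._noise_rngs[k].random((g1 - g0, T)) < self._src_p[k]
                active = (t_ms >= self._src_start[k]) & (t_ms < self._src_end[k])
                F[g0:g1] = draws & active
            self._noise_block = self.C @ F  # (N × T) weighted arrival increments
            self._noise_block_t0 = b0
        return self._noise_block[:, t_step - b0]

    # -- stepping ------------------------------------------------------------

    def step(self) -> np.ndarray:
        """Advance one time step; returns the boolean spike vector."""
        lif, t = self.lif, self.t_step
        L = self._pending.shape[0]
        slot = t % L

        self.I_syn *= self._decay_s
        self.I_syn += self._pending[slot]
        self._pending[slot] = 0.0
        if self.M:
            self.I_syn += self._noise_input(t)

        I_tot = self.I_ext + self.I_syn
        refractory = self.ref_count > 0
        self.u = self.u * self._decay_m + (1.0 - self._decay_m) * lif.R * I_tot
        self.u[refractory] = lif.u_r
        self.ref_count[refractory] -= 1

        spiked = self.u >= lif.u_th
        if not np.all(np.isfinite(self.u)):
            bad = int(np.flatnonzero(~np.isfinite(self.u))[0])
            raise FloatingPointError(
                f"non-finite membrane potential on neuron {bad} at step {t} "
                f"({t * lif.dt} ms); check weight/current scales")
        ids = np.flatnonzero(spiked)
        if len(ids):
            self.u[ids] = lif.u_r
            self.ref_count[ids] = self._t_ref_steps
            self._spike_t.append(np.full(len(ids), t * lif.dt))
            self._spike_id.append(ids)
            if len(ids) > 0.2 * self.N:
                # many spikers: one full pass over the synapse table is cheaper
                s = np.zeros(self.N)
                s[ids] = self._psc0
                for ds in self.delay_steps:
                    self._pending[(t + ds) % L] += self.WT[ds] @ s
            else:
                for ds in self.delay_steps:
                    rows = self.W[ds][ids]
                    if rows.nnz:
                        self._pending[(t + ds) % L] += self._psc0 * np.asarray(rows.sum(axis=0)).ravel()
        for i in self._membrane:
            self._membrane[i].append(self.u[i])
        self.t_step += 1
        return spiked

    def run(self, n_steps: int | None = None) -> None:
        total = int(round(self.cfg.duration_ms / self.lif.dt))
        stop = total if n_steps is None else min(total, self.t_step + n_steps)
        while self.t_step < stop:
            self.step()

    def record(self) -> SpikeRecord:
        """Snapshot the spikes emitted so far as a SpikeRecord."""
        if self._spike_t:
            t = np.concatenate(self._spike_t)
            i = np.concatenate(self._spike_id).astype(int)
        else:
            t = np.array([], dtype=float)
            i = np.array([], dtype=int)
        return SpikeRecord(
            times_ms=t, neurons=i, n_neurons=self.N,
            duration_ms=self.t_step * self.lif.dt,
            population_of=self._pop_of, populations=self.network.populations,
            membrane={k: np.asarray(v) for k, v in self._membrane.items()})


def simulate(network: NetworkSpec, lif: LIFParams, cfg: SimConfig) -> SpikeRecord:
    """Run the full configured duration and return the spike record.

    Deterministic: identical (network, lif, cfg) — including the seed — give
    identical records.
    """
    sim = Simulation(network, lif, cfg)
    sim.run()
    return sim.record()
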