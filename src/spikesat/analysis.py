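"""Observables of the stochastic search: microstates, entropy, activity, stats.

Spikes are binned into 200 ms windows (default).  Within each bin the network
microstate ψ is decoded at the variable level: for every variable the winning
value is the sub-population with the strictly largest spike count; ties or
silence leave the variable undecided.  From the decoded trace we derive the
Shannon entropy S(t) = −Σ p_i log₂ p_i of the visited-state distribution, the
mean per-neuron firing rate ν(t), the cumulative distinct-state count Ω(t),
bin-wise satisfaction flags, and — across repeated runs — the convergence-time
statistics (μ, σ, skewness γ₁, success ratio ξ, t_min).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sp_stats

from .csp import CSP, UNDECIDED, Assignment, check_assignment
from .simulate import SpikeRecord

__all__ = [
    "bin_spikes",
    "decode_states",
    "entropy_trace",
    "activity_trace",
    "states_count",
    "StateTrace",
    "build_state_trace",
    "final_state",
    "solve_time",
    "NOT_CONVERGED",
    "RunStats",
    "experiment_stats",
]

#: Sentinel for runs that never reach (stable) satisfaction.
NOT_CONVERGED = None


def bin_spikes(record: SpikeRecord, bin_width_ms: float = 200.0) -> np.ndarray:
    """Per-(population, bin) spike counts over half-open bins [k·w, (k+1)·w).

    The counts partition all events: they re-sum to the record's total.
    """
    if bin_width_ms <= 0:
        raise ValueError("bin width must be positive")
    n_bins = max(1, math.ceil(record.duration_ms / bin_width_ms))
    n_pops = len(record.populations)
    counts = np.zeros((n_pops, n_bins), dtype=int)
    if record.n_events:
        pops = record.population_of[record.neurons]
        bins = (record.times_ms // bin_width_ms).astype(int)
        np.add.at(counts, (pops, bins), 1)
    return counts


def decode_states(counts: np.ndarray, populations, n_variables: int) -> list[Assignment]:
    """Winner-take-all decoding of binned counts into one assignment per bin.

    The winner of a variable is the value sub-population with the strictly
    largest count; a tie for the maximum, or an all-silent variable, decodes
    as undecided — satisfaction is never granted on ambiguous activity.
    """
    n_bins = counts.shape[1]
    by_var: dict[int, list] = {}
    for p in populations:
        by_var.setdefault(p.variable, []).append(p)
    states = []
    for b in range(n_bins):
        values = []
        for var in range(n_variables):
            pops = by_var.get(var, [])
            c = np.array([counts[p.index, b] for p in pops])
            if c.size == 0 or c.max() == 0:
                values.append(UNDECIDED)
                continue
            top = np.flatnonzero(c == c.max())
            values.append(pops[top[0]].value if len(top) == 1 else UNDECIDED)
        states.append(Assignment(tuple(values)))
    return states


def entropy_trace(states: list[Assignment], window: int | None = None) -> np.ndarray:
    """Shannon entropy (bits) of the empirical microstate distribution.

    At bin t the distribution p_i is the frequency of each distinct decoded
    state over the trailing ``window`` bins ending at t (full history when
    ``window`` is None, matching a cumulative estimate).
    """
    if window is not None and window < 1:
        raise ValueError("window must be >= 1")
    out = np.zeros(len(states))
    for t in range(len(states)):
        lo = 0 if window is None else max(0, t + 1 - window)
        seen: dict = {}
        for s in states[lo:t + 1]:
            seen[s.values] = seen.get(s.values, 0) + 1
        n = sum(seen.values())
        out[t] = -sum((c / n) * math.log2(c / n) for c in seen.values()) + 0.0
    return out


def activity_trace(record: SpikeRecord, n_neurons: int | None = None,
                   bin_width_ms: float = 200.0) -> np.ndarray:
    """Mean firing rate per neuron per bin, in Hz: spikes / (N · bin width)."""
    n = record.n_neurons if n_neurons is None else n_neurons
    if n < 1:
        raise ValueError("n_neurons must be >= 1")
    n_bins = max(1, math.ceil(record.duration_ms / bin_width_ms))
    counts = np.zeros(n_bins)
    if record.n_events:
        np.add.at(counts, (record.times_ms // bin_width_ms).astype(int), 1)
    return counts / (n * bin_width_ms / 1000.0)


def states_count(states: list[Assignment]):
    """Cumulative distinct-state count Ω(t) with new/revisit/change flags.

    Ω is non-decreasing; ``new[t]`` marks first visits, ``revisit[t]`` returns
    to previously seen states, ``changed[t]`` bin-to-bin state changes.
    """
    seen: set = set()
    omega = np.zeros(len(states), dtype=int)
    new = np.zeros(len(states), dtype=bool)
    revisit = np.zeros(len(states), dtype=bool)
    changed = np.zeros(len(states), dtype=bool)
    prev = None
    for t, s in enumerate(states):
        if s.values not in seen:
            seen.add(s.values)
            new[t] = True
        else:
            revisit[t] = True
        omega[t] = len(seen)
        changed[t] = prev is not None and s.values != prev
        prev = s.values
    return omega, new, revisit, changed


@dataclass
class StateTrace:
    """Per-bin decoded view of one simulation run."""

    bin_width_ms: float
    counts: np.ndarray  # (population, bin) spike counts
    populations: list  # population index table of the record
    n_variables: int
    states: list[Assignment]
    entropy_bits: np.ndarray
    rate_hz: np.ndarray
    omega: np.ndarray
    new_state: np.ndarray
    revisit: np.ndarray
    changed: np.ndarray
    satisfied: np.ndarray
    metadata: dict = field(default_factory=dict)

    @property
    def n_bins(self) -> int:
        return len(self.states)

    def bin_start_ms(self, b: int) -> float:
        return b * self.bin_width_ms


def build_state_trace(record: SpikeRecord, csp: CSP, bin_width_ms: float = 200.0,
                      entropy_window: int | None = None) -> StateTrace:
    """Bin, decode and annotate a spike record against its CSP."""
    counts = bin_spikes(record, bin_width_ms)
    states = decode_states(counts, record.populations, csp.n_variables)
    sat = np.array([check_assignment(csp, s).satisfied for s in states])
    omega, new, revisit, changed = states_count(states)
    return StateTrace(
        bin_width_ms=bin_width_ms, counts=counts,
        populations=record.populations, n_variables=csp.n_variables, states=states,
        entropy_bits=entropy_trace(states, entropy_window),
        rate_hz=activity_trace(record, bin_width_ms=bin_width_ms),
        omega=omega, new_state=new, revisit=revisit, changed=changed,
        satisfied=sat)


def final_state(trace: StateTrace, window_bins: int = 5) -> Assignment:
    """Decode the end-of-run state from counts summed over the trailing bins.

    A wider window resolves variables whose activity is too sparse for a
    single bin (e.g. frustrated spin-glass sites); ties still decode as
    undecided.
    """
    agg = trace.counts[:, -window_bins:].sum(axis=1, keepdims=True)
    return decode_states(agg, trace.populations, trace.n_variables)[0]


def solve_time(trace: StateTrace, mode: str = "stable") -> float | None:
    """Model time (ms) at which the network first satisfies the CSP.

    ``first`` — start of the earliest satisfying bin.  ``stable`` — start of
    the earliest satisfying bin after which every later bin also satisfies;
    swaps between distinct satisfying states are allowed.  Returns
    ``NOT_CONVERGED`` (None) when no such bin exists.
    """
    sat = trace.satisfied
    if mode == "first":
        hits = np.flatnonzero(sat)
        return trace.bin_start_ms(int(hits[0])) if len(hits) else NOT_CONVERGED
    if mode == "stable":
        if not len(sat) or not sat[-1]:
            return NOT_CONVERGED
        # last False, then all True after it
        misses = np.flatnonzero(~sat)
        start = int(misses[-1]) + 1 if len(misses) else 0
        return trace.bin_start_ms(start)
    raise ValueError(f"unknown mode {mode!r} (expected 'first' or 'stable')")


@dataclass
class RunStats:
    """Convergence-time statistics over repeated runs.

    Moments (μ, σ, γ₁) and t_min are computed over successful runs only;
    the success ratio ξ over all runs.  Undefined moments (too few successes)
    are NaN, never fabricated.
    """

    n_runs: int
    n_success: int
    solve_times: list[float]  # successful runs, model time
    mean: float
    std: float
    skewness: float
    success_ratio: float
    t_min: float

    def __str__(self) -> str:  # pragma: no cover - formatting
        return (f"runs={self.n_runs} ξ={self.success_ratio:.2f} μ={self.mean:.3g} "
                f"σ={self.std:.3g} γ₁={self.skewness:.3g} t_min={self.t_min:.3g}")


def experiment_stats(run_times: list[float | None]) -> RunStats:
    """Aggregate per-run solve times (``None`` = failure) into RunStats.

    Sample skewness uses the adjusted Fisher–Pearson estimator.
    """
    if not run_times:
        raise ValueError("need at least one run")
    ok = [t for t in run_times if t is not None]
    n, k = len(run_times), len(ok)
    xi = k / n
    if k == 0:
        return RunStats(n, 0, [], math.nan, math.nan, math.nan, 0.0, math.nan)
    arr = np.asarray(ok, dtype=float)
    mean = float(arr.mean())
    std = float(arr.std(ddof=1)) if k >= 2 else math.nan
    skew = float(sp_stats.skew(arr, bias=False)) if k >= 3 else math.nan
    return RunStats(n, k, ok, mean, std, skew, xi, float(arr.min()))
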