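"""Binning, decoding, entropy, state counting and run statistics."""

import math

import numpy as np
import pytest

from spikesat import (
    Assignment,
    UNDECIDED,
    activity_trace,
    bin_spikes,
    build_state_trace,
    csp_from_graph_coloring,
    decode_states,
    entropy_trace,
    experiment_stats,
    solve_time,
    states_count,
)
from spikesat.analysis import StateTrace
from spikesat.compiler import Population
from spikesat.simulate import SpikeRecord


def make_record(events, populations, duration_ms):
    """Hand-built spike record: events as (time_ms, neuron_id)."""
    n = sum(p.size for p in populations)
    pop_of = np.empty(n, dtype=int)
    for p in populations:
        pop_of[p.offset:p.offset + p.size] = p.index
    ev = sorted(events)
    return SpikeRecord(
        times_ms=np.array([t for t, _ in ev], dtype=float),
        neurons=np.array([i for _, i in ev], dtype=int),
        n_neurons=n, duration_ms=duration_ms, population_of=pop_of,
        populations=populations)


# 2 variables × 2 values, 1 neuron per sub-population
POPS = [Population(0, 0, 0, 1, 0), Population(1, 0, 1, 1, 1),
        Population(2, 1, 0, 1, 2), Population(3, 1, 1, 1, 3)]


class TestBinning:
    def test_empty_record_all_zero(self):
        rec = make_record([], POPS, 600)
        counts = bin_spikes(rec, 200)
        assert counts.shape == (4, 3) and counts.sum() == 0

    def test_half_open_bins(self):
        rec = make_record([(250.0, 0)], POPS, 600)
        counts = bin_spikes(rec, 200)
        assert counts[0, 1] == 1 and counts.sum() == 1

    def test_counts_conserve_events(self):
        rng = np.random.default_rng(5)
        events = [(float(t), int(n)) for t, n in
                  zip(rng.integers(0, 600, 50), rng.integers(0, 4, 50))]
        rec = make_record(events, POPS, 600)
        assert bin_spikes(rec, 200).sum() == 50

    def test_boundary_spike_goes_to_later_bin(self):
        rec = make_record([(200.0, 0)], POPS, 400)
        counts = bin_spikes(rec, 200)
        assert counts[0, 1] == 1 and counts[0, 0] == 0


class TestDecoding:
    def test_strict_winner(self):
        counts = np.array([[10], [2], [0], [7]])
        states = decode_states(counts, POPS, 2)
        assert states[0].values == (0, 1)

    def test_tie_decodes_undecided(self):
        counts = np.array([[5], [5], [3], [0]])
        states = decode_states(counts, POPS, 2)
        assert states[0].values == (UNDECIDED, 0)

    def test_silent_bin_everything_undecided(self):
        counts = np.zeros((4, 2), dtype=int)
        states = decode_states(counts, POPS, 2)
        assert all(s.values == (UNDECIDED, UNDECIDED) for s in states)


class TestEntropy:
    def test_single_repeated_state_zero_bits(self):
        states = [Assignment((0, 1))] * 6
        assert entropy_trace(states)[-1] == 0.0

    def test_uniform_four_states_two_bits(self):
        states = [Assignment((i, 0)) for i in range(4)]
        assert entropy_trace(states)[-1] == pytest.approx(2.0)

    @pytest.mark.parametrize("k", [2, 3, 5])
    def test_equiprobable_support_reaches_log2k(self, k):
        states = [Assignment((i,)) for i in range(k)] * 4
        s = entropy_trace(states)
        assert s[-1] == pytest.approx(math.log2(k))
        assert np.all(s <= math.log2(k) + 1e-12)

    def test_sliding_window_bounds(self):
        rng = np.random.default_rng(0)
        states = [Assignment((int(v),)) for v in rng.integers(0, 4, 40)]
        w = 8
        s = entropy_trace(states, window=w)
        assert np.all(s >= 0) and np.all(s <= math.log2(w))
        # zero exactly when the trailing window holds a single distinct state
        for t in range(len(states)):
            lo = max(0, t + 1 - w)
            distinct = len({st.values for st in states[lo:t + 1]})
            assert (s[t] == 0) == (distinct == 1)


class TestActivity:
    def test_rate_arithmetic(self):
        # 2,000 spikes in one 200 ms bin over 100 neurons → 100 Hz
        pops = [Population(0, 0, 0, 100, 0)]
        events = [(float(t % 200), int(n)) for t, n in enumerate(range(2000))]
        events = [(float(i % 200), i % 100) for i in range(2000)]
        rec = make_record(events, pops, 200)
        assert activity_trace(rec, bin_width_ms=200)[0] == pytest.approx(100.0)

    def test_silent_bin_zero(self):
        rec = make_record([], POPS, 200)
        assert activity_trace(rec, bin_width_ms=200)[0] == 0.0

    def test_doubling_neurons_halves_rate(self):
        rec = make_record([(10.0, 0), (20.0, 1)], POPS, 200)
        r4 = activity_trace(rec, n_neurons=4, bin_width_ms=200)[0]
        r8 = activity_trace(rec, n_neurons=8, bin_width_ms=200)[0]
        assert r8 == pytest.approx(r4 / 2)

    def test_rate_times_n_times_width_resums_to_spikes(self):
        rng = np.random.default_rng(2)
        events = [(float(t), int(n)) for t, n in
                  zip(rng.integers(0, 1000, 77), rng.integers(0, 4, 77))]
        rec = make_record(events, POPS, 1000)
        nu = activity_trace(rec, bin_width_ms=200)
        assert nu.sum() * 4 * 0.2 == pytest.approx(77)


class TestStatesCount:
    def test_revisit_sequence(self):
        A, B = Assignment((0, 0)), Assignment((1, 1))
        omega, new, revisit, changed = states_count([A, A, B, A])
        assert omega.tolist() == [1, 1, 2, 2]
        assert revisit.tolist() == [False, True, False, True]
        assert changed.tolist() == [False, False, True, True]

    def test_constant_trace(self):
        omega, new, revisit, changed = states_count([Assignment((0,))] * 5)
        assert omega.tolist() == [1] * 5 and not changed.any()

    def test_all_distinct(self):
        states = [Assignment((i,)) for i in range(7)]
        omega, new, *_ = states_count(states)
        assert omega.tolist() == list(range(1, 8)) and new.all()

    def test_omega_monotone_and_bounded(self):
        rng = np.random.default_rng(1)
        states = [Assignment((int(a), int(b))) for a, b in rng.integers(0, 2, (30, 2))]
        omega, *_ = states_count(states)
        assert np.all(np.diff(omega) >= 0)
        assert omega[-1] <= min(30, 4)


def _trace_from_flags(flags, bin_width=200.0):
    n = len(flags)
    return StateTrace(bin_width, np.zeros((1, n), dtype=int), [POPS[0]], 1,
                      [Assignment((0,))] * n, np.zeros(n), np.zeros(n),
                      np.ones(n, dtype=int), np.zeros(n, dtype=bool),
                      np.zeros(n, dtype=bool), np.zeros(n, dtype=bool),
                      np.array(flags, dtype=bool))


class TestSolveTime:
    def test_stable_tail(self):
        tr = _trace_from_flags([False, False, True, True, True])
        assert solve_time(tr, "first") == 400.0
        assert solve_time(tr, "stable") == 400.0

    def test_transient_satisfaction_not_stable(self):
        tr = _trace_from_flags([False, True, False, False])
        assert solve_time(tr, "first") == 200.0
        assert solve_time(tr, "stable") is None

    def test_never_satisfied(self):
        tr = _trace_from_flags([False] * 4)
        assert solve_time(tr, "first") is None
        assert solve_time(tr, "stable") is None

    def test_satisfaction_flags_match_independent_check(self):
        """Trace satisfaction equals a direct re-check of each decoded bin
        against the constraints (reimplemented inline, not via check_assignment)."""
        csp = csp_from_graph_coloring([(0, 1), (1, 2), (0, 2)], 3)
        from spikesat import CompilerParams, LIFParams, SimConfig, compile_csp, simulate

        net = compile_csp(csp, CompilerParams(n=10, stim_size=10, stim_rate_hz=120.0,
                                              stim_weight=1.6, current=0.17), seed=2)
        rec = simulate(net, LIFParams(), SimConfig(4000, seed=2))
        tr = build_state_trace(rec, csp)
        for b in range(tr.n_bins):
            vals = tr.states[b].values
            ok = all(v != UNDECIDED for v in vals) and all(
                vals[c.u] != vals[c.v] for c in csp.constraints)
            assert tr.satisfied[b] == ok


class TestExperimentStats:
    def test_mixed_runs(self):
        st = experiment_stats([1000.0, 2000.0, 3000.0, None])
        assert st.mean == pytest.approx(2000.0)
        assert st.success_ratio == 0.75
        assert st.t_min == 1000.0
        assert st.n_success == 3

    def test_all_failures(self):
        st = experiment_stats([None, None])
        assert st.success_ratio == 0.0
        assert math.isnan(st.mean) and math.isnan(st.t_min)

    def test_single_success_undefined_spread(self):
        st = experiment_stats([5000.0, None])
        assert st.mean == 5000.0 and st.t_min == 5000.0
        assert math.isnan(st.std) and math.isnan(st.skewness)

    def test_moments_match_direct_formulas(self):
        times = [1.0, 2.0, 4.0, 8.0, 16.0]
        st = experiment_stats(times)
        x = np.array(times)
        assert st.mean == pytest.approx(x.mean())
        assert st.std == pytest.approx(x.std(ddof=1))
        n = len(x)
        g1 = ((x - x.mean()) ** 3).mean() / x.std(ddof=0) ** 3
        adj = math.sqrt(n * (n - 1)) / (n - 2) * g1
        assert st.skewness == pytest.approx(adj)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            experiment_stats([])
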