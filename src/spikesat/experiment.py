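"""End-to-end orchestration: compile → simulate → analyze, repeated runs.

A *run* compiles the instance under a run-specific seed, simulates in chunks,
and stops early once the decoded state satisfies the CSP (``stop='first'``)
or has satisfied it over a tail of consecutive bins (``stop='stable'``).
Every reported solution is re-verified against the CSP before being trusted;
an experiment aggregates per-run solve times into RunStats.  Per-run seeds
derive as (master seed + run index), so run subsets reproduce independently.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .analysis import NOT_CONVERGED, RunStats, build_state_trace, experiment_stats, solve_time
from .compiler import compile_csp, encode_clues, network_summary
from .csp import Assignment, check_assignment
from .fixtures import ProblemInstance, load_fixture
from .io import write_trace_tsv
from .simulate import SimConfig, Simulation

__all__ = ["RunResult", "ExperimentConfig", "run_single", "run_experiment", "solve"]

log = logging.getLogger("spikesat")


@dataclass
class RunResult:
    """Outcome of one seeded run."""

    seed: int
    t_first_ms: float | None
    t_stable_ms: float | None
    solved: bool
    assignment: Assignment | None
    trace: object  # StateTrace
    duration_ms: float


@dataclass
class ExperimentConfig:
    """Declarative description of a repeated-run experiment."""

    problem: str  # fixture name
    runs: int = 20
    seed: int = 1
    duration_ms: float | None = None  # None: the fixture's default budget
    stop: str = "stable"  # first | stable | none
    stable_bins: int = 5
    bin_width_ms: float = 200.0
    time_mode: str = "first"  # which solve time feeds the statistics
    outdir: str | None = None
    save_traces: bool = False
    compiler_overrides: dict = field(default_factory=dict)
    lif_overrides: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.runs < 1:
            raise ValueError("run count must be >= 1")
        if self.stop not in ("first", "stable", "none"):
            raise ValueError("stop must be 'first', 'stable' or 'none'")

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))

    def resolve_instance(self) -> ProblemInstance:
        inst = load_fixture(self.problem)
        if self.compiler_overrides:
            inst.params = dataclasses.replace(inst.params, **self.compiler_overrides)
        if self.lif_overrides:
            inst.lif = dataclasses.replace(inst.lif, **self.lif_overrides)
        if self.duration_ms:
            inst.duration_ms = self.duration_ms
        return inst


def run_single(
    instance: ProblemInstance,
    seed: int,
    duration_ms: float | None = None,
    stop: str = "stable",
    stable_bins: int = 5,
    bin_width_ms: float = 200.0,
    check_every_ms: float = 1000.0,
) -> RunResult:
    """One seeded compile-and-simulate run with early stopping.

    The same seed drives compilation (connectivity, weights, delays) and the
    noise streams, so a run is fully reproducible from (instance, seed).
    ``stop='none'`` always simulates the full duration.
    """
    if stop not in ("first", "stable", "none"):
        raise ValueError("stop must be 'first', 'stable' or 'none'")
    csp = instance.csp
    network = compile_csp(csp, instance.params, seed=seed)
    if instance.clues:
        network = encode_clues(network, instance.clues, instance.params)
    duration = duration_ms if duration_ms is not None else instance.duration_ms
    sim = Simulation(network, instance.lif, SimConfig(duration, seed=seed))
    chunk_steps = int(round(check_every_ms / instance.lif.dt))
    total_steps = int(round(duration / instance.lif.dt))
    trace = None
    while sim.t_step < total_steps:
        sim.run(chunk_steps)
        trace = build_state_trace(sim.record(), csp, bin_width_ms)
        sat = trace.satisfied
        if stop == "first" and sat.any():
            break
        if stop == "stable" and len(sat) >= stable_bins and sat[-stable_bins:].all():
            break
    if trace is None:
        trace = build_state_trace(sim.record(), csp, bin_width_ms)

    t_first = solve_time(trace, "first")
    t_stable = solve_time(trace, "stable")
    solved = False
    assignment = None
    if t_first is not NOT_CONVERGED:
        b = int(t_first // bin_width_ms)
        assignment = trace.states[b]
        # no trust in the dynamics: re-verify the decoded state
        if not check_assignment(csp, assignment).satisfied:
            raise RuntimeError(
                f"internal inconsistency: bin {b} flagged satisfied but re-verification failed")
        solved = True
    return RunResult(seed, t_first, t_stable, solved, assignment, trace,
                     duration_ms=sim.t_step * instance.lif.dt)


def run_experiment(cfg: ExperimentConfig) -> tuple[RunStats, list[RunResult]]:
    """Execute ``cfg.runs`` seeded runs and aggregate convergence statistics.

    With an ``outdir``, writes the resolved config, per-run solve times and
    solutions, aggregate stats, and (optionally) per-run state-trace tables.
    """
    inst = cfg.resolve_instance()
    log.info("experiment %s: %d runs, seed %d, duration %.0f ms",
             inst.name, cfg.runs, cfg.seed, inst.duration_ms)
    log.info("resolved compiler params: %s", inst.params)
    log.info("resolved LIF params: %s", inst.lif)
    log.info("network summary: %s", network_summary(
        compile_csp(inst.csp, inst.params, seed=cfg.seed)))
    results = []
    for i in range(cfg.runs):
        r = run_single(inst, seed=cfg.seed + i, stop=cfg.stop,
                       stable_bins=cfg.stable_bins, bin_width_ms=cfg.bin_width_ms)
        results.append(r)
        log.info("run %d (seed %d): first=%s ms stable=%s ms", i, r.seed,
                 r.t_first_ms, r.t_stable_ms)
    times = [r.t_first_ms if cfg.time_mode == "first" else r.t_stable_ms for r in results]
    stats = experiment_stats(times)

    if cfg.outdir:
        out = Path(cfg.outdir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "config.yaml").write_text(yaml.safe_dump(dataclasses.asdict(cfg)))
        rows = [{"run": i, "seed": r.seed, "t_first_ms": r.t_first_ms,
                 "t_stable_ms": r.t_stable_ms, "solved": r.solved,
                 "solution": list(r.assignment.values) if r.assignment else None}
                for i, r in enumerate(results)]
        (out / "runs.json").write_text(json.dumps(rows, indent=1))
        (out / "stats.yaml").write_text(yaml.safe_dump({
            "n_runs": stats.n_runs, "n_success": stats.n_success,
            "mean_ms": stats.mean, "std_ms": stats.std, "skewness": stats.skewness,
            "success_ratio": stats.success_ratio, "t_min_ms": stats.t_min}))
        if cfg.save_traces:
            for i, r in enumerate(results):
                write_trace_tsv(r.trace, out / f"trace_{i:03d}.tsv")
    return stats, results


def solve(instance: ProblemInstance, seed: int = 1, **kwargs) -> RunResult:
    """Convenience single-run solve of a problem instance."""
    return run_single(instance, seed=seed, **kwargs)
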