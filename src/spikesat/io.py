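"""Readers and writers: DIMACS .col graphs, Sudoku strings, network specs,
spike/trace tables.

All on-disk formats are plain text.  Network specs serialize to a canonical
JSON document (sorted keys, repr-exact floats) so that identical compiles are
byte-identical on disk.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .compiler import NetworkSpec, NoisePulse, NoiseSource, Population, Projection
from .csp import CSP, Constraint
from .problems import SpinSystem

__all__ = [
    "read_dimacs_col",
    "write_dimacs_col",
    "save_network",
    "load_network",
    "write_spikes_tsv",
    "write_trace_tsv",
    "save_csp",
    "load_csp",
    "save_spin_system",
    "load_spin_system",
]


def read_dimacs_col(source) -> tuple[list, list[tuple]]:
    """Parse a DIMACS .col graph: ``p edge n m`` header and ``e u v`` lines.

    Vertices are 1-based in the file.  Optional ``c label <i> <name>`` comment
    lines attach names; unnamed vertices keep their integer id.  Returns
    (vertex labels in index order, edge list over labels).
    """
    text = Path(source).read_text() if isinstance(source, (str, Path)) and "\n" not in str(source) else str(source)
    n = None
    labels: dict[int, str] = {}
    raw_edges: list[tuple[int, int]] = []
    for line in text.splitlines():
        parts = line.split()
        if not parts:
            continue
        if parts[0] == "c":
            if len(parts) >= 4 and parts[1] == "label":
                labels[int(parts[2])] = parts[3]
        elif parts[0] == "p":
            if parts[1] not in ("edge", "edges", "col"):
                raise ValueError(f"unsupported DIMACS problem line: {line!r}")
            n = int(parts[2])
        elif parts[0] == "e":
            raw_edges.append((int(parts[1]), int(parts[2])))
    if n is None:
        raise ValueError("missing 'p edge' header")
    for u, v in raw_edges:
        if not (1 <= u <= n and 1 <= v <= n):
            raise ValueError(f"edge ({u}, {v}) outside vertex range 1..{n}")
    names = [labels.get(i, i) for i in range(1, n + 1)]
    edges = [(names[u - 1], names[v - 1]) for u, v in raw_edges]
    return names, edges


def write_dimacs_col(path, vertices: list, edges: list[tuple], comment: str | None = None) -> None:
    idx = {v: i + 1 for i, v in enumerate(vertices)}
    lines = []
    if comment:
        lines += [f"c {c}" for c in comment.splitlines()]
    lines += [f"c label {i + 1} {v}" for i, v in enumerate(vertices)]
    lines.append(f"p edge {len(vertices)} {len(edges)}")
    lines += [f"e {idx[u]} {idx[v]}" for u, v in edges]
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# CSP serialization
# ---------------------------------------------------------------------------

def save_csp(csp: CSP, path) -> None:
    doc = {
        "domains": csp.domains,
        "constraints": [[c.u, c.v, c.sign, c.strength_tag] for c in csp.constraints],
        "metadata": _jsonable(csp.metadata),
    }
    Path(path).write_text(json.dumps(doc, sort_keys=True, indent=1) + "\n")


def load_csp(path) -> CSP:
    doc = json.loads(Path(path).read_text())
    return CSP(doc["domains"],
               [Constraint(u, v, s, tag) for u, v, s, tag in doc["constraints"]],
               metadata=doc.get("metadata", {}))


def save_spin_system(system: SpinSystem, path) -> None:
    doc = {
        "n_sites": system.n_sites,
        "lattice_shape": list(system.lattice_shape) if system.lattice_shape else None,
        "field": system.field,
        "bonds": [[i, j, J] for (i, j), J in sorted(system.couplings.items())],
        "metadata": _jsonable(system.metadata),
    }
    Path(path).write_text(json.dumps(doc, sort_keys=True, indent=1) + "\n")


def load_spin_system(path) -> SpinSystem:
    doc = json.loads(Path(path).read_text())
    shape = tuple(doc["lattice_shape"]) if doc.get("lattice_shape") else None
    return SpinSystem(doc["n_sites"], {(i, j): J for i, j, J in doc["bonds"]},
                      field=doc["field"], lattice_shape=shape,
                      metadata=doc.get("metadata", {}))


# ---------------------------------------------------------------------------
# network serialization
# ---------------------------------------------------------------------------

def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def save_network(network: NetworkSpec, path) -> None:
    """Write a NetworkSpec as canonical JSON (deterministic byte content)."""
    doc = {
        "populations": [[p.index, p.variable, p.value, p.size, p.offset]
                        for p in network.populations],
        "projections": [{
            "source": pr.source, "target": pr.target, "kind": pr.kind, "sign": pr.sign,
            "pre": pr.pre.tolist(), "post": pr.post.tolist(),
            "weight": pr.weight.tolist(), "delay_ms": pr.delay_ms.tolist(),
        } for pr in network.projections],
        "noise_sources": [{
            "index": s.index, "target": s.target, "kind": s.kind, "size": s.size,
            "rate_hz": s.rate_hz, "weight": s.weight,
            "pulse": [s.pulse.start_ms, s.pulse.duration_ms],
            "pre": s.pre.tolist(), "post": s.post.tolist(),
        } for s in network.noise_sources],
        "currents": network.currents.tolist(),
        "domain_sizes": network.domain_sizes,
        "metadata": _jsonable(network.metadata),
    }
    Path(path).write_text(json.dumps(doc, sort_keys=True) + "\n")


def load_network(path) -> NetworkSpec:
    doc = json.loads(Path(path).read_text())
    pops = [Population(*row) for row in doc["populations"]]
    projs = [Projection(p["source"], p["target"], p["kind"], p["sign"],
                        np.array(p["pre"], dtype=int), np.array(p["post"], dtype=int),
                        np.array(p["weight"], dtype=float), np.array(p["delay_ms"], dtype=float))
             for p in doc["projections"]]
    sources = [NoiseSource(s["index"], s["target"], s["kind"], s["size"], s["rate_hz"],
                           s["weight"], NoisePulse(s["pulse"][0], s["pulse"][1]),
                           np.array(s["pre"], dtype=int), np.array(s["post"], dtype=int))
               for s in doc["noise_sources"]]
    return NetworkSpec(pops, projs, sources, np.array(doc["currents"], dtype=float),
                       doc["domain_sizes"], doc.get("metadata", {}))


# ---------------------------------------------------------------------------
# run artifacts
# ---------------------------------------------------------------------------

def write_spikes_tsv(record, path) -> None:
    """Tab-separated spike events: time_ms, neuron_id, population_index."""
    with open(path, "w") as fh:
        fh.write("time_ms\tneuron\tpopulation\n")
        for t, n in zip(record.times_ms, record.neurons):
            fh.write(f"{t:g}\t{int(n)}\t{int(record.population_of[n])}\n")


def write_trace_tsv(trace, path) -> None:
    """Tab-separated per-bin observables of a StateTrace."""
    with open(path, "w") as fh:
        fh.write("bin\tt_start_ms\tentropy_bits\trate_hz\tomega\tsatisfied\tchanged\tstate\n")
        for b in range(trace.n_bins):
            state = ",".join(str(v) for v in trace.states[b].values)
            fh.write(f"{b}\t{trace.bin_start_ms(b):g}\t{trace.entropy_bits[b]:.6g}\t"
                     f"{trace.rate_hz[b]:.6g}\t{trace.omega[b]}\t"
                     f"{int(trace.satisfied[b])}\t{int(trace.changed[b])}\t{state}\n")
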