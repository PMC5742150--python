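"""Diagnostic figures: entropy/rate/state panels and solve-time histograms."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .analysis import RunStats, StateTrace

__all__ = ["plot_trace_panels", "plot_solve_time_histogram"]


def plot_trace_panels(trace: StateTrace, path=None):
    """Three stacked panels vs model time: entropy S, mean rate ν, states Ω.

    Bin markers follow the search bookkeeping: satisfied bins blue, state
    changes red, repeats green; on the state-count panel new states are black
    dots and revisits yellow.
    """
    t = (np.arange(trace.n_bins) * trace.bin_width_ms) / 1000.0
    colors = np.where(trace.satisfied, "tab:blue",
                      np.where(trace.changed, "tab:red", "tab:green"))
    fig, axes = plt.subplots(3, 1, sharex=True, figsize=(7, 6))
    axes[0].plot(t, trace.entropy_bits, lw=0.8, color="0.6")
    axes[0].scatter(t, trace.entropy_bits, c=colors, s=8)
    axes[0].set_ylabel("S (bits)")
    axes[1].plot(t, trace.rate_hz, lw=0.8, color="0.3")
    axes[1].set_ylabel("ν (Hz)")
    axes[2].plot(t, trace.omega, lw=0.8, color="0.6")
    axes[2].scatter(t, trace.omega, c=np.where(trace.new_state, "black", "gold"), s=8)
    axes[2].set_ylabel("Ω (states)")
    axes[2].set_xlabel("model time (s)")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_solve_time_histogram(stats: RunStats, path=None, bins=20):
    """Histogram of successful convergence times with μ, σ, γ₁, ξ, t_min."""
    fig, ax = plt.subplots(figsize=(6, 4))
    times_s = np.asarray(stats.solve_times) / 1000.0
    if len(times_s):
        ax.hist(times_s, bins=bins, color="tab:blue", alpha=0.8)
    ax.set_xlabel("time to solution (s)")
    ax.set_ylabel("runs")
    ax.set_title(f"μ={stats.mean / 1000:.2f} s  σ={stats.std / 1000:.2f} s  "
                 f"γ₁={stats.skewness:.2f}  ξ={stats.success_ratio:.2f}  "
                 f"t_min={stats.t_min / 1000:.2f} s")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
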