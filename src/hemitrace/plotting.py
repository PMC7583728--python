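"""Static plot export: raw/corrected trace with marked transitions."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .pipeline import AnalysisResult  # noqa: E402

__all__ = ["plot_result", "plot_conductance_histogram"]


def plot_conductance_histogram(conductances, components=(), bin_width=10.0,
                               path=None):
    """Max-normalized conductance histogram with fitted Gaussian overlays."""
    import numpy as np

    g = np.asarray(conductances, dtype=float)
    fig, ax = plt.subplots(figsize=(6, 4))
    edges = np.arange(0, g.max() + 2 * bin_width, bin_width)
    counts, _ = np.histogram(g, edges)
    ax.bar(edges[:-1], counts / counts.max(), width=bin_width, align="edge",
           color="0.7", edgecolor="0.4")
    x = np.linspace(0, edges[-1], 500)
    for comp in components:
        ax.plot(x, comp.amplitude * np.exp(-0.5 * ((x - comp.mean) / comp.sd) ** 2),
                lw=1.5, label=f"{comp.mean:.0f} ± {comp.sd:.0f} pS")
    if len(components):
        ax.legend(fontsize=8)
    ax.set_xlabel("conductance (pS)")
    ax.set_ylabel("normalized events")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_result(result: AnalysisResult, path: str | Path | None = None,
                decimate: int = 4):
    """Raw and corrected trace with openings (red) and closings (green)."""
    fig, (ax0, ax1) = plt.subplots(2, 1, figsize=(10, 6), sharex=True)
    raw = result.raw_trace
    cor = result.corrected_trace
    ax0.plot(raw.times[::decimate], raw.samples[::decimate],
             lw=0.4, color="tab:blue", label="raw")
    if result.baseline is not None:
        ax0.plot(raw.times[::decimate],
                 result.baseline.evaluate(raw)[::decimate],
                 lw=1.0, color="tab:orange", label="baseline fit")
    ax0.set_ylabel("current (pA)")
    ax0.legend(loc="upper right", fontsize=8)
    ax1.plot(cor.times[::decimate], cor.samples[::decimate],
             lw=0.4, color="0.4", label="corrected")
    for ev in result.events:
        color = "red" if ev.direction == "opening" else "green"
        ax1.axvline(ev.t_trans, color=color, lw=0.6, alpha=0.7)
    ax1.set_xlabel("time (s)")
    ax1.set_ylabel("current (pA)")
    fig.suptitle(f"trace {result.trace_id}  "
                 f"NPo={result.summary.npo:.3f}  "
                 f"events={result.summary.n_transitions_total}")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
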