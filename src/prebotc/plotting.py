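"""Figure-style trace plots for experiment results."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .experiments import SweepResult
from .simulate import MINUTE, Trace


def plot_trace(trace: Trace, ax, downsample: int = 10, label: str | None = None) -> None:
    """One condition's population-average voltage against time in minutes."""
    t = trace.t[::downsample] / MINUTE
    ax.plot(t, trace.v_avg[::downsample], lw=0.5, color="k")
    ax.set_ylabel("V (mV)")
    if label:
        ax.set_title(label, loc="left", fontsize=9)


def plot_experiment(result: SweepResult, path: str | Path, downsample: int = 10) -> Path:
    """Stack all conditions of a sweep into one figure (top to bottom in
    protocol order), mirroring the layout of the in-silico panels."""
    conds = [c for c in result.conditions if c in result.traces]
    if not conds:
        raise ValueError("result holds no traces; run with keep_traces or out_dir")
    fig, axes = plt.subplots(len(conds), 1, sharex=True,
                             figsize=(8, 1.8 * len(conds)), squeeze=False)
    for ax, cond in zip(axes[:, 0], conds):
        plot_trace(result.traces[cond], ax, downsample, label=cond)
    axes[-1, 0].set_xlabel("time (min)")
    fig.suptitle(result.name)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
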