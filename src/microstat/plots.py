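"""Optional matplotlib figures for logs and fits (file output only)."""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .analysis import LinearFit
from .logio import ExperimentLog


def plot_timeseries(log: ExperimentLog, path: str | Path) -> Path:
    """Filtered transmittance over time with refresh-cycle markers."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 3.5))
    s = log.samples
    ax.plot(s["time_s"] / 3600.0, s["filtered_pct"], lw=0.8, color="tab:blue")
    for t in log.refresh_cycles["time_s"]:
        ax.axvline(t / 3600.0, color="tab:orange", lw=0.3, alpha=0.5)
    ax.set_xlabel("time (h)")
    ax.set_ylabel("filtered transmittance (%)")
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def plot_fit(xs, ys, fit: LinearFit, path: str | Path, xlabel: str = "", ylabel: str = "") -> Path:
    """Calibration scatter with the fitted line."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    xs = np.asarray(xs, dtype=float)
    fig, ax = plt.subplots(figsize=(4.5, 3.5))
    ax.scatter(xs, ys, s=12, color="tab:blue")
    grid = np.linspace(xs.min(), xs.max(), 50)
    ax.plot(grid, fit.predict(grid), color="tab:red", lw=1,
            label=f"slope={fit.slope:.4g}, r²={fit.r2:.4f}")
    ax.set_xlabel(xlabel)
    ax.set_ylabel(ylabel)
    ax.legend(fontsize=8)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
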