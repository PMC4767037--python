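"""Optional matplotlib plots for simulations and regime maps."""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .scenarios import SweepResult
from .solver import SimulationResult


def plot_timeseries(result: SimulationResult, path: str | Path) -> Path:
    """Stomach/luminal/absorbed/exited masses against time."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4.5))
    t = result.times / 60.0
    ax.plot(t, result.stomach_glucose + result.stomach_starch, label="stomach")
    ax.plot(t, result.luminal_glucose + result.luminal_starch, label="lumen")
    ax.plot(t, result.absorbed, label="absorbed")
    ax.plot(t, result.exited, label="exited")
    ax.set_xlabel("time [min]")
    ax.set_ylabel("mass [g]")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)


def plot_regime_map(sweep: SweepResult, path: str | Path,
                    overlay=None) -> Path:
    """Log-log contour of fraction absorbed over (tau_emptying, tau_transfer).

    `overlay`, if given, is a DataFrame with tau_emptying/tau_transfer
    columns (e.g. from :func:`gutsim.scenarios.meals_to_groups`).
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    tau_e = sweep.axes["tau_emptying"]
    tau_t = sweep.axes["tau_transfer"]
    fig, ax = plt.subplots(figsize=(6, 5))
    cs = ax.contourf(tau_e, tau_t, sweep.response.T, levels=10, cmap="viridis")
    fig.colorbar(cs, ax=ax, label="fraction absorbed")
    if overlay is not None:
        ok = np.isfinite(overlay["tau_transfer"])
        ax.plot(overlay.loc[ok, "tau_emptying"], overlay.loc[ok, "tau_transfer"],
                "ws", mec="k", label="literature meals")
        ax.legend(loc="lower right")
    ax.set_xscale("log")
    ax.set_yscale("log")
    ax.set_xlabel(r"$\tau_{emptying}$")
    ax.set_ylabel(r"$\tau_{transfer}$")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)
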