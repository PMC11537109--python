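"""Plot helpers for calibration and sensitivity outputs (matplotlib)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .experiments import CalibrationResult, SensitivityResult
from .metrics import KEY_NODES


def plot_calibration(result: CalibrationResult, path) -> None:
    """Objective score against the candidate OnHold wait."""
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(result.grid, result.scores, "o-")
    ax.axvline(result.best, color="crimson", ls="--", label=f"best = {result.best:g} min")
    ax.set_xlabel("OnHold wait (min)")
    ax.set_ylabel(f"objective ({result.objective})")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_sensitivity(result: SensitivityResult, path) -> None:
    """Four panels: replicate and aggregate key-node means over the grid."""
    fig, axes = plt.subplots(2, 2, figsize=(9, 7), sharex=True)
    for ax, node in zip(axes.ravel(), KEY_NODES):
        reps = result.replicate_means.loc[result.replicate_means["node"] == node]
        ax.scatter(reps["onhold_min"], reps["mean_minutes"] / 60.0, s=10, alpha=0.4)
        agg = result.node_aggregate(node)
        ax.plot(agg["onhold_min"], agg["mean_minutes"] / 60.0, color="crimson")
        ax.set_title(node.replace("_", " "))
        ax.set_ylabel("mean interval (h)")
    for ax in axes[-1]:
        ax.set_xlabel(f"{result.role} OnHold wait (min)")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
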