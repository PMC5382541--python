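"""Line plots of functional connectivity curves and 2D-vs-3D bias."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .grids import Stratum

_COLORS = {
    Stratum.GREEN2D: "0.4",
    Stratum.GRASS: "#d4b82c",
    Stratum.SHRUB: "#2c7bd4",
    Stratum.TREE: "#2ca02c",
}


def plot_report(curves: dict, biases: dict, ci_threshold: float, path: str | Path) -> Path:
    """Two panels: CI vs dispersal distance per layer (left) and the
    per-stratum CI difference from the flat 2D view (right), with a
    dotted reference line at the high-connectivity CI threshold."""
    fig, (ax_ci, ax_bias) = plt.subplots(1, 2, figsize=(10, 4))

    for layer, curve in curves.items():
        ax_ci.plot(
            curve.distances_m,
            curve.ci_values,
            color=_COLORS[layer],
            label=layer.value,
        )
    ax_ci.axhline(ci_threshold, linestyle=":", color="k", linewidth=1)
    ax_ci.set_xlabel("dispersal capacity (m)")
    ax_ci.set_ylabel("CI (1 = disconnected)")
    ax_ci.set_ylim(-0.02, 1.02)
    ax_ci.legend(frameon=False, fontsize=8)

    for layer, bias in biases.items():
        ax_bias.plot(bias.distances_m, bias.delta_ci, color=_COLORS[layer], label=layer.value)
    ax_bias.axhline(0.0, color="k", linewidth=0.8)
    ax_bias.set_xlabel("dispersal capacity (m)")
    ax_bias.set_ylabel("CI difference vs 2D")
    if biases:
        ax_bias.legend(frameon=False, fontsize=8)

    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
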