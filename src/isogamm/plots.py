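"""Publication-style figures: torque-angle curves and H:Q ratio curves."""

from __future__ import annotations

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .analysis import CurveDraws, RatioCurve
from .data import rescale_extension_angle

PANEL_ORDER = (("extension", "concentric"), ("extension", "eccentric"),
               ("flexion", "concentric"), ("flexion", "eccentric"))


def _display_axis(grid: np.ndarray, action: str) -> tuple[np.ndarray, str]:
    if action == "extension":
        return rescale_extension_angle(grid), "extension progress (deg)"
    return grid, "knee flexion angle (deg)"


def plot_curves(curves: dict[tuple[str, str], CurveDraws], path,
                level: float = 0.95) -> None:
    fig, axes = plt.subplots(2, 2, figsize=(9, 7), sharey=True)
    for ax, (action, mode) in zip(axes.ravel(), PANEL_ORDER):
        cd = curves.get((action, mode))
        if cd is None:
            ax.set_visible(False)
            continue
        x, xlabel = _display_axis(cd.grid, action)
        order = np.argsort(x)
        lo, hi = cd.band(level)
        ax.fill_between(x[order], lo[order], hi[order], alpha=0.3, lw=0)
        ax.plot(x[order], cd.mean[order])
        ax.set_title(f"{action} {mode}")
        ax.set_xlabel(xlabel)
        ax.set_ylabel("moment of force (N*m)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_ratios(ratios: dict[str, RatioCurve], path, level: float = 0.95) -> None:
    fig, axes = plt.subplots(1, 2, figsize=(9, 4), sharey=True)
    for ax, name in zip(axes, ("extension", "flexion")):
        rc = ratios.get(name)
        if rc is None:
            ax.set_visible(False)
            continue
        x, xlabel = _display_axis(rc.grid, name if name == "extension" else "flexion")
        order = np.argsort(x)
        lo, hi = rc.band(level)
        ax.fill_between(x[order], lo[order], hi[order], alpha=0.3, lw=0)
        ax.plot(x[order], rc.mean[order])
        ax.axhline(1.0, ls="--", c="k", lw=0.8)  # point of equality
        ax.set_title(f"functional H:Q ratio, knee {name}")
        ax.set_xlabel(xlabel)
        ax.set_ylabel("H:Q ratio")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
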