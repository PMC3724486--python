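"""Cost-effectiveness plane and acceptability-curve figures."""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
from matplotlib.patches import Ellipse as MplEllipse

from .psa import CEResult

__all__ = ["plot_ce_plane", "plot_ceac"]


def plot_ce_plane(
    results: Sequence[tuple[str, CEResult]],
    path: str | Path,
    show_draws: bool = False,
) -> None:
    """CE plane: per-subgroup mean incremental (QALY, cost) with its
    confidence ellipse; effects on the x-axis, costs on the y-axis."""
    fig, ax = plt.subplots(figsize=(6.5, 5.5))
    colors = plt.cm.tab10(np.linspace(0, 1, max(len(results), 1)))
    for (label, res), color in zip(results, colors):
        if show_draws:
            ax.scatter(res.draws[:, 1], res.draws[:, 0], s=4, alpha=0.15, color=color)
        ell = res.ellipse
        if ell is not None and not ell.degenerate:
            # ellipse is fitted on (cost, effect); the plane plots (effect, cost)
            angle_deg = np.degrees(np.arctan2(np.cos(ell.angle), np.sin(ell.angle)))
            patch = MplEllipse(
                xy=(ell.center[1], ell.center[0]),
                width=2 * ell.semi_axes[0],
                height=2 * ell.semi_axes[1],
                angle=angle_deg,
                fill=False,
                color=color,
                lw=1.5,
            )
            ax.add_patch(patch)
        ax.plot(
            res.mean_inc_qaly, res.mean_inc_cost, "o", color=color, label=label
        )
    ax.axhline(0.0, color="0.4", lw=0.8)
    ax.axvline(0.0, color="0.4", lw=0.8)
    ax.set_xlabel("Incremental effects (QALY)")
    ax.set_ylabel("Incremental costs (\N{EURO SIGN})")
    ax.legend(fontsize=8, loc="best")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_ceac(results: Sequence[tuple[str, CEResult]], path: str | Path) -> None:
    """Acceptability curves with the vertical-axis intercept annotated."""
    fig, ax = plt.subplots(figsize=(6.5, 5.0))
    for label, res in results:
        intercept = res.ceac_at(0.0)
        ax.plot(
            res.thresholds,
            res.ceac,
            label=f"{label} (intercept {intercept:.0%})",
        )
    ax.set_xlabel("Cost-effectiveness threshold (\N{EURO SIGN}/QALY)")
    ax.set_ylabel("Probability cost-effective")
    ax.set_ylim(0.0, 1.0)
    ax.legend(fontsize=8, loc="best")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
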