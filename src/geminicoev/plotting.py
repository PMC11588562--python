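"""Figure builders: the region diagram and the prevalence curves.

Both figures are regenerable from the CSV tables the CLI writes;
the functions here only consume in-memory objects.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import pandas as pd

from .ovulation import OvulationEcology, ecology_curve, partition_resource_space

__all__ = ["region_diagram", "prevalence_figure"]

_REGION_COLOURS = {
    (False, True): "#c6dbef",   # double-ov favoured, twinning costly
    (False, False): "#fcbba1",  # mono-ov favoured, twinning costly
    (True, True): "#74c476",    # double-ov favoured, twinning adaptive
    (True, False): "#fdd0a2",   # mono-ov favoured, twinning adaptive (edge case)
}


def region_diagram(eco: OvulationEcology, n_grid: int = 401, tol: float = 1e-9):
    """Fitness curves with the adaptive regions shaded on the E axis."""
    curve = ecology_curve(eco, n_grid=n_grid)
    regions = partition_resource_space(eco, tol=tol)

    fig, ax = plt.subplots(figsize=(7, 4.5))
    for reg in regions:
        ax.axvspan(
            reg.lower,
            reg.upper,
            color=_REGION_COLOURS[(reg.twinning_adaptive, reg.double_ov_favoured)],
            alpha=0.5,
            lw=0,
        )
        label = ("2-ov" if reg.double_ov_favoured else "1-ov") + (
            "\ntwin+" if reg.twinning_adaptive else "\ntwin-"
        )
        ax.text(
            0.5 * (reg.lower + reg.upper),
            ax.get_ylim()[1] * 0.05,
            label,
            ha="center",
            fontsize=8,
        )
    ax.plot(curve["E"], curve["W_P"], label=r"$W_P$ (double-ovulation)", color="#08519c")
    ax.plot(curve["E"], curve["W_S"], label=r"$W_S$ (mono-ovulation)", color="#a63603")
    if 0 < eco.E_star < 1:
        ax.axvline(eco.E_star, ls="--", color="grey", lw=1)
        ax.annotate(r"$E^*$", (eco.E_star, ax.get_ylim()[1] * 0.9), ha="left", fontsize=10)
    ax.set_xlabel("resource endowment $E$")
    ax.set_ylabel("fitness")
    ax.legend(loc="upper left", fontsize=8)
    fig.tight_layout()
    return fig


def prevalence_figure(table: pd.DataFrame):
    """Cumulative twin-maternity probability vs pregnancy count, one curve per x."""
    fig, ax = plt.subplots(figsize=(6, 4))
    for x, sub in table.groupby("x"):
        ax.plot(sub["P"], sub["T"], marker="o", ms=3, label=f"x = {x:g}")
        final = sub.iloc[-1]
        ax.axhline(final["T"], ls="--", lw=0.8, color="grey")
    ax.set_xlabel("number of successful pregnancies $P$")
    ax.set_ylabel("probability of becoming a mother of twins $T$")
    ax.set_ylim(0, 1)
    ax.legend()
    fig.tight_layout()
    return fig
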