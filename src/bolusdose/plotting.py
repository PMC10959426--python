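"""Publication-style scenario plots: solid water PDD, dashed RD curves."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt

from .analysis import PDDCurve, RDProfile

__all__ = ["plot_scenario"]


def plot_scenario(water_pdd: PDDCurve, rd_profiles: dict[str, "RDProfile"],
                  interfaces: dict | None = None, title: str = "",
                  ax: "plt.Axes | None" = None) -> "plt.Axes":
    """Water PDD (solid, left axis) with RD curves (dashed, right axis).

    ``interfaces`` may carry ``skin_surface`` and ``lung_top`` depths; the
    lung region is shaded and the skin boundary marked, mirroring the usual
    presentation of layered-phantom depth-dose comparisons.
    """
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4.5))
    ax.plot(water_pdd.depths, water_pdd.pdd, "k-", label="water PDD")
    ax.set_xlabel("depth from bolus top (cm)")
    ax.set_ylabel("PDD (%)")
    ax2 = ax.twinx()
    for material, prof in sorted(rd_profiles.items()):
        ax2.plot(prof.depths, prof.rd, "--", label=f"RD {material}")
    ax2.set_ylabel("RD (%)")
    ax2.axhline(100.0, color="0.7", lw=0.5)
    if interfaces:
        if "skin_surface" in interfaces:
            ax.axvline(interfaces["skin_surface"], color="0.5", ls=":",
                       label="skin surface")
        if "lung_top" in interfaces:
            ax.axvspan(interfaces["lung_top"], water_pdd.depths[-1],
                       color="0.9", label="lung")
    handles1, labels1 = ax.get_legend_handles_labels()
    handles2, labels2 = ax2.get_legend_handles_labels()
    ax.legend(handles1 + handles2, labels1 + labels2, fontsize=8, loc="upper right")
    if title:
        ax.set_title(title)
    return ax
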