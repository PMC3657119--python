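"""Optional figures: lamp spectra over pigment curves, and class summaries."""

from __future__ import annotations

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .pigments import default_grid, template_absorbance

_LAMP_COLORS = {"LPS": "#e08214", "HPS": "#d94801", "LED": "#4393c3", "MH": "#762a83"}


def plot_spectra_with_pigments(lamp_spectra, lambda_maxes, path):
    """One panel per lamp: emission spectrum (filled) with normalized pigment
    absorbance curves overlaid, the visual comparison behind the overlap
    index."""
    grid = default_grid()
    fig, axes = plt.subplots(len(lamp_spectra), 1, figsize=(7, 2.4 * len(lamp_spectra)),
                             sharex=True)
    axes = np.atleast_1d(axes)
    for ax, lamp in zip(axes, lamp_spectra):
        irr = lamp.irradiance / lamp.irradiance.max()
        ax.fill_between(lamp.grid, irr, color=_LAMP_COLORS.get(lamp.lamp_type, "grey"),
                        alpha=0.4, label=lamp.lamp_type)
        for lmax in lambda_maxes:
            curve = template_absorbance(lmax, grid)
            ax.plot(curve.grid, curve.values, "k-", lw=0.8)
        ax.axhline(0.5, ls="--", color="grey", lw=0.7)
        ax.set_ylabel("relative")
        ax.legend(loc="upper right", frameon=False)
    axes[-1].set_xlabel("wavelength (nm)")
    axes[-1].set_xlim(300, 750)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_class_summary(result, path):
    """Two panels: (a) class visual ranges (mean min/max with CIs),
    (b) mean percent of range stimulated per class and lamp with CIs."""
    fig, (ax1, ax2) = plt.subplots(2, 1, figsize=(8, 8))

    cvr = result.class_visual_ranges
    ypos = np.arange(len(cvr))
    for y, (_, row) in zip(ypos, cvr.iterrows()):
        ax1.plot([row["mean_min"], row["mean_max"]], [y, y], "-", color="grey", lw=2)
        ax1.errorbar(row["mean_min"], y,
                     xerr=[[row["mean_min"] - row["ci_low_min"]],
                           [row["ci_high_min"] - row["mean_min"]]],
                     fmt="o", color="k", capsize=3)
        ax1.errorbar(row["mean_max"], y,
                     xerr=[[row["mean_max"] - row["ci_low_max"]],
                           [row["ci_high_max"] - row["mean_max"]]],
                     fmt="o", color="k", capsize=3)
    ax1.set_yticks(ypos, cvr["level"])
    ax1.set_xlabel("wavelength (nm)")
    ax1.set_title("half-maximum sensitivity range by class")

    gm = result.group_means_percent.copy()
    gm[["class", "lamp"]] = gm["level"].str.split(" x ", expand=True)
    classes = sorted(gm["class"].unique())
    lamp_order = [lt for lt in ("LPS", "HPS", "LED", "MH")
                  if lt in set(gm["lamp"])] or sorted(gm["lamp"].unique())
    width = 0.8 / len(lamp_order)
    for j, lamp in enumerate(lamp_order):
        sub = gm[gm["lamp"] == lamp].set_index("class").reindex(classes)
        x = np.arange(len(classes)) + (j - (len(lamp_order) - 1) / 2) * width
        ax2.bar(x, sub["mean"], width=width * 0.9,
                color=_LAMP_COLORS.get(lamp, "grey"), label=lamp)
        ax2.errorbar(x, sub["mean"],
                     yerr=[sub["mean"] - sub["ci_low"], sub["ci_high"] - sub["mean"]],
                     fmt="none", ecolor="k", capsize=2)
    ax2.set_xticks(np.arange(len(classes)), classes)
    ax2.set_ylabel("% of visual range stimulated")
    ax2.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
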