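"""Diagnostic plots."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .association import EgwasResult


def qq_plot(result: EgwasResult, path=None, ax=None):
    """Observed vs expected -log10 p quantile-quantile plot for one analysis.

    Points above the identity line indicate an excess of small p-values;
    the genomic-control lambda is printed in the corner.
    """
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    ax.scatter(result.qq["expected"], result.qq["observed"], s=6, alpha=0.6,
               edgecolors="none")
    lim = max(result.qq["expected"].max(), result.qq["observed"].max()) * 1.05
    ax.plot([0, lim], [0, lim], color="grey", lw=1)
    ax.set_xlabel("expected $-\\log_{10} p$")
    ax.set_ylabel("observed $-\\log_{10} p$")
    ax.set_title(f"{result.tissue} / {result.cohort}")
    ax.text(0.05, 0.95, f"$\\lambda$ = {result.lambda_gc:.3f}",
            transform=ax.transAxes, va="top")
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
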