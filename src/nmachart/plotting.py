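"""Optional chart rendering (kept separate so headless use never imports it)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .io import RunReport

__all__ = ["plot_report"]


def plot_report(report: RunReport, path) -> None:
    """Draw both endpoint MA series with their control limits to a PNG."""
    table = report.table
    fig, axes = plt.subplots(1, 2, figsize=(11, 4), sharex=True)
    for ax, side in zip(axes, ("lower", "upper")):
        ax.plot(table["sr"], table[f"ma_{side}"], marker="o", lw=1, label="MA")
        for lim, style in ((f"lcl_{side}", "--"), (f"ucl_{side}", "--")):
            ax.axhline(table[lim].iloc[0], color="red", ls=style, lw=1)
        out = table[f"flag_{side}"] == "out"
        if out.any():
            ax.plot(
                table.loc[out, "sr"], table.loc[out, f"ma_{side}"], "rx", ms=9,
                label="signal",
            )
        ax.set_title(f"{side} endpoint")
        ax.set_xlabel("subgroup")
        ax.legend(loc="best", fontsize=8)
    axes[0].set_ylabel("moving average (transformed units)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
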