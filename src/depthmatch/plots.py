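"""Optional plotting of matching results (requires matplotlib)."""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .model import ABSENT

_CONDITION_ORDER = ["opaque", "semi_transparent", "highly_transparent", ABSENT]


def plot_matches(summaries: pd.DataFrame, path: str | Path, surface_distance: float = 1.2):
    """Mean matched vs. target distance per condition, with CI error bars."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for cond in [c for c in _CONDITION_ORDER if c in set(summaries["condition"])]:
        grp = summaries[summaries["condition"] == cond]
        ax.errorbar(
            grp["target_distance_m"], grp["mean_matched_m"], yerr=grp["ci_halfwidth_m"],
            marker="o", capsize=2, label=cond,
        )
    lims = (summaries["target_distance_m"].min(), summaries["target_distance_m"].max())
    ax.plot(lims, lims, "k--", lw=1, label="veridical")
    ax.axvline(surface_distance, color="0.7", lw=4, alpha=0.5, zorder=0)
    ax.set_xlabel("target distance (m)")
    ax.set_ylabel("mean matched distance (m)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def plot_signed_differences(differences: pd.DataFrame, path: str | Path, surface_distance: float = 1.2):
    """Baseline-minus-condition match difference per distance and condition."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for cond in [c for c in _CONDITION_ORDER if c in set(differences["condition"])]:
        grp = differences[differences["condition"] == cond]
        ax.plot(grp["target_distance_m"], grp["difference_m"], marker="o", label=cond)
    ax.axhline(0.0, color="k", lw=1, ls="--")
    ax.axvline(surface_distance, color="0.7", lw=4, alpha=0.5, zorder=0)
    ax.set_xlabel("target distance (m)")
    ax.set_ylabel("absent minus condition match (m)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
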