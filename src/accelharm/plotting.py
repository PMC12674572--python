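"""Static figures: between-person boxplots and pairwise scatterplots."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .pipeline import CATEGORIES, cohort_wide
from .signal_core import LOCATIONS


def plot_between_person_boxplots(participant_means, metric: str, path) -> Path:
    """Boxplots of participant means per activity, grouped by location.

    Shorter boxes indicate smaller between-person variance.
    """
    data = participant_means[participant_means["metric"] == metric]
    fig, axes = plt.subplots(
        1, len(LOCATIONS), figsize=(3.2 * len(LOCATIONS), 4), sharey=True
    )
    for ax, loc in zip(axes, LOCATIONS):
        sub = data[data["location"] == loc]
        groups = [
            sub.loc[sub["category"] == cat, "participant_mean"].to_numpy()
            for cat in CATEGORIES
        ]
        ax.boxplot([g for g in groups if len(g)] or [[]])
        ax.set_xticklabels(
            [c for c, g in zip(CATEGORIES, groups) if len(g)],
            rotation=60, ha="right", fontsize=7,
        )
        ax.set_title(loc, fontsize=9)
    axes[0].set_ylabel(f"participant mean ({metric})")
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def plot_pair_scatter(cohort, label_x: str, label_y: str, path) -> Path:
    """Second-level scatter of one series pair, coloured by activity category."""
    wide = cohort_wide(cohort)
    cats = (
        cohort.drop_duplicates(["participant", "condition", "second"])
        .set_index(["participant", "condition", "second"])["category"]
        .reindex(wide.index)
    )
    fig, ax = plt.subplots(figsize=(5, 5))
    for cat in CATEGORIES:
        mask = (cats == cat).to_numpy()
        if mask.any():
            ax.scatter(
                wide.loc[mask, label_x], wide.loc[mask, label_y],
                s=4, alpha=0.4, label=cat,
            )
    ax.set_xlabel(label_x)
    ax.set_ylabel(label_y)
    ax.legend(fontsize=7, markerscale=2)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
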