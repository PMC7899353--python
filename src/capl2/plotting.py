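"""Interpretation-grouped bar plots of domain scores."""

from __future__ import annotations

import logging
from typing import Sequence

import matplotlib

matplotlib.use("Agg", force=False)

import matplotlib.pyplot as plt
import numpy as np

from ._missing import is_missing
from .model import CATEGORIES

__all__ = ["bar_plot", "DEFAULT_COLORS"]

logger = logging.getLogger(__name__)

DEFAULT_COLORS: tuple[str, str, str, str] = ("#a6cee3", "#1f78b4", "#b2df8a", "#33a02c")


def bar_plot(
    scores: Sequence,
    interpretations: Sequence,
    x_label: str,
    y_label: str,
    colors: Sequence[str] | None = None,
):
    """Bar plot of mean score per interpretive category.

    One bar per category in ascending category order; rows with a missing
    score or interpretation are excluded from the means, and each bar is
    annotated with its mean.  ``colors``, when given, must hold exactly four
    colour values.
    """
    if len(scores) != len(interpretations):
        raise ValueError("scores and interpretations must be aligned")
    if colors is None:
        colors = DEFAULT_COLORS
    elif len(colors) != 4:
        raise ValueError(f"colors must hold exactly 4 values, got {len(colors)}")

    grouped: dict[str, list[float]] = {category: [] for category in CATEGORIES}
    for score, interpretation in zip(scores, interpretations):
        if is_missing(score) or is_missing(interpretation):
            continue
        if interpretation in grouped:
            grouped[interpretation].append(float(score))

    if not any(grouped.values()):
        logger.warning("all interpretations missing; rendering an empty plot")

    fig, ax = plt.subplots(figsize=(7, 5))
    positions = np.arange(len(CATEGORIES))
    means = [float(np.mean(grouped[c])) if grouped[c] else 0.0 for c in CATEGORIES]
    bars = ax.bar(positions, means, color=list(colors))
    for bar, category, mean in zip(bars, CATEGORIES, means):
        if grouped[category]:
            ax.annotate(
                f"{mean:.1f}",
                (bar.get_x() + bar.get_width() / 2, bar.get_height()),
                ha="center",
                va="bottom",
            )
    ax.set_xticks(positions)
    ax.set_xticklabels(CATEGORIES)
    ax.set_xlabel(x_label)
    ax.set_ylabel(y_label)
    fig.tight_layout()
    return fig
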