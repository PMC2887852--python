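"""Boxplot-style figures of per-patient native-vs-graft differences."""

from __future__ import annotations

from pathlib import Path
from typing import Sequence, Union

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

__all__ = ["boxplot_deltas", "boxplot_beat_delay"]

_LABELS = {
    "d_rel_upslope": "Δ relative upslope (%)",
    "d_rel_si_max": "Δ relative SImax (%)",
    "d_t50": "Δ T_SI50%max (s)",
    "d_tmax": "Δ T_SImax (s)",
    "beat_delay": "time-to-peak delay (beats)",
    "addup_score": "add-up score",
}


def _class_frames(comparisons: pd.DataFrame):
    yield "all CABG", comparisons
    yield "LIMA", comparisons[comparisons.graft_kind == "lima_graft"]
    yield "venous", comparisons[comparisons.graft_kind == "venous_graft"]


def boxplot_deltas(
    comparisons: pd.DataFrame,
    columns: Sequence[str] = ("d_rel_upslope", "d_rel_si_max", "d_t50", "d_tmax"),
    path: Union[str, Path, None] = None,
):
    """Boxplots of signed graft-minus-native differences per graft class.

    Negative values mean the graft territory enhances less or later than the
    native reference of the same patient.
    """
    fig, axes = plt.subplots(1, len(columns), figsize=(3.2 * len(columns), 3.4))
    for ax, col in zip(axes if len(columns) > 1 else [axes], columns):
        labels, data = [], []
        for name, sub in _class_frames(comparisons):
            if len(sub):
                labels.append(f"{name}\n(n={len(sub)})")
                data.append(sub[col].to_numpy())
        ax.boxplot(data, tick_labels=labels)
        ax.axhline(0.0, color="grey", lw=0.8, ls="--")
        ax.set_ylabel(_LABELS.get(col, col))
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig


def boxplot_beat_delay(comparisons: pd.DataFrame, path: Union[str, Path, None] = None):
    """Boxplot of the graft-minus-native time-to-peak delay in heart beats."""
    fig, ax = plt.subplots(figsize=(4.2, 3.4))
    labels, data = [], []
    for name, sub in _class_frames(comparisons):
        if len(sub):
            labels.append(f"{name}\n(n={len(sub)})")
            data.append(sub["beat_delay"].to_numpy())
    ax.boxplot(data, tick_labels=labels)
    ax.axhline(0.0, color="grey", lw=0.8, ls="--")
    ax.set_ylabel(_LABELS["beat_delay"])
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
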