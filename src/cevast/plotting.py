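"""Severity-curve figures: fitted severity vs normalized SI position."""

from __future__ import annotations

import warnings
from pathlib import Path

import matplotlib

matplotlib.use("Agg", force=False)
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

__all__ = ["plot_patient_curves", "plot_all_patients"]


def plot_patient_curves(curves: pd.DataFrame, patient_id: str, ax=None):
    """One patient's curves (all raters) with error bands, axes 0-1 / 0-3.

    Missing grid points are rendered as gaps, never interpolated across.
    """
    sub = curves[curves.patient_id == patient_id]
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 3.2))
    for rater, grp in sub.groupby("rater"):
        grp = grp.sort_values("position")
        p = grp["position"].to_numpy()
        v = grp["value"].to_numpy()
        e = grp["stderr"].to_numpy()
        ax.plot(p, v, label=str(rater), lw=1.5)
        ax.fill_between(p, v - e, v + e, alpha=0.15)
    ax.set_xlim(0, 1)
    ax.set_ylim(0, 3)
    ax.set_xlabel("normalized SI position (0 = pylorus, 1 = cecum)")
    ax.set_ylabel("celiac severity (0-3)")
    ax.set_title(f"patient {patient_id}")
    ax.legend(fontsize=7)
    return ax


def plot_all_patients(curves: pd.DataFrame, out_dir) -> list[Path]:
    """Write one figure per patient; returns the written paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    if len(curves) == 0:
        warnings.warn("no curves to plot")
        return paths
    for pid in curves["patient_id"].unique():
        ax = plot_patient_curves(curves, pid)
        path = out_dir / f"curves_{pid}.png"
        ax.figure.savefig(path, dpi=110, bbox_inches="tight")
        plt.close(ax.figure)
        paths.append(path)
    return paths
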