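"""Report figures: dose trends, slope-collagen scatter, ROC curves."""

from __future__ import annotations

from pathlib import Path
from typing import Dict

import numpy as np
import pandas as pd

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

_TREND_VARS = ["cc_ibs", "mcv", "lvef_pct", "sf_pct"]


def _ensure_dir(path: Path) -> Path:
    path.parent.mkdir(parents=True, exist_ok=True)
    return path


def dose_trends(summary: pd.DataFrame, path: str | Path) -> None:
    """Mean ± SD of each index across cumulative dose groups."""
    path = _ensure_dir(Path(path))
    vars_present = [v for v in _TREND_VARS if (summary["variable"] == v).any()]
    fig, axes = plt.subplots(2, 2, figsize=(9, 7), constrained_layout=True)
    for ax, var in zip(axes.flat, vars_present):
        sub = summary[summary["variable"] == var].sort_values("dose_mg_per_kg")
        ax.errorbar(
            sub["dose_mg_per_kg"], sub["mean"], yerr=sub["sd"], marker="o", capsize=3
        )
        ax.set_xlabel("cumulative dose (mg/kg)")
        ax.set_title(var)
    for ax in axes.flat[len(vars_present):]:
        ax.set_visible(False)
    fig.savefig(path, dpi=110)
    plt.close(fig)


def beta_collagen_scatter(
    betas: pd.DataFrame, hearts: pd.DataFrame, path: str | Path
) -> None:
    """Per-animal dose slopes against terminal collagen content."""
    path = _ensure_dir(Path(path))
    fig, axes = plt.subplots(2, 2, figsize=(9, 7), constrained_layout=True)
    for ax, var in zip(axes.flat, _TREND_VARS):
        sub = betas[betas["variable"] == var].set_index("animal_id")["slope"]
        joined = hearts.join(sub, on="animal_id").dropna(subset=["slope"])
        ax.scatter(joined["heart_pct"], joined["slope"], s=18)
        ax.set_xlabel("collagen (%)")
        ax.set_ylabel(f"beta({var}) per mg/kg")
    fig.savefig(path, dpi=110)
    plt.close(fig)


def _roc_points(scores: np.ndarray, labels: np.ndarray):
    order = np.argsort(-scores, kind="stable")
    labels = labels[order]
    tps = np.concatenate([[0], np.cumsum(labels)])
    fps = np.concatenate([[0], np.cumsum(~labels)])
    return fps / max(fps[-1], 1), tps / max(tps[-1], 1)


def roc_curves(
    records: pd.DataFrame, collagen: pd.DataFrame, report: Dict, path: str | Path
) -> None:
    """ROC curves for each marker against the collagen-derived disease label."""
    from .pipeline import MARKER_ORIENTATION, _last_observed

    if not report.get("threshold"):
        return
    path = _ensure_dir(Path(path))
    thr = report["threshold"]["threshold"]
    hearts = collagen.drop_duplicates("animal_id")
    fig, ax = plt.subplots(figsize=(6, 6), constrained_layout=True)
    for var, res in report["roc"].items():
        svals = _last_observed(records, var).rename("score")
        joined = hearts.join(svals, on="animal_id").dropna(subset=["score"])
        labels = (joined["heart_pct"] > thr).to_numpy()
        scores = MARKER_ORIENTATION[var] * joined["score"].to_numpy()
        fpr, tpr = _roc_points(scores, labels)
        ax.plot(fpr, tpr, label=f"{var} (AUC={res['auc']:.2f})")
    ax.plot([0, 1], [0, 1], "k--", lw=0.8)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.legend()
    fig.savefig(path, dpi=110)
    plt.close(fig)
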