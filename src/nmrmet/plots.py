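"""Score and loading plots.

Conventions: predictive scores on the horizontal axis, first orthogonal (or
second) component vertical; loading heights are the bucket/response
covariance, colored by the Pearson correlation R.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import matplotlib

matplotlib.use("Agg")
matplotlib.rcParams["svg.hashsalt"] = "nmrmet"  # deterministic SVG output
import matplotlib.pyplot as plt
import numpy as np

from .multivariate import LatentModel, LoadingProfile

__all__ = ["score_plot", "loading_plot"]


def score_plot(
    model: LatentModel,
    labels: Sequence[str],
    path: str | Path,
    title: str = "",
) -> None:
    t1 = model.T_pred[:, 0]
    if model.kind == "opls" and model.T_orth is not None and model.T_orth.shape[1] > 0:
        t2 = model.T_orth[:, 0]
        ylab = "T_orth[1]"
    elif model.T_pred.shape[1] > 1:
        t2 = model.T_pred[:, 1]
        ylab = "component 2"
    else:
        t2 = np.zeros_like(t1)
        ylab = ""
    fig, ax = plt.subplots(figsize=(5, 4))
    for group in dict.fromkeys(labels):
        mask = np.array([l == group for l in labels])
        ax.scatter(t1[mask], t2[mask], label=group, s=30)
    ax.axhline(0, color="gray", lw=0.5)
    ax.axvline(0, color="gray", lw=0.5)
    ax.set_xlabel("T_pred" if model.kind == "opls" else "component 1")
    ax.set_ylabel(ylab)
    ax.legend(fontsize=8)
    if title:
        ax.set_title(title, fontsize=10)
    fig.tight_layout()
    _save(fig, path)


def loading_plot(profile: LoadingProfile, path: str | Path, title: str = "") -> None:
    fig, ax = plt.subplots(figsize=(8, 3.5))
    points = ax.scatter(
        profile.bucket_centers,
        profile.covariance,
        c=profile.R,
        cmap="coolwarm",
        vmin=-1,
        vmax=1,
        s=4,
    )
    ax.invert_xaxis()  # NMR convention: ppm decreasing left to right
    ax.set_xlabel("ppm")
    ax.set_ylabel("covariance with response")
    fig.colorbar(points, ax=ax, label="R")
    if title:
        ax.set_title(title, fontsize=10)
    fig.tight_layout()
    _save(fig, path)


def _save(fig, path) -> None:
    path = Path(path)
    metadata = {"Date": None} if path.suffix == ".svg" else None
    fig.savefig(path, metadata=metadata)
    plt.close(fig)
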