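"""Figure rendering for pipeline reports.

Conventions: CD_A heat maps use a diverging red/blue colormap with red for
positive (downward, away from the probe) motion; layer-profile panels plot
the 10-layer mean CD_A from the epicardial to the endocardial layer with
the fitted TMI line overlaid.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import TYPE_CHECKING

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    from .pipeline import RunReport

logger = logging.getLogger("cardiomotion")


def render_figures(report: "RunReport", outdir: str | Path) -> dict[str, str]:
    """Write CD_A heat map and per-segment layer-profile figures as PNG."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}

    # --- CD_A heat map -----------------------------------------------------
    cda = report.cda
    masked = np.where(report.segmentation.myocardium_mask, cda.values, np.nan)
    vmax = np.nanmax(np.abs(masked)) or 1.0
    frame = report.frames[0]
    extent = (
        frame.lateral_positions_mm[0],
        frame.lateral_positions_mm[-1],
        frame.axial_positions_mm[-1],
        frame.axial_positions_mm[0],
    )
    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(masked, cmap="RdBu_r", vmin=-vmax, vmax=vmax, extent=extent, aspect="auto")
    ax.set_xlabel("lateral (mm)")
    ax.set_ylabel("depth (mm)")
    ax.set_title("Cumulative axial displacement CD$_A$ (red = downward)")
    fig.colorbar(im, ax=ax, label="CD$_A$ (mm)")
    p = outdir / "cda_heatmap.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    paths["fig_cda"] = str(p)

    # --- 10-layer profiles with fitted TMI line ---------------------------
    table = report.segment_table
    if table.empty or "layer_1" not in table.columns:
        logger.warning("segment table lacks layer profiles; skipping profile figure")
        return paths
    layer_cols = [f"layer_{k}" for k in range(1, 11)]
    n_idx = np.arange(1, 11)
    fig, axes = plt.subplots(2, 3, figsize=(11, 6), sharex=True)
    for ax, (_, row) in zip(axes.ravel(), table.iterrows()):
        prof = row[layer_cols].to_numpy(dtype=float)
        ax.plot(n_idx, prof, "o-", ms=4, label="layer mean CD$_A$")
        fit = row["intercept_mm"] + row["tmi_mm_per_layer"] * n_idx
        ax.plot(n_idx, fit, "--", label=f"TMI = {row['tmi_mm_per_layer']:.4f} mm/layer")
        ax.set_title(row["segment"], fontsize=10)
        ax.legend(fontsize=7)
    for ax in axes[-1]:
        ax.set_xlabel("layer (EpiL $\\rightarrow$ EndoL)")
    for ax in axes[:, 0]:
        ax.set_ylabel("CD$_A$ (mm)")
    fig.tight_layout()
    p = outdir / "layer_profiles.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    paths["fig_profiles"] = str(p)
    return paths
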