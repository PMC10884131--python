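"""Bullseye polar maps and joint-histogram figures.

Figures are always regenerated from serialized tables (CSV), never from
in-memory state, so every plot in a report bundle is auditable.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from matplotlib.patches import Circle, Wedge

from .metrics import log_display
from .segment17 import N_SEGMENTS

# (ring radius inner/outer, sector span deg, first-segment centre angle)
_RING_LAYOUT = {
    "basal": (0.75, 1.0, 60, range(1, 7)),
    "mid": (0.5, 0.75, 60, range(7, 13)),
    "apical": (0.25, 0.5, 90, range(13, 17)),
}


def bullseye(
    values: np.ndarray,
    ax=None,
    cmap: str = "RdYlBu_r",
    vmin: float | None = None,
    vmax: float | None = None,
    annotate: bool = True,
    fmt: str = "{:.1f}",
):
    """Draw the 17-segment bullseye.

    Matplotlib angles are measured counter-clockwise from the +x axis; the
    package's angular convention puts segment 1 (anterior) at the top, so
    the sector centred on package-angle a sits at display angle 90 + a.
    """
    values = np.asarray(values, dtype=float)
    if values.shape != (N_SEGMENTS,):
        raise ValueError("expected 17 values")
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    vmin = float(values.min()) if vmin is None else vmin
    vmax = float(values.max()) if vmax is None else vmax
    span = vmax - vmin or 1.0
    cm = plt.get_cmap(cmap)

    def color(v):
        return cm((v - vmin) / span)

    for ring, (r0, r1, width, segs) in _RING_LAYOUT.items():
        for k, seg in enumerate(segs):
            centre = 90 + k * width  # display degrees
            w = Wedge(
                (0, 0), r1, centre - width / 2, centre + width / 2,
                width=r1 - r0, facecolor=color(values[seg - 1]),
                edgecolor="k", linewidth=0.8,
            )
            ax.add_patch(w)
            if annotate:
                mid = np.deg2rad(centre)
                rr = (r0 + r1) / 2
                ax.text(
                    rr * np.cos(mid), rr * np.sin(mid),
                    fmt.format(values[seg - 1]),
                    ha="center", va="center", fontsize=7,
                )
    apex = Circle((0, 0), 0.25, facecolor=color(values[16]), edgecolor="k", linewidth=0.8)
    ax.add_patch(apex)
    if annotate:
        ax.text(0, 0, fmt.format(values[16]), ha="center", va="center", fontsize=7)
    ax.set_xlim(-1.05, 1.05)
    ax.set_ylim(-1.05, 1.05)
    ax.set_aspect("equal")
    ax.axis("off")
    return ax


def bullseye_from_csv(
    csv_path: str | Path, out_png: str | Path, value_column: str = "value", **kwargs
) -> None:
    df = pd.read_csv(csv_path)
    values = (
        df.sort_values("segment")[value_column].to_numpy()
        if "segment" in df.columns
        else df[value_column].to_numpy()
    )
    fig, ax = plt.subplots(figsize=(5, 5))
    bullseye(values, ax=ax, **kwargs)
    fig.savefig(out_png, dpi=120, bbox_inches="tight")
    plt.close(fig)


def joint_histogram_png(
    counts_csv: str | Path, out_png: str | Path, title: str = ""
) -> None:
    """Render a log10-scaled joint histogram from its CSV of raw counts."""
    counts = np.loadtxt(counts_csv, delimiter=",")
    fig, ax = plt.subplots(figsize=(5, 4))
    im = ax.imshow(
        log_display(counts).T, origin="lower", extent=[0, 100, 0, 100],
        aspect="equal", cmap="viridis",
    )
    fig.colorbar(im, ax=ax, label="log10(count + 1)")
    ax.set_xlabel("reference voxel value")
    ax.set_ylabel("test voxel value")
    if title:
        ax.set_title(title)
    fig.savefig(out_png, dpi=120, bbox_inches="tight")
    plt.close(fig)
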