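"""Overlay and density-map rendering (matplotlib, Agg backend)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.patches as mpatches
import matplotlib.pyplot as plt
import numpy as np

from .detect import CLASS_LONG_SPARK, CLASS_MINIWAVE, CLASS_SPARK, CLASS_WAVE

CLASS_COLORS = {
    CLASS_SPARK: "lime",
    CLASS_LONG_SPARK: "orange",
    CLASS_MINIWAVE: "cyan",
    CLASS_WAVE: "blue",
}


def render_overlay(image, events, path) -> None:
    """Save the image with class-coloured bounding boxes (space horizontal,
    time downward)."""
    fig, ax = plt.subplots(figsize=(8, 10))
    ax.imshow(image.pixels, cmap="gray", aspect="auto", interpolation="nearest")
    dt, dx = image.time_step, image.pixel_size
    for ev in events:
        t0, t1, x0, x1 = ev.bbox
        rect = mpatches.Rectangle(
            (x0 / dx - 0.5, t0 / dt - 0.5),
            (x1 - x0) / dx,
            (t1 - t0) / dt,
            fill=False,
            edgecolor=CLASS_COLORS.get(ev.event_class, "red"),
            linewidth=1.0,
        )
        ax.add_patch(rect)
    ax.set_xlabel("space (px)")
    ax.set_ylabel("time (lines)")
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)


def render_latency_map(lat_ms: np.ndarray, valid: np.ndarray, path) -> None:
    """Save the spark-latency density map; invalid pixels are masked out."""
    fig, ax = plt.subplots(figsize=(8, 10))
    shown = np.ma.masked_where(~valid, lat_ms)
    im = ax.imshow(shown, cmap="inferno", aspect="auto", interpolation="nearest")
    fig.colorbar(im, ax=ax, label="time since preceding event (ms)")
    ax.set_xlabel("space (px)")
    ax.set_ylabel("time (lines)")
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
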