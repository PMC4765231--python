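"""Raster rendering of property maps and GIF assembly.

Each frame is drawn as a point cloud on fixed axes spanning the full Miller
extent (longitude ±180°, ordinate ±131.96°-equivalent) so all frames of an
animation share the same canvas and are directly comparable. Colours come
from a continuous two-colour gradient over a value range that defaults to
the field's min/max; animations normally pass a shared range across frames
so colours mean the same thing in every frame.

Output is deterministic: identical input and configuration produce
byte-identical files (no timestamps are embedded), which is what makes the
parallel-rendering contract testable by digest comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
from matplotlib.colors import LinearSegmentedColormap
from PIL import Image

from .errors import MolcartoError
from .projection import MILLER_Y_MAX
from .smoothing import PropertyField

__all__ = ["RenderConfig", "render_frame", "assemble_animation"]

_RAD2DEG = 180.0 / np.pi


@dataclass
class RenderConfig:
    """Appearance and output options for frames and animations."""

    colour_low: str = "#ffffcc"
    colour_high: str = "#800026"
    background: str = "white"
    show_frame_id: bool = False
    dpi: int = 100
    value_range: tuple[float, float] | None = None
    delay_ms: int = 100
    output_format: str = "tiff"
    point_size: float = 6.0

    def __post_init__(self) -> None:
        if self.delay_ms < 0:
            raise ValueError("delay_ms must be >= 0")
        if self.dpi <= 0:
            raise ValueError("dpi must be positive")

    def colormap(self) -> LinearSegmentedColormap:
        return LinearSegmentedColormap.from_list(
            "molcarto", [self.colour_low, self.colour_high]
        )


def render_frame(
    field: PropertyField,
    cfg: RenderConfig,
    out: str | Path,
    frame_id: str | None = None,
) -> Path:
    """Write one map figure; returns the output path.

    Points are plotted at (x·180/π, y·180/π). The value range defaults to
    the field's own min/max; pass ``cfg.value_range`` to pin it (required
    for comparable animation frames).
    """
    if len(field) == 0:
        raise MolcartoError("cannot render an empty field")
    out = Path(out)
    vmin, vmax = cfg.value_range if cfg.value_range is not None else (
        float(field.values.min()), float(field.values.max()))
    if vmin == vmax:  # constant field: centre it in the gradient
        vmin, vmax = vmin - 0.5, vmax + 0.5

    y_extent = MILLER_Y_MAX * _RAD2DEG
    fig, ax = plt.subplots(figsize=(8, 5), dpi=cfg.dpi)
    fig.patch.set_facecolor(cfg.background)
    ax.set_facecolor(cfg.background)
    ax.scatter(
        field.x * _RAD2DEG,
        field.y * _RAD2DEG,
        c=field.values,
        cmap=cfg.colormap(),
        vmin=vmin,
        vmax=vmax,
        s=cfg.point_size,
        marker="s",
        linewidths=0,
        antialiased=False,
        rasterized=True,
    )
    ax.set_xlim(-180.0, 180.0)
    ax.set_ylim(-y_extent, y_extent)
    ax.set_xlabel("longitude (°)")
    ax.set_ylabel("Miller ordinate (°-equivalent)")
    title = field.descriptor_name or "property"
    if cfg.show_frame_id and frame_id:
        title = f"{title} — {frame_id}"
    ax.set_title(title)
    try:
        fig.savefig(
            out,
            format=cfg.output_format if out.suffix == "" else None,
            dpi=cfg.dpi,
            facecolor=cfg.background,
        )
    except OSError as exc:
        raise MolcartoError(f"cannot write figure to {out}: {exc}") from exc
    finally:
        plt.close(fig)
    return out


def assemble_animation(
    frame_files: list[str | Path],
    cfg: RenderConfig,
    out: str | Path,
) -> Path:
    """Assemble rendered frames (in the given order) into a looping GIF.

    Consecutive frames with identical pixels are coalesced by the GIF
    encoder, with their delays summed, so the total animation time is
    preserved; frames of a real series rendered with a shared value range
    are normally all distinct.
    """
    if not frame_files:
        raise MolcartoError("no frames to assemble")
    images = [Image.open(p).convert("RGB") for p in frame_files]
    sizes = {im.size for im in images}
    if len(sizes) != 1:
        raise MolcartoError(f"frame dimension mismatch: {sorted(sizes)}")
    out = Path(out)
    palettized = [im.quantize(colors=256, dither=Image.Dither.NONE) for im in images]
    palettized[0].save(
        out,
        save_all=True,
        append_images=palettized[1:],
        duration=cfg.delay_ms,
        loop=0,
    )
    for im in images:
        im.close()
    return out
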