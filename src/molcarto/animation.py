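"""Multi-frame orchestration with whole-frame parallelism.

A series of pre-superposed PDB frames is turned into one map figure per
frame plus a looping GIF. Parallelism distributes *whole frames* across a
worker pool (one frame, one task); because every frame's output depends
only on its input file and the shared configuration — never on worker
assignment or completion order — the assembled GIF is byte-identical
regardless of the number of workers.

Colour normalization is global by default: the value range is the min/max
over all frames' smoothed values (or the user override), so colours are
comparable between frames. A per-frame mode exists for exploratory use.
"""

from __future__ import annotations

import multiprocessing
from dataclasses import replace
from pathlib import Path

from .errors import FrameSeriesError, MolcartoError, StageError
from .pipeline import FrameOptions, FrameResult, run_frame
from .properties import DescriptorRegistry, default_registry
from .rendering import RenderConfig, assemble_animation, render_frame

__all__ = ["render_series"]


def _compute_one(args) -> FrameResult:
    path, descriptor, registry, options = args
    return run_frame(path, descriptor, registry, options)


def _render_one(args) -> Path:
    frame_result, cfg, out_path = args
    return render_frame(frame_result.field, cfg, out_path, frame_result.source_id)


def _map(tasks, fn, cores: int):
    if cores <= 1 or len(tasks) <= 1:
        return [fn(t) for t in tasks]
    ctx = multiprocessing.get_context()
    with ctx.Pool(processes=min(cores, len(tasks))) as pool:
        return pool.map(fn, tasks)


def render_series(
    frame_paths: list[Path],
    descriptor: str,
    outdir: str | Path,
    registry: DescriptorRegistry | None = None,
    options: FrameOptions | None = None,
    cfg: RenderConfig | None = None,
    cores: int = 1,
    keep_frames: bool = True,
    per_frame_scaling: bool = False,
    gif_name: str = "animation.gif",
) -> tuple[Path, list[FrameResult]]:
    """Render every frame and assemble the GIF; returns (gif path, results).

    Frames are processed in the given order; ``cores`` workers handle whole
    frames. On any frame failure the run aborts naming the frame, and
    partially rendered figures are removed unless ``keep_frames``.
    """
    if not frame_paths:
        raise FrameSeriesError("no input frames")
    if cores < 1:
        raise ValueError("cores must be >= 1")
    registry = registry if registry is not None else default_registry()
    options = options or FrameOptions()
    cfg = cfg or RenderConfig()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    suffix = {"tiff": ".tif", "png": ".png"}.get(cfg.output_format, ".tif")
    frame_files = [outdir / f"{Path(p).stem}{suffix}" for p in frame_paths]

    try:
        tasks = [(Path(p), descriptor, registry, options) for p in frame_paths]
        try:
            results: list[FrameResult] = _map(tasks, _compute_one, cores)
        except StageError as exc:
            raise FrameSeriesError(f"frame processing failed: {exc}") from exc

        if cfg.value_range is None and not per_frame_scaling:
            lo = min(float(r.field.values.min()) for r in results)
            hi = max(float(r.field.values.max()) for r in results)
            cfg = replace(cfg, value_range=(lo, hi))

        render_tasks = list(zip(results, [cfg] * len(results), frame_files))
        _map(render_tasks, _render_one, cores)

        gif = assemble_animation(frame_files, cfg, outdir / gif_name)
    except MolcartoError:
        for f in frame_files:
            if not keep_frames:
                f.unlink(missing_ok=True)
        raise
    if not keep_frames:
        for f in frame_files:
            f.unlink(missing_ok=True)
    return gif, results
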