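"""Render simulated vesicle traces into two-channel time-lapse stacks.

Channel 0 emulates the membrane dye (an annular ring at the vesicle
equator); channel 1 emulates the lumenal pH dye: each vesicle's disc is
filled with the calibration intensity of its lumen pH, and the
surrounding solution carries the intensity of the external pH.  Shot
noise (Poisson) and Gaussian read noise are applied per pixel from an
explicit seed; renders are bit-identical for a fixed seed.

No optical model (PSF, z-sectioning, bleaching) is applied.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import tifffile

from .calibration import CalibrationCurve, ph_to_intensity
from .simulate import TimeSeriesTrace

__all__ = ["ImageRenderConfig", "render_timelapse", "write_timelapse",
           "read_timelapse"]


@dataclass(frozen=True)
class ImageRenderConfig:
    """Geometry, intensity and noise settings for synthetic stacks."""

    shape: tuple[int, int] = (256, 256)  # (rows, cols) px
    pixel_size: float = 0.5  # um/px
    frame_interval: float = 5.0  # s
    positions: tuple[tuple[float, float], ...] = ((128.0, 128.0),)  # (row, col) px
    drift: tuple[tuple[float, float], ...] | None = None  # px/frame per vesicle
    ring_intensity: float = 3000.0
    ring_thickness: float = 3.0  # px
    membrane_background: float = 100.0
    poisson_scale: float = 1.0  # photons per intensity unit; 0 disables
    read_noise_sd: float = 3.0  # Gaussian sd, intensity units; 0 disables
    seed: int | None = None
    dtype: str = "float32"  # output dtype; float64 for exact noiseless work

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be > 0")
        if self.poisson_scale < 0 or self.read_noise_sd < 0:
            raise ValueError("noise amplitudes must be >= 0")


def _radius_px(trace: TimeSeriesTrace, cfg: ImageRenderConfig) -> float:
    return trace.radius * 1e4 / cfg.pixel_size  # cm -> um -> px


def render_timelapse(traces: Sequence[TimeSeriesTrace],
                     curve: CalibrationCurve,
                     cfg: ImageRenderConfig) -> np.ndarray:
    """Render traces into a (frames, 2, rows, cols) float32 stack.

    Traces must share their time base (sampled at the frame interval).
    Raises if a vesicle disc (plus its ring) would leave the frame.
    """
    if len(traces) == 0:
        raise ValueError("no traces to render")
    if len(cfg.positions) != len(traces):
        raise ValueError("one position per trace is required")
    n_frames = len(traces[0].times)
    for tr in traces:
        if len(tr.times) != n_frames:
            raise ValueError("traces must share a common time base")
    dt = np.diff(traces[0].times)
    if dt.size and abs(dt[0] - cfg.frame_interval) > 1e-9:
        raise ValueError("traces are not sampled at the frame interval")
    noisy = cfg.poisson_scale > 0 or cfg.read_noise_sd > 0
    if noisy and cfg.seed is None:
        raise ValueError("a seed is required when rendering with noise")

    rows, cols = cfg.shape
    yy, xx = np.mgrid[0:rows, 0:cols].astype(float)
    drift = cfg.drift or tuple((0.0, 0.0) for _ in traces)
    # bounds check over the full drift range
    for tr, (r0, c0), (dr, dc) in zip(traces, cfg.positions, drift):
        rad = _radius_px(tr, cfg) + cfg.ring_thickness
        for f in (0, n_frames - 1):
            rr, cc = r0 + dr * f, c0 + dc * f
            if (rr - rad < 0 or rr + rad >= rows or
                    cc - rad < 0 or cc + rad >= cols):
                raise ValueError(
                    f"vesicle {tr.vesicle_id} leaves the frame at frame {f}"
                )

    rng = np.random.default_rng(cfg.seed) if noisy else None
    stack = np.empty((n_frames, 2, rows, cols), dtype=np.dtype(cfg.dtype))
    for f in range(n_frames):
        bg = ph_to_intensity(traces[0].pH_o[f], curve)
        lumen = np.full((rows, cols), bg, dtype=float)
        mem = np.full((rows, cols), cfg.membrane_background, dtype=float)
        for tr, (r0, c0), (dr, dc) in zip(traces, cfg.positions, drift):
            rad = _radius_px(tr, cfg)
            d = np.hypot(yy - (r0 + dr * f), xx - (c0 + dc * f))
            lumen[d <= rad] = ph_to_intensity(tr.pH_i[f], curve)
            ring = np.abs(d - rad) <= cfg.ring_thickness / 2.0
            mem[ring] = cfg.ring_intensity
        for ch, img in enumerate((mem, lumen)):
            if noisy:
                if cfg.poisson_scale > 0:
                    img = rng.poisson(img * cfg.poisson_scale) / cfg.poisson_scale
                if cfg.read_noise_sd > 0:
                    img = img + rng.normal(0.0, cfg.read_noise_sd, img.shape)
            stack[f, ch] = img
    return stack


def write_timelapse(path, stack: np.ndarray,
                    cfg: ImageRenderConfig | None = None) -> None:
    """Write an interleaved multi-page TIFF with TCYX axis metadata."""
    meta = {"axes": "TCYX"}
    if cfg is not None:
        meta["pixel_size_um"] = cfg.pixel_size
        meta["frame_interval_s"] = cfg.frame_interval
        meta["channels"] = "membrane,lumen"
    tifffile.imwrite(path, stack, metadata=meta)


def read_timelapse(path) -> np.ndarray:
    """Read a stack written by :func:`write_timelapse` as (T, C, Y, X)."""
    arr = tifffile.imread(path)
    if arr.ndim == 3:  # single frame (C, Y, X)
        arr = arr[None]
    if arr.ndim != 4:
        raise ValueError("expected a (frames, channels, rows, cols) stack")
    return arr
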