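"""Vesicle detection, tracking and intensity measurement.

Vesicles are located in the membrane channel with a circular Hough
transform on a Canny edge map, linked across frames by greedy
nearest-neighbour matching of centroids (ascending pair distance, gated
by a maximum displacement), and measured in the lumen channel as the
mean over a concentric disc shrunk below the membrane ring.  The
extravesicular background is the mean over all pixels outside every
(dilated) vesicle disc.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.draw import disk
from skimage.feature import canny
from skimage.transform import hough_circle, hough_circle_peaks

__all__ = [
    "Detection",
    "VesicleTrack",
    "detect_vesicles",
    "track_vesicles",
    "measure_lumen_intensity",
    "measure_background",
    "measure_stack",
]


@dataclass(frozen=True)
class Detection:
    """One circle found in one frame (pixel coordinates, 0-based)."""

    frame_index: int
    center: tuple[float, float]  # (row, col) px
    radius: float  # px
    score: float  # Hough accumulator value


@dataclass
class VesicleTrack:
    """Per-ID sequence of detections with measured intensities."""

    vesicle_id: int
    frames: list[int] = field(default_factory=list)
    centers: list[tuple[float, float]] = field(default_factory=list)
    radii: list[float] = field(default_factory=list)
    lumen_intensity: list[float] = field(default_factory=list)
    background_intensity: list[float] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.frames)


def _refine_radius(frame: np.ndarray, center: tuple[float, float],
                   radius_range: tuple[int, int]) -> float:
    """Snap a detected radius to the ring centreline.

    The Hough accumulator peaks on an edge of the membrane ring (inner
    or outer, depending on noise); the unbiased radius is the argmax of
    the radial mean-intensity profile around the detected centre.
    """
    r_lo, r_hi = radius_range
    cy, cx = center
    y0 = max(0, int(cy - r_hi - 2))
    y1 = min(frame.shape[0], int(cy + r_hi + 3))
    x0 = max(0, int(cx - r_hi - 2))
    x1 = min(frame.shape[1], int(cx + r_hi + 3))
    patch = frame[y0:y1, x0:x1]
    yy, xx = np.mgrid[y0:y1, x0:x1]
    d = np.hypot(yy - cy, xx - cx)
    radii = np.arange(r_lo, r_hi + 1)
    profile = np.array([
        patch[(d >= r - 0.5) & (d < r + 0.5)].mean() if
        ((d >= r - 0.5) & (d < r + 0.5)).any() else -np.inf
        for r in radii
    ])
    # centre of mass of the ring peak (argmax alone breaks ties low)
    k = int(np.argmax(profile))
    lo, hi = max(0, k - 2), min(len(radii), k + 3)
    w = np.clip(profile[lo:hi] - np.median(profile[np.isfinite(profile)]),
                0.0, None)
    if w.sum() <= 0:
        return float(radii[k])
    return float(np.round(np.sum(w * radii[lo:hi]) / w.sum()))


def detect_vesicles(frame: np.ndarray,
                    radius_range: tuple[int, int] = (12, 30),
                    sensitivity: float = 0.4,
                    canny_sigma: float = 2.0,
                    radius_step: int = 1) -> list[Detection]:
    """Find circular membrane rings in a single-channel image.

    Candidate circles come from a circular Hough accumulator over an
    edge map; overlapping candidates are suppressed, keeping the higher
    accumulator score when two centres are closer than the smaller of
    the two radii.  Deterministic for a given image.
    """
    frame = np.asarray(frame, dtype=float)
    if frame.ndim != 2 or frame.size == 0:
        raise ValueError("frame must be a non-empty 2-D image")
    r_lo, r_hi = radius_range
    if not (0 < r_lo < r_hi):
        raise ValueError("radius_range must satisfy 0 < min < max")
    span = np.ptp(frame)
    if span == 0:
        return []
    norm = (frame - frame.min()) / span
    edges = canny(norm, sigma=canny_sigma)
    if not edges.any():
        return []
    radii = np.arange(r_lo, r_hi + 1, radius_step)
    accum = hough_circle(edges, radii)
    n_max = 64  # generous cap; overlap suppression prunes the rest
    scores, cols, rows, found_r = hough_circle_peaks(
        accum, radii, min_xdistance=r_lo, min_ydistance=r_lo,
        threshold=sensitivity, total_num_peaks=n_max,
    )
    # suppress overlapping candidates: order by score, drop any candidate
    # whose centre is within the smaller radius of an accepted one
    order = np.argsort(-scores, kind="stable")
    kept: list[Detection] = []
    for i in order:
        c = (float(rows[i]), float(cols[i]))
        r = float(found_r[i])
        clash = any(
            np.hypot(c[0] - k.center[0], c[1] - k.center[1]) < min(r, k.radius)
            for k in kept
        )
        if not clash:
            r = _refine_radius(frame, c, radius_range)
            kept.append(Detection(frame_index=0, center=c, radius=r,
                                  score=float(scores[i])))
    kept.sort(key=lambda d: (d.center[0], d.center[1]))
    return kept


def track_vesicles(detections: list[list[Detection]],
                   max_displacement: float = 10.0,
                   max_gap: int = 1) -> list[VesicleTrack]:
    """Link per-frame detections into tracks with stable IDs.

    Greedy assignment in order of ascending centroid distance between
    unmatched detections and active tracks (tracks may skip up to
    ``max_gap`` frames); links farther than ``max_displacement`` open a
    new ID.  IDs are never reused and the outcome is independent of the
    ordering of detections within a frame.
    """
    tracks: list[VesicleTrack] = []
    active: list[VesicleTrack] = []
    next_id = 0
    for f, dets in enumerate(detections):
        dets = sorted(dets, key=lambda d: (d.center[0], d.center[1]))
        live = [t for t in active if f - t.frames[-1] - 1 <= max_gap]
        pairs = []
        for ti, t in enumerate(live):
            ty, tx = t.centers[-1]
            for di, d in enumerate(dets):
                dist = float(np.hypot(d.center[0] - ty, d.center[1] - tx))
                if dist <= max_displacement:
                    pairs.append((dist, t.vesicle_id, di, ti))
        pairs.sort()
        used_t: set[int] = set()
        used_d: set[int] = set()
        for dist, _tid, di, ti in pairs:
            if ti in used_t or di in used_d:
                continue
            used_t.add(ti)
            used_d.add(di)
            t = live[ti]
            d = dets[di]
            t.frames.append(f)
            t.centers.append(d.center)
            t.radii.append(d.radius)
        for di, d in enumerate(dets):
            if di in used_d:
                continue
            t = VesicleTrack(vesicle_id=next_id)
            next_id += 1
            t.frames.append(f)
            t.centers.append(d.center)
            t.radii.append(d.radius)
            tracks.append(t)
        active = tracks
    return tracks


def measure_lumen_intensity(frame: np.ndarray, det: Detection,
                            shrink: float = 0.7) -> float:
    """Mean lumen intensity over the disc of radius shrink*r at the centre.

    The shrink factor excludes the membrane ring and rim artefacts.
    """
    if not (0 < shrink < 1):
        raise ValueError("shrink must lie in (0, 1)")
    frame = np.asarray(frame, dtype=float)
    rr, cc = disk(det.center, shrink * det.radius, shape=None)
    if (rr.min() < 0 or cc.min() < 0 or rr.max() >= frame.shape[0]
            or cc.max() >= frame.shape[1]):
        raise ValueError("measurement disc exits the frame")
    return float(frame[rr, cc].mean())


def measure_background(frame: np.ndarray, detections: list[Detection],
                       margin: float = 1.2) -> float:
    """Mean intensity outside every vesicle disc dilated by ``margin``."""
    frame = np.asarray(frame, dtype=float)
    mask = np.ones(frame.shape, dtype=bool)
    for det in detections:
        rr, cc = disk(det.center, margin * det.radius, shape=frame.shape)
        mask[rr, cc] = False
    if not mask.any():
        raise ValueError("no background pixels outside the vesicle discs")
    return float(frame[mask].mean())


def measure_stack(stack: np.ndarray, *,
                  pixel_size: float,
                  frame_interval: float,
                  radius_range: tuple[int, int] = (12, 30),
                  sensitivity: float = 0.4,
                  max_displacement: float = 10.0,
                  max_gap: int = 1,
                  shrink: float = 0.7,
                  background_margin: float = 1.2,
                  membrane_channel: int = 0,
                  lumen_channel: int = 1) -> pd.DataFrame:
    """Detect, track and measure a (T, C, Y, X) stack into a tidy table.

    Returns one row per (vesicle_id, frame) with columns
    vesicle_id, frame, t_s, x_px, y_px, radius_px, radius_um,
    lumen_intensity, background_intensity.
    """
    if stack.ndim != 4:
        raise ValueError("expected a (frames, channels, rows, cols) stack")
    per_frame: list[list[Detection]] = []
    for f in range(stack.shape[0]):
        dets = detect_vesicles(stack[f, membrane_channel], radius_range,
                               sensitivity)
        per_frame.append([Detection(f, d.center, d.radius, d.score)
                          for d in dets])
    tracks = track_vesicles(per_frame, max_displacement, max_gap)
    backgrounds = {
        f: measure_background(stack[f, lumen_channel], per_frame[f],
                              background_margin)
        for f in range(stack.shape[0])
    }
    rows = []
    for t in tracks:
        for f, (cy, cx), r in zip(t.frames, t.centers, t.radii):
            lum = measure_lumen_intensity(
                stack[f, lumen_channel],
                Detection(f, (cy, cx), r, 0.0), shrink)
            rows.append({
                "vesicle_id": t.vesicle_id, "frame": f,
                "t_s": f * frame_interval,
                "x_px": cx, "y_px": cy, "radius_px": r,
                "radius_um": r * pixel_size,
                "lumen_intensity": lum,
                "background_intensity": backgrounds[f],
            })
    return pd.DataFrame(rows)
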