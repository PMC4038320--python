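"""Markerless single-target localisation and path statistics.

The target position in each frame is the center of the largest connected
supra-threshold component of the isolated difference map.  Positions over
time form the path, from which total path length and duration follow; with a
pixels-to-meters factor (``px2m``) the statistics are reported in meters.

Coordinate convention: origin at the top-left pixel center, x rightward
(columns), y downward (rows), 0-based.  Path statistics are independent of
this convention; plots are not.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage

from .colorize import TimeColormap
from .preprocess import DifferenceStack

__all__ = ["PathTrack", "detect_target", "extract_path", "render_path",
           "write_track_csv"]

_EIGHT = np.ones((3, 3), dtype=int)


@dataclass
class PathTrack:
    """Time-ordered target positions with derived statistics."""

    t: np.ndarray  # seconds, strictly increasing
    x: np.ndarray  # px or m
    y: np.ndarray  # px or m
    units: str = "pixels"  # "pixels" | "meters"
    px2m: float | None = None
    path_pps: float = float("nan")
    interpolated: np.ndarray | None = None  # bool; interior gap fills

    def __len__(self) -> int:
        return len(self.t)

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0])

    @property
    def path_length(self) -> float:
        """Sum of Euclidean distances between consecutive samples."""
        return float(np.hypot(np.diff(self.x), np.diff(self.y)).sum())

    @property
    def step_lengths(self) -> np.ndarray:
        return np.hypot(np.diff(self.x), np.diff(self.y))


def detect_target(
    diff: np.ndarray,
    thresh_trim: float,
    area_min: int = 1,
    weighted: bool = False,
) -> tuple[float, float] | None:
    """Locate the target as the center of the largest thresholded component.

    Binarizes ``diff`` at ``thresh_trim`` and labels 8-connected components;
    returns the (x, y) centroid of the largest one, or ``None`` if the
    largest component is smaller than ``area_min`` pixels (no credible
    target).  Equal-area ties are broken by total intensity, then label
    order.  ``weighted=True`` uses the intensity-weighted center of mass
    instead of the binary centroid.
    """
    binary = diff > thresh_trim
    labels, n = ndimage.label(binary, structure=_EIGHT)
    if n == 0:
        return None
    idx = np.arange(1, n + 1)
    areas = ndimage.sum_labels(binary, labels, index=idx)
    best = areas == areas.max()
    if best.sum() > 1:
        sums = ndimage.sum_labels(diff, labels, index=idx)
        sums = np.where(best, sums, -np.inf)
        label = int(idx[np.argmax(sums)])
    else:
        label = int(idx[np.argmax(areas)])
    if areas[label - 1] < area_min:
        return None
    if weighted:
        cy, cx = ndimage.center_of_mass(diff, labels, label)
    else:
        cy, cx = ndimage.center_of_mass(labels == label)
    return float(cx), float(cy)


def extract_path(
    stack: DifferenceStack,
    path_sampling: float | None = None,
    thresh_trim: float = 0.2,
    area_min: int = 1,
    px2m: float | None = None,
    weighted: bool = False,
) -> PathTrack:
    """Assemble the target's path from a difference stack.

    The stack is typically built at a higher sampling rate than the STL
    image.  If ``path_sampling`` (positions/s) is below the stack's rate the
    stack is subsampled to match.  Start and end are re-determined here: a
    frame with no component of at least ``area_min`` px yields no detection,
    and leading/trailing non-detections are dropped; interior misses are
    filled by linear interpolation between neighbours.
    """
    n = len(stack)
    step = 1
    if path_sampling is not None and np.isfinite(stack.pps) and stack.pps > 0:
        step = max(1, int(round(stack.pps / path_sampling)))
    sel = list(range(0, n, step))
    times = np.array([stack.timestamps[i] for i in sel])
    hits: list[tuple[float, float] | None] = [
        detect_target(stack.diffs[i], thresh_trim, area_min, weighted)
        for i in sel
    ]
    have = [h is not None for h in hits]
    if not any(have):
        raise ValueError(
            "target was never detected; check thresh_trim and area_min"
        )
    first = have.index(True)
    last = len(have) - 1 - have[::-1].index(True)
    times = times[first : last + 1]
    hits = hits[first : last + 1]

    x = np.array([np.nan if h is None else h[0] for h in hits])
    y = np.array([np.nan if h is None else h[1] for h in hits])
    interp = np.isnan(x)
    if interp.any():
        good = ~interp
        x[interp] = np.interp(times[interp], times[good], x[good])
        y[interp] = np.interp(times[interp], times[good], y[good])

    units = "pixels"
    if px2m is not None:
        x, y = x * px2m, y * px2m
        units = "meters"
    pps = stack.pps / step if np.isfinite(stack.pps) else float("nan")
    return PathTrack(
        t=times, x=x, y=y, units=units, px2m=px2m,
        path_pps=pps, interpolated=interp,
    )


def _disk_offsets(radius: int) -> tuple[np.ndarray, np.ndarray]:
    yy, xx = np.mgrid[-radius : radius + 1, -radius : radius + 1]
    keep = yy**2 + xx**2 <= radius**2
    return yy[keep], xx[keep]


def render_path(
    track: PathTrack,
    background: np.ndarray,
    colormap: TimeColormap,
    marker_color: tuple[float, float, float] = (0.0, 0.0, 0.0),
    marker_radius: int = 3,
) -> np.ndarray:
    """Draw the time-colored path over a background image.

    Markers are filled disks in the frame's time-specific color with a
    1-px border in ``marker_color``, connected in order by line segments.
    Track coordinates must be in pixels.
    """
    if len(track) == 0:
        raise ValueError("empty track")
    if track.units != "pixels":
        raise ValueError("render_path needs pixel coordinates")
    if background.ndim == 2:
        img = np.repeat(background[..., None], 3, axis=-1).astype(float)
    else:
        img = background[..., :3].astype(float).copy()
    h, w = img.shape[:2]

    def put(rows: np.ndarray, cols: np.ndarray, rgb) -> None:
        keep = (rows >= 0) & (rows < h) & (cols >= 0) & (cols < w)
        img[rows[keep], cols[keep]] = rgb

    # connecting segments first, markers on top
    for k in range(len(track) - 1):
        x0, y0, x1, y1 = track.x[k], track.y[k], track.x[k + 1], track.y[k + 1]
        npts = max(2, int(np.hypot(x1 - x0, y1 - y0)) * 2)
        xs = np.round(np.linspace(x0, x1, npts)).astype(int)
        ys = np.round(np.linspace(y0, y1, npts)).astype(int)
        put(ys, xs, marker_color)

    in_dy, in_dx = _disk_offsets(marker_radius)
    out_dy, out_dx = _disk_offsets(marker_radius + 1)
    denom = max(len(track) - 1, 1)
    for k in range(len(track)):
        cy, cx = int(round(track.y[k])), int(round(track.x[k]))
        ci = min(int(round(k / denom * (colormap.n - 1))), colormap.n - 1)
        put(out_dy + cy, out_dx + cx, marker_color)  # border ring
        put(in_dy + cy, in_dx + cx, colormap.colors[ci])
    return np.clip(img, 0.0, 1.0)


def write_track_csv(track: PathTrack, out_dir: str | Path, stem: str) -> Path:
    """Export the track as ``<stem>_path.csv`` (columns t_s, x, y, units)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / f"{stem}_path.csv"
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["t_s", "x", "y", "units"])
        for t, x, y in zip(track.t, track.x, track.y):
            writer.writerow([f"{t:.6f}", f"{x:.4f}", f"{y:.4f}", track.units])
    return path
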