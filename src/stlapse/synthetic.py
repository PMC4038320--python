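"""Synthetic single-target videos with exact ground truth.

Generates the kind of footage the toolbox is designed for — a single compact
target moving over a mostly static background — with the target's true
sub-pixel center known at every frame.  Emulated nuisance features: additive
pixel noise, a bright hard-coded overlay (timestamp) region, slow background
drift, and empty lead/tail frames before the target enters and after it
leaves.  It does not emulate deformable bodies, shadows, or occlusion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Literal

import numpy as np

from . import avi
from .video_io import FrameSequence

__all__ = [
    "FixtureSpec",
    "GroundTruth",
    "generate_fixture",
    "fixture_sequence",
    "stationary",
    "linear",
    "circular",
    "piecewise",
]

Trajectory = Callable[[float], tuple[float, float]]


def stationary(x: float, y: float) -> Trajectory:
    """Target fixed at (x, y)."""
    return lambda t: (x, y)


def linear(x0: float, y0: float, vx: float, vy: float) -> Trajectory:
    """Constant-velocity straight-line motion from (x0, y0), px/s."""
    return lambda t: (x0 + vx * t, y0 + vy * t)


def circular(
    cx: float, cy: float, radius: float, omega: float, phase: float = 0.0
) -> Trajectory:
    """Constant angular speed ``omega`` rad/s on a circle of ``radius`` px."""

    def traj(t: float) -> tuple[float, float]:
        a = phase + omega * t
        return cx + radius * np.cos(a), cy + radius * np.sin(a)

    return traj


def piecewise(waypoints: list[tuple[float, float, float]]) -> Trajectory:
    """Piecewise-linear path through ``(t, x, y)`` waypoints.

    Repeating a position across consecutive waypoints produces a pause.
    Times must be strictly increasing; positions are held constant outside
    the waypoint range.
    """
    ts = np.array([w[0] for w in waypoints], dtype=float)
    xs = np.array([w[1] for w in waypoints], dtype=float)
    ys = np.array([w[2] for w in waypoints], dtype=float)
    if len(ts) < 1 or np.any(np.diff(ts) <= 0):
        raise ValueError("waypoint times must be strictly increasing")

    def traj(t: float) -> tuple[float, float]:
        return float(np.interp(t, ts, xs)), float(np.interp(t, ts, ys))

    return traj


@dataclass
class FixtureSpec:
    """Parameters of a synthetic single-target video.

    The defaults describe a typical desk-scale behavioural recording: a
    320x240 video at 30 fps with a mid-grey arena and a dark target of
    radius 6 px, roughly the scale of a rodent viewed from above.
    """

    size: tuple[int, int] = (240, 320)  # (H, W)
    fps: float = 30.0
    n_frames: int = 300
    background: float | Callable[[int], float] = 0.6
    blob_radius: float = 6.0
    blob_amplitude: float = -0.45  # negative = target darker than background
    blob_profile: Literal["disk", "gaussian"] = "disk"
    trajectory: Trajectory = field(default_factory=lambda: stationary(160, 120))
    lead_empty: int = 0
    tail_empty: int = 0
    noise_sd: float = 0.0
    overlay_box: tuple[int, int, int, int] | None = None  # (row0, col0, h, w)
    seed: int = 0


@dataclass
class GroundTruth:
    """Exact per-frame target state of a generated fixture."""

    t: np.ndarray  # seconds, all frames
    x: np.ndarray  # true center column, px (NaN when absent)
    y: np.ndarray  # true center row, px (NaN when absent)
    present: np.ndarray  # bool per frame

    @property
    def path_length(self) -> float:
        xs, ys = self.x[self.present], self.y[self.present]
        return float(np.hypot(np.diff(xs), np.diff(ys)).sum())


def _render_blob(
    canvas: np.ndarray, cx: float, cy: float, spec: FixtureSpec
) -> None:
    h, w = canvas.shape
    r = spec.blob_radius
    pad = int(np.ceil(r)) + 3
    r0, r1 = int(np.floor(cy)) - pad, int(np.ceil(cy)) + pad + 1
    c0, c1 = int(np.floor(cx)) - pad, int(np.ceil(cx)) + pad + 1
    if r0 < 0 or c0 < 0 or r1 > h or c1 > w:
        raise ValueError(
            f"blob at ({cx:.1f}, {cy:.1f}) with radius {r} leaves the "
            f"{h}x{w} frame"
        )
    yy, xx = np.mgrid[r0:r1, c0:c1]
    d = np.hypot(xx - cx, yy - cy)
    if spec.blob_profile == "gaussian":
        cover = np.exp(-(d**2) / (2 * (r / 2.0) ** 2))
    else:
        # anti-aliased hard disk: linear sub-pixel edge coverage
        cover = np.clip(r + 0.5 - d, 0.0, 1.0)
    canvas[r0:r1, c0:c1] += spec.blob_amplitude * cover


def generate_fixture(
    spec: FixtureSpec, out_path: str | Path | None = None
) -> tuple[np.ndarray, GroundTruth]:
    """Render a fixture video and its exact ground-truth track.

    Returns ``(frames, truth)`` where ``frames`` is an ``(n, H, W)`` float
    array on [0, 1].  Deterministic given ``spec.seed``.  If ``out_path`` is
    given the frames are additionally written as a lossless uncompressed AVI.
    """
    h, w = spec.size
    rng = np.random.default_rng(spec.seed)
    frames = np.empty((spec.n_frames, h, w), dtype=np.float64)
    t = np.arange(spec.n_frames) / spec.fps
    x = np.full(spec.n_frames, np.nan)
    y = np.full(spec.n_frames, np.nan)
    present = np.zeros(spec.n_frames, dtype=bool)
    first = spec.lead_empty
    last = spec.n_frames - spec.tail_empty  # exclusive

    for k in range(spec.n_frames):
        bg = spec.background(k) if callable(spec.background) else spec.background
        frame = np.full((h, w), float(bg))
        if first <= k < last:
            cx, cy = spec.trajectory(t[k])
            _render_blob(frame, cx, cy, spec)
            x[k], y[k], present[k] = cx, cy, True
        if spec.overlay_box is not None:
            r0, c0, bh, bw = spec.overlay_box
            frame[r0 : r0 + bh, c0 : c0 + bw] = 1.0
        if spec.noise_sd > 0:
            frame += rng.normal(0.0, spec.noise_sd, size=(h, w))
        frames[k] = np.clip(frame, 0.0, 1.0)

    truth = GroundTruth(t=t, x=x, y=y, present=present)
    if out_path is not None:
        avi.write_avi(out_path, frames, spec.fps)
    return frames, truth


def fixture_sequence(
    spec: FixtureSpec,
    sampling: int = 1,
    videospeed: float = 1.0,
) -> tuple[FrameSequence, GroundTruth]:
    """Generate a fixture directly as an in-memory :class:`FrameSequence`.

    Bypasses the AVI round-trip (no 8-bit quantization); sampling semantics
    match :func:`stlapse.video_io.load_video`.
    """
    frames, truth = generate_fixture(spec)
    indices = list(range(0, spec.n_frames, sampling))
    seq = FrameSequence(
        frames=[frames[k] for k in indices],
        frame_indices=indices,
        timestamps=[k / spec.fps * videospeed for k in indices],
        fps_source=spec.fps,
        pps=spec.fps / sampling / videospeed,
        videospeed=videospeed,
    )
    return seq, truth
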