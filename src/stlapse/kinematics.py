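"""Instantaneous velocity and acceleration from a tracked path.

Velocity is the distance travelled between consecutive path samples divided
by the elapsed time, timestamped at the interval midpoint; acceleration is
the finite difference of velocities at the midpoints of those midpoints.  A
centered weighted moving average (``velSmooth``) suppresses the detection
jitter these finite differences amplify.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .path_analysis import PathTrack

__all__ = [
    "KinematicsSeries",
    "velocity_series",
    "acceleration_series",
    "smooth_series",
    "compute_kinematics",
    "render_velocity_plot",
    "write_kinematics_csv",
]

DEFAULT_WEIGHTS = (0.25, 0.5, 0.25)


@dataclass
class KinematicsSeries:
    """Velocity/acceleration series with their midpoint timestamps.

    ``len(velocity) == n_samples - 1`` and
    ``len(acceleration) == n_samples - 2`` for a track of ``n_samples``.
    """

    t_velocity: np.ndarray  # interval midpoints, s
    velocity: np.ndarray  # units/s, nonnegative
    t_acceleration: np.ndarray = field(
        default_factory=lambda: np.empty(0)
    )
    acceleration: np.ndarray = field(default_factory=lambda: np.empty(0))
    units: str = "pixels"
    smooth_weights: np.ndarray | None = None


def velocity_series(track: PathTrack) -> KinematicsSeries:
    """Speed over each sampling interval of the track.

    ``v_k = |sample_{k+1} - sample_k| / (t_{k+1} - t_k)``, reported at the
    interval midpoint.  By construction ``sum(v_k * dt_k)`` equals the
    track's path length exactly.
    """
    if len(track) < 2:
        raise ValueError("velocity needs at least 2 path samples")
    dt = np.diff(track.t)
    if np.any(dt <= 0):
        raise ValueError("track timestamps must be strictly increasing")
    v = track.step_lengths / dt
    tmid = (track.t[:-1] + track.t[1:]) / 2.0
    return KinematicsSeries(t_velocity=tmid, velocity=v, units=track.units)


def acceleration_series(series: KinematicsSeries) -> KinematicsSeries:
    """Finite-difference acceleration between consecutive velocities."""
    if len(series.velocity) < 2:
        raise ValueError("acceleration needs at least 2 velocity values")
    dt = np.diff(series.t_velocity)
    a = np.diff(series.velocity) / dt
    ta = (series.t_velocity[:-1] + series.t_velocity[1:]) / 2.0
    return KinematicsSeries(
        t_velocity=series.t_velocity,
        velocity=series.velocity,
        t_acceleration=ta,
        acceleration=a,
        units=series.units,
        smooth_weights=series.smooth_weights,
    )


def smooth_series(values: np.ndarray, weights) -> np.ndarray:
    """Centered weighted moving average; ends renormalize the clipped window.

    ``weights`` must be an odd-length nonnegative sequence summing to 1.
    """
    w = np.asarray(weights, dtype=np.float64)
    if w.ndim != 1 or len(w) % 2 == 0:
        raise ValueError("weights must be a 1-D odd-length sequence")
    if np.any(w < 0) or not np.isclose(w.sum(), 1.0):
        raise ValueError("weights must be nonnegative and sum to 1")
    values = np.asarray(values, dtype=np.float64)
    if values.size == 0:
        raise ValueError("empty series")
    half = len(w) // 2
    out = np.empty_like(values)
    n = len(values)
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        ww = w[half - (i - lo) : half + (hi - i)]
        out[i] = np.dot(values[lo:hi], ww) / ww.sum()
    return out


def compute_kinematics(
    track: PathTrack, weights=DEFAULT_WEIGHTS
) -> KinematicsSeries:
    """Velocity and acceleration of a track, smoothed with ``weights``.

    Velocities are smoothed before differencing so that noise is not
    amplified twice; the resulting accelerations are smoothed with the same
    window.
    """
    series = velocity_series(track)
    w = np.asarray(weights, dtype=np.float64)
    series.velocity = smooth_series(series.velocity, w)
    series = acceleration_series(series)
    series.acceleration = smooth_series(series.acceleration, w)
    series.smooth_weights = w
    return series


def render_velocity_plot(
    series: KinematicsSeries, out_dir: str | Path, stem: str
) -> Path:
    """Save a velocity-and-acceleration-versus-time plot as
    ``<stem>_vel.png``."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if len(series.velocity) == 0:
        raise ValueError("empty kinematics series")
    unit = "m" if series.units == "meters" else "px"
    fig, ax_v = plt.subplots(figsize=(8, 4))
    ax_v.plot(series.t_velocity, series.velocity, color="tab:blue",
              label="velocity")
    ax_v.set_xlabel("time (s)")
    ax_v.set_ylabel(f"velocity ({unit}/s)", color="tab:blue")
    ax_v.set_xlim(series.t_velocity[0], series.t_velocity[-1])
    if len(series.acceleration):
        ax_a = ax_v.twinx()
        ax_a.plot(series.t_acceleration, series.acceleration,
                  color="tab:red", alpha=0.7, label="acceleration")
        ax_a.set_ylabel(f"acceleration ({unit}/s²)", color="tab:red")
        ax_a.axhline(0.0, color="tab:red", lw=0.5, alpha=0.3)
    fig.tight_layout()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / f"{stem}_vel.png"
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def write_kinematics_csv(
    series: KinematicsSeries, out_dir: str | Path, stem: str
) -> Path:
    """Export ``<stem>_vel.csv`` with columns t_s, velocity, acceleration.

    Acceleration is defined between velocity samples, so the trailing
    velocity row has a blank acceleration field.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / f"{stem}_vel.csv"
    accel = list(series.acceleration) + [None] * (
        len(series.velocity) - len(series.acceleration)
    )
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["t_s", "velocity", "acceleration"])
        for t, v, a in zip(series.t_velocity, series.velocity, accel):
            writer.writerow(
                [f"{t:.6f}", f"{v:.6f}", "" if a is None else f"{a:.6f}"]
            )
    return path
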