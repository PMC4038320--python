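"""Loading and sampling video into grey-scale frame sequences.

Positions are usually needed at a far lower rate than the camera's acquisition
rate, so only every *i*-th frame is kept (``sampling``).  Timestamps are
reported in real-world seconds: for footage that was slowed or sped relative
to real time (``videospeed``, e.g. 0.1 for a 10x-slowed high-speed recording)
the timestamps and the effective positions-per-second (pps) are corrected
accordingly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import avi

__all__ = ["FrameSequence", "load_video", "get_frame", "to_grey"]

#: ITU-R BT.601 luma weights used for grey-scale conversion.
LUMA_WEIGHTS = np.array([0.299, 0.587, 0.114])


@dataclass
class FrameSequence:
    """Ordered grey-scale frames with real-world timing metadata.

    Attributes
    ----------
    frames
        List of 2-D float arrays with values in [0, 1], identical shapes.
    frame_indices
        0-based frame numbers of each retained frame in the source video.
    timestamps
        Real-world seconds of each frame: ``index / fps_source * videospeed``.
    fps_source
        Acquisition frame rate of the source video.
    pps
        Effective positions-per-second after sampling and videospeed
        correction: ``fps_source / sampling / videospeed``.
    videospeed
        Real-time multiplier of the source footage (1.0 = real time).
    """

    frames: list[np.ndarray]
    frame_indices: list[int]
    timestamps: list[float]
    fps_source: float
    pps: float
    videospeed: float = 1.0
    path: Path | None = field(default=None, compare=False)

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames[0].shape

    @property
    def duration(self) -> float:
        return self.timestamps[-1] - self.timestamps[0] if self.frames else 0.0


def to_grey(frame: np.ndarray) -> np.ndarray:
    """Convert a frame to grey-scale floats on [0, 1].

    RGB frames use the standard luma weighting 0.299 R + 0.587 G + 0.114 B;
    integer inputs are assumed to be on [0, 255].
    """
    frame = np.asarray(frame)
    if np.issubdtype(frame.dtype, np.integer):
        frame = frame.astype(np.float64) / 255.0
    else:
        frame = frame.astype(np.float64)
    if frame.ndim == 3:
        frame = frame[..., :3] @ LUMA_WEIGHTS
    return np.clip(frame, 0.0, 1.0)


def _decode(path: str | Path) -> tuple[np.ndarray, float]:
    """Decode all frames of a video file; returns (frames, fps)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if avi.is_uncompressed_avi(path):
        frames, info = avi.read_avi(path)
        return frames, info.fps
    # other containers need an imageio video plugin (e.g. ffmpeg)
    import imageio.v3 as iio

    try:
        frames = iio.imread(path, index=None)
        meta = iio.immeta(path)
    except Exception as exc:  # noqa: BLE001 - plugin errors vary
        raise ValueError(f"cannot decode {path}: {exc}") from exc
    return np.asarray(frames), float(meta.get("fps", 25.0))


def load_video(
    path: str | Path,
    sampling: int = 1,
    start_frame: int | None = None,
    end_frame: int | None = None,
    videospeed: float = 1.0,
) -> FrameSequence:
    """Load a video as a sampled grey-scale :class:`FrameSequence`.

    Every ``sampling``-th frame within ``[start_frame, end_frame]``
    (0-based, both inclusive; sampling anchored at ``start_frame``) is
    converted to grey-scale on [0, 1].

    Parameters
    ----------
    path
        Video file. Uncompressed AVI is decoded natively; other containers
        require an imageio video plugin.
    sampling
        Keep every ``sampling``-th frame (>= 1).
    start_frame, end_frame
        Optional 0-based inclusive frame range.
    videospeed
        Real-time multiplier of the footage; timestamps are scaled by it so
        they are in real-world seconds.

    Raises
    ------
    ValueError
        On invalid sampling/range arguments or an empty selection.
    """
    if sampling < 1 or int(sampling) != sampling:
        raise ValueError(f"sampling must be a positive integer, got {sampling}")
    if videospeed <= 0:
        raise ValueError(f"videospeed must be positive, got {videospeed}")
    raw, fps = _decode(path)
    n = len(raw)
    if n == 0:
        raise ValueError(f"{path}: video contains no frames")

    start = 0 if start_frame is None else int(start_frame)
    end = n - 1 if end_frame is None else int(end_frame)
    if not (0 <= start < n) or not (0 <= end < n):
        raise IndexError(
            f"frame range [{start}, {end}] outside video of {n} frames"
        )
    if start > end:
        raise ValueError(f"start_frame {start} > end_frame {end}")

    indices = list(range(start, end + 1, int(sampling)))
    if not indices:
        raise ValueError("frame selection is empty")
    frames = [to_grey(raw[k]) for k in indices]
    timestamps = [k / fps * videospeed for k in indices]
    return FrameSequence(
        frames=frames,
        frame_indices=indices,
        timestamps=timestamps,
        fps_source=fps,
        pps=fps / sampling / videospeed,
        videospeed=videospeed,
        path=Path(path),
    )


def get_frame(path: str | Path, k: int) -> np.ndarray:
    """Return grey-scale frame ``k`` (0-based) of a video, for inspection.

    Useful for choosing start/end frames before a full run.
    """
    raw, _ = _decode(path)
    if not (0 <= k < len(raw)):
        raise IndexError(f"frame {k} out of range for {len(raw)}-frame video")
    return to_grey(raw[k])
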