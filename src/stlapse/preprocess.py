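"""Target isolation: reference subtraction, smoothing, masking, trimming.

Five per-frame calculations isolate the moving target: (1) subtract a
reference frame, (2) Gaussian-smooth the difference, (3) normalize polarity
so target intensity is positive whether the animal is darker or lighter than
the background, (4) mask out irrelevant regions (a pre-made static mask
and/or dynamic removal of bright overlays such as burnt-in timestamps), and
(5) trim frames from the start and end of the video in which the target is
absent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
from scipy import ndimage

from .video_io import FrameSequence, to_grey

__all__ = [
    "ReferenceSpec",
    "PreprocessConfig",
    "DifferenceStack",
    "compute_reference",
    "difference_frame",
    "smooth_frame",
    "normalize_polarity",
    "apply_masks",
    "trim_frames",
    "preprocess",
    "load_mask",
]

Polarity = Literal["target_darker", "target_lighter"]


@dataclass
class ReferenceSpec:
    """How the reference frame is obtained.

    ``first``/``last`` use that single frame; ``moving_average`` uses, for
    each frame, the mean of a centered window of ``window`` frames (truncated
    at the sequence ends) — useful when the background changes slowly over
    time (lighting, bedding material).
    """

    mode: Literal["first", "last", "moving_average"] = "first"
    window: int = 5

    def __post_init__(self) -> None:
        if self.mode not in ("first", "last", "moving_average"):
            raise ValueError(f"unknown reference mode {self.mode!r}")
        if self.mode == "moving_average":
            if self.window < 1:
                raise ValueError("window must be >= 1")
            if self.window % 2 == 0:
                raise ValueError("window must be odd for a centered average")


@dataclass
class PreprocessConfig:
    """Settings for the per-frame isolation calculations.

    All intensity thresholds are on the normalized [0, 1] scale.

    Attributes
    ----------
    smooth_sigma
        Gaussian kernel sigma in pixels; calibrate to the target's apparent
        size (kernel truncated at 3 sigma). 0 disables smoothing.
    do_mask, mask_path
        Apply a pre-made static mask image (nonzero = keep).
    clean_white, white
        Zero pixels whose *source-frame* intensity exceeds ``white`` —
        removes hard-coded overlays such as timestamps.
    thresh_mask
        Intensity threshold separating target from residual noise.
    thresh_trim
        Peak-intensity threshold a connected region must exceed for a frame
        to count as containing the target.
    disable_trim
        Keep all frames regardless of target presence.
    polarity
        ``auto`` detects from the sign of the extreme summed difference;
        or force ``target_darker`` / ``target_lighter``.
    """

    smooth_sigma: float = 2.0
    do_mask: bool = False
    mask_path: str | Path | None = None
    clean_white: bool = False
    white: float = 0.95
    thresh_mask: float = 0.1
    thresh_trim: float = 0.2
    disable_trim: bool = False
    polarity: Literal["auto", "target_darker", "target_lighter"] = "auto"

    def __post_init__(self) -> None:
        for name in ("white", "thresh_mask", "thresh_trim"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.smooth_sigma < 0:
            raise ValueError("smooth_sigma must be >= 0")
        if self.do_mask and self.mask_path is None:
            raise ValueError("do_mask is set but mask_path is missing")


@dataclass
class DifferenceStack:
    """Per-frame target-isolated intensity maps.

    ``diffs`` are nonnegative after polarity normalization; ``retained``
    marks the contiguous frame span that contains the target.
    """

    diffs: list[np.ndarray]
    retained: np.ndarray  # bool per frame
    timestamps: list[float]
    polarity: Polarity
    pps: float = float("nan")

    def __len__(self) -> int:
        return len(self.diffs)

    @property
    def retained_indices(self) -> np.ndarray:
        return np.flatnonzero(self.retained)

    def retained_diffs(self) -> list[np.ndarray]:
        return [self.diffs[i] for i in self.retained_indices]

    def retained_timestamps(self) -> list[float]:
        return [self.timestamps[i] for i in self.retained_indices]


def compute_reference(
    seq: FrameSequence, spec: ReferenceSpec | None = None
) -> np.ndarray:
    """Reference frame(s) to subtract from every sampled frame.

    Returns a single ``(H, W)`` map for ``first``/``last`` or an
    ``(n, H, W)`` per-frame stack for ``moving_average`` (window mean,
    truncated at the ends).
    """
    spec = spec or ReferenceSpec()
    if len(seq) == 0:
        raise ValueError("empty frame sequence")
    if spec.mode == "first":
        return seq.frames[0].copy()
    if spec.mode == "last":
        return seq.frames[-1].copy()
    if spec.window > len(seq):
        raise ValueError(
            f"moving-average window {spec.window} exceeds sequence "
            f"length {len(seq)}"
        )
    stack = np.stack(seq.frames)
    csum = np.cumsum(stack, axis=0)
    half = spec.window // 2
    n = len(seq)
    out = np.empty_like(stack)
    for k in range(n):
        lo, hi = max(0, k - half), min(n, k + half + 1)  # truncated window
        total = csum[hi - 1] - (csum[lo - 1] if lo > 0 else 0)
        out[k] = total / (hi - lo)
    return out


def difference_frame(frame: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Signed difference ``frame - reference``; isolates what changed."""
    if frame.shape != reference.shape:
        raise ValueError(
            f"shape mismatch: frame {frame.shape} vs reference "
            f"{reference.shape}"
        )
    return frame - reference


def smooth_frame(diff: np.ndarray, sigma: float) -> np.ndarray:
    """Gaussian spatial smoothing (reflect boundary, 3-sigma truncation)."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if sigma == 0:
        return diff.copy()
    return ndimage.gaussian_filter(diff, sigma=sigma, mode="reflect", truncate=3.0)


def normalize_polarity(
    diffs: list[np.ndarray],
    polarity: Literal["auto", "target_darker", "target_lighter"] = "auto",
) -> tuple[list[np.ndarray], Polarity]:
    """Flip sign if the target is lighter than background; clip residuals.

    A darker target yields negative difference values; a lighter one
    positive.  The stack is oriented so target intensity is always positive,
    then negative residuals are clipped to zero.  Auto-detection uses the
    sign of the extreme value over the whole stack (ties -> darker).
    """
    if not diffs:
        raise ValueError("empty difference stack")
    if polarity == "auto":
        lo = min(float(d.min()) for d in diffs)
        hi = max(float(d.max()) for d in diffs)
        detected: Polarity = "target_lighter" if hi > -lo else "target_darker"
    else:
        detected = polarity
    sign = -1.0 if detected == "target_darker" else 1.0
    return [np.clip(sign * d, 0.0, None) for d in diffs], detected


def load_mask(path: str | Path, shape: tuple[int, int]) -> np.ndarray:
    """Read a static mask image (PNG/BMP); nonzero = keep."""
    import imageio.v3 as iio

    mask = to_grey(iio.imread(path)) > 0
    if mask.shape != shape:
        raise ValueError(
            f"mask shape {mask.shape} does not match frame shape {shape}"
        )
    return mask


def apply_masks(
    diff: np.ndarray,
    source_frame: np.ndarray,
    config: PreprocessConfig,
    static_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Zero irrelevant regions: static mask and/or bright-overlay pixels."""
    out = diff.copy()
    if static_mask is not None:
        if static_mask.shape != diff.shape:
            raise ValueError(
                f"mask shape {static_mask.shape} does not match "
                f"{diff.shape}"
            )
        out[static_mask == 0] = 0.0
    if config.clean_white:
        out[source_frame > config.white] = 0.0
    return out


def _contains_target(
    diff: np.ndarray, thresh_mask: float, thresh_trim: float
) -> bool:
    """A frame contains the target if some connected supra-``thresh_mask``
    region peaks above ``thresh_trim``."""
    binary = diff > thresh_mask
    if not binary.any():
        return False
    labels, n = ndimage.label(binary, structure=np.ones((3, 3), dtype=int))
    peaks = ndimage.maximum(diff, labels, index=np.arange(1, n + 1))
    return bool(np.max(peaks) > thresh_trim)


def trim_frames(
    diffs: list[np.ndarray],
    thresh_mask: float,
    thresh_trim: float,
    disable_trim: bool = False,
) -> np.ndarray:
    """Flag the contiguous frame span containing the target.

    Frames before the first and after the last target-containing frame are
    dropped; interior frames are kept even if momentarily empty (trimming
    only removes from the ends).
    """
    if not diffs:
        raise ValueError("empty difference stack")
    n = len(diffs)
    if disable_trim:
        return np.ones(n, dtype=bool)
    hits = [
        _contains_target(d, thresh_mask, thresh_trim) for d in diffs
    ]
    if not any(hits):
        raise ValueError(
            "no frame contains the target at the current thresholds "
            f"(thresh_mask={thresh_mask}, thresh_trim={thresh_trim}); "
            "lower the thresholds or set disable_trim"
        )
    first = hits.index(True)
    last = n - 1 - hits[::-1].index(True)
    retained = np.zeros(n, dtype=bool)
    retained[first : last + 1] = True
    return retained


def preprocess(
    seq: FrameSequence,
    refspec: ReferenceSpec | None = None,
    config: PreprocessConfig | None = None,
    reference: np.ndarray | None = None,
) -> DifferenceStack:
    """Run the full isolation pipeline on a sampled sequence.

    Order: subtract reference -> Gaussian smooth -> polarity normalization
    -> masks -> end trimming.  A precomputed ``reference`` may be supplied
    to reuse across STL and path passes.
    """
    config = config or PreprocessConfig()
    if reference is None:
        reference = compute_reference(seq, refspec)
    per_frame_ref = reference.ndim == 3

    static_mask = None
    if config.do_mask:
        static_mask = load_mask(config.mask_path, seq.shape)

    signed = []
    for k, frame in enumerate(seq.frames):
        ref_k = reference[k] if per_frame_ref else reference
        signed.append(smooth_frame(difference_frame(frame, ref_k), config.smooth_sigma))
    diffs, polarity = normalize_polarity(signed, config.polarity)
    diffs = [
        apply_masks(d, f, config, static_mask)
        for d, f in zip(diffs, seq.frames)
    ]
    retained = trim_frames(
        diffs, config.thresh_mask, config.thresh_trim, config.disable_trim
    )
    return DifferenceStack(
        diffs=diffs,
        retained=retained,
        timestamps=list(seq.timestamps),
        polarity=polarity,
        pps=seq.pps,
    )
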