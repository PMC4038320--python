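"""Time-to-color mapping, frame averaging, and STL image composition.

Each retained frame gets a time-specific fully-saturated hue; the colorized
frames are averaged into a single layer, its saturation is amplified for
visibility, and the layer is composited over the (saturation-boosted)
reference frame.  Three legend bars are drawn at the bottom left: a bar whose
length equals a fixed amount of real time, a per-frame black/white strip
flagging frames that strongly overlap their neighbour (pauses), and the
time-color mapping itself.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from skimage import color as skcolor

__all__ = [
    "TimeColormap",
    "STLImage",
    "build_time_colormap",
    "colorize_frame",
    "average_colorized",
    "amplify_saturation",
    "compute_overlap",
    "overlap_flags",
    "compose_stl",
    "export_image",
]


@dataclass
class TimeColormap:
    """Retained-frame index -> RGB color, over ``cycles`` hue-wheel cycles."""

    n: int
    cycles: float
    colors: np.ndarray  # (n, 3) RGB in [0, 1]

    def __getitem__(self, k: int) -> np.ndarray:
        return self.colors[k]

    def hue(self, k: int) -> float:
        """Hue in [0, 1) assigned to retained frame ``k``."""
        if self.n == 1:
            return 0.0
        return (k / (self.n - 1) * self.cycles) % 1.0


@dataclass
class STLImage:
    """Composited STL image plus its legend geometry."""

    pixels: np.ndarray  # (H, W, 3) RGB in [0, 1]
    time_bar_px: int
    overlap: np.ndarray  # bool per retained frame
    colormap: TimeColormap


def build_time_colormap(n: int, cycles: float = 1.0) -> TimeColormap:
    """Assign each of ``n`` retained frames a fully saturated hue.

    Hues advance linearly so the wheel is traversed ``cycles`` times from the
    first to the last frame (wrapping past 1).  One or two cycles are
    typical; two make fine temporal structure easier to distinguish at the
    cost of an ambiguous global direction.
    """
    if n < 1:
        raise ValueError("need at least one retained frame")
    if cycles <= 0:
        raise ValueError("cycles must be positive")
    k = np.arange(n)
    hue = (k / max(n - 1, 1) * cycles) % 1.0
    hsv = np.stack([hue, np.ones(n), np.ones(n)], axis=-1)
    colors = skcolor.hsv2rgb(hsv[None])[0]
    return TimeColormap(n=n, cycles=cycles, colors=colors)


def colorize_frame(
    diff: np.ndarray, rgb: np.ndarray, thresh_mask: float
) -> np.ndarray:
    """Paint supra-threshold pixels in the frame's color.

    Returns an ``(H, W, 4)`` RGBA layer: alpha is the per-frame-normalized
    difference intensity where ``diff > thresh_mask`` (faint detections
    contribute proportionally), zero elsewhere.
    """
    keep = diff > thresh_mask
    alpha = np.zeros(diff.shape, dtype=np.float64)
    if keep.any():
        alpha[keep] = diff[keep] / diff[keep].max()
    out = np.zeros(diff.shape + (4,), dtype=np.float64)
    out[..., :3] = np.asarray(rgb, dtype=np.float64)
    out[..., 3] = alpha
    out[..., :3] *= alpha[..., None]  # premultiplied
    return out


def average_colorized(frames: list[np.ndarray]) -> np.ndarray:
    """Average colorized frames into one RGBA layer.

    The mean is taken over premultiplied color (transparent pixels contribute
    zero), so a position occupied in one of *n* frames keeps its own hue at
    1/n intensity before saturation amplification.
    """
    if not frames:
        raise ValueError("no colorized frames to average")
    return np.mean(np.stack(frames), axis=0)


def amplify_saturation(img: np.ndarray, factor: float) -> np.ndarray:
    """Scale HSV saturation by ``factor`` (clipped to 1), keep hue and value."""
    if factor < 0:
        raise ValueError("factor must be >= 0")
    rgb = img[..., :3] if img.shape[-1] == 4 else img
    hsv = skcolor.rgb2hsv(np.clip(rgb, 0.0, 1.0))
    hsv[..., 1] = np.clip(hsv[..., 1] * factor, 0.0, 1.0)
    out = skcolor.hsv2rgb(hsv)
    if img.shape[-1] == 4:
        out = np.concatenate([out, img[..., 3:]], axis=-1)
    return out


def compute_overlap(
    diff_a: np.ndarray, diff_b: np.ndarray, thresh_mask: float
) -> float:
    """Fraction of the smaller supra-threshold region shared by both frames.

    ``|A & B| / min(|A|, |B|)``; 0 if either region is empty.  Near 1 when
    the target barely moved between the frames (a pause).
    """
    if diff_a.shape != diff_b.shape:
        raise ValueError(f"shape mismatch: {diff_a.shape} vs {diff_b.shape}")
    a = diff_a > thresh_mask
    b = diff_b > thresh_mask
    na, nb = int(a.sum()), int(b.sum())
    if na == 0 or nb == 0:
        return 0.0
    return float(np.logical_and(a, b).sum() / min(na, nb))


def overlap_flags(
    diffs: list[np.ndarray], thresh_mask: float, thresh_adjac: float
) -> np.ndarray:
    """Per-frame flag: does this frame overlap its successor above threshold?

    The last frame reuses the overlap with its predecessor so the strip has
    one entry per retained frame.
    """
    n = len(diffs)
    if n == 1:
        return np.array([True])
    adj = np.array(
        [
            compute_overlap(diffs[k], diffs[k + 1], thresh_mask)
            for k in range(n - 1)
        ]
    )
    flags = np.empty(n, dtype=bool)
    flags[:-1] = adj >= thresh_adjac
    flags[-1] = flags[-2]
    return flags


_BAR_GAP = 2  # px between legend bars
_BAR_MARGIN = 4  # px from image edges


def compose_stl(
    avg: np.ndarray,
    reference: np.ndarray,
    oversat_ref: float,
    colormap: TimeColormap,
    overlap: np.ndarray,
    time_bar_s: float = 10.0,
    bar_size: int = 4,
    pps: float = 1.0,
    oversat_col: float = 1.0,
) -> STLImage:
    """Composite the averaged color layer over the reference and add legends.

    The color layer's saturation is amplified by ``oversat_col`` and alpha-
    blended over the grey reference (whose own saturation is boosted by
    ``oversat_ref``) using the layer's aggregate alpha, rescaled so the
    strongest detection is fully opaque.  Legend bars (height ``bar_size``)
    are stacked bottom-left: real-time bar of ``time_bar_s`` seconds, the
    black/white overlap strip, and the colormap strip; one retained frame
    occupies a fixed number of columns in the strips, making the three bars
    mutually comparable.
    """
    if reference.ndim == 2:
        ref_rgb = np.repeat(reference[..., None], 3, axis=-1)
    else:
        ref_rgb = reference
    ref_rgb = amplify_saturation(ref_rgb, oversat_ref)

    colorized = amplify_saturation(avg, oversat_col)
    alpha = colorized[..., 3] if colorized.shape[-1] == 4 else np.zeros(
        colorized.shape[:2]
    )
    rgbsum = colorized[..., :3]
    amax = alpha.max()
    # un-premultiply to recover each pixel's hue, then blend with the
    # aggregate alpha scaled so the strongest detection is fully opaque
    unprem = np.where(alpha[..., None] > 0, rgbsum / np.maximum(alpha, 1e-12)[..., None], 0.0)
    a = (alpha / amax)[..., None] if amax > 0 else alpha[..., None]
    out = ref_rgb * (1.0 - a) + unprem * a

    h, w = out.shape[:2]
    n = colormap.n
    ppf = max(1, int((w - 2 * _BAR_MARGIN) // max(n, 1)))  # px per frame
    strip_len = min(ppf * n, w - 2 * _BAR_MARGIN)
    time_bar_px = int(round(time_bar_s * pps * ppf))
    time_bar_px = max(1, min(time_bar_px, w - 2 * _BAR_MARGIN))

    x0 = _BAR_MARGIN
    y_cmap = h - _BAR_MARGIN - bar_size
    y_olap = y_cmap - _BAR_GAP - bar_size
    y_time = y_olap - _BAR_GAP - bar_size

    out[y_time : y_time + bar_size, x0 : x0 + time_bar_px] = 1.0
    for k in range(n):
        seg = slice(x0 + k * ppf, min(x0 + (k + 1) * ppf, x0 + strip_len))
        out[y_olap : y_olap + bar_size, seg] = 1.0 if overlap[k] else 0.0
        out[y_cmap : y_cmap + bar_size, seg] = colormap.colors[k]

    return STLImage(
        pixels=np.clip(out, 0.0, 1.0),
        time_bar_px=time_bar_px,
        overlap=np.asarray(overlap, dtype=bool),
        colormap=colormap,
    )


def export_image(
    img: STLImage | np.ndarray, out_dir: str | Path, stem: str,
    suffix: str = "stl",
) -> Path:
    """Write an image as ``<stem>_<suffix>.png`` in ``out_dir`` (created if
    needed); returns the path."""
    import imageio.v3 as iio

    pixels = img.pixels if isinstance(img, STLImage) else img
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / f"{stem}_{suffix}.png"
    iio.imwrite(path, (np.clip(pixels, 0.0, 1.0) * 255.0).round().astype(np.uint8))
    return path
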