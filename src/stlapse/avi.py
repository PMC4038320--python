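"""Minimal uncompressed AVI (RIFF) reader and writer.

Uncompressed AVI is the reference interchange format for this toolbox: frames
are stored as 24-bit bottom-up BGR device-independent bitmaps (biCompression
BI_RGB) in ``00db`` chunks, so reading requires no codec.  The writer emits a
single-stream, index-terminated RIFF file that this reader (and common players)
can open.  Only features needed for that profile are implemented.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = ["AviInfo", "read_avi", "write_avi", "is_uncompressed_avi"]


@dataclass(frozen=True)
class AviInfo:
    """Shape and timing metadata of an AVI file."""

    width: int
    height: int
    fps: float
    n_frames: int


def _pad_width(width: int) -> int:
    # DIB rows are padded to 4-byte boundaries
    return (width * 3 + 3) & ~3


def is_uncompressed_avi(path: str | Path) -> bool:
    """True if *path* looks like a RIFF AVI file (any codec)."""
    try:
        with open(path, "rb") as fh:
            head = fh.read(12)
    except OSError:
        return False
    return len(head) == 12 and head[:4] == b"RIFF" and head[8:12] == b"AVI "


def write_avi(path: str | Path, frames: np.ndarray, fps: float) -> Path:
    """Write frames as an uncompressed (BI_RGB) AVI.

    Parameters
    ----------
    frames
        Array of shape ``(n, H, W)`` (grey) or ``(n, H, W, 3)`` (RGB).
        Float arrays are interpreted on [0, 1]; integer arrays on [0, 255].
    fps
        Frames per second recorded in the stream header.
    """
    frames = np.asarray(frames)
    if frames.ndim == 3:
        frames = np.repeat(frames[..., None], 3, axis=-1)
    if frames.ndim != 4 or frames.shape[-1] != 3:
        raise ValueError(f"expected (n, H, W[, 3]) frames, got {frames.shape}")
    if np.issubdtype(frames.dtype, np.floating):
        frames = (np.clip(frames, 0.0, 1.0) * 255.0).round().astype(np.uint8)
    else:
        frames = frames.astype(np.uint8)

    n, height, width, _ = frames.shape
    row_bytes = _pad_width(width)
    frame_bytes = row_bytes * height
    usec_per_frame = int(round(1_000_000 / fps))

    avih = struct.pack(
        "<14I",
        usec_per_frame,  # dwMicroSecPerFrame
        frame_bytes * int(fps),  # dwMaxBytesPerSec (approximate)
        0,  # dwPaddingGranularity
        0x10,  # dwFlags: AVIF_HASINDEX
        n,  # dwTotalFrames
        0,  # dwInitialFrames
        1,  # dwStreams
        frame_bytes,  # dwSuggestedBufferSize
        width,
        height,
        0, 0, 0, 0,  # reserved
    )
    # fccType, fccHandler, flags, prio+lang, init frames, scale, rate,
    # start, length, bufsize, quality, sample size, rcFrame
    strh = struct.pack(
        "<4s4sI2HI2I3IiI4H",
        b"vids", b"DIB ", 0, 0, 0, 0,
        1_000_000, int(round(fps * 1_000_000)),
        0, n, frame_bytes, -1, 0,
        0, 0, width, height,
    )
    # BITMAPINFOHEADER; positive height => bottom-up rows
    strf = struct.pack(
        "<I2i2H2I2i2I",
        40, width, height, 1, 24, 0, frame_bytes, 0, 0, 0, 0,
    )

    def chunk(fourcc: bytes, payload: bytes) -> bytes:
        pad = b"\x00" if len(payload) % 2 else b""
        return fourcc + struct.pack("<I", len(payload)) + payload + pad

    def list_chunk(fourcc: bytes, payload: bytes) -> bytes:
        return chunk(b"LIST", fourcc + payload)

    strl = list_chunk(b"strl", chunk(b"strh", strh) + chunk(b"strf", strf))
    hdrl = list_chunk(b"hdrl", chunk(b"avih", avih) + strl)

    movi_payload = b"movi"
    index_entries = []
    for frame in frames:
        bgr = frame[::-1, :, ::-1]  # bottom-up rows, BGR channel order
        if row_bytes != width * 3:
            padded = np.zeros((height, row_bytes), dtype=np.uint8)
            padded[:, : width * 3] = bgr.reshape(height, width * 3)
            payload = padded.tobytes()
        else:
            payload = bgr.tobytes()
        index_entries.append((len(movi_payload) - 4, len(payload)))
        movi_payload += chunk(b"00db", payload)
    movi = chunk(b"LIST", movi_payload)

    idx1 = b"".join(
        struct.pack("<4s3I", b"00db", 0x10, off + 4, size)
        for off, size in index_entries
    )
    riff_payload = b"AVI " + hdrl + movi + chunk(b"idx1", idx1)

    path = Path(path)
    with open(path, "wb") as fh:
        fh.write(b"RIFF" + struct.pack("<I", len(riff_payload)) + riff_payload)
    return path


def _iter_chunks(buf: bytes, start: int, end: int):
    pos = start
    while pos + 8 <= end:
        fourcc = buf[pos : pos + 4]
        (size,) = struct.unpack_from("<I", buf, pos + 4)
        yield fourcc, pos + 8, size
        pos += 8 + size + (size & 1)


def read_avi(path: str | Path) -> tuple[np.ndarray, AviInfo]:
    """Read an uncompressed AVI into an ``(n, H, W, 3)`` uint8 RGB array."""
    buf = Path(path).read_bytes()
    if len(buf) < 12 or buf[:4] != b"RIFF" or buf[8:12] != b"AVI ":
        raise ValueError(f"{path}: not a RIFF AVI file")

    width = height = None
    rate = scale = None
    bit_count = None
    compression = None
    frame_payloads: list[tuple[int, int]] = []

    def walk(start: int, end: int) -> None:
        nonlocal width, height, rate, scale, bit_count, compression
        for fourcc, off, size in _iter_chunks(buf, start, end):
            if fourcc == b"LIST":
                walk(off + 4, off + size)
            elif fourcc == b"avih":
                _, _, _, _, _, _, _, _, width, height = struct.unpack_from(
                    "<10I", buf, off
                )
            elif fourcc == b"strh" and buf[off : off + 4] == b"vids":
                scale, rate = struct.unpack_from("<2I", buf, off + 20)
            elif fourcc == b"strf" and bit_count is None:
                _, _, _, _, bit_count, compression = struct.unpack_from(
                    "<I2i2HI", buf, off
                )
            elif fourcc in (b"00db", b"00dc") and size > 0:
                frame_payloads.append((off, size))

    walk(12, len(buf))

    if width is None or height is None:
        raise ValueError(f"{path}: missing AVI main header")
    if compression not in (0, None):
        raise ValueError(
            f"{path}: compressed AVI (biCompression={compression}) is not "
            "supported; convert to uncompressed AVI first"
        )
    if bit_count not in (24, 32):
        raise ValueError(f"{path}: unsupported bit depth {bit_count}")
    fps = (rate / scale) if rate and scale else 25.0

    row_bytes = _pad_width(width) if bit_count == 24 else width * 4
    nch = 3 if bit_count == 24 else 4
    frames = np.empty((len(frame_payloads), height, width, 3), dtype=np.uint8)
    for i, (off, size) in enumerate(frame_payloads):
        if size < row_bytes * height:
            raise ValueError(f"{path}: truncated frame chunk {i}")
        rows = np.frombuffer(buf, np.uint8, row_bytes * height, off)
        rows = rows.reshape(height, row_bytes)[:, : width * nch]
        bgr = rows.reshape(height, width, nch)[::-1, :, :3]
        frames[i] = bgr[..., ::-1]
    info = AviInfo(width=width, height=height, fps=fps, n_frames=len(frames))
    return frames, info
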