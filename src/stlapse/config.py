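"""Run configuration and end-to-end pipeline orchestration.

Setting names deliberately match the original toolbox's italicized
configuration variables (``startFrame``, ``threshMask``, ``oversatCol``, ...)
so users migrating a working configuration can carry values across verbatim.
The file format is flat YAML key-value pairs.
"""

from __future__ import annotations

import logging
import time
import warnings
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from . import colorize, kinematics, path_analysis, preprocess, video_io

logger = logging.getLogger("stlapse")

__all__ = ["RunConfig", "load_config", "run_pipeline"]

_COLOR_NAMES = {
    "black": (0.0, 0.0, 0.0),
    "white": (1.0, 1.0, 1.0),
}


@dataclass
class RunConfig:
    """All user-adjustable settings, grouped as in the pipeline stages.

    Input: ``path_raw`` video file; ``sampling`` keeps every i-th frame for
    the STL image; ``startFrame``/``endFrame`` give an inclusive 0-based
    frame range (set ``oneBased`` for parity with the original MATLAB
    toolbox's 1-based indices); ``videospeed`` is the real-time multiplier
    of the footage.

    Reference: ``refFrame`` in {first, last, moving_average}; ``refSmooth``
    is the moving-average window in frames (odd).

    Pre-processing: ``smooth`` Gaussian sigma in px; ``doMask``/``maskName``
    static mask; ``cleanWhite``/``white`` bright-overlay removal;
    ``threshMask``/``threshTrim`` intensity thresholds on [0, 1];
    ``disableTrim`` keeps all frames.

    Rendering: ``cmap`` color cycles; ``oversatCol``/``oversatRef``
    saturation gains for the color layer and the reference; ``timeBar``
    seconds of real time the first legend bar spans; ``threshAdjac``
    overlap fraction above which a frame is flagged as pausing; ``barSize``
    legend bar height in px; ``showSTL`` is accepted for compatibility (no
    interactive display in this implementation).

    Path: ``doPath`` toggle; ``pathSampling`` positions/s for tracking
    (often higher than the STL rate); ``pathBack`` background for the path
    image ("stl" or "ref"); ``pathCol`` marker border color; ``areamin``
    minimum component area in px²; ``px2m`` meters per pixel.

    Kinematics: ``doVel`` toggle (requires ``doPath``); ``velSmooth``
    odd-length nonnegative weights summing to 1.

    Output: ``path_out`` folder for all generated files.
    """

    path_raw: str | None = None
    sampling: int = 30
    startFrame: int | None = None
    endFrame: int | None = None
    oneBased: bool = False
    videospeed: float = 1.0

    refFrame: str = "first"
    refSmooth: int = 5

    smooth: float = 2.0
    doMask: bool = False
    maskName: str | None = None
    cleanWhite: bool = False
    white: float = 0.95
    threshMask: float = 0.1
    threshTrim: float = 0.2
    disableTrim: bool = False
    polarity: str = "auto"

    cmap: float = 1.0
    oversatCol: float = 2.0
    oversatRef: float = 1.0
    timeBar: float = 10.0
    threshAdjac: float = 0.5
    barSize: int = 4
    showSTL: bool = False

    doPath: bool = True
    pathSampling: float = 6.0
    pathBack: str = "stl"
    pathCol: Any = "black"
    areamin: int = 10
    px2m: float | None = None

    doVel: bool = True
    velSmooth: list[float] = field(
        default_factory=lambda: list(kinematics.DEFAULT_WEIGHTS)
    )

    path_out: str = "stl_out"

    def validate(self) -> None:
        """Raise ``ValueError`` listing every violated constraint."""
        problems: list[str] = []
        for name in ("threshMask", "threshTrim", "white", "threshAdjac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                problems.append(f"{name} must be in [0, 1], got {v}")
        if self.sampling < 1:
            problems.append(f"sampling must be >= 1, got {self.sampling}")
        if self.videospeed <= 0:
            problems.append("videospeed must be positive")
        if self.refFrame not in ("first", "last", "moving_average"):
            problems.append(f"unknown refFrame {self.refFrame!r}")
        if self.smooth < 0:
            problems.append("smooth must be >= 0")
        if self.doMask and not self.maskName:
            problems.append("doMask requires maskName")
        if self.cmap <= 0:
            problems.append("cmap (color cycles) must be positive")
        if self.pathSampling <= 0:
            problems.append("pathSampling must be positive")
        if self.pathBack not in ("stl", "ref"):
            problems.append(f"pathBack must be 'stl' or 'ref', got {self.pathBack!r}")
        if self.areamin < 1:
            problems.append("areamin must be >= 1")
        if self.doVel and not self.doPath:
            problems.append("doVel requires doPath (kinematics needs the path)")
        w = np.asarray(self.velSmooth, dtype=float)
        if w.ndim != 1 or len(w) % 2 == 0 or np.any(w < 0) or not np.isclose(w.sum(), 1.0):
            problems.append(
                "velSmooth must be odd-length nonnegative weights summing to 1"
            )
        if problems:
            raise ValueError("invalid configuration:\n  " + "\n  ".join(problems))

    @property
    def marker_color(self) -> tuple[float, float, float]:
        if isinstance(self.pathCol, str):
            try:
                return _COLOR_NAMES[self.pathCol.lower()]
            except KeyError:
                raise ValueError(f"unknown pathCol {self.pathCol!r}") from None
        return tuple(float(c) for c in self.pathCol)

    def frame_range(self) -> tuple[int | None, int | None]:
        """0-based inclusive start/end, honoring the ``oneBased`` flag."""
        off = 1 if self.oneBased else 0
        start = None if self.startFrame is None else self.startFrame - off
        end = None if self.endFrame is None else self.endFrame - off
        return start, end


def load_config(path: str | Path | None = None, **overrides: Any) -> RunConfig:
    """Load and validate a YAML configuration file.

    Omitted keys take documented defaults; unknown keys produce a warning;
    invalid values raise a single error listing all violations.
    """
    known = {f.name for f in fields(RunConfig)}
    data: dict[str, Any] = {}
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, dict):
            raise ValueError(f"{path}: config must be a mapping of key: value")
        for key in list(loaded):
            if key not in known:
                warnings.warn(f"unknown configuration key {key!r} ignored",
                              stacklevel=2)
                loaded.pop(key)
        data.update(loaded)
    data.update({k: v for k, v in overrides.items() if v is not None})
    cfg = RunConfig(**data)
    cfg.validate()
    return cfg


def _preprocess_config(cfg: RunConfig) -> preprocess.PreprocessConfig:
    return preprocess.PreprocessConfig(
        smooth_sigma=cfg.smooth,
        do_mask=cfg.doMask,
        mask_path=cfg.maskName,
        clean_white=cfg.cleanWhite,
        white=cfg.white,
        thresh_mask=cfg.threshMask,
        thresh_trim=cfg.threshTrim,
        disable_trim=cfg.disableTrim,
        polarity=cfg.polarity,
    )


def _stage(name: str):
    logger.info("stage %s", name)
    return time.perf_counter()


def run_pipeline(cfg: RunConfig) -> dict[str, Any]:
    """Execute the full pipeline on ``cfg.path_raw``.

    Stages: load/sample -> isolate target -> colorize/average -> compose and
    export the STL image; optionally track the path (image + CSV) and
    compute kinematics (plot + CSV).  Returns a summary with timing rates,
    the retained span, path statistics and the paths of all written files.
    """
    cfg.validate()
    if not cfg.path_raw:
        raise ValueError("path_raw is not set")
    stem = Path(cfg.path_raw).stem
    out_dir = Path(cfg.path_out)
    refspec = preprocess.ReferenceSpec(mode=cfg.refFrame, window=cfg.refSmooth)
    pconf = _preprocess_config(cfg)
    start, end = cfg.frame_range()

    t0 = _stage("A: load video")
    seq = video_io.load_video(
        cfg.path_raw, cfg.sampling, start, end, cfg.videospeed
    )
    logger.info(
        "source %.6g fps; STL sampled at %.6g pps", seq.fps_source, seq.pps
    )

    _stage("B: pre-process")
    reference = preprocess.compute_reference(seq, refspec)
    stack = preprocess.preprocess(seq, refspec, pconf, reference=reference)
    ret = stack.retained_indices
    logger.info(
        "retained frames %d..%d of %d (%.1f s of %.1f s)",
        ret[0], ret[-1], len(stack),
        stack.retained_timestamps()[-1] - stack.retained_timestamps()[0],
        seq.duration,
    )

    _stage("C-E: colorize and compose")
    diffs = stack.retained_diffs()
    cmap = colorize.build_time_colormap(len(diffs), cfg.cmap)
    layers = [
        colorize.colorize_frame(d, cmap.colors[k], cfg.threshMask)
        for k, d in enumerate(diffs)
    ]
    avg = colorize.average_colorized(layers)
    flags = colorize.overlap_flags(diffs, cfg.threshMask, cfg.threshAdjac)
    ref_for_display = reference if reference.ndim == 2 else reference[0]
    stl = colorize.compose_stl(
        avg, ref_for_display, cfg.oversatRef, cmap, flags,
        time_bar_s=cfg.timeBar, bar_size=cfg.barSize, pps=seq.pps,
        oversat_col=cfg.oversatCol,
    )
    stl_path = colorize.export_image(stl, out_dir, stem)
    outputs = {"stl_image": stl_path}
    summary: dict[str, Any] = {
        "fps_source": seq.fps_source,
        "pps": seq.pps,
        "n_sampled": len(stack),
        "retained_span": (int(ret[0]), int(ret[-1])),
        "outputs": outputs,
    }

    if cfg.doPath:
        _stage("F: path analysis")
        stride = max(
            1, int(round(seq.fps_source / (cfg.pathSampling * cfg.videospeed)))
        )
        pseq = video_io.load_video(
            cfg.path_raw, stride, start, end, cfg.videospeed
        )
        pstack = preprocess.preprocess(pseq, refspec, pconf)
        track = path_analysis.extract_path(
            pstack, cfg.pathSampling, cfg.threshTrim, cfg.areamin, cfg.px2m
        )
        logger.info(
            "path: %d samples at %.6g pps, length %.2f %s over %.2f s",
            len(track), track.path_pps, track.path_length, track.units,
            track.duration,
        )
        background = stl.pixels if cfg.pathBack == "stl" else ref_for_display
        draw = track
        if track.units == "meters":
            draw = path_analysis.PathTrack(
                t=track.t, x=track.x / cfg.px2m, y=track.y / cfg.px2m,
                units="pixels", path_pps=track.path_pps,
            )
        path_img = path_analysis.render_path(
            draw, background, cmap, cfg.marker_color
        )
        outputs["path_image"] = colorize.export_image(
            path_img, out_dir, stem, suffix="path"
        )
        outputs["path_csv"] = path_analysis.write_track_csv(track, out_dir, stem)
        summary["path_length"] = track.path_length
        summary["path_units"] = track.units
        summary["duration"] = track.duration

        if cfg.doVel:
            _stage("G: kinematics")
            series = kinematics.compute_kinematics(track, cfg.velSmooth)
            outputs["vel_plot"] = kinematics.render_velocity_plot(
                series, out_dir, stem
            )
            outputs["vel_csv"] = kinematics.write_kinematics_csv(
                series, out_dir, stem
            )
            summary["mean_velocity"] = float(np.mean(series.velocity))
    return summary
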