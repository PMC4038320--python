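# Methods

## The spectral time-lapse model

`stlapse` summarizes the movement of a single animal in a pre-recorded video
as one image: the target's position at each sampled time is painted in a
time-specific color and overlaid on a reference frame of the video, so both
*where* and *when* are visible at once.  The same isolated-target maps drive
markerless tracking: per-frame position, total path length, duration, and
instantaneous velocity/acceleration.

The method assumes a single compact target moving over a mostly static
background, recorded by a stationary camera.  It performs background
subtraction, not object recognition: anything that differs from the
reference is "the target", which is why the largest connected component and
an area floor are used to reject residual noise.  Multiple targets,
occlusion recovery and lens-distortion correction are out of scope.

## Pipeline

1. **Load and sample.** Every *i*-th frame (`sampling`) of the requested
   0-based inclusive frame range is converted to grey (luma weights
   0.299/0.587/0.114) on [0, 1].  Timestamps are real-world seconds:
   `index / fps * videospeed`, where `videospeed` is the real-time
   multiplier of the footage (0.1 for a 10x-slowed high-speed recording).
   The effective positions-per-second is `pps = fps / sampling / videospeed`.
   Uncompressed AVI (RIFF 'DIB ' bitmaps) is decoded by the package itself;
   other containers go through imageio when a video plugin is installed.
2. **Reference.** First frame, last frame, or a per-frame moving average
   (window `refSmooth`, odd, truncated at the ends).  The moving average
   tolerates slow background change at the cost of partially subtracting a
   slow-moving target.
3. **Isolation.** Subtract the reference, Gaussian-smooth (sigma `smooth`
   px, reflect boundary, 3-sigma truncation — reflect avoids dark halos at
   frame edges), flip sign if the target is lighter than background (auto
   polarity = sign of the extreme summed difference, overridable), zero
   masked pixels (static mask image and/or source pixels brighter than
   `white`, which removes burnt-in timestamps), then trim.
4. **Trimming.** A frame "contains the target" when its difference map,
   binarized at `threshMask`, has a connected component whose peak exceeds
   `threshTrim`.  Retention is the contiguous span from the first to the
   last such frame: trimming removes only lead/tail frames, interior lulls
   are kept.  This peak-per-component criterion is one concrete choice for
   "sufficiently different from the reference"; it is monotone in both
   thresholds, but other toolboxes may binarize or count differently, so
   threshold values are not portable across implementations.
5. **Colorize and compose.** Retained frame *k* of *n* gets HSV hue
   `frac(k/(n-1) * cmap)` at full saturation/value; `cmap` is the number of
   hue-wheel cycles (1 by default; 2 doubles temporal resolution of the
   colors but makes global direction ambiguous).  Supra-`threshMask` pixels
   are painted with alpha proportional to the per-frame-normalized
   intensity, frames are averaged in premultiplied RGBA, saturation of the
   average is multiplied by `oversatCol`, and the layer is alpha-blended
   over the reference (its own saturation boosted by `oversatRef`) with the
   aggregate alpha rescaled so the strongest detection is opaque.  Pixels no
   frame touched are exactly the boosted reference.  Legend bars (height
   `barSize`, bottom-left, top to bottom): a white bar spanning `timeBar`
   seconds at the colormap strip's pixels-per-frame scale; a per-frame strip
   that is white where the thresholded region overlaps its neighbour's by at
   least `threshAdjac` (pauses) and black otherwise; the colormap itself.
   Overlap is intersection-over-minimum, which reads as "did the target stay
   where it was", and is less sensitive than IoU to size fluctuation of the
   thresholded blob.
6. **Path.** The position per frame is the unweighted centroid of the
   largest 8-connected supra-`threshTrim` component; components smaller than
   `areamin` px² yield "absent".  (An intensity-weighted centroid is
   available as an option and is roughly 2x more precise on the synthetic
   fixtures, but the binary centroid is the documented default because it is
   insensitive to the intensity profile of the target.)  Path extraction is
   usually run at a higher rate (`pathSampling`) than the STL image; leading
   and trailing absents re-determine the start/end, interior absents are
   linearly interpolated.  Path length is the polyline sum; with `px2m` set,
   coordinates and statistics are in meters.  Coordinates are 0-based pixel
   centers, origin top-left, y downward.
7. **Kinematics.** `v_k = |p_{k+1} - p_k| / dt` at interval midpoints
   (chord speed, a slight underestimate of arc speed, O(dt²));
   `a_k` is the finite difference of velocities at midpoints of midpoints.
   Both are smoothed by a centered weighted moving average (`velSmooth`,
   default (0.25, 0.5, 0.25); ends renormalize the truncated window).
   Velocities are smoothed before differencing so centroid jitter is not
   amplified twice.

## Parameters that matter

| name | unit | default | why |
|---|---|---|---|
| `sampling` | frames | 30 | 1 pps from a 30 fps camera; positions per second, not per frame, carry the behaviour |
| `smooth` | px (sigma) | 2.0 | ~1/3 of a radius-6 target; large enough to suppress pixel noise, small enough not to erode the blob |
| `threshMask` | intensity | 0.1 | noise floor of the smoothed difference |
| `threshTrim` | intensity | 0.2 | peak a real target reaches after smoothing |
| `areamin` | px² | 10 | rejects speckle components; well below a radius-6 target's ~110 px |
| `pathSampling` | positions/s | 6 | tracking benefits from a higher rate than the visualization |
| `velSmooth` | weights | (.25,.5,.25) | minimal binomial kernel; wider windows trade response time for noise |
| `cmap` | cycles | 1 | unambiguous time direction |
| `threshAdjac` | fraction | 0.5 | half the smaller region shared = "paused" |

## Synthetic fixtures

The generator renders what the pipeline assumes: a constant (or slowly
drifting) grey background, one disk- or Gaussian-profile target darker or
lighter than the background, parametric trajectories (stationary, linear,
circular, piecewise with pauses), empty lead/tail frames, optional additive
Gaussian pixel noise and a saturated overlay rectangle emulating a burnt-in
timestamp.  Disk edges are anti-aliased with linear sub-pixel coverage so
sub-pixel centroid recovery is meaningful; noise is applied after
compositing and clipped to [0, 1].  Generation is deterministic given the
seed.  It does **not** emulate deformable or rotating bodies, shadows,
specular reflections, interlacing, or compression artifacts — passing tests
demonstrate correctness of the algorithm, not robustness to every field
recording.

## Verification problem sizes and numerical choices

End-to-end checks run on a 320x240, 30 fps, 10 s recording with a radius-6
target — the scale of a desk behavioural setup.  Straight-line tracking at
6 positions/s recovers the path with ~0.1 px RMSE and path length within
0.1 % of the analytic value; at the full 30 pps the polyline inflates by
~1 % because centroid jitter accumulates on sub-pixel steps, which is why
the path rate, not the camera rate, is the accuracy dial.  Uniform-motion
acceleration is checked at 1 position/s, where the finite-difference noise
amplification (2/dt² times the position error) stays below 0.05 px/s² after
smoothing.  Trimming is exact on noise-free fixtures by construction of the
peak criterion.  Gaussian smoothing, component labelling/centroids and
weighted smoothing are verified against brute-force re-implementations
(direct convolution, BFS labelling, explicit weighted sums).

Degenerate inputs: a single retained frame maps to hue 0 (red); an all-zero
difference stack reports polarity `target_darker`; equal-area component
ties break by total intensity, then scan order; `smooth = 0` and
`oversat* = 1` are exact identities.

## Known limitations

Single target only; no occlusion handling (an occluded target splinters
into components and the largest may be wrong); no lens-distortion
correction (path lengths from wide-angle footage are biased); background
motion (bedding, reflections) can out-compete a small target unless masked;
the AVI reader handles only uncompressed RGB streams.
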