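"""Per-frame ellipse fitting, speed, and stretch-attend posture gating.

A stretch-attend posture (SAP) is an elongated, stationary (or slowly
creeping) body configuration.  Per frame, the segmented body is summarised
by the ellipse with matching second central moments; its eccentricity is
the elongation proxy.  A frame is SAP-positive when

* the body ellipse's eccentricity exceeds the eccentricity threshold
  (default 0.90 for an open field; 0.89 for an elevated plus maze), and
* the centroid speed does *not* exceed the speed threshold (default
  12 cm/s open field; 8 cm/s plus maze) — an elongated but fast animal is
  running, not stretch-attending.

Runs of positive frames no longer than half a second are then suppressed
(SAP is assumed never to last <= 0.5 s), and frames are aggregated to
seconds: a second is SAP-positive when at least one of its frames is.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .segmentation import MorphParams, binarize_frame, largest_component, remove_tail
from .video_io import VideoSequence

__all__ = [
    "BodyEllipse",
    "FrameTrack",
    "DetectionParams",
    "SapTrace",
    "SapSummary",
    "fit_ellipse",
    "track_frames",
    "detect_sap",
    "gate_frames",
    "suppress_short_runs",
    "frames_to_seconds",
    "min_bout_frames",
    "count_bouts",
    "summarize",
]


class EmptyRegionError(ValueError):
    """Raised when an ellipse is requested for an empty component."""


@dataclass(frozen=True)
class BodyEllipse:
    """Ellipse with the same normalised second central moments as a region.

    ``centroid_x_px`` is the column index, ``centroid_y_px`` the row index
    (0-based, sub-pixel).  ``orientation_rad`` is the angle of the major
    axis from the +x image axis (towards +y, i.e. clockwise on screen),
    in (-pi/2, pi/2].
    """

    centroid_x_px: float
    centroid_y_px: float
    major_axis_len_px: float
    minor_axis_len_px: float
    orientation_rad: float
    eccentricity: float
    area_px: int


@dataclass(frozen=True)
class FrameTrack:
    """Per-frame body shape and centroid speed for one video.

    ``eccentricity`` and the centroid arrays hold NaN on invalid frames
    (frames in which no animal was found).  ``speed_cms`` is assigned to
    the later frame of each consecutive *valid* pair; the first valid frame
    and the first valid frame after a gap get speed 0 (a reappearing still
    animal is not speed-vetoed).
    """

    eccentricity: np.ndarray
    speed_cms: np.ndarray
    valid: np.ndarray
    centroid_x_cm: np.ndarray
    centroid_y_cm: np.ndarray
    fps: float
    ellipses: Sequence[Optional[BodyEllipse]] = field(default=(), repr=False)

    @property
    def n_frames(self) -> int:
        return len(self.valid)


@dataclass(frozen=True)
class DetectionParams:
    """Thresholds of the SAP gate.

    Defaults are the open-field operating point (eccentricity > 0.90,
    speed <= 12 cm/s); for an elevated plus maze 0.89 and 8 cm/s are the
    established choice (mice bend into the open arms, shortening the
    ellipse, and have less room to gain speed).
    """

    ecc_threshold: float = 0.90
    speed_threshold_cms: float = 12.0
    fps: float = 10.0

    def __post_init__(self) -> None:
        if not 0 <= self.ecc_threshold < 1:
            raise ValueError("ecc_threshold must lie in [0, 1)")
        if self.speed_threshold_cms <= 0:
            raise ValueError("speed_threshold_cms must be positive")
        if self.fps <= 0:
            raise ValueError("fps must be positive")


@dataclass(frozen=True)
class SapTrace:
    """Binary SAP detection at frame and second resolution."""

    frame_flags: np.ndarray
    second_flags: np.ndarray
    fps: float


@dataclass(frozen=True)
class SapSummary:
    """Per-video SAP totals: duration, percentage, bouts, frequency."""

    duration_s: float
    sap_percent: float
    bouts: int
    freq_per_min: float
    video_length_s: float


def fit_ellipse(component: np.ndarray) -> BodyEllipse:
    """Fit the moment-equivalent ellipse to a binary region.

    The per-pixel coordinate covariance is computed with a +1/12 variance
    correction on both diagonal terms (each pixel is a unit square, not a
    point mass); axis lengths are ``4*sqrt(eigenvalue)``, so a rendered
    filled ellipse recovers its own generating axes.  Eccentricity is
    ``sqrt(1 - lambda2/lambda1)``, equal to ``sqrt(1 - (b/a)^2)`` of the
    equivalent ellipse.
    """
    ys, xs = np.nonzero(np.asarray(component, dtype=bool))
    n = len(xs)
    if n == 0:
        raise EmptyRegionError("empty region: cannot fit an ellipse")
    cx = xs.mean()
    cy = ys.mean()
    dx = xs - cx
    dy = ys - cy
    uxx = (dx @ dx) / n + 1.0 / 12.0
    uyy = (dy @ dy) / n + 1.0 / 12.0
    uxy = (dx @ dy) / n
    common = np.hypot(uxx - uyy, 2.0 * uxy)
    lam1 = (uxx + uyy + common) / 2.0
    lam2 = (uxx + uyy - common) / 2.0
    lam2 = max(lam2, 0.0)
    orientation = 0.5 * np.arctan2(2.0 * uxy, uxx - uyy)
    if orientation <= -np.pi / 2:
        orientation += np.pi
    return BodyEllipse(
        centroid_x_px=float(cx),
        centroid_y_px=float(cy),
        major_axis_len_px=float(4.0 * np.sqrt(lam1)),
        minor_axis_len_px=float(4.0 * np.sqrt(lam2)),
        orientation_rad=float(orientation),
        eccentricity=float(np.sqrt(1.0 - lam2 / lam1)),
        area_px=int(n),
    )


def track_frames(video: VideoSequence, seg_params: MorphParams) -> FrameTrack:
    """Segment and fit every frame, then derive centroid speeds.

    Each frame runs binarise -> opening (tail removal) -> largest
    component -> ellipse fit.  Speed on frame ``i`` is the centroid
    displacement from the previous frame times ``cm_per_px * fps``,
    assigned only across consecutive valid frames; after a gap (frames
    with no detectable animal) speed restarts at 0.
    """
    n = video.n_frames
    ecc = np.full(n, np.nan)
    cx_cm = np.full(n, np.nan)
    cy_cm = np.full(n, np.nan)
    valid = np.zeros(n, dtype=bool)
    ellipses: list[Optional[BodyEllipse]] = []
    scale = video.cm_per_px
    for i in range(n):
        mask = binarize_frame(video.frames[i], video.background, seg_params.binary_threshold)
        opened = remove_tail(mask, seg_params)
        component, found = largest_component(opened)
        if not found:
            ellipses.append(None)
            continue
        e = fit_ellipse(component)
        ellipses.append(e)
        ecc[i] = e.eccentricity
        cx_cm[i] = e.centroid_x_px * scale
        cy_cm[i] = e.centroid_y_px * scale
        valid[i] = True
    if not valid.any():
        raise ValueError("no animal detected in video")
    speed = np.zeros(n)
    prev: Optional[int] = None
    for i in range(n):
        if not valid[i]:
            prev = None
            continue
        if prev is not None and prev == i - 1:
            speed[i] = float(
                np.hypot(cx_cm[i] - cx_cm[prev], cy_cm[i] - cy_cm[prev]) * video.fps
            )
        prev = i
    return FrameTrack(
        eccentricity=ecc,
        speed_cms=speed,
        valid=valid,
        centroid_x_cm=cx_cm,
        centroid_y_cm=cy_cm,
        fps=video.fps,
        ellipses=tuple(ellipses),
    )


def min_bout_frames(fps: float) -> int:
    """Longest run length still suppressed by the half-second bout filter."""
    return int(round(fps / 2.0))


def suppress_short_runs(flags: np.ndarray, max_suppressed: int) -> np.ndarray:
    """Zero every maximal run of 1s of length <= ``max_suppressed``.

    Idempotent; never creates 1s.  ``max_suppressed`` <= 0 is the identity.
    """
    flags = np.asarray(flags).astype(np.int8)
    if max_suppressed <= 0 or flags.size == 0:
        return flags.copy()
    out = flags.copy()
    padded = np.concatenate([[0], out, [0]])
    edges = np.flatnonzero(np.diff(padded))
    starts, ends = edges[::2], edges[1::2]
    for s, e in zip(starts, ends):
        if e - s <= max_suppressed:
            out[s:e] = 0
    return out


def frames_to_seconds(frame_flags: np.ndarray, fps: float) -> np.ndarray:
    """At-least-one-frame aggregation of frame flags to per-second flags.

    Frame ``i`` belongs to second ``floor(i / fps)``.  A trailing partial
    second (when ``n_frames`` is not a multiple of ``fps``) is aggregated
    by the same rule.
    """
    frame_flags = np.asarray(frame_flags)
    if frame_flags.size == 0:
        return np.zeros(0, dtype=np.int8)
    sec_idx = np.floor(np.arange(len(frame_flags)) / fps).astype(int)
    out = np.zeros(sec_idx[-1] + 1, dtype=np.int8)
    np.maximum.at(out, sec_idx, frame_flags.astype(np.int8))
    return out


def gate_frames(
    eccentricity: np.ndarray,
    speed_cms: np.ndarray,
    valid: np.ndarray,
    params: DetectionParams,
) -> np.ndarray:
    """Apply the eccentricity gate, speed veto and bout filter to traces.

    Comparators follow the detector's definition exactly: SAP requires
    eccentricity strictly greater than the threshold, and speed strictly
    greater than the threshold vetoes the frame.  Invalid frames are
    non-SAP and break runs.
    """
    ecc = np.asarray(eccentricity, dtype=float)
    speed = np.asarray(speed_cms, dtype=float)
    valid = np.asarray(valid, dtype=bool)
    with np.errstate(invalid="ignore"):
        raw = valid & (ecc > params.ecc_threshold) & ~(speed > params.speed_threshold_cms)
    return suppress_short_runs(raw.astype(np.int8), min_bout_frames(params.fps))


def detect_sap(track: FrameTrack, params: DetectionParams) -> SapTrace:
    """Per-frame SAP gating plus frame-to-second aggregation."""
    if track.n_frames == 0:
        raise ValueError("no frames in track")
    frame_flags = gate_frames(track.eccentricity, track.speed_cms, track.valid, params)
    return SapTrace(
        frame_flags=frame_flags,
        second_flags=frames_to_seconds(frame_flags, params.fps),
        fps=params.fps,
    )


def count_bouts(frame_flags: np.ndarray) -> int:
    """Number of maximal runs of 1s."""
    padded = np.concatenate([[0], np.asarray(frame_flags, dtype=np.int8)])
    return int(np.sum(np.diff(padded) == 1))


def summarize(trace: SapTrace, fps: float) -> SapSummary:
    """Per-video totals: SAP duration (frames/fps), percentage, bout count
    and bout frequency per minute."""
    n = len(trace.frame_flags)
    video_length_s = n / fps
    duration_s = float(np.sum(trace.frame_flags)) / fps
    bouts = count_bouts(trace.frame_flags)
    return SapSummary(
        duration_s=duration_s,
        sap_percent=100.0 * duration_s / video_length_s if video_length_s else 0.0,
        bouts=bouts,
        freq_per_min=bouts / (video_length_s / 60.0) if video_length_s else 0.0,
        video_length_s=video_length_s,
    )
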