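"""Reading, writing and calibrating multi-page TIFF video stacks.

Overhead rodent videos are prepared as grayscale multi-page TIFFs cropped
1:1 to the arena, with a rodent-free image of the apparatus appended as the
*last* page.  That last page is the background used for subtraction; all
preceding pages are the analysed frames.  Intensities are normalised to
[0, 1] regardless of the source bit depth, so the binary-conversion
threshold is a dimensionless value in (0, 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import tifffile

__all__ = [
    "VideoFormatError",
    "VideoSequence",
    "ThresholdSweep",
    "load_video",
    "write_video",
    "sweep_thresholds",
]

#: Maximum relative disagreement tolerated between the horizontal and
#: vertical cm-per-pixel scales (videos are cropped to a 1:1 aspect ratio,
#: so the two should agree up to cropping round-off).
SQUARE_PIXEL_TOL = 0.02

MIN_DIM_PX = 8


class VideoFormatError(ValueError):
    """Raised when a video stack violates the expected layout."""


@dataclass(frozen=True)
class VideoSequence:
    """A calibrated grayscale frame stack with a designated background frame.

    Parameters
    ----------
    frames
        Array of shape ``(n_frames, height, width)`` with intensities in
        ``[0, 1]``.  The background frame is *not* included.
    background
        Rodent-free frame of shape ``(height, width)``.
    fps
        Acquisition rate in frames per second.
    arena_width_cm, arena_height_cm
        Physical extent of the (cropped) field of view.
    """

    frames: np.ndarray
    background: np.ndarray
    fps: float
    arena_width_cm: float
    arena_height_cm: float

    def __post_init__(self) -> None:
        frames = np.asarray(self.frames, dtype=float)
        background = np.asarray(self.background, dtype=float)
        if frames.ndim != 3 or len(frames) < 1:
            raise VideoFormatError("frames must be a non-empty (n, h, w) stack")
        if background.shape != frames.shape[1:]:
            raise VideoFormatError("background shape differs from frames")
        h, w = background.shape
        if h < MIN_DIM_PX or w < MIN_DIM_PX:
            raise VideoFormatError(f"frames must be at least {MIN_DIM_PX}x{MIN_DIM_PX} px")
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        if self.arena_width_cm <= 0 or self.arena_height_cm <= 0:
            raise ValueError("arena dimensions must be positive")
        sx = self.arena_width_cm / w
        sy = self.arena_height_cm / h
        if abs(sx - sy) > SQUARE_PIXEL_TOL * max(sx, sy):
            raise VideoFormatError(
                "non-square pixels: horizontal scale "
                f"{sx:.4g} cm/px vs vertical {sy:.4g} cm/px (>2% apart); "
                "crop the video 1:1 to the arena"
            )
        object.__setattr__(self, "frames", frames)
        object.__setattr__(self, "background", background)

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def height_px(self) -> int:
        return self.background.shape[0]

    @property
    def width_px(self) -> int:
        return self.background.shape[1]

    @property
    def cm_per_px(self) -> float:
        """Physical pixel pitch, derived from the arena width."""
        return self.arena_width_cm / self.width_px

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.fps


@dataclass(frozen=True)
class ThresholdSweep:
    """Foreground fraction of a background-subtracted frame per threshold."""

    thresholds: np.ndarray
    foreground_fraction: np.ndarray
    frame_index: int = 0

    def __post_init__(self) -> None:
        t = np.asarray(self.thresholds, dtype=float)
        f = np.asarray(self.foreground_fraction, dtype=float)
        if t.shape != f.shape:
            raise ValueError("thresholds and fractions differ in length")
        object.__setattr__(self, "thresholds", t)
        object.__setattr__(self, "foreground_fraction", f)


def _normalize_pages(pages: np.ndarray) -> np.ndarray:
    """Rescale raw page intensities to float in [0, 1] by the dtype maximum."""
    if np.issubdtype(pages.dtype, np.integer):
        info = np.iinfo(pages.dtype)
        return pages.astype(float) / info.max
    out = pages.astype(float)
    if out.size and (out.min() < 0 or out.max() > 1):
        raise VideoFormatError("float TIFF pages must already lie in [0, 1]")
    return out


def load_video(
    path,
    fps: float,
    arena_width_cm: float,
    arena_height_cm: float,
    invert: bool = False,
    background_path=None,
) -> VideoSequence:
    """Load a multi-page TIFF video with the background-as-last-page convention.

    Parameters
    ----------
    path
        Multi-page grayscale TIFF; the last page must be a rodent-free
        background image unless ``background_path`` overrides it.
    invert
        Set when the rodent is *darker* than the background; every intensity
        ``v`` becomes ``1 - v`` so downstream code can always assume a
        bright animal on a dark arena.
    background_path
        Optional separate single-page TIFF holding the background; when
        given, *all* pages of ``path`` are treated as frames.
    """
    with tifffile.TiffFile(path) as tif:
        shapes = {p.shape for p in tif.pages}
        if len(shapes) > 1:
            raise VideoFormatError("ragged stack: pages have differing dimensions")
        pages = tif.asarray()
    if pages.ndim == 2:
        pages = pages[None]
    if pages.ndim != 3:
        raise VideoFormatError("expected single-channel grayscale pages")
    pages = _normalize_pages(pages)

    if background_path is not None:
        background = _normalize_pages(np.atleast_2d(tifffile.imread(background_path)))
        if background.ndim == 3:
            background = background[0]
        frames = pages
    else:
        if len(pages) < 2:
            raise VideoFormatError(
                "no background frame: need at least 2 pages (frames + trailing background)"
            )
        frames, background = pages[:-1], pages[-1]

    if invert:
        frames = 1.0 - frames
        background = 1.0 - background
    return VideoSequence(
        frames=frames,
        background=background,
        fps=fps,
        arena_width_cm=arena_width_cm,
        arena_height_cm=arena_height_cm,
    )


def write_video(video: VideoSequence, path) -> str:
    """Write frames followed by the background as an 8-bit multi-page TIFF.

    Round-tripping through :func:`load_video` reproduces intensities within
    the 8-bit quantisation step (1/255 per pixel).
    """
    stack = np.concatenate([video.frames, video.background[None]], axis=0)
    as_u8 = np.round(np.clip(stack, 0.0, 1.0) * 255).astype(np.uint8)
    tifffile.imwrite(path, as_u8, photometric="minisblack")
    return str(path)


def subtract_background(frame: np.ndarray, background: np.ndarray) -> np.ndarray:
    """Background-subtracted intensity, clamped at zero.

    With a bright animal on a dark arena negative residuals carry no signal,
    so ``max(frame - background, 0)`` is used throughout.
    """
    if frame.shape != background.shape:
        raise ValueError("incompatible frames: shape mismatch")
    return np.clip(np.asarray(frame, dtype=float) - background, 0.0, None)


def sweep_thresholds(video: VideoSequence, frame_index: int, thresholds) -> ThresholdSweep:
    """Headless threshold previewer.

    For each candidate binary-conversion threshold, report the fraction of
    pixels of the background-subtracted sample frame that would be classed
    as foreground.  A sensible threshold leaves roughly the animal's
    silhouette (body area / frame area) as foreground.
    """
    thresholds = np.asarray(list(thresholds), dtype=float)
    if thresholds.size == 0:
        raise ValueError("no thresholds given")
    if np.any((thresholds <= 0) | (thresholds >= 1)):
        raise ValueError("thresholds must lie strictly in (0, 1)")
    if not 0 <= frame_index < video.n_frames:
        raise IndexError(f"frame_index {frame_index} out of range")
    order = np.argsort(thresholds)
    thresholds = thresholds[order]
    diff = subtract_background(video.frames[frame_index], video.background)
    fractions = np.array([(diff > t).mean() for t in thresholds])
    return ThresholdSweep(
        thresholds=thresholds, foreground_fraction=fractions, frame_index=frame_index
    )
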