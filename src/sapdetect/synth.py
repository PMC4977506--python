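"""Synthetic overhead rodent videos with analytic ground truth.

Scenes emulate the imaging conditions the detector is designed for: a
bright elongate mouse body on a dark square arena filmed from above, an
attached tapering tail, an optional painted floor grid, additive sensor
noise, and the background-appended-as-last-frame multi-page TIFF
convention.  The body is a filled ellipse whose semi-axes, heading and
centroid follow per-frame schedules, so eccentricity and speed — and hence
the stretch-attend-posture (SAP) label — are known *analytically* from the
schedules, never measured from the rendered pixels.  That separation means
a rendering change can never silently shift the labels the detector is
tested against.

Default geometry is an open-field-like 30 x 30 cm arena at 10 fps with an
adult-mouse body scale (roughly 8 cm nose-to-rump when elongated, matching
a 32-40 g animal).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import NamedTuple, Optional

import numpy as np

from .posture import DetectionParams, frames_to_seconds, gate_frames
from .video_io import VideoSequence

__all__ = [
    "SynthScenario",
    "GroundTruth",
    "RenderedScenario",
    "render_scenario",
    "standard_suite",
    "threshold_grid_scenario",
]

DEFAULT_ARENA_CM = 30.0
DEFAULT_WIDTH_PX = 200
DEFAULT_FPS = 10.0

# Adult-mouse body scale: semi-axes of the body ellipse in cm.
ROUND_AXES_CM = (1.5, 1.5)
ELONGATED_AXES_CM = (2.4, 0.75)  # eccentricity sqrt(1-(0.75/2.4)^2) = 0.950


@dataclass(frozen=True)
class SynthScenario:
    """Full parametric description of one synthetic video.

    Per-frame schedules (`a_cm`, `b_cm`, `heading_rad`, `x_cm`, `y_cm`)
    all have length ``n_frames``; `a_cm >= b_cm > 0` is required and the
    trajectory must keep the body at least ``a_cm`` away from the arena
    edge.  ``noise_sd`` is the standard deviation of additive Gaussian
    intensity noise (frames only; the background page stays noise-free).
    """

    name: str
    a_cm: np.ndarray
    b_cm: np.ndarray
    heading_rad: np.ndarray
    x_cm: np.ndarray
    y_cm: np.ndarray
    arena_width_cm: float = DEFAULT_ARENA_CM
    arena_height_cm: float = DEFAULT_ARENA_CM
    width_px: int = DEFAULT_WIDTH_PX
    fps: float = DEFAULT_FPS
    tail: bool = True
    tail_length_cm: float = 3.0
    tail_width_cm: float = 0.4
    tail_bend_cm: float = 0.8
    background_level: float = 0.15
    body_level: float = 0.85
    grid: bool = True
    grid_level: float = 0.30
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for key in ("a_cm", "b_cm", "heading_rad", "x_cm", "y_cm"):
            object.__setattr__(self, key, np.asarray(getattr(self, key), dtype=float))
        n = len(self.a_cm)
        if any(len(getattr(self, k)) != n for k in ("b_cm", "heading_rad", "x_cm", "y_cm")):
            raise ValueError("per-frame schedules must share one length")
        if n == 0:
            raise ValueError("scenario needs at least one frame")
        if np.any(self.b_cm <= 0) or np.any(self.a_cm < self.b_cm):
            raise ValueError("need a_cm >= b_cm > 0 on every frame")
        if self.body_level <= self.background_level:
            raise ValueError("body must be brighter than the background")

    @property
    def n_frames(self) -> int:
        return len(self.a_cm)

    @property
    def cm_per_px(self) -> float:
        return self.arena_width_cm / self.width_px

    @property
    def height_px(self) -> int:
        return int(round(self.arena_height_cm / self.cm_per_px))


@dataclass(frozen=True)
class GroundTruth:
    """Analytic per-frame traces and the SAP labels they imply.

    ``eccentricity`` comes straight from the semi-axis schedule
    (``sqrt(1 - (b/a)^2)``); ``speed_cms`` is the frame-to-frame centroid
    displacement times fps (the same discrete definition the tracker
    uses); ``frame_flags``/``second_flags`` apply the full SAP gate
    (eccentricity threshold, speed veto, half-second bout filter,
    at-least-one-frame aggregation) to those analytic traces.
    """

    eccentricity: np.ndarray
    speed_cms: np.ndarray
    frame_flags: np.ndarray
    second_flags: np.ndarray
    params: DetectionParams


class RenderedScenario(NamedTuple):
    scenario: SynthScenario
    video: VideoSequence
    truth: GroundTruth


def _paint_background(s: SynthScenario) -> np.ndarray:
    h, w = s.height_px, s.width_px
    bg = np.full((h, w), s.background_level)
    if s.grid:
        # 16-square painted floor grid: lines at the quarter positions
        for frac in (0.25, 0.5, 0.75):
            r = int(round(frac * h))
            c = int(round(frac * w))
            bg[max(r - 1, 0) : r + 1, :] = s.grid_level
            bg[:, max(c - 1, 0) : c + 1] = s.grid_level
    return bg


def _body_mask(s: SynthScenario, i: int, yy: np.ndarray, xx: np.ndarray) -> np.ndarray:
    a, b = s.a_cm[i], s.b_cm[i]
    th = s.heading_rad[i]
    dx = xx - s.x_cm[i]
    dy = yy - s.y_cm[i]
    u = dx * np.cos(th) + dy * np.sin(th)
    v = -dx * np.sin(th) + dy * np.cos(th)
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def _tail_mask(s: SynthScenario, i: int, shape: tuple[int, int]) -> np.ndarray:
    """Quadratically bending, linearly tapering tail attached at the rear vertex."""
    mask = np.zeros(shape, dtype=bool)
    a = s.a_cm[i]
    th = s.heading_rad[i]
    scale = s.cm_per_px
    back = np.array([-np.cos(th), -np.sin(th)])
    perp = np.array([-np.sin(th), np.cos(th)])
    root = np.array([s.x_cm[i], s.y_cm[i]]) + (a - 0.1) * back
    n_steps = max(20, int(s.tail_length_cm / (0.25 * scale)))
    t = np.linspace(0.0, 1.0, n_steps)
    pts = root[None, :] + np.outer(t * s.tail_length_cm, back) + np.outer(s.tail_bend_cm * t**2, perp)
    half_w = 0.5 * (s.tail_width_cm * (1.0 - t) + 0.1 * t)  # taper root -> 0.05 cm tip
    h, w = shape
    for (px, py), hw in zip(pts, half_w):
        r_px = max(1, int(np.ceil(hw / scale)))
        cx = px / scale - 0.5
        cy = py / scale - 0.5
        r0 = max(0, int(np.floor(cy - r_px - 1)))
        r1 = min(h, int(np.ceil(cy + r_px + 2)))
        c0 = max(0, int(np.floor(cx - r_px - 1)))
        c1 = min(w, int(np.ceil(cx + r_px + 2)))
        if r0 >= r1 or c0 >= c1:
            continue
        sub_y = np.arange(r0, r1)[:, None] - cy
        sub_x = np.arange(c0, c1)[None, :] - cx
        mask[r0:r1, c0:c1] |= sub_y**2 + sub_x**2 <= (hw / scale) ** 2
    return mask


def _analytic_truth(s: SynthScenario, params: DetectionParams) -> GroundTruth:
    ecc = np.sqrt(1.0 - (s.b_cm / s.a_cm) ** 2)
    speed = np.zeros(s.n_frames)
    if s.n_frames > 1:
        speed[1:] = np.hypot(np.diff(s.x_cm), np.diff(s.y_cm)) * s.fps
    valid = np.ones(s.n_frames, dtype=bool)
    flags = gate_frames(ecc, speed, valid, params)
    return GroundTruth(
        eccentricity=ecc,
        speed_cms=speed,
        frame_flags=flags,
        second_flags=frames_to_seconds(flags, s.fps),
        params=params,
    )


def render_scenario(
    s: SynthScenario, params: Optional[DetectionParams] = None
) -> RenderedScenario:
    """Render a scenario into a video plus its analytic ground truth.

    ``params`` are the gating thresholds used to derive the ground-truth
    SAP labels (default: the open-field operating point at the scenario's
    fps).  Raises when the trajectory lets the body touch the arena edge.
    """
    if params is None:
        params = DetectionParams(fps=s.fps)
    margin = s.a_cm
    if (
        np.any(s.x_cm - margin < 0)
        or np.any(s.x_cm + margin > s.arena_width_cm)
        or np.any(s.y_cm - margin < 0)
        or np.any(s.y_cm + margin > s.arena_height_cm)
    ):
        raise ValueError("trajectory out of bounds: body would leave the arena")

    h, w = s.height_px, s.width_px
    scale = s.cm_per_px
    # physical coordinates of pixel centres
    xx = (np.arange(w) + 0.5)[None, :] * scale
    yy = (np.arange(h) + 0.5)[:, None] * scale
    background = _paint_background(s)
    rng = np.random.default_rng(s.seed)
    frames = np.empty((s.n_frames, h, w))
    for i in range(s.n_frames):
        frame = background.copy()
        animal = _body_mask(s, i, yy, xx)
        if s.tail:
            animal |= _tail_mask(s, i, (h, w))
        frame[animal] = s.body_level
        if s.noise_sd > 0:
            frame = frame + rng.normal(0.0, s.noise_sd, size=frame.shape)
        frames[i] = np.clip(frame, 0.0, 1.0)

    video = VideoSequence(
        frames=frames,
        background=background,
        fps=s.fps,
        arena_width_cm=s.arena_width_cm,
        arena_height_cm=s.arena_height_cm,
    )
    return RenderedScenario(scenario=s, video=video, truth=_analytic_truth(s, params))


def _const(val: float, n: int) -> np.ndarray:
    return np.full(n, float(val))


def _circle_path(
    center: tuple[float, float], radius_cm: float, speed_cms: float, fps: float, n: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Constant-speed circular trajectory; heading tangent to the path."""
    omega = speed_cms / radius_cm / fps  # radians per frame
    phi = omega * np.arange(n)
    x = center[0] + radius_cm * np.cos(phi)
    y = center[1] + radius_cm * np.sin(phi)
    heading = phi + np.pi / 2
    return x, y, heading


def _still(
    pos: tuple[float, float], heading: float, n: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    return _const(pos[0], n), _const(pos[1], n), _const(heading, n)


def standard_suite(seed: int = 0) -> list[RenderedScenario]:
    """Deterministic battery of scenarios covering every detection regime.

    1. still round body (no SAP),
    2. still elongated body (sustained SAP),
    3. fast elongated body circling at 20 cm/s (speed-vetoed),
    4. brief 0.3 s elongation (suppressed by the half-second bout filter),
    5. mixed schedule alternating the regimes second-by-second,
    6. tail-free twin of (2),
    7. noisy replicate of (5) at noise_sd 0.05.

    Geometry: 30 cm square arena, 10 fps, 200 px across.  ``seed`` offsets
    every scenario's noise seed, so two calls with the same seed are
    bit-identical.
    """
    fps = DEFAULT_FPS
    n5 = int(5 * fps)
    c = (15.0, 15.0)
    ar, br = ROUND_AXES_CM
    ae, be = ELONGATED_AXES_CM

    scenarios: list[SynthScenario] = []

    x, y, hd = _still(c, 0.4, n5)
    scenarios.append(
        SynthScenario("still_round", _const(ar, n5), _const(br, n5), hd, x, y, seed=seed * 101 + 1)
    )

    x, y, hd = _still(c, 0.9, n5)
    scenarios.append(
        SynthScenario("still_elongated", _const(ae, n5), _const(be, n5), hd, x, y, seed=seed * 101 + 2)
    )

    x, y, hd = _circle_path(c, 8.0, 20.0, fps, n5)
    scenarios.append(
        SynthScenario("fast_elongated", _const(ae, n5), _const(be, n5), hd, x, y, seed=seed * 101 + 3)
    )

    a = _const(ar, n5)
    b = _const(br, n5)
    brief = slice(int(2 * fps), int(2 * fps) + 3)  # 0.3 s at 10 fps
    a[brief], b[brief] = ae, be
    x, y, hd = _still(c, -0.7, n5)
    scenarios.append(SynthScenario("brief_elongation", a, b, hd, x, y, seed=seed * 101 + 4))

    # mixed: 3 s round-still, 3 s elongated-still, 3 s elongated-fast,
    # 3 s elongated-still again
    n3 = int(3 * fps)
    a = np.concatenate([_const(ar, n3), _const(ae, n3), _const(ae, n3), _const(ae, n3)])
    b = np.concatenate([_const(br, n3), _const(be, n3), _const(be, n3), _const(be, n3)])
    xs, ys, hs = _still(c, 0.2, n3)
    x2, y2, h2 = _still(c, 0.2, n3)
    x3, y3, h3 = _circle_path(c, 8.0, 20.0, fps, n3)
    x4, y4, h4 = _still((x3[-1], y3[-1]), h3[-1], n3)
    x = np.concatenate([xs, x2, x3, x4])
    y = np.concatenate([ys, y2, y3, y4])
    hd = np.concatenate([hs, h2, h3, h4])
    mixed = SynthScenario("mixed_regimes", a, b, hd, x, y, seed=seed * 101 + 5)
    scenarios.append(mixed)

    x, y, hd = _still(c, 0.9, n5)
    scenarios.append(
        SynthScenario(
            "still_elongated_tailfree",
            _const(ae, n5),
            _const(be, n5),
            hd,
            x,
            y,
            tail=False,
            seed=seed * 101 + 2,
        )
    )

    scenarios.append(replace(mixed, name="mixed_regimes_noisy", noise_sd=0.05, seed=seed * 101 + 7))

    return [render_scenario(s) for s in scenarios]


def threshold_grid_scenario(
    seed: int = 0,
    ecc_levels: tuple = (0.855, 0.875, 0.895, 0.905, 0.915, 0.935),
    speed_levels_cms: tuple = (0.0, 6.0, 10.5, 11.5, 12.5, 16.0),
    fps: float = DEFAULT_FPS,
) -> SynthScenario:
    """Scenario cycling through every (eccentricity, speed) combination.

    One second per combination, in a seed-shuffled order, with eccentricity
    levels straddling the 0.90 operating threshold and speed levels
    straddling the 12 cm/s veto.  Used to test that scanning an MCC
    surface against ground truth labelled at (0.90, 12 cm/s) recovers
    those thresholds.  The animal walks with per-second speeds along a
    heading that reflects off a safety margin inside the arena walls.
    """
    rng = np.random.default_rng(seed)
    combos = [(e, v) for e in ecc_levels for v in speed_levels_cms]
    rng.shuffle(combos)
    spf = int(fps)
    n = len(combos) * spf
    a = np.empty(n)
    b = np.empty(n)
    x = np.empty(n)
    y = np.empty(n)
    heading = np.empty(n)
    a_body = ELONGATED_AXES_CM[0]
    # generous safety margin: one frame-step at the fastest level is 1.6 cm
    margin = a_body + 2.0
    lo, hi = margin, DEFAULT_ARENA_CM - margin
    px, py = 15.0, 15.0
    ang = rng.uniform(0, 2 * np.pi)
    k = 0
    for e, v in combos:
        step = v / fps
        for _ in range(spf):
            a[k] = a_body
            b[k] = a_body * np.sqrt(1.0 - e**2)
            x[k], y[k] = px, py
            heading[k] = ang
            nx = px + step * np.cos(ang)
            ny = py + step * np.sin(ang)
            # reflect off the walls' safety margin
            if nx < lo or nx > hi:
                ang = np.pi - ang
                nx = px + step * np.cos(ang)
            if ny < lo or ny > hi:
                ang = -ang
                ny = py + step * np.sin(ang)
            px, py = nx, ny
            k += 1
        # small random turn between blocks keeps the path well inside
        ang += rng.uniform(-0.5, 0.5)
    return SynthScenario(
        f"threshold_grid_{seed}", a, b, heading, x, y, fps=fps, seed=seed * 101 + 11
    )
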