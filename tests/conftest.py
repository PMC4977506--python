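import numpy as np
import pytest

import sapdetect as sd


@pytest.fixture(scope="session")
def suite():
    """Rendered deterministic synthetic scenario battery (seed 0)."""
    return sd.standard_suite(0)


@pytest.fixture(scope="session")
def suite_detections(suite):
    """name -> (rendered, track, trace) running the full detector on the suite."""
    out = {}
    for rendered in suite:
        radius = sd.morph_radius_px_from_cm(rendered.video.cm_per_px)
        track = sd.track_frames(rendered.video, sd.MorphParams(0.3, radius))
        trace = sd.detect_sap(track, sd.DetectionParams(fps=rendered.scenario.fps))
        out[rendered.scenario.name] = (rendered, track, trace)
    return out


def render_filled_ellipse(a_px, b_px, theta_rad=0.0, pad=6):
    """Boolean raster of a filled ellipse with semi-axes a_px >= b_px.

    Pixel (r, c) is set when its centre lies inside the ellipse centred in
    the image and rotated by theta (x = columns, y = rows, y down).
    """
    half = int(np.ceil(max(a_px, b_px))) + pad
    n = 2 * half + 1
    yy, xx = np.mgrid[0:n, 0:n]
    dx = xx - half
    dy = yy - half
    u = dx * np.cos(theta_rad) + dy * np.sin(theta_rad)
    v = -dx * np.sin(theta_rad) + dy * np.cos(theta_rad)
    return (u / a_px) ** 2 + (v / b_px) ** 2 <= 1.0
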