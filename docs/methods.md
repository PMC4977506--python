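# Methods

## Detection model

A stretch-attend posture (SAP) is operationalised per frame by two
measurements of the segmented body silhouette:

- **Elongation** — eccentricity `e = √(1 − λ₂/λ₁)` of the ellipse sharing
  the silhouette's second central moments. Coordinate covariances carry a
  +1/12 correction on both diagonal terms because each pixel is a unit
  square rather than a point mass; axis lengths are `4·√λ`, so a rendered
  filled ellipse recovers its generating semi-axes. This is the standard
  region-properties ellipse; a verbal construction via "the longest chord"
  would be noisier and is not used.
- **Speed** — Euclidean centroid displacement between consecutive valid
  frames × `cm_per_px` × fps, assigned to the later frame. The first valid
  frame, and the first frame after a detection gap, get speed 0: a still
  animal that reappears should not be speed-vetoed.

A frame is SAP-positive iff the animal was found, `e >` the eccentricity
threshold, and speed is **not** `>` the speed threshold (both comparators
strict). Runs of positive frames of length ≤ `round(fps/2)` are then
zeroed — SAP is assumed never to last half a second or less — and a second
is SAP-positive when at least one of its frames is. A trailing partial
second is aggregated by the same rule. `round()` is Python's (banker's)
rounding; it only differs at odd frame rates (e.g. fps 25 → 12 frames).

Per-video totals: duration = positive frames / fps (the canonical,
frame-based definition; the per-second tables allow the second-based
variant), percentage of video length, bout count (maximal frame-level
runs — frame resolution deliberately, so brief interruptions split bouts),
and bouts per minute.

### Default parameters

| parameter | default | units | rationale |
|---|---|---|---|
| `ecc_threshold` | 0.90 (OF), 0.89 (EPM) | — | established operating points for 32–40 g male Swiss mice; EPM lowered because mice bend into open arms, shortening the ellipse |
| `speed_threshold_cms` | 12 (OF), 8 (EPM) | cm/s | running veto; lower in the EPM's 5 cm-wide arms where momentum is limited |
| `morph_radius_cm` | 0.25 | cm | opening disk radius: twice it (0.5 cm) exceeds a mouse tail's width but not the body's (~1.5 cm), converted to pixels via `cm_per_px`, floor 1 px |
| `binary_threshold` | user-set | — | contrast-dependent; choose with the threshold sweep (`preview`) so the foreground fraction ≈ body area / arena area |
| confidence level | 0.95 | — | Wald intervals; 0.99 available (`level=`) |

Other fixed choices: connectivity is 8-connected; equal-size component
ties resolve to the component whose first pixel in row-major order is
smallest (reproducibility); frames with no foreground are flagged invalid,
score non-SAP, and break bout runs rather than aborting a batch; intensity
is normalised to [0, 1] by the source dtype's maximum, so thresholds are
dimensionless; calibration uses the arena width only, with a 2 %
horizontal/vertical consistency check (videos must be cropped 1:1).

## Evaluation statistics

Consensus is a strict majority per second; with an even rater count an
exact tie resolves to 0 (conservative about calling SAP). Metrics follow
the usual 2×2 definitions; Wald intervals are `p ± z·√(p(1−p)/n)` clamped
to [0, 1], appropriate for the n > 30, non-extreme proportions arising
here. MCC returns 0 when a margin is degenerate (undefined correlation
treated as none); the F-score warns and returns 0 when no positives are
predicted. AUC is the plain trapezoidal sum over (fpr, tpr) points sorted
by fpr with (0,0) and (1,1) anchors. The threshold scan re-runs the *full*
gate (including the bout filter and second aggregation) at every grid
pair, so the MCC surface reflects exactly what the detector would have
done; argmax ties break towards higher thresholds (prefer specificity).
ICC is the two-way random-effects, absolute-agreement, average-measures
form (McGraw–Wong A,k):

    ICC(A,k) = (MSR − MSE) / (MSR + (MSC − MSE)/n)

with MSR/MSC/MSE the subject, rater and residual mean squares and n the
number of subjects. Binary rater scores are treated as numeric, as is
conventional when panels are analysed with a continuous-model ICC.

## Synthetic data

The generator renders what the detector assumes: a bright filled body
ellipse (per-frame semi-axes, heading, centroid schedules) with a
quadratically bending, linearly tapering tail attached at the rear vertex,
on a dark arena with an optional painted quarter-grid, additive seeded
Gaussian noise clamped to [0, 1], and a noise-free background as the last
TIFF page. Defaults: 30 cm square arena, 10 fps, 200 px across
(0.15 cm/px — typical for a cropped behavioural recording), body
2.4 × 0.75 cm elongated (eccentricity 0.950) or 1.5 cm round, tail 3 cm ×
0.4 cm root, intensities 0.85 body / 0.15 floor / 0.30 grid, noise sd 0.05
in the noisy replicate. Ground-truth labels are computed **from the
schedules** (analytic eccentricity, chord speeds, then the same gating
code), never from rendered pixels.

The standard suite covers each regime the gate distinguishes — still
round, still elongated, fast elongated, sub-half-second elongation, a
mixed schedule, tailed/tail-free twins, and a noisy replicate — and the
threshold-grid scenario cycles one second per (eccentricity, speed)
combination with levels straddling the operating point, shuffled per seed,
with a reflecting walk keeping the body inside the arena.

What the synthetic scenes do *not* model: fur texture, shadows and
reflections, motion blur, lens distortion, occlusion by plus-maze walls,
rearing (which shortens the apparent body), or multiple animals. Passing
tests therefore demonstrate the correctness of the pipeline's geometry,
gating and statistics under the stated imaging assumptions — not
performance on arbitrary real footage, where threshold choice and video
preparation dominate.

## Numerical and design notes

- Background subtraction clamps at zero before thresholding; with a
  bright-on-dark (or inverted) scene, negative residuals are noise.
- The eccentricity-recovery tolerance (±0.02 for rendered ellipses with
  semi-axes ≥ 20 px) applies to meaningful elongations (b/a ≤ 0.95): near
  b = a the map `√(1 − (b/a)²)` amplifies sub-pixel axis differences
  beyond what any raster can resolve, so the bound is ill-posed there.
- Problem sizes in tests and the acceptance script (5–12 s clips at
  200 px, 72 scanned seconds per threshold-recovery video, 3000-subject
  ICC panels) were chosen as the smallest sizes at which the measured
  quantities are stable to well within their tolerances.
- The interactive threshold previewer is realised headlessly as a
  deterministic sweep of foreground fractions; batch outputs are CSV and
  PNG only, pure functions of (inputs, config), so re-runs are
  byte-identical.
- Known limitations: single-animal assumption; no protected/unprotected
  SAP zoning or object-directed (forward) SAP; thresholds are
  strain/weight-specific and should be re-optimized (`optimize`) for other
  animals.
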